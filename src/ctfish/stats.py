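"""Population-level summaries of pairing, volume and association data.

Implements the published analysis conventions:

* per-chromosome pairing tables count nuclei with one signal (paired) vs
  two signals (unpaired); stage means and SDs are unweighted across the
  20 classifiable chromosomes (autosomes 1–19 plus X) with the sample
  (n−1) standard deviation;
* Pearson correlations between chromosome features and paired
  percentages use a two-sided t-based p-value with df = n−2;
* the NOR comparison is a pooled-variance two-sample Student t-test
  (Welch available as an option);
* heterologous association rates get Wald 95% confidence intervals,
  switching to the Wilson score interval whenever no association was
  observed, and a pair is flagged significant when its whole interval
  lies above or below the overall weighted mean association rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .types import (
    CLASSIFIABLE_CHROMOSOMES,
    CTFishError,
    NOR_CHROMOSOMES,
    PAIRED,
    STAGE_I,
    STAGE_II,
    UNPAIRED,
)

FEATURE_COLUMNS = ("size_mb", "gc_percent", "gene_density")

ABOVE_MEAN = "above_mean"
BELOW_MEAN = "below_mean"
NOT_SIGNIFICANT = "ns"


class StatsError(CTFishError):
    pass


def _chromosome_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


# ---------------------------------------------------------------------------
# pairing tables
# ---------------------------------------------------------------------------

def build_pairing_table(calls) -> pd.DataFrame:
    """Aggregate pairing calls into per-stage, per-chromosome signal counts.

    Paired verdicts count as one-signal nuclei, unpaired as two-signal;
    uncallable calls are dropped from the totals.  ``pct_one_signal`` is
    null where a (stage, chromosome) cell has no callable nucleus.
    """
    rows = []
    for call in calls:
        if call.stage is None:
            raise StatsError(f"call for {call.chromosome_id} in {call.nucleus_id} has no stage")
        if call.verdict in (PAIRED, UNPAIRED):
            rows.append((call.stage, call.chromosome_id, call.verdict))
    if not rows:
        return pd.DataFrame(columns=["stage", "chromosome", "n_two_signal",
                                     "n_one_signal", "total", "pct_one_signal"])
    df = pd.DataFrame(rows, columns=["stage", "chromosome", "verdict"])
    table = (
        df.groupby(["stage", "chromosome"])["verdict"]
        .agg(n_one_signal=lambda v: int((v == PAIRED).sum()),
             n_two_signal=lambda v: int((v == UNPAIRED).sum()))
        .reset_index()
    )
    return _finish_pairing_table(table)


def pairing_table_from_fixture(fixture: pd.DataFrame) -> pd.DataFrame:
    """Convert the packaged pairing-count table to the working table shape."""
    table = fixture[["stage", "chromosome", "n_two_signal", "n_one_signal"]].copy()
    return _finish_pairing_table(table)


def _finish_pairing_table(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["total"] = table["n_one_signal"] + table["n_two_signal"]
    with np.errstate(invalid="ignore"):
        table["pct_one_signal"] = np.where(
            table["total"] > 0, 100.0 * table["n_one_signal"] / table["total"], np.nan)
    table = table.sort_values(
        ["stage", "chromosome"],
        key=lambda col: col.map(_chromosome_sort_key) if col.name == "chromosome" else col,
    ).reset_index(drop=True)
    return table[["stage", "chromosome", "n_two_signal", "n_one_signal",
                  "total", "pct_one_signal"]]


@dataclass
class StageSummary:
    stage: str
    mean_paired_pct: float
    sd_paired_pct: float
    n_chromosomes: int


def _stage_percentages(table: pd.DataFrame, stage: str) -> pd.Series:
    sub = table[(table["stage"] == stage)
                & table["chromosome"].isin(CLASSIFIABLE_CHROMOSOMES)]
    missing = set(CLASSIFIABLE_CHROMOSOMES) - set(sub["chromosome"])
    if missing:
        raise StatsError(
            f"stage {stage!r} is missing chromosomes {sorted(missing, key=_chromosome_sort_key)}"
        )
    sub = sub.set_index("chromosome").loc[list(CLASSIFIABLE_CHROMOSOMES)]
    if sub["pct_one_signal"].isna().any():
        bad = sub.index[sub["pct_one_signal"].isna()].tolist()
        raise StatsError(f"stage {stage!r}: no callable nuclei for chromosomes {bad}")
    return sub["pct_one_signal"]


def stage_summary(table: pd.DataFrame, stage: str) -> StageSummary:
    """Unweighted mean and sample SD of the 20 per-chromosome paired percentages."""
    pcts = _stage_percentages(table, stage)
    return StageSummary(stage=stage,
                        mean_paired_pct=float(pcts.mean()),
                        sd_paired_pct=float(pcts.std(ddof=1)),
                        n_chromosomes=len(pcts))


# ---------------------------------------------------------------------------
# chromosome-feature analyses
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    feature: str
    stage: str
    r: float
    p: float
    n: int


def feature_correlation(table: pd.DataFrame, features: pd.DataFrame, stage: str,
                        feature_name: str) -> CorrelationResult:
    """Pearson correlation of a chromosome feature with paired percentages.

    Only meaningful at the two early stages, where unpaired chromosomes
    exist; the p-value is two-sided from t = r·√(n−2)/√(1−r²).
    """
    if stage not in (STAGE_I, STAGE_II):
        raise StatsError("correlations are defined only for the two early stages")
    if feature_name not in FEATURE_COLUMNS:
        raise StatsError(f"unknown feature {feature_name!r}; expected one of {FEATURE_COLUMNS}")
    pcts = _stage_percentages(table, stage)
    feat = features.set_index("chromosome").loc[list(CLASSIFIABLE_CHROMOSOMES), feature_name]
    x = feat.to_numpy(dtype=float)
    y = pcts.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined: zero-variance input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(feature=feature_name, stage=stage,
                             r=float(r), p=float(p), n=len(x))


@dataclass
class NORComparison:
    stage: str
    t: float
    p: float
    mean_nor: float
    mean_non_nor: float
    n_nor: int
    n_non_nor: int


def nor_comparison(table: pd.DataFrame, features: pd.DataFrame, stage: str,
                   welch: bool = False) -> NORComparison:
    """Compare paired percentages of NOR-bearing vs other chromosomes.

    Two-sample two-sided t-test, pooled-variance Student by default.
    """
    pcts = _stage_percentages(table, stage)
    nor_flag = features.set_index("chromosome").loc[list(CLASSIFIABLE_CHROMOSOMES), "nor"]
    nor = pcts[nor_flag.to_numpy(dtype=bool)]
    non = pcts[~nor_flag.to_numpy(dtype=bool)]
    assert set(nor.index) == NOR_CHROMOSOMES
    if len(nor) < 2 or len(non) < 2:
        raise StatsError("each NOR group needs at least two chromosomes")
    t, p = sps.ttest_ind(nor, non, equal_var=not welch)
    return NORComparison(stage=stage, t=float(t), p=float(p),
                         mean_nor=float(nor.mean()), mean_non_nor=float(non.mean()),
                         n_nor=len(nor), n_non_nor=len(non))


# ---------------------------------------------------------------------------
# nuclear volume proportions
# ---------------------------------------------------------------------------

def nvp_table_from_records(records) -> pd.DataFrame:
    """Tidy per-signal NVP table: one row per record."""
    rows = [(r.stage, r.chromosome_id, r.signal_kind, r.nucleus_id, r.nvp_pct)
            for r in records]
    return pd.DataFrame(rows, columns=["stage", "chromosome", "signal_kind",
                                       "nucleus_id", "nvp_pct"])


def nvp_summary(records_or_table) -> pd.DataFrame:
    """Per-chromosome mean NVP by stage and signal kind."""
    table = (records_or_table if isinstance(records_or_table, pd.DataFrame)
             else nvp_table_from_records(records_or_table))
    out = (table.groupby(["stage", "chromosome", "signal_kind"])
           .agg(n_observations=("nvp_pct", "size"), nvp_pct=("nvp_pct", "mean"))
           .reset_index())
    return out.sort_values(
        ["stage", "signal_kind", "chromosome"],
        key=lambda c: c.map(_chromosome_sort_key) if c.name == "chromosome" else c,
    ).reset_index(drop=True)


def nvp_column_averages(per_chromosome: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean over the chromosome rows, per stage and signal kind."""
    return (per_chromosome.groupby(["stage", "signal_kind"])["nvp_pct"]
            .mean().reset_index(name="average_nvp_pct"))


# ---------------------------------------------------------------------------
# heterologous associations
# ---------------------------------------------------------------------------

def wald_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wald (asymptotic normal) confidence interval for a proportion."""
    return tuple(float(v) for v in proportion_confint(k, n, alpha=alpha, method="normal"))


def wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score confidence interval for a proportion (always within [0, 1])."""
    return tuple(float(v) for v in proportion_confint(k, n, alpha=alpha, method="wilson"))


@dataclass
class AssociationSummary:
    table: pd.DataFrame          # one row per chromosome pair
    weighted_mean: float         # Σk / Σn over all pairs
    mean_overlap_pct: float      # mean territory overlap across records


def association_summary(records, alpha: float = 0.05,
                        bonferroni: bool = False) -> AssociationSummary:
    """Summarize heterologous association records across a population.

    Per pair: association rate k/n with its 95% CI — Wald by default,
    Wilson whenever k = 0 — and a significance flag set when the whole
    interval lies above or below the overall weighted mean rate.
    ``bonferroni=True`` divides alpha by the number of pairs (an extension;
    no correction is applied by default).
    """
    per_pair: dict[tuple, dict] = {}
    overlaps: list[float] = []
    for rec in records:
        a, b = sorted((rec.chromosome_a, rec.chromosome_b), key=_chromosome_sort_key)
        pa, pb = ((rec.overlap_pct_a, rec.overlap_pct_b)
                  if (a, b) == (rec.chromosome_a, rec.chromosome_b)
                  else (rec.overlap_pct_b, rec.overlap_pct_a))
        entry = per_pair.setdefault((a, b), {"k": 0, "n": 0, "ov_a": [], "ov_b": []})
        entry["n"] += 1
        entry["k"] += int(rec.associated)
        entry["ov_a"].append(pa)
        entry["ov_b"].append(pb)
        overlaps.extend((pa, pb))
    if not per_pair:
        raise StatsError("no association records")
    total_k = sum(e["k"] for e in per_pair.values())
    total_n = sum(e["n"] for e in per_pair.values())
    weighted_mean = total_k / total_n
    eff_alpha = alpha / len(per_pair) if bonferroni else alpha
    rows = []
    for (a, b), e in sorted(per_pair.items(),
                            key=lambda kv: tuple(map(_chromosome_sort_key, kv[0]))):
        k, n = e["k"], e["n"]
        p_hat = k / n
        method = "wilson" if k == 0 else "wald"
        lower, upper = (wilson_ci if method == "wilson" else wald_ci)(k, n, alpha=eff_alpha)
        if lower > weighted_mean:
            flag = ABOVE_MEAN
        elif upper < weighted_mean:
            flag = BELOW_MEAN
        else:
            flag = NOT_SIGNIFICANT
        rows.append((a, b, k, n, p_hat, method, lower, upper, flag,
                     float(np.mean(e["ov_a"])), float(np.mean(e["ov_b"]))))
    table = pd.DataFrame(rows, columns=[
        "chromosome_a", "chromosome_b", "k_associated", "n_observed", "p_hat",
        "ci_method", "ci_lower", "ci_upper", "flag",
        "mean_overlap_pct_a", "mean_overlap_pct_b"])
    return AssociationSummary(table=table, weighted_mean=float(weighted_mean),
                              mean_overlap_pct=float(np.mean(overlaps)))
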