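"""Population statistics: tables, correlations, t-tests, CIs, flags."""

import math

import numpy as np
import pandas as pd
import pytest

from ctfish import stats as ctstats
from ctfish.io import load_fixture
from ctfish.stats import (
    ABOVE_MEAN,
    BELOW_MEAN,
    NOT_SIGNIFICANT,
    StatsError,
    association_summary,
    build_pairing_table,
    feature_correlation,
    nor_comparison,
    nvp_column_averages,
    nvp_summary,
    pairing_table_from_fixture,
    stage_summary,
    wald_ci,
    wilson_ci,
)
from ctfish.types import (
    AssociationRecord,
    NVPRecord,
    ONE_CHROMOSOME,
    PAIRED,
    PairingCall,
    STAGE_I,
    STAGE_II,
    TWO_CHROMOSOME,
    UNCALLABLE,
    UNPAIRED,
)


@pytest.fixture(scope="module")
def fixture_table():
    return pairing_table_from_fixture(load_fixture("pairing_counts"))


@pytest.fixture(scope="module")
def features():
    return load_fixture("features")


def call(chrom, verdict, nucleus="n1", stage=STAGE_I):
    n = {PAIRED: 1, UNPAIRED: 2, UNCALLABLE: 0}[verdict]
    return PairingCall(nucleus_id=nucleus, chromosome_id=chrom, verdict=verdict,
                       n_components=n, component_voxel_counts=(50,) * n, stage=stage)


# ---------------------------------------------------------------------------
# pairing tables
# ---------------------------------------------------------------------------

def test_build_pairing_table_counts_and_percentages():
    calls = ([call("1", PAIRED, f"n{i}") for i in range(3)]
             + [call("1", UNPAIRED, "n3")]
             + [call("1", UNCALLABLE, "n4")]          # dropped
             + [call("2", UNPAIRED, f"n{i}") for i in range(2)])
    table = build_pairing_table(calls)
    row1 = table[table.chromosome == "1"].iloc[0]
    assert (row1.n_one_signal, row1.n_two_signal, row1.total) == (3, 1, 4)
    assert row1.pct_one_signal == pytest.approx(75.0)
    row2 = table[table.chromosome == "2"].iloc[0]
    assert (row2.n_one_signal, row2.n_two_signal) == (0, 2)
    assert row2.pct_one_signal == pytest.approx(0.0)


def test_build_pairing_table_requires_stage():
    bad = PairingCall(nucleus_id="n1", chromosome_id="1", verdict=PAIRED,
                      n_components=1, component_voxel_counts=(9,), stage=None)
    with pytest.raises(StatsError, match="stage"):
        build_pairing_table([bad])


def test_empty_call_list_gives_empty_table():
    assert len(build_pairing_table([])) == 0


def test_fixture_table_round_trips_published_percentages(fixture_table):
    sub = fixture_table[(fixture_table.stage == STAGE_I)
                        & (fixture_table.chromosome == "19")].iloc[0]
    assert sub.pct_one_signal == pytest.approx(100 * 24 / 26, abs=5e-3)


# ---------------------------------------------------------------------------
# stage summaries
# ---------------------------------------------------------------------------

def test_stage_summaries_match_published_mean_and_sd(fixture_table):
    s1 = stage_summary(fixture_table, STAGE_I)
    s2 = stage_summary(fixture_table, STAGE_II)
    assert s1.n_chromosomes == s2.n_chromosomes == 20
    assert s1.mean_paired_pct == pytest.approx(73.83, abs=5e-3)
    assert s1.sd_paired_pct == pytest.approx(6.78, abs=5e-3)
    assert s2.mean_paired_pct == pytest.approx(84.60, abs=5e-3)
    assert s2.sd_paired_pct == pytest.approx(6.40, abs=5e-3)


def test_stage_summary_missing_chromosome_errors(fixture_table):
    truncated = fixture_table[fixture_table.chromosome != "7"]
    with pytest.raises(StatsError, match="missing"):
        stage_summary(truncated, STAGE_I)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def test_pearson_matches_covariance_oracle(fixture_table, features):
    res = feature_correlation(fixture_table, features, STAGE_I, "size_mb")
    sub = fixture_table[(fixture_table.stage == STAGE_I)
                        & fixture_table.chromosome.isin(features.chromosome)
                        & (fixture_table.chromosome != "Y")]
    merged = sub.merge(features, on="chromosome")
    x = merged["size_mb"].to_numpy(float)
    y = merged["pct_one_signal"].to_numpy(float)
    r_oracle = (np.mean((x - x.mean()) * (y - y.mean()))
                / (x.std(ddof=0) * y.std(ddof=0)))
    assert res.r == pytest.approx(r_oracle, abs=1e-12)
    assert res.n == 20
    # two-sided p from the t transform
    t = r_oracle * math.sqrt((res.n - 2) / (1 - r_oracle ** 2))
    from scipy.stats import t as tdist
    assert res.p == pytest.approx(2 * tdist.sf(abs(t), res.n - 2), abs=1e-12)


def test_perfectly_linear_data_has_r_one():
    table = pd.DataFrame({
        "stage": STAGE_I, "chromosome": list(ctstats.CLASSIFIABLE_CHROMOSOMES),
        "n_two_signal": 1, "n_one_signal": 1,
        "total": 2, "pct_one_signal": np.arange(20, dtype=float)})
    feats = pd.DataFrame({
        "chromosome": list(ctstats.CLASSIFIABLE_CHROMOSOMES),
        "size_mb": 2.0 * np.arange(20) + 7.0,
        "gc_percent": 40.0, "gene_density": 1000, "nor": False})
    res = feature_correlation(table, feats, STAGE_I, "size_mb")
    assert res.r == pytest.approx(1.0)
    assert res.p < 1e-12


def test_zero_variance_feature_errors(fixture_table, features):
    flat = features.copy()
    flat["gc_percent"] = 41.0
    with pytest.raises(StatsError, match="zero-variance"):
        feature_correlation(fixture_table, flat, STAGE_I, "gc_percent")


def test_correlation_only_defined_for_early_stages(fixture_table, features):
    with pytest.raises(StatsError):
        feature_correlation(fixture_table, features, "pachytene", "size_mb")


def test_unknown_feature_errors(fixture_table, features):
    with pytest.raises(StatsError, match="unknown feature"):
        feature_correlation(fixture_table, features, STAGE_I, "length_cm")


# ---------------------------------------------------------------------------
# NOR comparison
# ---------------------------------------------------------------------------

def test_nor_groups_have_published_sizes(fixture_table, features):
    res = nor_comparison(fixture_table, features, STAGE_I)
    assert (res.n_nor, res.n_non_nor) == (6, 14)


def test_identical_groups_give_t_zero_p_one(features):
    table = pd.DataFrame({
        "stage": STAGE_I, "chromosome": list(ctstats.CLASSIFIABLE_CHROMOSOMES),
        "n_two_signal": 1, "n_one_signal": 1, "total": 2,
        "pct_one_signal": np.tile([60.0, 80.0], 10)})
    # make both NOR and non-NOR groups contain the same two values
    table.loc[table.chromosome.isin(["11", "12", "15"]), "pct_one_signal"] = 60.0
    table.loc[table.chromosome.isin(["16", "18", "19"]), "pct_one_signal"] = 80.0
    nor_mean = table[table.chromosome.isin(["11", "12", "15", "16", "18", "19"])][
        "pct_one_signal"].mean()
    rest = ~table.chromosome.isin(["11", "12", "15", "16", "18", "19"])
    table.loc[rest, "pct_one_signal"] = np.tile([60.0, 80.0], 7)
    res = nor_comparison(table, features, STAGE_I)
    assert res.mean_nor == pytest.approx(nor_mean)
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_welch_option_changes_dof_not_direction(fixture_table, features):
    student = nor_comparison(fixture_table, features, STAGE_I)
    welch = nor_comparison(fixture_table, features, STAGE_I, welch=True)
    assert np.sign(student.t) == np.sign(welch.t)
    assert student.p != welch.p


# ---------------------------------------------------------------------------
# NVP summaries
# ---------------------------------------------------------------------------

def nvp_record(chrom, kind, pct, nucleus="n1", stage=STAGE_I):
    return NVPRecord(nucleus_id=nucleus, chromosome_id=chrom, signal_kind=kind,
                     nvp_pct=pct, signal_voxels=100, nucleus_voxels=10000, stage=stage)


def test_nvp_summary_means_per_chromosome():
    records = [nvp_record("1", TWO_CHROMOSOME, 2.0),
               nvp_record("1", TWO_CHROMOSOME, 4.0, "n2"),
               nvp_record("2", ONE_CHROMOSOME, 1.0)]
    summary = nvp_summary(records)
    row = summary[(summary.chromosome == "1")
                  & (summary.signal_kind == TWO_CHROMOSOME)].iloc[0]
    assert row.nvp_pct == pytest.approx(3.0)
    assert row.n_observations == 2


def test_nvp_column_averages_are_unweighted():
    per_chrom = pd.DataFrame({
        "stage": STAGE_I, "chromosome": ["1", "2", "3"],
        "signal_kind": ONE_CHROMOSOME, "n_observations": [100, 1, 1],
        "nvp_pct": [3.0, 1.0, 2.0]})
    avg = nvp_column_averages(per_chrom)
    assert avg.average_nvp_pct.iloc[0] == pytest.approx(2.0)  # not pulled to 3.0


def test_fixture_nvp_column_averages_match_published():
    nvp = load_fixture("nvp").rename(columns={"n_observations": "n"})
    avg = nvp_column_averages(nvp).set_index(["stage", "signal_kind"])
    assert avg.loc[(STAGE_I, ONE_CHROMOSOME), "average_nvp_pct"] == pytest.approx(1.11, abs=5e-3)
    assert avg.loc[(STAGE_II, TWO_CHROMOSOME), "average_nvp_pct"] == pytest.approx(2.37, abs=5e-3)


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def test_wald_ci_matches_closed_form():
    lower, upper = wald_ci(20, 50)
    p_hat = 0.4
    half = 1.959963984540054 * math.sqrt(p_hat * (1 - p_hat) / 50)
    assert lower == pytest.approx(p_hat - half, abs=1e-12)
    assert upper == pytest.approx(p_hat + half, abs=1e-12)
    assert (round(lower, 3), round(upper, 3)) == (0.264, 0.536)


def test_wilson_ci_zero_count_example():
    lower, upper = wilson_ci(0, 35)
    assert lower == 0.0
    z = 1.959963984540054
    assert upper == pytest.approx(z * z / (35 + z * z), abs=1e-9)
    assert upper == pytest.approx(0.0989, abs=5e-5)


@pytest.mark.parametrize("n", [1, 5, 35, 200])
def test_wilson_ci_always_within_unit_interval_at_zero_count(n):
    lower, upper = wilson_ci(0, n)
    assert 0.0 <= lower <= upper <= 1.0


def test_wald_ci_degenerates_at_zero_count():
    # motivates the Wilson switch: at k=0 the Wald interval has zero width
    lower, upper = wald_ci(0, 50)
    assert lower == upper == 0.0
    _, wilson_upper = wilson_ci(0, 50)
    assert wilson_upper > 0.0


# ---------------------------------------------------------------------------
# association summaries
# ---------------------------------------------------------------------------

def assoc(a, b, associated, nucleus, pct=5.0):
    return AssociationRecord(nucleus_id=nucleus, chromosome_a=a, chromosome_b=b,
                             associated=associated,
                             shared_voxels=10 if associated else 0,
                             overlap_pct_a=pct if associated else 0.0,
                             overlap_pct_b=pct / 2 if associated else 0.0,
                             stage=STAGE_I)


def build_records(spec):
    """spec: {(a, b): (k, n)} → one record per observation."""
    records = []
    for (a, b), (k, n) in spec.items():
        for i in range(n):
            records.append(assoc(a, b, i < k, f"n{i}"))
    return records


def test_association_summary_counts_and_weighted_mean():
    records = build_records({("1", "2"): (30, 40), ("1", "3"): (2, 40),
                             ("2", "3"): (8, 40)})
    summary = association_summary(records)
    assert summary.weighted_mean == pytest.approx(40 / 120)
    table = summary.table.set_index(["chromosome_a", "chromosome_b"])
    assert table.loc[("1", "2"), "k_associated"] == 30
    assert table.loc[("1", "2"), "p_hat"] == pytest.approx(0.75)


def test_flags_partition_above_below_ns():
    records = build_records({("1", "2"): (38, 40),   # clearly above
                             ("1", "3"): (0, 40),    # clearly below, k=0
                             ("2", "3"): (14, 40)})  # near the mean
    summary = association_summary(records)
    table = summary.table.set_index(["chromosome_a", "chromosome_b"])
    assert table.loc[("1", "2"), "flag"] == ABOVE_MEAN
    assert table.loc[("1", "3"), "flag"] == BELOW_MEAN
    assert table.loc[("2", "3"), "flag"] == NOT_SIGNIFICANT


def test_wilson_used_exactly_when_no_association_observed():
    records = build_records({("1", "2"): (0, 30), ("1", "3"): (1, 30)})
    table = association_summary(records).table.set_index(
        ["chromosome_a", "chromosome_b"])
    assert table.loc[("1", "2"), "ci_method"] == "wilson"
    assert table.loc[("1", "3"), "ci_method"] == "wald"


def test_pair_order_is_canonical():
    records = [assoc("5", "2", True, "n0"), assoc("2", "5", True, "n1")]
    table = association_summary(records).table
    assert len(table) == 1
    assert (table.chromosome_a.iloc[0], table.chromosome_b.iloc[0]) == ("2", "5")
    assert table.n_observed.iloc[0] == 2


def test_bonferroni_widens_intervals():
    records = build_records({("1", "2"): (10, 40), ("1", "3"): (12, 40),
                             ("2", "3"): (9, 40)})
    plain = association_summary(records).table
    corrected = association_summary(records, bonferroni=True).table
    width_plain = (plain.ci_upper - plain.ci_lower).to_numpy()
    width_corr = (corrected.ci_upper - corrected.ci_lower).to_numpy()
    assert (width_corr > width_plain).all()


def test_mean_overlap_percentages_reported():
    records = [assoc("1", "2", True, "n0", pct=10.0),
               assoc("1", "2", True, "n1", pct=20.0)]
    summary = association_summary(records)
    row = summary.table.iloc[0]
    assert row.mean_overlap_pct_a == pytest.approx(15.0)
    assert row.mean_overlap_pct_b == pytest.approx(7.5)


def test_no_records_errors():
    with pytest.raises(StatsError):
        association_summary([])
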