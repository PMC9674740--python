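"""Image and table I/O.

Stacks are written as multi-page TIFF, one file per nucleus per round with
the channel axis first (``(channel, z, y, x)``), accompanied by a JSON
sidecar holding the voxel spacing, stage label and channel → chromosome
mapping.  Masks are 8-bit TIFFs (0/255).  The in-package reference tables
(chromosome features, per-stage pairing counts, nuclear volume proportions)
ship as CSV and are validated on load.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import (
    ALL_CHROMOSOMES,
    ALL_STAGE_LABELS,
    CTFishError,
    NOR_CHROMOSOMES,
    NucleusRecord,
    STAGES,
    VoxelStack,
)


class FixtureError(CTFishError):
    """A packaged reference table failed validation."""


class ImageIOError(CTFishError):
    """A stack or sidecar on disk is inconsistent."""


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "features": "chromosome_features.csv",
    "pairing_counts": "pairing_counts.csv",
    "nvp": "nuclear_volume_proportion.csv",
}


def _read_packaged_csv(filename: str) -> pd.DataFrame:
    ref = resources.files("ctfish").joinpath("data", filename)
    with ref.open("r") as handle:
        return pd.read_csv(handle, dtype={"chromosome": str})


def load_fixture(table_name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables, validated.

    Parameters
    ----------
    table_name:
        ``"features"`` (chromosome size in Mb, %GC, gene count, NOR flag),
        ``"pairing_counts"`` (per-stage one-signal/two-signal nucleus counts)
        or ``"nvp"`` (per-chromosome nuclear volume proportions by signal
        kind).
    """
    if table_name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {table_name!r}; expected one of {sorted(_FIXTURE_FILES)}")
    df = _read_packaged_csv(_FIXTURE_FILES[table_name])
    validator = {
        "features": _validate_features,
        "pairing_counts": _validate_pairing_counts,
        "nvp": _validate_nvp,
    }[table_name]
    validator(df)
    return df


def _validate_features(df: pd.DataFrame) -> None:
    if list(df["chromosome"]) != list(ALL_CHROMOSOMES):
        raise FixtureError("features table must hold exactly chromosomes 1-19, X, Y in order")
    if not (df["size_mb"] > 0).all():
        raise FixtureError("chromosome sizes must be positive")
    if not df["gc_percent"].between(0, 100, inclusive="neither").all():
        raise FixtureError("%GC out of range")
    nor = set(df.loc[df["nor"], "chromosome"])
    if nor != set(NOR_CHROMOSOMES):
        raise FixtureError(f"NOR chromosomes {sorted(nor)} != expected {sorted(NOR_CHROMOSOMES)}")


def _validate_pairing_counts(df: pd.DataFrame) -> None:
    expected_rows = len(ALL_CHROMOSOMES) * len(STAGES)
    if len(df) != expected_rows:
        raise FixtureError(f"pairing counts: expected {expected_rows} rows, found {len(df)}")
    if set(df["stage"]) != set(STAGES):
        raise FixtureError("pairing counts: unexpected stage labels")
    if (df["n_two_signal"] < 0).any() or (df["n_one_signal"] < 0).any():
        raise FixtureError("pairing counts: negative counts")
    # printed percentages must agree with the counts where present
    has_pct = df["pct_one_signal"].notna()
    if df.loc[~has_pct, "chromosome"].ne("Y").any():
        raise FixtureError("pairing counts: only the single-copy Y row may omit percentages")
    sub = df.loc[has_pct]
    total = sub["n_two_signal"] + sub["n_one_signal"]
    recomputed = (100 * sub["n_one_signal"] / total).round(2)
    bad = (recomputed - sub["pct_one_signal"]).abs() > 0.005
    if bad.any():
        rows = sub.loc[bad, ["chromosome", "stage"]].to_records(index=False)
        raise FixtureError(f"pairing counts: printed percentage disagrees with counts at {list(rows)}")


def _validate_nvp(df: pd.DataFrame) -> None:
    if set(df["signal_kind"]) != {"one_chromosome", "two_chromosome"}:
        raise FixtureError("NVP table: unexpected signal kinds")
    if not df["nvp_pct"].between(0, 100, inclusive="right").all():
        raise FixtureError("NVP table: percentages out of (0, 100]")
    for (stage, kind), group in df.groupby(["stage", "signal_kind"]):
        if list(group["chromosome"]) != list(ALL_CHROMOSOMES):
            raise FixtureError(f"NVP table: chromosome set wrong for {stage}/{kind}")


# ---------------------------------------------------------------------------
# stacks and masks on disk
# ---------------------------------------------------------------------------

def _round_tiff_name(nucleus_id: str, round_id: int) -> str:
    return f"{nucleus_id}_round{round_id}.tif"


def write_nucleus(record: NucleusRecord, out_dir: str | Path) -> Path:
    """Write one nucleus (all rounds) as TIFF stacks plus a JSON sidecar.

    Returns the sidecar path.  Ground truth, if attached, is not written
    here; see :func:`ctfish.synthetic.write_ground_truth`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "nucleus_id": record.nucleus_id,
        "stage": record.stage,
        "voxel_spacing_um": list(next(iter(record.stacks.values())).voxel_spacing_um),
        "rounds": {},
    }
    for rid in sorted(record.stacks):
        stack = record.stacks[rid]
        fluors = sorted(stack.intensities)
        data = np.stack([stack.intensities[f] for f in fluors]).astype(np.float32)
        fname = _round_tiff_name(record.nucleus_id, rid)
        tifffile.imwrite(out_dir / fname, data)
        meta["rounds"][str(rid)] = {
            "file": fname,
            "channels": [{"fluorochrome": f, "chromosome": stack.channel_map[f]} for f in fluors],
        }
    sidecar = out_dir / f"{record.nucleus_id}.json"
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_nucleus(sidecar: str | Path) -> NucleusRecord:
    """Read a nucleus written by :func:`write_nucleus` from its sidecar path."""
    sidecar = Path(sidecar)
    try:
        meta = json.loads(sidecar.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ImageIOError(f"cannot read sidecar {sidecar}: {exc}") from exc
    stage = meta.get("stage")
    if stage not in ALL_STAGE_LABELS:
        raise ImageIOError(f"{sidecar}: unknown stage label {stage!r}")
    spacing = tuple(meta["voxel_spacing_um"])
    stacks: dict[int, VoxelStack] = {}
    for rid_str, round_meta in meta["rounds"].items():
        path = sidecar.parent / round_meta["file"]
        if not path.exists():
            raise ImageIOError(f"{sidecar}: missing stack file {path}")
        data = tifffile.imread(path)
        if data.ndim == 3:  # single channel stored without channel axis
            data = data[None]
        channels = round_meta["channels"]
        if data.shape[0] != len(channels):
            raise ImageIOError(
                f"{path}: sidecar names {len(channels)} channels but stack holds {data.shape[0]}"
            )
        intensities = {c["fluorochrome"]: np.asarray(data[i], dtype=np.float32)
                       for i, c in enumerate(channels)}
        channel_map = {c["fluorochrome"]: c["chromosome"] for c in channels}
        stacks[int(rid_str)] = VoxelStack(
            intensities=intensities,
            voxel_spacing_um=spacing,
            round_id=int(rid_str),
            channel_map=channel_map,
        )
    return NucleusRecord(nucleus_id=meta["nucleus_id"], stage=stage, stacks=stacks)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit (0/255) multi-page TIFF."""
    tifffile.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back to boolean."""
    return tifffile.imread(Path(path)) > 0
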