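"""Synthetic 3D-FISH nucleus generator with voxel-level ground truth.

Emulates the imaging situation of a chromosome-painting experiment: an
ellipsoidal nucleus sampled on an anisotropic confocal grid (z-step
0.17 µm), containing one irregular blob-shaped territory per chromosome
copy, imaged over several hybridization rounds of three fluorochromes
each, with Gaussian blur standing in for the point-spread function and
additive Gaussian noise.

The generator controls the quantities the downstream analysis is supposed
to recover:

* whether the two homologs of each chromosome image as one connected
  voxel group (*paired*) or as two territories separated by a background
  gap (*unpaired*), drawn per chromosome from a stage-specific
  probability;
* whether two heterologous territories in the same round share voxels
  (*associated*), forced with a configurable per-pair probability;
* the volume of paired versus unpaired signals (paired signals are grown
  to a configurable multiple, default 1.6×, of a single territory).

All randomness flows from the integer seed in the spec; no global state
is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json
import math

import numpy as np
from scipy import ndimage

from . import io as ctio
from .types import (
    ALL_CHROMOSOMES,
    ALL_STAGE_LABELS,
    CLASSIFIABLE_CHROMOSOMES,
    CTFishError,
    LYMPHOCYTE,
    NucleusRecord,
    PAIRED,
    STAGE_III,
    STAGE_IV,
    StagePreset,
    UNPAIRED,
    VoxelStack,
)

FLUOROCHROMES = ("deac", "fitc", "texasred")

#: Somatic baseline: mean fraction of homolog pairs imaging as one signal
#: in lymphocytes, used for the lymphocyte preset.
LYMPHOCYTE_PAIRED_FRACTION = 0.1947

SINGLE = "single"  # ground-truth state of the single-copy Y territory


class GenerationError(CTFishError):
    """The requested nucleus cannot be generated."""


@dataclass(frozen=True)
class ChannelSpec:
    round_id: int
    fluorochrome_id: str
    chromosome_id: str


@dataclass
class NucleusSpec:
    """Full recipe for one synthetic nucleus.

    ``semiaxes_um`` and ``voxel_spacing_um`` are ``(z, y, x)`` triples;
    ``territory_voxels`` is the target voxel count of a single-chromosome
    signal; a paired signal is grown to ``paired_volume_factor`` times
    that.  ``shape_irregularity`` in [0, 1] blends compact (0) and rough
    random-aggregation (1) blob growth.  ``min_gap_voxels`` is the
    background gap separating the two copies of an unpaired chromosome
    (Chebyshev distance ``min_gap_voxels + 1``), which keeps them
    non-adjacent under both 6- and 26-connectivity for any gap ≥ 1.

    The default ``territory_voxels`` puts a single territory at ~1.1% of
    the default nucleus volume, the typical single-signal nuclear volume
    proportion for this kind of data.  ``blur_sigma_um`` defaults to the
    diffraction-limited lateral PSF sigma of a 1.4-NA oil objective at
    ~500 nm emission (≈0.21·λ/NA).
    """

    channels: list[ChannelSpec]
    pairing_probability: dict[str, float]
    seed: int
    semiaxes_um: tuple[float, float, float] = (2.0, 3.0, 3.0)
    voxel_spacing_um: tuple[float, float, float] = (0.17, 0.1, 0.1)
    territory_voxels: int = 500
    paired_volume_factor: float = 1.6
    shape_irregularity: float = 0.5
    association_probability: "float | dict[frozenset, float]" = 0.4
    signal_amplitude: float = 200.0
    nucleoplasm_intensity: float = 40.0
    noise_sd: float = 8.0
    blur_sigma_um: float = 0.075
    min_gap_voxels: int = 3

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes_um) or len(self.semiaxes_um) != 3:
            raise ValueError(f"semiaxes must be 3 positive lengths, got {self.semiaxes_um}")
        if any(s <= 0 for s in self.voxel_spacing_um) or len(self.voxel_spacing_um) != 3:
            raise ValueError(f"spacing must be 3 positive lengths, got {self.voxel_spacing_um}")
        for chrom, p in self.pairing_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pairing probability for {chrom} is {p}, outside [0, 1]")
        for p in (self._assoc_values() or [0.0]):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"association probability {p} outside [0, 1]")
        if not 0.0 <= self.shape_irregularity <= 1.0:
            raise ValueError("shape_irregularity must be in [0, 1]")
        if self.territory_voxels < 1:
            raise ValueError("territory_voxels must be >= 1")
        if self.min_gap_voxels < 1:
            raise ValueError("min_gap_voxels must be >= 1")
        if self.noise_sd < 0 or self.blur_sigma_um < 0:
            raise ValueError("noise_sd and blur_sigma_um must be non-negative")
        if self.paired_volume_factor <= 0:
            raise ValueError("paired_volume_factor must be positive")
        for rid in {c.round_id for c in self.channels}:
            chroms = [c.chromosome_id for c in self.channels if c.round_id == rid]
            if len(chroms) != len(set(chroms)):
                raise ValueError(f"round {rid} paints a chromosome more than once")

    def association_for(self, a: str, b: str) -> float:
        if isinstance(self.association_probability, dict):
            return float(self.association_probability.get(frozenset((a, b)), 0.0))
        return float(self.association_probability)

    def _assoc_values(self):
        if isinstance(self.association_probability, dict):
            return list(self.association_probability.values())
        return [self.association_probability]


@dataclass
class GroundTruthChromosome:
    chromosome_id: str
    state: str  # paired | unpaired | single
    copies: list[np.ndarray]  # boolean masks, one per homolog copy

    def union(self) -> np.ndarray:
        out = self.copies[0].copy()
        for extra in self.copies[1:]:
            out |= extra
        return out


@dataclass
class GroundTruth:
    nucleus_mask: np.ndarray
    voxel_spacing_um: tuple[float, float, float]
    chromosomes: dict[str, GroundTruthChromosome]
    #: realized shared-voxel counts for every same-round heterologous pair
    associations: dict[frozenset, int] = field(default_factory=dict)

    def pairing_state(self, chromosome_id: str) -> str:
        return self.chromosomes[chromosome_id].state

    def shared_voxels(self, a: str, b: str) -> int:
        return self.associations[frozenset((a, b))]


# ---------------------------------------------------------------------------
# presets and channel plans
# ---------------------------------------------------------------------------

def stage_preset(stage_label: str, lymphocyte_p: float = LYMPHOCYTE_PAIRED_FRACTION) -> StagePreset:
    """Per-chromosome one-signal probabilities for a cell stage.

    For the two early meiotic intervals the probabilities are the observed
    one-signal fractions of the packaged pairing-count table; pachytene and
    round spermatids are fully paired (probability 1 everywhere); the
    lymphocyte preset applies a uniform somatic baseline (default 19.47%).
    """
    if stage_label not in ALL_STAGE_LABELS:
        raise KeyError(f"unknown stage label {stage_label!r}; expected one of {ALL_STAGE_LABELS}")
    if stage_label == LYMPHOCYTE:
        probs = {c: float(lymphocyte_p) for c in CLASSIFIABLE_CHROMOSOMES}
        return StagePreset(stage=stage_label, pairing_probability=probs)
    counts = ctio.load_fixture("pairing_counts")
    sub = counts[(counts["stage"] == stage_label) & (counts["chromosome"] != "Y")]
    probs = {
        row.chromosome: row.n_one_signal / (row.n_one_signal + row.n_two_signal)
        for row in sub.itertuples()
    }
    if stage_label in (STAGE_III, STAGE_IV):
        assert all(p == 1.0 for p in probs.values())
    return StagePreset(stage=stage_label, pairing_probability=probs)


def default_channel_plan(chromosomes=ALL_CHROMOSOMES) -> list[ChannelSpec]:
    """Group chromosomes three per hybridization round, cycling fluorochromes."""
    plan = []
    for i, chrom in enumerate(chromosomes):
        plan.append(ChannelSpec(round_id=i // 3 + 1,
                                fluorochrome_id=FLUOROCHROMES[i % 3],
                                chromosome_id=str(chrom)))
    return plan


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def ellipsoid_mask(semiaxes_um, spacing_um, pad: int = 2) -> np.ndarray:
    """Boolean ellipsoid on an anisotropic (z, y, x) grid with a background pad."""
    half = [int(math.ceil(a / s)) for a, s in zip(semiaxes_um, spacing_um)]
    shape = tuple(2 * h + 1 + 2 * pad for h in half)
    center = tuple(h + pad for h in half)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    val = sum(
        ((idx - c) * s / a) ** 2
        for idx, c, s, a in zip((zz, yy, xx), center, spacing_um, semiaxes_um)
    )
    return val <= 1.0


_NEI6 = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def _grow_blob(rng, allowed: np.ndarray, seed_vox: tuple, target: int,
               irregularity: float) -> np.ndarray:
    """Grow a 6-connected blob of ``target`` voxels by random aggregation.

    With probability ``irregularity`` each accretion step takes a uniformly
    random frontier voxel (rough, Eden-like growth); otherwise the oldest
    frontier voxel (breadth-first, compact growth).
    """
    shape = allowed.shape
    blob = np.zeros(shape, dtype=bool)
    if not allowed[seed_vox]:
        raise GenerationError(f"territory seed {seed_vox} falls outside its allowed region")
    blob[seed_vox] = True
    count = 1
    frontier: list[tuple] = []
    queued = np.zeros(shape, dtype=bool)

    def push(v):
        z, y, x = v
        for dz, dy, dx in _NEI6:
            n = (z + dz, y + dy, x + dx)
            if (0 <= n[0] < shape[0] and 0 <= n[1] < shape[1] and 0 <= n[2] < shape[2]
                    and allowed[n] and not blob[n] and not queued[n]):
                frontier.append(n)
                queued[n] = True

    push(seed_vox)
    while count < target:
        if not frontier:
            raise GenerationError(
                f"territory growth blocked at {count}/{target} voxels; nucleus too crowded"
            )
        i = int(rng.integers(len(frontier))) if rng.random() < irregularity else 0
        v = frontier.pop(i)
        blob[v] = True
        count += 1
        push(v)
    return blob


def _random_voxel(rng, mask: np.ndarray) -> tuple:
    flat = np.flatnonzero(mask)
    if flat.size == 0:
        raise GenerationError("no voxel available for territory placement")
    return tuple(int(c) for c in np.unravel_index(int(rng.choice(flat)), mask.shape))


def _grow_with_retries(rng, allowed: np.ndarray, seed_region: np.ndarray, target: int,
                       irregularity: float, attempts: int = 8) -> np.ndarray:
    """Grow a blob from a random seed, retrying if the seed sits in a pocket
    of ``allowed`` too small to hold the territory."""
    last: GenerationError | None = None
    for _ in range(attempts):
        seed = _random_voxel(rng, seed_region & allowed)
        try:
            return _grow_blob(rng, allowed, seed, target, irregularity)
        except GenerationError as exc:
            last = exc
    raise GenerationError(f"territory placement failed after {attempts} attempts: {last}")


# ---------------------------------------------------------------------------
# nucleus generation
# ---------------------------------------------------------------------------

def _signal_targets(spec: NucleusSpec, chrom: str, paired: bool) -> list[int]:
    """Target voxel counts per homolog copy for one chromosome."""
    if chrom == "Y":
        return [spec.territory_voxels]
    if paired:
        total = max(2, round(spec.paired_volume_factor * spec.territory_voxels))
        return [total - total // 2, total // 2]
    return [spec.territory_voxels, spec.territory_voxels]


def generate_nucleus(spec: NucleusSpec) -> tuple[dict[int, VoxelStack], GroundTruth]:
    """Render one synthetic nucleus: per-round stacks plus voxel ground truth.

    Deterministic for a fixed spec (including seed).  Raises
    :class:`GenerationError` when the requested territories cannot fit in
    the nucleus.
    """
    rng = np.random.default_rng(spec.seed)
    nucleus = ellipsoid_mask(spec.semiaxes_um, spec.voxel_spacing_um)
    nucleus_voxels = int(np.count_nonzero(nucleus))

    plan = sorted(spec.channels, key=lambda c: (c.round_id, c.fluorochrome_id))
    worst_per_round: dict[int, int] = {}
    for ch in plan:
        targets = _signal_targets(spec, ch.chromosome_id, paired=False)
        if max(_signal_targets(spec, ch.chromosome_id, paired=True) + targets) > nucleus_voxels:
            raise GenerationError(
                f"territory target for chromosome {ch.chromosome_id} exceeds the "
                f"nucleus volume of {nucleus_voxels} voxels"
            )
        worst_per_round[ch.round_id] = worst_per_round.get(ch.round_id, 0) + sum(targets)
    # territories of one hybridization round tile the nucleus without overlap
    # (associated pairs excepted), so capacity is a per-round constraint
    for rid, worst_total in worst_per_round.items():
        if worst_total > nucleus_voxels:
            raise GenerationError(
                f"round {rid} requests territories ({worst_total} voxels) exceeding "
                f"the nucleus volume ({nucleus_voxels} voxels)"
            )

    gt_chroms: dict[str, GroundTruthChromosome] = {}
    occupied_by_round: dict[int, np.ndarray] = {}
    cube = np.ones((3, 3, 3), dtype=bool)  # 26-neighbourhood structuring element
    for ch in plan:
        chrom = ch.chromosome_id
        if chrom == "Y":
            state = SINGLE
        else:
            if chrom not in spec.pairing_probability:
                raise GenerationError(f"no pairing probability configured for chromosome {chrom}")
            state = PAIRED if rng.random() < spec.pairing_probability[chrom] else UNPAIRED

        # heterologous association: possibly seed inside an earlier same-round territory
        partner_union = None
        for other in plan:
            if other.round_id != ch.round_id or other.chromosome_id == chrom:
                continue
            if other.chromosome_id not in gt_chroms:
                continue  # generated later in this round; pair handled from its side
            if rng.random() < spec.association_for(chrom, other.chromosome_id):
                if partner_union is None:
                    partner_union = gt_chroms[other.chromosome_id].union()

        targets = _signal_targets(spec, chrom, paired=(state == PAIRED))
        # territories exclude other same-round territories, so two chromosomes
        # share voxels only when association was drawn for their pair
        occupied = occupied_by_round.setdefault(ch.round_id,
                                                np.zeros_like(nucleus))
        allowed_base = nucleus & ~occupied
        if partner_union is not None:
            allowed_base |= partner_union
        seed_region = partner_union if partner_union is not None else allowed_base
        copy1 = _grow_with_retries(rng, allowed_base, seed_region, targets[0],
                                   spec.shape_irregularity)

        copies = [copy1]
        if len(targets) == 2:
            if state == PAIRED:
                # second homolog grows from a face-neighbour of the first, so the
                # union is one connected component under 6- and 26-connectivity
                adjacent = ndimage.binary_dilation(copy1) & allowed_base & ~copy1
                copy2 = _grow_with_retries(rng, allowed_base & ~copy1, adjacent,
                                           targets[1], spec.shape_irregularity)
            else:
                forbidden = ndimage.binary_dilation(copy1, structure=cube,
                                                    iterations=spec.min_gap_voxels)
                allowed = allowed_base & ~forbidden
                copy2 = _grow_with_retries(rng, allowed, allowed, targets[1],
                                           spec.shape_irregularity)
            copies.append(copy2)
        gt_chroms[chrom] = GroundTruthChromosome(chromosome_id=chrom, state=state, copies=copies)
        for copy in copies:
            occupied |= copy

    associations: dict[frozenset, int] = {}
    for i, a in enumerate(plan):
        for b in plan[i + 1:]:
            if a.round_id != b.round_id:
                continue
            shared = int(np.count_nonzero(
                gt_chroms[a.chromosome_id].union() & gt_chroms[b.chromosome_id].union()
            ))
            associations[frozenset((a.chromosome_id, b.chromosome_id))] = shared

    # render channels
    sigma_vox = [spec.blur_sigma_um / s for s in spec.voxel_spacing_um]
    stacks: dict[int, VoxelStack] = {}
    for rid in sorted({c.round_id for c in plan}):
        intensities: dict[str, np.ndarray] = {}
        channel_map: dict[str, str] = {}
        for ch in sorted((c for c in plan if c.round_id == rid),
                         key=lambda c: c.fluorochrome_id):
            img = np.zeros(nucleus.shape, dtype=np.float32)
            img[nucleus] = spec.nucleoplasm_intensity
            img[gt_chroms[ch.chromosome_id].union()] = spec.signal_amplitude
            if spec.blur_sigma_um > 0:
                img = ndimage.gaussian_filter(img, sigma=sigma_vox)
            if spec.noise_sd > 0:
                img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            np.clip(img, 0.0, None, out=img)
            intensities[ch.fluorochrome_id] = img.astype(np.float32)
            channel_map[ch.fluorochrome_id] = ch.chromosome_id
        stacks[rid] = VoxelStack(intensities=intensities,
                                 voxel_spacing_um=spec.voxel_spacing_um,
                                 round_id=rid, channel_map=channel_map)

    truth = GroundTruth(nucleus_mask=nucleus, voxel_spacing_um=spec.voxel_spacing_um,
                        chromosomes=gt_chroms, associations=associations)
    return stacks, truth


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def generate_population(preset: StagePreset, n_cells: int, seed: int,
                        spec_template: NucleusSpec | None = None,
                        nucleus_id_prefix: str = "n"):
    """Yield ``n_cells`` independent synthetic nuclei for one stage.

    Each nucleus draws its pairing states from the preset probabilities, so
    realized per-chromosome paired counts are Binomial(n_cells, p).  The
    per-nucleus seeds are spawned from ``seed``; the output is a generator
    of :class:`~ctfish.types.NucleusRecord` with ground truth attached.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if spec_template is None:
        spec_template = population_spec_template(preset)
    children = np.random.SeedSequence(seed).spawn(n_cells)
    for i in range(n_cells):
        child_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
        spec = replace(spec_template,
                       pairing_probability=dict(preset.pairing_probability),
                       seed=child_seed)
        stacks, truth = generate_nucleus(spec)
        yield NucleusRecord(nucleus_id=f"{nucleus_id_prefix}{i:04d}", stage=preset.stage,
                            stacks=stacks, ground_truth=truth)


def population_spec_template(preset: StagePreset,
                             chromosomes=None) -> NucleusSpec:
    """Default per-nucleus recipe for population runs.

    Uses a slightly coarser in-plane sampling (0.12 µm) than the
    single-nucleus default so that a whole-karyotype population remains
    cheap to simulate; the z-step stays at the instrument's 0.17 µm.
    """
    if chromosomes is None:
        chromosomes = tuple(preset.pairing_probability) + (
            ("Y",) if preset.stage != LYMPHOCYTE else ())
    return NucleusSpec(
        channels=default_channel_plan(chromosomes),
        pairing_probability=dict(preset.pairing_probability),
        seed=0,
        semiaxes_um=(1.9, 2.6, 2.6),
        voxel_spacing_um=(0.17, 0.12, 0.12),
        territory_voxels=240,
    )


# ---------------------------------------------------------------------------
# ground truth on disk
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize ground truth as JSON (voxel coordinate lists)."""
    payload = {
        "voxel_spacing_um": list(truth.voxel_spacing_um),
        "shape": list(truth.nucleus_mask.shape),
        "nucleus_voxels": np.argwhere(truth.nucleus_mask).tolist(),
        "chromosomes": {
            chrom: {
                "state": g.state,
                "copies": [np.argwhere(c).tolist() for c in g.copies],
            }
            for chrom, g in truth.chromosomes.items()
        },
        "associations": [
            {"pair": sorted(pair), "shared_voxels": shared}
            for pair, shared in truth.associations.items()
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])

    def unmask(coords):
        out = np.zeros(shape, dtype=bool)
        if coords:
            idx = np.asarray(coords, dtype=int)
            out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return out

    chroms = {
        chrom: GroundTruthChromosome(
            chromosome_id=chrom, state=g["state"],
            copies=[unmask(c) for c in g["copies"]],
        )
        for chrom, g in payload["chromosomes"].items()
    }
    associations = {frozenset(a["pair"]): int(a["shared_voxels"])
                    for a in payload["associations"]}
    return GroundTruth(nucleus_mask=unmask(payload["nucleus_voxels"]),
                       voxel_spacing_um=tuple(payload["voxel_spacing_um"]),
                       chromosomes=chroms, associations=associations)
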