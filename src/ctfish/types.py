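"""Core containers for 3D-FISH territory analysis.

Conventions used across the package, stated once:

* Voxel grids are numpy arrays indexed ``(z, y, x)``, 0-based.
* Physical voxel spacing is a ``(z, y, x)`` triple in micrometres, aligned
  with the array axes.  The confocal z-step is 0.17 µm by default; the
  in-plane sampling defaults to 0.1 µm.
* Binary masks share the frame of the intensity stack they were derived
  from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Meiotic-interval labels (plus the somatic control) accepted as stages.
STAGE_I = "spermatogonia-early-preleptotene"
STAGE_II = "mid-preleptotene-zygotene"
STAGE_III = "pachytene"
STAGE_IV = "round-spermatid"
LYMPHOCYTE = "lymphocyte"
STAGES = (STAGE_I, STAGE_II, STAGE_III, STAGE_IV)
ALL_STAGE_LABELS = STAGES + (LYMPHOCYTE,)

#: Mouse karyotype as painted: 19 autosomes, X and Y.
AUTOSOMES = tuple(str(i) for i in range(1, 20))
CLASSIFIABLE_CHROMOSOMES = AUTOSOMES + ("X",)  # Y is single copy, never called
ALL_CHROMOSOMES = CLASSIFIABLE_CHROMOSOMES + ("Y",)

#: Chromosomes carrying nucleolus organizer regions.
NOR_CHROMOSOMES = frozenset({"11", "12", "15", "16", "18", "19"})

PAIRED = "paired"
UNPAIRED = "unpaired"
UNCALLABLE = "uncallable"

ONE_CHROMOSOME = "one_chromosome"
TWO_CHROMOSOME = "two_chromosome"


class CTFishError(Exception):
    """Base class for package errors."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be 3 strictly positive values, got {spacing}")
    return spacing


@dataclass
class VoxelStack:
    """One hybridization round of one nucleus: up to three fluorochrome channels.

    ``intensities`` maps fluorochrome id to a ``(z, y, x)`` float array;
    ``channel_map`` maps fluorochrome id to the painted chromosome id.
    """

    intensities: dict[str, np.ndarray]
    voxel_spacing_um: tuple[float, float, float]
    round_id: int
    channel_map: dict[str, str]

    def __post_init__(self) -> None:
        self.voxel_spacing_um = _check_spacing(self.voxel_spacing_um)
        if not self.intensities:
            raise ValueError("a stack needs at least one channel")
        shapes = {img.shape for img in self.intensities.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree in shape: {sorted(shapes)}")
        if set(self.channel_map) != set(self.intensities):
            raise ValueError(
                "channel_map fluorochromes "
                f"{sorted(self.channel_map)} != intensity channels {sorted(self.intensities)}"
            )
        for name, img in self.intensities.items():
            if img.ndim != 3:
                raise ValueError(f"channel {name!r} is not a 3D array")
            if np.any(img < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.intensities.values())).shape

    def chromosome_channel(self, chromosome_id: str) -> str:
        """Return the fluorochrome that paints ``chromosome_id`` in this round."""
        for fluor, chrom in self.channel_map.items():
            if chrom == chromosome_id:
                return fluor
        raise KeyError(f"chromosome {chromosome_id!r} not painted in round {self.round_id}")


@dataclass
class NucleusRecord:
    """All imaging rounds of a single nucleus plus its stage metadata."""

    nucleus_id: str
    stage: str
    stacks: dict[int, VoxelStack]
    ground_truth: "object | None" = None

    def __post_init__(self) -> None:
        if self.stage not in ALL_STAGE_LABELS:
            raise ValueError(f"unknown stage label {self.stage!r}; expected one of {ALL_STAGE_LABELS}")
        spacings = {s.voxel_spacing_um for s in self.stacks.values()}
        if len(spacings) > 1:
            raise ValueError(f"rounds disagree in voxel spacing: {sorted(spacings)}")

    def channel_plan(self) -> list[tuple[int, str, str]]:
        """(round_id, fluorochrome, chromosome) triples across all rounds."""
        plan = []
        for rid in sorted(self.stacks):
            stack = self.stacks[rid]
            for fluor in sorted(stack.channel_map):
                plan.append((rid, fluor, stack.channel_map[fluor]))
        return plan


@dataclass
class NucleusMask:
    """Binary nucleus segmentation with volumes in voxels and µm³."""

    nucleus_id: str
    mask: np.ndarray
    voxel_spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxel_spacing_um = _check_spacing(self.voxel_spacing_um)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def volume_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def volume_um3(self) -> float:
        return self.volume_voxels * float(np.prod(self.voxel_spacing_um))


@dataclass
class SignalMask:
    """Binary mask of one chromosome's hybridization signal in one nucleus."""

    nucleus_id: str
    chromosome_id: str
    round_id: int
    mask: np.ndarray
    voxel_spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxel_spacing_um = _check_spacing(self.voxel_spacing_um)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class PairingCall:
    """Homolog pairing verdict for one chromosome in one nucleus.

    One retained connected component means the two homologs form a single
    continuous voxel group (paired → scored as *one signal*); two or more
    components mean separate territories (unpaired → *two signals*); no
    component above the size floor means the signal could not be scored.
    """

    nucleus_id: str
    chromosome_id: str
    verdict: str
    n_components: int
    component_voxel_counts: tuple[int, ...]
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.verdict not in (PAIRED, UNPAIRED, UNCALLABLE):
            raise ValueError(f"bad verdict {self.verdict!r}")
        expected = {PAIRED: self.n_components == 1,
                    UNPAIRED: self.n_components >= 2,
                    UNCALLABLE: self.n_components == 0}[self.verdict]
        if not expected:
            raise ValueError(
                f"verdict {self.verdict!r} inconsistent with {self.n_components} components"
            )


@dataclass
class AssociationRecord:
    """Heterologous (nonhomologous) territory overlap for one chromosome pair.

    Overlap percentages are normalized per territory: ``overlap_pct_a`` is
    the percentage of chromosome *a*'s voxels shared with *b*, and vice
    versa, so the record is ordered even though ``shared_voxels`` is
    symmetric.
    """

    nucleus_id: str
    chromosome_a: str
    chromosome_b: str
    associated: bool
    shared_voxels: int
    overlap_pct_a: float
    overlap_pct_b: float
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.chromosome_a == self.chromosome_b:
            raise ValueError("association is defined for two different chromosomes")
        if self.associated != (self.shared_voxels > 0):
            raise ValueError("associated flag must equal shared_voxels > 0")
        for pct in (self.overlap_pct_a, self.overlap_pct_b):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"overlap percentage {pct} outside [0, 100]")


@dataclass
class NVPRecord:
    """Nuclear volume proportion of one signal (percent of nucleus voxels)."""

    nucleus_id: str
    chromosome_id: str
    signal_kind: str
    nvp_pct: float
    signal_voxels: int
    nucleus_voxels: int
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.signal_kind not in (ONE_CHROMOSOME, TWO_CHROMOSOME):
            raise ValueError(f"bad signal kind {self.signal_kind!r}")
        if not 0.0 < self.nvp_pct <= 100.0:
            raise ValueError(f"NVP {self.nvp_pct} outside (0, 100]")


@dataclass
class StagePreset:
    """Per-chromosome probability that the two homologs image as one signal."""

    stage: str
    pairing_probability: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in ALL_STAGE_LABELS:
            raise ValueError(f"unknown stage label {self.stage!r}")
        for chrom, p in self.pairing_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pairing probability for chromosome {chrom} is {p}, outside [0, 1]")
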