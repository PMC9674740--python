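"""Per-nucleus territory metrics: pairing calls, associations, volume proportions.

The pairing rule is purely topological: the two homologs of a chromosome
are *paired* when all their signal voxels form one continuous (connected)
group, and *unpaired* when they form two or more separate groups sharing
no voxel.  Connectivity defaults to 26 (corner-touching voxels count as
continuous) and is configurable to 6 or 18.  Components smaller than
``min_size`` voxels are treated as speckle and ignored, with the same
default floor the segmentation stage uses so the two stages agree on what
a signal is.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .segmentation import connectivity_structure
from .types import (
    CTFishError,
    AssociationRecord,
    NucleusMask,
    NVPRecord,
    ONE_CHROMOSOME,
    PAIRED,
    PairingCall,
    SignalMask,
    TWO_CHROMOSOME,
    UNCALLABLE,
    UNPAIRED,
)


class MetricsError(CTFishError):
    pass


def label_components(mask: np.ndarray, connectivity: int = 26) -> list[np.ndarray]:
    """Split a binary 3D mask into its connected components.

    Returns one boolean mask per maximal connected voxel set, sorted by
    voxel count, largest first (ties broken by first-label order).  An
    empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=connectivity_structure(connectivity))
    if n == 0:
        return []
    sizes = ndimage.sum_labels(np.ones(mask.shape), labels, index=range(1, n + 1))
    order = np.argsort(-sizes, kind="stable")
    return [labels == (int(i) + 1) for i in order]


def classify_pairing(signal: SignalMask, min_size: int = 5,
                     connectivity: int = 26, stage: str | None = None) -> PairingCall:
    """Call a chromosome paired/unpaired/uncallable from its signal mask.

    One retained component ⇒ paired; two or more ⇒ unpaired; none above
    the speckle floor ⇒ uncallable.  The single-copy Y chromosome has no
    homolog and is rejected.
    """
    if signal.chromosome_id == "Y":
        raise MetricsError("single-copy chromosome Y is not classifiable for pairing")
    components = label_components(signal.mask, connectivity=connectivity)
    counts = tuple(int(np.count_nonzero(c)) for c in components)
    retained = tuple(c for c in counts if c >= min_size)
    if len(retained) == 0:
        verdict = UNCALLABLE
    elif len(retained) == 1:
        verdict = PAIRED
    else:
        verdict = UNPAIRED
    return PairingCall(nucleus_id=signal.nucleus_id, chromosome_id=signal.chromosome_id,
                       verdict=verdict, n_components=len(retained),
                       component_voxel_counts=retained, stage=stage)


def association(mask_a: SignalMask, mask_b: SignalMask,
                stage: str | None = None) -> AssociationRecord:
    """Heterologous association of two territories: shared voxels and overlap.

    ``overlap_pct_a`` is the percentage of *a*'s voxels inside the
    intersection (and likewise for *b*), so the shared-voxel count is
    symmetric while the percentages are normalized per territory.
    """
    if mask_a.chromosome_id == mask_b.chromosome_id:
        raise MetricsError("association needs two different chromosomes")
    if mask_a.mask.shape != mask_b.mask.shape:
        raise MetricsError(
            f"masks disagree in dimensions: {mask_a.mask.shape} vs {mask_b.mask.shape}"
        )
    shared = int(np.count_nonzero(mask_a.mask & mask_b.mask))
    size_a, size_b = mask_a.voxel_count, mask_b.voxel_count
    return AssociationRecord(
        nucleus_id=mask_a.nucleus_id,
        chromosome_a=mask_a.chromosome_id,
        chromosome_b=mask_b.chromosome_id,
        associated=shared > 0,
        shared_voxels=shared,
        overlap_pct_a=100.0 * shared / size_a if size_a else 0.0,
        overlap_pct_b=100.0 * shared / size_b if size_b else 0.0,
        stage=stage,
    )


def nuclear_volume_proportion(signal: SignalMask, nucleus: NucleusMask,
                              call: PairingCall | None, min_size: int = 5,
                              connectivity: int = 26,
                              stage: str | None = None) -> list[NVPRecord]:
    """Nuclear volume proportion (NVP) records for one chromosome's signal.

    A paired chromosome contributes one record whose signal is composed of
    two chromosomes; an unpaired chromosome contributes one
    one-chromosome record per retained component.  ``call=None`` marks a
    single-copy chromosome (Y), scored as one-chromosome records.  An
    uncallable signal contributes nothing.
    """
    nucleus_voxels = nucleus.volume_voxels
    if nucleus_voxels == 0:
        raise MetricsError("empty nucleus mask")
    components = [c for c in label_components(signal.mask, connectivity=connectivity)
                  if np.count_nonzero(c) >= min_size]
    if call is not None and call.verdict == UNCALLABLE:
        return []
    records: list[NVPRecord] = []
    if call is not None and call.verdict == PAIRED:
        voxels = sum(int(np.count_nonzero(c)) for c in components)
        records.append(NVPRecord(
            nucleus_id=signal.nucleus_id, chromosome_id=signal.chromosome_id,
            signal_kind=TWO_CHROMOSOME, nvp_pct=100.0 * voxels / nucleus_voxels,
            signal_voxels=voxels, nucleus_voxels=nucleus_voxels, stage=stage))
    else:
        for comp in components:
            voxels = int(np.count_nonzero(comp))
            records.append(NVPRecord(
                nucleus_id=signal.nucleus_id, chromosome_id=signal.chromosome_id,
                signal_kind=ONE_CHROMOSOME, nvp_pct=100.0 * voxels / nucleus_voxels,
                signal_voxels=voxels, nucleus_voxels=nucleus_voxels, stage=stage))
    return records
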