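"""Binary segmentation of nuclei and chromosome territories.

The nucleus is taken as the largest connected foreground object of the
summed-channel image after optional Gaussian pre-smoothing, Otsu
thresholding and hole filling.  Each territory is thresholded (Otsu,
computed within the nucleus only, so the threshold is relative and the
mask is invariant to uniform intensity scaling), restricted to the
nucleus, cleaned of sub-``min_size`` speckles, and hole-filled.

Territory channels are thresholded without pre-smoothing by default:
painting signals are only a few voxels across, so smoothing both drags
the Otsu threshold into the blur shell (dilating the mask) and erases
genuine boundary detail.  For low-SNR data a pre-smoothing ``sigma``
can be supplied; the nucleus, being orders of magnitude larger than
the smoothing kernel, keeps a pre-smoothing default of 1 voxel.

Segmentation runs on the anisotropic voxel grid directly; physical
spacing only enters when volumes are converted to µm³.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .types import CTFishError, NucleusMask, SignalMask, VoxelStack


class SegmentationError(CTFishError):
    """Segmentation could not produce a valid mask."""


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D structuring element for 6-, 18- or 26-connectivity."""
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}") from None
    return ndimage.generate_binary_structure(3, rank)


def _smooth(img: np.ndarray, sigma: float, spacing) -> np.ndarray:
    """Gaussian pre-smoothing with sigma given in xy voxels, scaled for z."""
    if sigma <= 0:
        return img
    sz, sy, sx = spacing
    sigma_z = sigma * sy / sz  # keep the physical smoothing scale isotropic
    return ndimage.gaussian_filter(img.astype(np.float64), sigma=(sigma_z, sigma, sigma))


def segment_nucleus(stacks: VoxelStack | Sequence[VoxelStack], nucleus_id: str = "nucleus",
                    sigma: float = 1.0, connectivity: int = 26) -> NucleusMask:
    """Segment the nucleus body from one or several rounds of one nucleus.

    All channels of all supplied stacks are summed; the nucleoplasm
    background makes the whole nucleus foreground relative to the outside.
    Raises :class:`SegmentationError` for a blank stack.
    """
    if isinstance(stacks, VoxelStack):
        stacks = [stacks]
    if not stacks:
        raise SegmentationError("no stacks supplied")
    spacing = stacks[0].voxel_spacing_um
    summed = np.zeros(stacks[0].shape, dtype=np.float64)
    for stack in stacks:
        if stack.shape != summed.shape or stack.voxel_spacing_um != spacing:
            raise SegmentationError("stacks disagree in dimensions or spacing")
        for img in stack.intensities.values():
            summed += img
    if not np.any(summed > 0):
        raise SegmentationError("no nucleus found: stack is blank")
    smoothed = _smooth(summed, sigma, spacing)
    thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any():
        raise SegmentationError("no nucleus found: nothing above threshold")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg, structure=connectivity_structure(connectivity))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return NucleusMask(nucleus_id=nucleus_id, mask=fg, voxel_spacing_um=spacing)


def segment_territory(stack: VoxelStack, fluorochrome: str, nucleus: NucleusMask,
                      sigma: float = 0.0, min_size: int = 5,
                      connectivity: int = 26) -> SignalMask:
    """Segment one chromosome's painting signal within the nucleus mask.

    A channel with no contrast inside the nucleus yields an empty mask
    (callability is decided downstream, not here).  ``sigma`` is optional
    pre-smoothing for low-SNR data; it is off by default because it
    systematically dilates small signals (see module docstring).
    """
    if fluorochrome not in stack.intensities:
        raise SegmentationError(f"round {stack.round_id} has no channel {fluorochrome!r}")
    if stack.shape != nucleus.mask.shape:
        raise SegmentationError("stack and nucleus mask disagree in dimensions")
    img = stack.intensities[fluorochrome]
    chromosome_id = stack.channel_map[fluorochrome]
    smoothed = _smooth(img, sigma, stack.voxel_spacing_um)
    inside = smoothed[nucleus.mask]
    empty = SignalMask(nucleus_id=nucleus.nucleus_id, chromosome_id=chromosome_id,
                       round_id=stack.round_id,
                       mask=np.zeros(stack.shape, dtype=bool),
                       voxel_spacing_um=stack.voxel_spacing_um)
    if inside.size == 0 or inside.max() <= 0 or inside.min() == inside.max():
        return empty
    thr = threshold_otsu(inside)
    mask = (smoothed > thr) & nucleus.mask
    if min_size > 1:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]  # skimage connectivity rank
        # drop components strictly smaller than min_size voxels
        mask = remove_small_objects(mask, max_size=min_size - 1, connectivity=rank)
    mask = ndimage.binary_fill_holes(mask) & nucleus.mask
    empty.mask = mask
    return empty
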