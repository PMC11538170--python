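"""Normal / egg-shape template construction and weighted template mixing.

A template is an occipital-normalized average image in standard space.
The adaptive method represents each subject as a convex mixture
``w * normal + (1 - w) * egg`` with the normal-template fraction ``w``
on a 0.001 grid; the split variant composes different weights for the
left and right hemispheres across the mid-sagittal plane.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .imaging_core import (
    BinaryVOI,
    Grid,
    Volume,
    fwhm_to_sigma,
    grids_compatible,
    masked_mean,
)
from .io_formats import LabelVolume

W_MIN = 0.001
W_MAX = 0.999

LEFT_LABEL = 1
RIGHT_LABEL = 2


class TemplatePair:
    """Normal and disease (egg-shape) templates on a shared grid.

    Both parents are occipital-normalized (occipital mean = 1) so any
    weighted mixture stays on the same intensity scale without further
    rescaling.
    """

    def __init__(self, normal: Volume, egg: Volume, occipital: BinaryVOI | None = None):
        if not grids_compatible(normal.grid, egg.grid):
            raise ValueError("normal and egg templates are not on the same grid")
        if np.any(normal.data < 0) or np.any(egg.data < 0):
            raise ValueError("templates must be nonnegative")
        if occipital is not None:
            for name, vol in (("normal", normal), ("egg", egg)):
                m = masked_mean(vol, occipital)
                if abs(m - 1.0) > 1e-6:
                    raise ValueError(
                        f"{name} template occipital mean is {m:.6f}, expected 1"
                    )
        self.normal = normal
        self.egg = egg
        self.occipital = occipital

    @property
    def grid(self) -> Grid:
        return self.normal.grid


def build_template(normalized_subjects: list[Volume], occipital_voi: BinaryVOI) -> Volume:
    """Average spatially standardized volumes after occipital normalization.

    Each input is divided by its own occipital mean, then the voxelwise
    arithmetic mean is taken; the result has occipital mean exactly 1.
    """
    if len(normalized_subjects) == 0:
        raise ValueError("need at least one standardized subject")
    grid = normalized_subjects[0].grid
    acc = np.zeros(grid.shape)
    for i, vol in enumerate(normalized_subjects):
        if not grids_compatible(vol.grid, grid):
            raise ValueError(f"subject {i} is not on the template grid")
        occ = masked_mean(vol, occipital_voi)
        if occ <= 0:
            raise ValueError(f"subject {i} has non-positive occipital mean {occ}")
        acc += vol.data / occ
    return Volume(acc / len(normalized_subjects), grid)


def _check_w(w: float) -> float:
    w = float(w)
    if not (W_MIN <= w <= W_MAX):
        raise ValueError(f"weight {w} outside [{W_MIN}, {W_MAX}]")
    return w


def weighted_template(pair: TemplatePair, w: float) -> Volume:
    """Voxelwise mixture ``w * normal + (1 - w) * egg``."""
    w = _check_w(w)
    return Volume(w * pair.normal.data + (1.0 - w) * pair.egg.data, pair.grid)


def hemisphere_labels(grid: Grid) -> LabelVolume:
    """Partition a grid at the mid-sagittal plane (world x = 0).

    Left hemisphere (world x < 0, RAS) gets label 1, right gets label 2;
    voxels exactly on the plane are assigned to the right.
    """
    x_world = grid.world_coordinates()[..., 0]
    labels = np.where(x_world < 0, LEFT_LABEL, RIGHT_LABEL).astype(np.int16)
    return LabelVolume(labels, grid, {LEFT_LABEL: "left", RIGHT_LABEL: "right"})


def _left_fraction(hemisphere_mask: LabelVolume, blend_fwhm_mm: float) -> np.ndarray:
    """Soft left-hemisphere indicator, feathered across the midline."""
    labels = hemisphere_mask.labels
    if not np.all(np.isin(labels, (LEFT_LABEL, RIGHT_LABEL))):
        raise ValueError("hemisphere mask must partition the grid into left/right")
    left = (labels == LEFT_LABEL).astype(float)
    if blend_fwhm_mm <= 0:
        return left
    sigma_vox = fwhm_to_sigma(blend_fwhm_mm) / hemisphere_mask.grid.spacing
    return ndimage.gaussian_filter(left, sigma=sigma_vox, mode="nearest")


def compose_split_template(
    pair: TemplatePair,
    w_left: float,
    w_right: float,
    hemisphere_mask: LabelVolume,
    blend_fwhm_mm: float = 4.0,
) -> Volume:
    """Asymmetric template: per-hemisphere weights with a feathered seam.

    Away from the midline the result equals ``weighted_template`` at the
    hemisphere's own weight.  A Gaussian blend band (default 4 mm FWHM,
    0 = hard split) interpolates the local weight across the plane so
    the seam injects no gradient discontinuity into registration.
    """
    w_left = _check_w(w_left)
    w_right = _check_w(w_right)
    if not grids_compatible(hemisphere_mask.grid, pair.grid):
        raise ValueError("hemisphere mask is not on the template grid")
    alpha = _left_fraction(hemisphere_mask, blend_fwhm_mm)
    w_map = alpha * w_left + (1.0 - alpha) * w_right
    data = w_map * pair.normal.data + (1.0 - w_map) * pair.egg.data
    return Volume(data, pair.grid)
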