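"""Resolution-matched binary VOIs from an atlas label volume.

The recipe follows the SPECT-resolution matching rule: set the region
indicator to 100, smooth with an 8 mm FWHM 3D Gaussian, keep voxels
whose value is strictly greater than 50.  This shrinks thin structures
(which genuinely cannot be resolved) while leaving the half-maximum
boundary of large regions on the original edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_core import BinaryVOI, Volume, gaussian_smooth
from .io_formats import LabelVolume

#: AAL-style names of the occipital reference components
OCCIPITAL_REGION_NAMES = (
    "Occipital_Inf",
    "Occipital_Mid",
    "Occipital_Sup",
    "Lingual",
    "Cuneus",
    "Calcarine",
)

INDICATOR_VALUE = 100.0
DEFAULT_FWHM_MM = 8.0
DEFAULT_THRESHOLD_PCT = 50.0


@dataclass(frozen=True)
class VoiRecipe:
    """A named union of atlas label ids, optionally restricted to one side."""

    name: str
    label_ids: frozenset
    side: str = "both"  # left | right | both

    def __post_init__(self) -> None:
        if not self.label_ids:
            raise ValueError(f"recipe {self.name!r} has no label ids")
        if self.side not in ("left", "right", "both"):
            raise ValueError(f"invalid side {self.side!r}")


class EmptyVoiError(ValueError):
    """The region is thinner than the SPECT resolution allows."""


def build_voi(
    atlas: LabelVolume,
    recipe: VoiRecipe,
    fwhm_mm: float = DEFAULT_FWHM_MM,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> BinaryVOI:
    """Indicator-100 / smooth / strict->threshold VOI construction.

    Laterality is restricted at the mid-sagittal plane (world x = 0,
    left means x < 0) before smoothing, so a bilateral label pair can
    be split without feathered cross-talk.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if not (0 < threshold_pct < 100):
        raise ValueError("threshold_pct must be inside (0, 100)")
    missing = recipe.label_ids - set(atlas.label_map)
    if missing:
        raise ValueError(f"recipe {recipe.name!r} references unknown ids {sorted(missing)}")
    indicator = atlas.mask_for_ids(recipe.label_ids).astype(float)
    if recipe.side != "both":
        x_world = atlas.grid.world_coordinates()[..., 0]
        keep = x_world < 0 if recipe.side == "left" else x_world >= 0
        indicator = indicator * keep
    smoothed = gaussian_smooth(
        Volume(indicator * INDICATOR_VALUE, atlas.grid), fwhm_mm
    )
    mask = smoothed.data > threshold_pct  # strictly "more than 50%"
    if not mask.any():
        raise EmptyVoiError(
            f"VOI {recipe.name!r} is empty after resolution matching "
            f"(region thinner than {fwhm_mm} mm FWHM supports)"
        )
    return BinaryVOI(mask, atlas.grid, name=recipe.name)


def _ids(atlas: LabelVolume, names, what: str) -> frozenset:
    ids = atlas.ids_for(names)
    if not ids:
        raise ValueError(f"atlas provides no labels for {what} (looked for {list(names)})")
    return frozenset(ids)


def standard_voi_set(
    atlas: LabelVolume,
    fwhm_mm: float = DEFAULT_FWHM_MM,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> dict[str, BinaryVOI]:
    """The standard analysis set: caudate, putamen, striatum per side
    plus the merged bilateral occipital reference.

    Composite regions (striatum = caudate ∪ putamen; occipital = six
    AAL components) are built from the union indicator *before*
    smoothing, so feathered edges are not double counted.
    """
    names = set(atlas.label_map.values())
    caudate_names = {n for n in names if n.startswith("Caudate")}
    putamen_names = {n for n in names if n.startswith("Putamen")}
    occ_names = {
        n
        for n in names
        if any(n == o or n.startswith(o + "_") for o in OCCIPITAL_REGION_NAMES)
    }
    caudate = _ids(atlas, caudate_names, "caudate")
    putamen = _ids(atlas, putamen_names, "putamen")
    occipital = _ids(atlas, occ_names, "the occipital reference")

    recipes = [
        VoiRecipe("caudate_left", caudate, "left"),
        VoiRecipe("caudate_right", caudate, "right"),
        VoiRecipe("putamen_left", putamen, "left"),
        VoiRecipe("putamen_right", putamen, "right"),
        VoiRecipe("striatum_left", caudate | putamen, "left"),
        VoiRecipe("striatum_right", caudate | putamen, "right"),
        VoiRecipe("occipital", occipital, "both"),
    ]
    return {r.name: build_voi(atlas, r, fwhm_mm, threshold_pct) for r in recipes}


def voi_volume_report(vois: dict[str, BinaryVOI]) -> dict[str, float]:
    """Volume in mL of each VOI, for provenance records."""
    return {name: v.volume_mm3() / 1000.0 for name, v in vois.items()}
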