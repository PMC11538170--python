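"""Striatal uptake ratios, high/low sides, asymmetry and binding ratios.

All quantities are referenced to the mean uptake of the occipital VOI,
so they are invariant to the global intensity scale of the image:

* uptake ratio       R = mean(region) / mean(occipital)
* asymmetry index   AI = |L - R| / (L + R) * 200   (percent)
* binding ratio    SBR = R - 1   (the specific-binding scale used for
  comparison with the Southampton method, which corrects for
  nonspecific accumulation by subtracting one)
"""

from __future__ import annotations

from dataclasses import dataclass

from .imaging_core import BinaryVOI, Volume, masked_mean

#: regions with a left/right pair in the standard VOI set
PAIRED_REGIONS = ("striatum", "caudate", "putamen")


def uptake_ratio(vol: Volume, region: BinaryVOI, reference: BinaryVOI) -> float:
    """Mean uptake in a region divided by the occipital reference mean."""
    ref = masked_mean(vol, reference)
    if ref <= 0:
        raise ValueError(
            f"reference {reference.name!r} mean is {ref:.4g}; ratio undefined"
        )
    return masked_mean(vol, region) / ref


def asymmetry_index(left: float, right: float) -> float:
    """AI = |L - R| / (L + R) * 200, in percent."""
    if left + right <= 0:
        raise ValueError("asymmetry index undefined for non-positive L + R")
    return abs(left - right) / (left + right) * 200.0


@dataclass(frozen=True)
class RegionResult:
    """Left/right uptake ratios of one region with derived quantities."""

    ratio_left: float
    ratio_right: float

    @property
    def ratio_high(self) -> float:
        return max(self.ratio_left, self.ratio_right)

    @property
    def ratio_low(self) -> float:
        return min(self.ratio_left, self.ratio_right)

    @property
    def ai(self) -> float:
        return asymmetry_index(self.ratio_left, self.ratio_right)

    @property
    def binding_ratio_left(self) -> float:
        return self.ratio_left - 1.0

    @property
    def binding_ratio_right(self) -> float:
        return self.ratio_right - 1.0


@dataclass(frozen=True)
class RegionRatios:
    """Per-region occipital-referenced results for one normalized image."""

    striatum: RegionResult
    caudate: RegionResult
    putamen: RegionResult

    def region(self, name: str) -> RegionResult:
        return getattr(self, name)

    def rows(self, subject: str = "", mode: str = "", weights: dict | None = None):
        """Flatten into table rows (one per region) for CSV export."""
        weights = weights or {}
        out = []
        for name in PAIRED_REGIONS:
            r = self.region(name)
            out.append(
                {
                    "subject": subject,
                    "mode": mode,
                    "region": name,
                    "ratio_left": r.ratio_left,
                    "ratio_right": r.ratio_right,
                    "ratio_high": r.ratio_high,
                    "ratio_low": r.ratio_low,
                    "ai": r.ai,
                    "binding_ratio_left": r.binding_ratio_left,
                    "binding_ratio_right": r.binding_ratio_right,
                    "selected_w": weights.get("w"),
                    "selected_w_left": weights.get("w_left"),
                    "selected_w_right": weights.get("w_right"),
                }
            )
        return out


def quantify(normalized: Volume, vois: dict[str, BinaryVOI]) -> RegionRatios:
    """Compute the full ratio set from a normalized volume and standard VOIs.

    High/low assignment is made independently per region: each
    structure's own lower-uptake side marks its more affected
    hemisphere.
    """
    reference = vois["occipital"]
    results = {}
    for name in PAIRED_REGIONS:
        left = uptake_ratio(normalized, vois[f"{name}_left"], reference)
        right = uptake_ratio(normalized, vois[f"{name}_right"], reference)
        results[name] = RegionResult(ratio_left=left, ratio_right=right)
    return RegionRatios(**results)
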