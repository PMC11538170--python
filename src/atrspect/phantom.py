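"""Deterministic digital DAT-SPECT phantoms with matching atlas and truth.

The generator emulates the accumulation patterns seen in ioflupane
SPECT: a brain-shaped background of low nonspecific uptake (the
occipital level defines ratio 1), left/right caudate and putamen with
configurable specific uptake, posterior putamen loss (the egg-shape
pattern), a smooth random geometric deformation standing in for
inter-subject anatomy, scanner blur, and noise.  Every output is fully
determined by the spec and seed.

Geometry is parametric-analytic (ellipsoids with truncations), so the
ground truth is exact and nothing needs to be downloaded.  Anatomical
labels describe the *anatomy* (the full structures); disease reduces
uptake inside them, not their extent, exactly as an atlas VOI sees it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging_core import Grid, Volume, centered_grid, fwhm_to_sigma, gaussian_smooth
from .io_formats import LabelVolume

# AAL1-style label ids for the fixture atlas
LABELS = {
    71: "Caudate_L",
    72: "Caudate_R",
    73: "Putamen_L",
    74: "Putamen_R",
    43: "Calcarine_L",
    44: "Calcarine_R",
    51: "Occipital_Mid_L",
    52: "Occipital_Mid_R",
}

# world-mm geometry (RAS, mid-sagittal plane at x = 0); one side given,
# the other is mirrored in x
BRAIN_CENTER = (0.0, -5.0, 0.0)
BRAIN_SEMI = (70.0, 85.0, 60.0)
# deep white matter: lower nonspecific uptake than the cortical ribbon,
# giving registration visible structure inside the brain outline
WHITE_CENTER = (0.0, -5.0, 2.0)
WHITE_SEMI = (52.0, 64.0, 44.0)
WHITE_LEVEL = 0.75  # relative to cortical/occipital background
CAUDATE_CENTER = (13.0, 16.0, 8.0)
CAUDATE_SEMI = (9.0, 15.0, 11.0)
PUTAMEN_CENTER = (28.0, -4.0, 2.0)
PUTAMEN_SEMI = (10.0, 21.0, 10.0)
OCCIPITAL_MID_CENTER = (24.0, -62.0, 4.0)
OCCIPITAL_MID_SEMI = (18.0, 18.0, 20.0)
CALCARINE_CENTER = (8.0, -66.0, -6.0)
CALCARINE_SEMI = (8.0, 16.0, 10.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    Ratios are true uptake ratios relative to the occipital/cortical
    background (which is 1 by construction).
    ``putamen_posterior_fraction_*`` models posterior putamen loss:
    1 keeps the whole putamen active, 0.5 keeps the anterior half.
    Default grid matches a 128 x 128 SPECT matrix at 1.72 mm pixels;
    default blur matches an 8.5 mm FWHM collimator resolution.
    """

    shape: tuple[int, int, int] = (128, 128, 90)
    spacing: tuple[float, float, float] = (1.72, 1.72, 1.72)
    background_uptake: float = 1.0
    caudate_ratio_left: float = 4.0
    caudate_ratio_right: float = 4.0
    putamen_ratio_left: float = 4.0
    putamen_ratio_right: float = 4.0
    putamen_posterior_fraction_left: float = 1.0
    putamen_posterior_fraction_right: float = 1.0
    deformation_amplitude_mm: float = 0.0
    deformation_smoothing_mm: float = 25.0
    noise_model: str = "none"  # none | gaussian | poisson
    noise_sigma_pct: float = 0.0  # gaussian sigma as % of image max
    poisson_scale: float = 100.0  # expected counts per unit uptake
    blur_fwhm_mm: float = 8.5

    def __post_init__(self) -> None:
        for name in (
            "caudate_ratio_left",
            "caudate_ratio_right",
            "putamen_ratio_left",
            "putamen_ratio_right",
        ):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1 (background-relative)")
        for name in ("putamen_posterior_fraction_left", "putamen_posterior_fraction_right"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def grid(self) -> Grid:
        return centered_grid(self.shape, self.spacing)


@dataclass
class PhantomTruth:
    """Exact generating quantities of one phantom.

    ``ratios``/``ai`` are the pre-blur generating values (label-mask
    means of the uptake map).  ``ratios_at_resolution``/``ai_at_resolution``
    are the ideal-measurement values: the standard VOI quantification of
    the undeformed, noise-free phantom at scanner blur.  The latter play
    the role of a standard of truth for end-to-end comparisons — like a
    reference normalization, they measure the blurred image, so
    partial-volume losses cancel out of the comparison.
    """

    ratios: dict  # region -> {"left": r, "right": r}
    ai: dict  # region -> percent
    ratios_at_resolution: dict = field(default_factory=dict)
    ai_at_resolution: dict = field(default_factory=dict)
    seed: int | None = None
    generating_weight: float | None = None
    flags: list = field(default_factory=list)
    deformation_amplitude_mm: float = 0.0


def _soft_ellipsoid(
    world: np.ndarray, center, semi, spacing, y_min: float | None = None
) -> np.ndarray:
    """Ellipsoid indicator with a ~1 voxel anti-aliased edge in [0, 1]."""
    semi = np.asarray(semi, float)
    rel = (world - np.asarray(center, float)) / semi
    rho = np.sqrt((rel**2).sum(axis=-1))
    # approximate signed distance to the surface in mm
    sdist = (1.0 - rho) * semi.min()
    edge = float(np.mean(spacing))
    w = np.clip(0.5 + sdist / edge, 0.0, 1.0)
    if y_min is not None:
        cut = np.clip(0.5 + (world[..., 1] - y_min) / edge, 0.0, 1.0)
        w = w * cut
    return w


def _mirror(center) -> tuple:
    return (-center[0], center[1], center[2])


def _structures(grid: Grid, spec: PhantomSpec | None = None) -> dict[str, np.ndarray]:
    """Soft indicators of every structure; putamen uptake truncation is
    applied only when a spec is given (labels use the full anatomy)."""
    world = grid.world_coordinates()
    sp = grid.spacing
    out = {}
    out["brain"] = _soft_ellipsoid(world, BRAIN_CENTER, BRAIN_SEMI, sp)
    out["white"] = _soft_ellipsoid(world, WHITE_CENTER, WHITE_SEMI, sp)
    for side, mirror in (("right", False), ("left", True)):
        suffix = "_left" if side == "left" else "_right"
        cc = _mirror(CAUDATE_CENTER) if mirror else CAUDATE_CENTER
        pc = _mirror(PUTAMEN_CENTER) if mirror else PUTAMEN_CENTER
        oc = _mirror(OCCIPITAL_MID_CENTER) if mirror else OCCIPITAL_MID_CENTER
        kc = _mirror(CALCARINE_CENTER) if mirror else CALCARINE_CENTER
        out["caudate" + suffix] = _soft_ellipsoid(world, cc, CAUDATE_SEMI, sp)
        y_min = None
        if spec is not None:
            frac = getattr(spec, f"putamen_posterior_fraction{suffix}")
            if frac < 1.0:
                # posterior is -y; keep `frac` of the length from the anterior end
                y_min = (pc[1] + PUTAMEN_SEMI[1]) - 2.0 * PUTAMEN_SEMI[1] * frac
        out["putamen" + suffix] = _soft_ellipsoid(world, pc, PUTAMEN_SEMI, sp, y_min=y_min)
        out["occipital_mid" + suffix] = _soft_ellipsoid(world, oc, OCCIPITAL_MID_SEMI, sp)
        out["calcarine" + suffix] = _soft_ellipsoid(world, kc, CALCARINE_SEMI, sp)
    return out


def canonical_atlas(grid: Grid) -> LabelVolume:
    """The fixture atlas on a grid: anatomical labels, no disease applied."""
    s = _structures(grid)
    labels = np.zeros(grid.shape, dtype=np.int16)
    order = [
        ("occipital_mid_left", 51),
        ("occipital_mid_right", 52),
        ("calcarine_left", 43),
        ("calcarine_right", 44),
        ("caudate_left", 71),
        ("caudate_right", 72),
        ("putamen_left", 73),
        ("putamen_right", 74),
    ]
    for name, lab in order:
        labels[s[name] > 0.5] = lab
    return LabelVolume(labels, grid, LABELS)


def _uptake_map(grid: Grid, spec: PhantomSpec) -> np.ndarray:
    """Pre-blur uptake: cortical ribbon at the reference level, deep white
    matter slightly below it, specific uptake on the (possibly truncated)
    striatal structures, and the occipital regions pinned to the
    reference level (they define ratio 1)."""
    bg = spec.background_uptake
    s = _structures(grid, spec)
    u = bg * (s["brain"] - (1.0 - WHITE_LEVEL) * s["white"])
    # occipital cortex sits at exactly the reference level
    for name in ("occipital_mid_left", "occipital_mid_right", "calcarine_left", "calcarine_right"):
        ind = s[name]
        u = u * (1.0 - ind) + bg * ind
    for region in ("caudate", "putamen"):
        for side in ("left", "right"):
            ratio = getattr(spec, f"{region}_ratio_{side}")
            ind = s[f"{region}_{side}"]
            u = u * (1.0 - ind) + ratio * bg * ind
    return u


def _true_ratios(grid: Grid, spec: PhantomSpec) -> dict:
    """Exact label-mask means of the pre-blur uptake, per region and side."""
    uptake = _uptake_map(grid, spec)
    atlas, _ = grid_assets(grid)
    ids = {
        ("caudate", "left"): [71],
        ("caudate", "right"): [72],
        ("putamen", "left"): [73],
        ("putamen", "right"): [74],
        ("striatum", "left"): [71, 73],
        ("striatum", "right"): [72, 74],
    }
    out: dict = {"striatum": {}, "caudate": {}, "putamen": {}}
    for (region, side), labs in ids.items():
        m = np.isin(atlas.labels, labs)
        out[region][side] = float(uptake[m].mean()) / spec.background_uptake
    return out


_ASSET_CACHE: dict = {}


def grid_assets(grid: Grid) -> tuple[LabelVolume, dict]:
    """Canonical atlas and standard VOI set for a grid, memoized.

    The atlas geometry is deterministic, so caching per (shape, spacing)
    saves rebuilding VOIs for every phantom in a cohort.
    """
    from .voi import standard_voi_set

    key = (grid.shape, tuple(np.round(grid.spacing, 9)), tuple(np.round(grid.affine[:3, 3], 6)))
    if key not in _ASSET_CACHE:
        atlas = canonical_atlas(grid)
        _ASSET_CACHE[key] = (atlas, standard_voi_set(atlas))
    return _ASSET_CACHE[key]


def _resolution_truth(grid: Grid, spec: PhantomSpec) -> tuple[dict, dict]:
    """Ideal-measurement ratios: standard quantification of the blurred,
    undeformed, noise-free phantom on the truth grid."""
    from .quant import PAIRED_REGIONS, quantify

    _, vois = grid_assets(grid)
    img = gaussian_smooth(Volume(_uptake_map(grid, spec), grid), spec.blur_fwhm_mm)
    rr = quantify(img, vois)
    ratios = {
        region: {
            "left": rr.region(region).ratio_left,
            "right": rr.region(region).ratio_right,
        }
        for region in PAIRED_REGIONS
    }
    ai = {region: rr.region(region).ai for region in PAIRED_REGIONS}
    return ratios, ai


def _random_deformation(grid: Grid, amplitude_mm, smoothing_mm, rng) -> np.ndarray:
    """Smooth zero-mean random displacement with max magnitude = amplitude."""
    sigma_vox = smoothing_mm / np.asarray(grid.spacing)
    u = np.stack(
        [
            ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma_vox, mode="nearest")
            for _ in range(3)
        ]
    )
    mag = np.sqrt((u**2).sum(axis=0)).max()
    if mag > 0:
        u *= amplitude_mm / mag
    return u


def generate_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[Volume, LabelVolume, PhantomTruth]:
    """One synthetic subject: image, atlas labels (pre-blur), exact truth.

    Processing order: uptake map -> geometric deformation -> scanner
    blur -> noise.  The atlas is emitted undeformed (it lives in
    template space); the deformation stands in for the subject's own
    anatomy, which registration is expected to undo.
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid()
    truth_ratios = _true_ratios(grid, spec)
    ai = {
        region: abs(v["left"] - v["right"]) / (v["left"] + v["right"]) * 200.0
        for region, v in truth_ratios.items()
    }
    flags = []
    for side in ("left", "right"):
        kept = 2 * PUTAMEN_SEMI[1] * getattr(spec, f"putamen_posterior_fraction_{side}")
        if kept < spec.blur_fwhm_mm:
            msg = f"{side} putamen active length {kept:.1f} mm below blur FWHM"
            flags.append(msg)
            warnings.warn(msg, stacklevel=2)

    uptake = _uptake_map(grid, spec)
    if spec.deformation_amplitude_mm > 0:
        u = _random_deformation(
            grid, spec.deformation_amplitude_mm, spec.deformation_smoothing_mm, rng
        )
        idx = np.indices(grid.shape, dtype=np.float64)
        coords = [idx[ax] + u[ax] / grid.spacing[ax] for ax in range(3)]
        uptake = ndimage.map_coordinates(
            uptake, coords, order=1, mode="constant", cval=0.0, prefilter=False
        )
    img = gaussian_smooth(Volume(uptake, grid), spec.blur_fwhm_mm)
    data = img.data
    if spec.noise_model == "gaussian" and spec.noise_sigma_pct > 0:
        sigma = spec.noise_sigma_pct / 100.0 * data.max()
        data = data + rng.normal(0.0, sigma, size=data.shape)
    elif spec.noise_model == "poisson":
        data = rng.poisson(np.clip(data, 0, None) * spec.poisson_scale) / spec.poisson_scale

    res_ratios, res_ai = _resolution_truth(grid, spec)
    truth = PhantomTruth(
        ratios=truth_ratios,
        ai=ai,
        ratios_at_resolution=res_ratios,
        ai_at_resolution=res_ai,
        seed=seed,
        flags=flags,
        deformation_amplitude_mm=spec.deformation_amplitude_mm,
    )
    atlas, _ = grid_assets(grid)
    return Volume(data, grid), atlas, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: accumulation-type mix of a referral population (fractions sum to 1)
DEFAULT_TYPE_MIX = {
    "normal": 136 / 300,
    "eagle_wing": 42 / 300,
    "egg_shape": 86 / 300,
    "mixed": 23 / 300,
    "burst": 13 / 300,
}

ACCUMULATION_TYPES = tuple(DEFAULT_TYPE_MIX)


def _type_params(kind: str, rng: np.random.Generator) -> dict:
    """Per-type parameter ranges; the generator's own conventions."""
    u = rng.uniform

    def asym(base: float, rel: float) -> tuple[float, float]:
        d = u(0.0, rel)
        if rng.random() < 0.5:
            return base * (1 + d / 2), base * (1 - d / 2)
        return base * (1 - d / 2), base * (1 + d / 2)

    if kind == "normal":
        cl, cr = asym(u(3.5, 5.5), 0.06)
        pl, pr = asym(u(3.5, 5.5), 0.06)
        fl = fr = 1.0
    elif kind == "eagle_wing":
        cl, cr = asym(u(2.5, 4.0), 0.2)
        pl, pr = asym(u(1.4, 2.2), 0.25)
        fl, fr = u(0.55, 0.8), u(0.55, 0.8)
    elif kind == "egg_shape":
        cl, cr = asym(u(1.5, 2.5), 0.2)
        pl, pr = asym(u(1.3, 2.0), 0.2)
        fl, fr = u(0.3, 0.6), u(0.3, 0.6)
    elif kind == "mixed":
        # one near-normal and one egg-like hemisphere
        normal_left = rng.random() < 0.5
        cn, pn, fn = u(3.0, 4.5), u(2.5, 4.0), u(0.85, 1.0)
        ce, pe, fe = u(1.5, 2.5), u(1.3, 1.8), u(0.35, 0.6)
        if normal_left:
            cl, pl, fl, cr, pr, fr = cn, pn, fn, ce, pe, fe
        else:
            cl, pl, fl, cr, pr, fr = ce, pe, fe, cn, pn, fn
    elif kind == "burst":
        cl, cr = asym(u(1.05, 1.4), 0.15)
        pl, pr = asym(u(1.05, 1.4), 0.15)
        fl, fr = u(0.25, 0.45), u(0.25, 0.45)
    else:
        raise ValueError(f"unknown accumulation type {kind!r}")
    return dict(
        caudate_ratio_left=max(cl, 1.0),
        caudate_ratio_right=max(cr, 1.0),
        putamen_ratio_left=max(pl, 1.0),
        putamen_ratio_right=max(pr, 1.0),
        putamen_posterior_fraction_left=fl,
        putamen_posterior_fraction_right=fr,
    )


def generate_cohort(
    n: int,
    type_mix: dict | None = None,
    seed: int | None = None,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[str, PhantomSpec, Volume, LabelVolume, PhantomTruth]]:
    """A reproducible cohort of phantoms drawn from the type mix.

    Returns one (type, spec, volume, atlas, truth) tuple per subject.
    ``base_spec`` carries the grid, noise, blur and deformation settings
    shared by the cohort; the per-type uptake parameters are drawn on
    top of it.
    """
    mix = dict(type_mix or DEFAULT_TYPE_MIX)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"type proportions sum to {total}, expected 1")
    rng = np.random.default_rng(seed)
    base = base_spec or PhantomSpec()
    kinds = list(mix)
    probs = np.array([mix[k] for k in kinds])
    out = []
    for i in range(int(n)):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        spec = replace(base, **_type_params(kind, rng))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vol, atlas, truth = generate_phantom(spec, seed=sub_seed)
        out.append((kind, spec, vol, atlas, truth))
    return out


def ratio_ladder_specs(
    n: int,
    seed: int | None = None,
    base_spec: PhantomSpec | None = None,
    asymmetric_fraction: float = 1 / 3,
) -> list[PhantomSpec]:
    """A cohort design spanning true striatal ratios ~1.5-6 for linearity
    studies: uptake levels drawn uniformly over the clinical range, with a
    configurable fraction of clearly asymmetric subjects (relative
    left/right difference 0.25-0.45) and posterior putamen loss at the
    lower levels."""
    rng = np.random.default_rng(seed)
    base = base_spec or PhantomSpec()
    specs = []
    for i in range(int(n)):
        level = rng.uniform(1.5, 6.5)
        if rng.random() < asymmetric_fraction:
            asym = rng.uniform(0.25, 0.45)
        else:
            asym = rng.uniform(0.0, 0.1)
        cl, cr = level * (1 + asym / 2), level * (1 - asym / 2)
        specs.append(
            replace(
                base,
                caudate_ratio_left=max(cl, 1.0),
                caudate_ratio_right=max(cr, 1.0),
                putamen_ratio_left=max(cl * rng.uniform(0.85, 1.1), 1.0),
                putamen_ratio_right=max(cr * rng.uniform(0.85, 1.1), 1.0),
                putamen_posterior_fraction_left=1.0 if cl > 3 else rng.uniform(0.4, 0.9),
                putamen_posterior_fraction_right=1.0 if cr > 3 else rng.uniform(0.4, 0.9),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# template-pair assets built from phantoms
# ---------------------------------------------------------------------------


def make_template_pair(
    grid_shape=(64, 64, 64),
    spacing=3.44,
    seed: int = 0,
    n_subjects: int = 8,
):
    """Build normal and egg-shape templates from averaged phantom cohorts.

    Emulates the template-construction protocol: ``n_subjects``
    standardized subjects per class, each occipital-normalized, then
    voxelwise averaged.  Returns (pair, atlas, vois) on the given grid;
    the VOI set comes from the canonical atlas so the occipital
    normalization uses the same reference as the quantification.
    """
    from .templates import TemplatePair, build_template
    from .voi import standard_voi_set

    base = PhantomSpec(
        shape=tuple(grid_shape),
        spacing=(spacing, spacing, spacing) if np.isscalar(spacing) else tuple(spacing),
    )
    grid = base.grid()
    atlas = canonical_atlas(grid)
    vois = standard_voi_set(atlas)
    rng = np.random.default_rng(seed)

    def parents(kind: str) -> list[Volume]:
        vols = []
        for _ in range(n_subjects):
            spec = replace(base, **_type_params(kind, rng))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vol, _, _ = generate_phantom(spec, seed=int(rng.integers(0, 2**31 - 1)))
            vols.append(vol)
        return vols

    normal = build_template(parents("normal"), vois["occipital"])
    egg = build_template(parents("egg_shape"), vois["occipital"])
    pair = TemplatePair(normal, egg, occipital=vois["occipital"])
    return pair, atlas, vois
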