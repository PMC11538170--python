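"""Linear and nonlinear spatial normalization to a template.

The linear stage is a 12-parameter affine (translation, rotation,
log-scale, shear) maximizing zero-mean normalized cross-correlation
(ZNCC) under a brain mask, optimized with a derivative-free Powell
search over a 3-level multiresolution pyramid.  The nonlinear stage is
a small-deformation demons-style iteration with Gaussian field
regularization and an accept-only-if-improved update rule, so the
masked ZNCC is non-decreasing by construction.

Both stages are deterministic: fixed schedules, no stochastic sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .imaging_core import (
    FWHM_PER_SIGMA,
    BinaryVOI,
    Grid,
    Volume,
    fwhm_to_sigma,
    grids_compatible,
)


class RegistrationError(RuntimeError):
    """Raised when an optimization diverges or a field folds."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform:
    """A 4x4 world->world map; by convention fixed-world -> moving-world.

    Resampling the moving image through this transform onto the fixed
    grid aligns it with the fixed image (pull-back convention).
    """

    matrix: np.ndarray
    metric_value: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine transform must be 4x4")
        det = float(np.linalg.det(self.matrix[:3, :3]))
        if not (0.2 <= abs(det) <= 5.0):
            raise ValueError(f"affine determinant {det:.4g} outside sanity bounds [0.2, 5]")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def __call__(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))


def params_to_matrix(params: np.ndarray) -> np.ndarray:
    """Build a 4x4 matrix from 12 parameters.

    Layout: translation (mm, 3), rotation (rad, 3, applied x-y-z),
    log-scale (3), shear (xy, xz, yz).  Matrix = T . Rx Ry Rz . Shear . Scale.
    """
    t = params[0:3]
    rx, ry, rz = params[3:6]
    scale = np.exp(params[6:9])
    hxy, hxz, hyz = params[9:12]

    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    R = (
        np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        @ np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        @ np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    )
    H = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]], dtype=float)
    M = np.eye(4)
    M[:3, :3] = R @ H @ np.diag(scale)
    M[:3, 3] = t
    return M


@dataclass
class DeformationField:
    """Per-voxel displacement (mm, world offsets) on the template grid.

    The induced map is phi(x) = x + u(x); sampling the moving image at
    phi(x) pulls it into template space.  Grids must be axis-aligned
    (diagonal affine) — all template grids in this package are.
    """

    displacement: np.ndarray  # (3, nx, ny, nz), mm
    grid: Grid
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.shape != (3, *self.grid.shape):
            raise ValueError("displacement must be (3, nx, ny, nz) on the grid")
        _require_axis_aligned(self.grid)

    @classmethod
    def zero(cls, grid: Grid) -> "DeformationField":
        return cls(np.zeros((3, *grid.shape)), grid)

    def warp(self, vol: Volume) -> Volume:
        """Resample a volume on the same grid through phi(x) = x + u(x)."""
        if not grids_compatible(vol.grid, self.grid):
            raise ValueError("volume is not on the deformation grid")
        coords = _phi_voxel_coords(self.displacement, self.grid)
        data = ndimage.map_coordinates(
            vol.data, coords, order=1, mode="constant", cval=0.0, prefilter=False
        )
        return Volume(data.reshape(self.grid.shape), self.grid)

    def jacobian_determinants(self) -> np.ndarray:
        """Voxelwise det of d(phi)/dx; positive everywhere means no folding."""
        sp = self.grid.spacing
        J = np.empty((3, 3, *self.grid.shape))
        for i in range(3):
            grads = np.gradient(self.displacement[i], *sp)
            for j in range(3):
                J[i, j] = grads[j]
        for i in range(3):
            J[i, i] += 1.0
        J = np.moveaxis(J, (0, 1), (-2, -1))
        return np.linalg.det(J)

    def check_no_folding(self) -> None:
        dets = self.jacobian_determinants()
        interior = dets[1:-1, 1:-1, 1:-1]
        if interior.min() <= 0:
            loc = np.unravel_index(int(np.argmin(interior)), interior.shape)
            loc = tuple(int(v) + 1 for v in loc)
            raise RegistrationError(
                f"deformation field folds (Jacobian {interior.min():.4g} at voxel {loc})"
            )

    def max_displacement(self) -> float:
        return float(np.sqrt((self.displacement**2).sum(axis=0)).max())


def _min_jacobian(displacement: np.ndarray, spacing) -> float:
    """Minimum Jacobian determinant of x -> x + u(x), forward differences.

    Forward differences see single-voxel slopes that central differences
    average away, so this is the stricter guard for accept/reject tests.
    """
    core = tuple([slice(0, s - 1) for s in displacement.shape[1:]])
    J = np.empty((3, 3, *[s - 1 for s in displacement.shape[1:]]))
    for i in range(3):
        ui = displacement[i]
        for j in range(3):
            shifted = np.roll(ui, -1, axis=j)
            J[i, j] = ((shifted - ui) / spacing[j])[core]
    for i in range(3):
        J[i, i] += 1.0
    dets = np.linalg.det(np.moveaxis(J, (0, 1), (-2, -1)))
    return float(dets.min())


def _require_axis_aligned(grid: Grid) -> None:
    lin = grid.affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-9):
        raise ValueError("deformation fields require an axis-aligned grid")


def _phi_voxel_coords(displacement: np.ndarray, grid: Grid) -> np.ndarray:
    sp = grid.spacing
    idx = np.indices(grid.shape, dtype=np.float64)
    coords = np.empty((3, int(np.prod(grid.shape))))
    for ax in range(3):
        coords[ax] = (idx[ax] + displacement[ax] / sp[ax]).ravel()
    return coords


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def _zncc_vals(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


# ---------------------------------------------------------------------------
# affine registration
# ---------------------------------------------------------------------------


@dataclass
class AffineConfig:
    levels: int = 3
    max_evals_per_level: tuple[int, ...] = (400, 300, 150)
    smooth_factor_fwhm: float = 1.0  # FWHM per downsampling factor, in voxels
    # optimizer step scale per parameter block
    scales: tuple[float, ...] = (10.0, 10.0, 10.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.05, 0.05, 0.05)


def _smoothed(vol: Volume, fwhm_vox: float) -> Volume:
    if fwhm_vox <= 0.01:
        return vol
    sigma = fwhm_to_sigma(fwhm_vox)
    return vol.copy_with(
        ndimage.gaussian_filter(vol.data, sigma=sigma, mode="constant", cval=0.0)
    )


def _default_mask(fixed: Volume, frac: float = 0.1) -> np.ndarray:
    return fixed.data > frac * fixed.data.max()


def _center_of_mass_world(vol: Volume) -> np.ndarray:
    d = np.clip(vol.data, 0, None)
    total = d.sum()
    if total <= 0:
        return vol.grid.voxel_to_world((np.asarray(vol.grid.shape) - 1) / 2.0)
    com_vox = np.array(ndimage.center_of_mass(d))
    return vol.grid.voxel_to_world(com_vox)


def affine_register(
    moving: Volume,
    fixed: Volume,
    mask: BinaryVOI | None = None,
    config: AffineConfig | None = None,
) -> AffineTransform:
    """Recover the 12-parameter world map aligning moving to fixed.

    Maximizes ZNCC between the fixed image and the moving image sampled
    through the candidate transform, over the masked fixed voxels only.
    Raises :class:`RegistrationError` if the final similarity is below
    the identity-initialized starting value.
    """
    cfg = config or AffineConfig()
    if moving.data.std() == 0 or fixed.data.std() == 0:
        raise ValueError("cannot register constant volumes")
    mask_arr = mask.mask if mask is not None else _default_mask(fixed)
    if mask_arr.sum() < 8:
        raise ValueError("similarity mask too small for affine registration")

    # initialize translation from centers of mass
    init = np.zeros(12)
    init[:3] = _center_of_mass_world(moving) - _center_of_mass_world(fixed)

    scales = np.asarray(cfg.scales)
    params = init.copy()
    trace: list[tuple[int, float]] = []

    ijk = np.argwhere(mask_arr)
    xyz_full = fixed.grid.voxel_to_world(ijk)
    fvals_full = fixed.data[mask_arr]
    inv_mov = np.linalg.inv(moving.grid.affine)

    def metric(mat: np.ndarray, xyz, fvals, mov_data) -> float:
        src = xyz @ mat[:3, :3].T + mat[:3, 3]
        vox = src @ inv_mov[:3, :3].T + inv_mov[:3, 3]
        vals = ndimage.map_coordinates(
            mov_data, vox.T, order=1, mode="constant", cval=0.0, prefilter=False
        )
        return _zncc_vals(vals, fvals)

    start_score = metric(params_to_matrix(params), xyz_full, fvals_full, moving.data)

    for level in range(cfg.levels):
        factor = 2 ** (cfg.levels - 1 - level)
        fwhm_vox = cfg.smooth_factor_fwhm * (factor - 1)
        mov_s = _smoothed(moving, fwhm_vox)
        # coarse levels: smoothed images, strided subset of masked voxels
        sel = slice(None, None, factor**2) if factor > 1 else slice(None)
        xyz = xyz_full[sel]
        fix_s = _smoothed(fixed, fwhm_vox)
        fvals = fix_s.data[mask_arr][sel]
        if len(fvals) < 8 or fvals.std() == 0:
            continue

        def objective(z):
            return -metric(
                params_to_matrix(z * scales), xyz, fvals, mov_s.data
            )

        res = optimize.minimize(
            objective,
            params / scales,
            method="Powell",
            options={
                "maxfev": cfg.max_evals_per_level[min(level, len(cfg.max_evals_per_level) - 1)],
                "xtol": 1e-4,
                "ftol": 1e-7,
            },
        )
        params = res.x * scales
        trace.append((factor, -float(res.fun)))

    final_score = metric(params_to_matrix(params), xyz_full, fvals_full, moving.data)
    if final_score < start_score - 1e-9:
        raise RegistrationError(
            f"affine registration diverged (ZNCC {start_score:.4f} -> {final_score:.4f})",
            trace=trace,
        )
    return AffineTransform(params_to_matrix(params), metric_value=final_score)


# ---------------------------------------------------------------------------
# nonlinear (demons-style) registration
# ---------------------------------------------------------------------------


@dataclass
class NonlinearConfig:
    levels: int = 3
    iterations_per_level: tuple[int, ...] = (40, 30, 25)
    field_smoothing_fwhm: float = 3.0  # mm, diffusion-like regularization
    update_smoothing_fwhm: float = 6.0  # mm, fluid-like update smoothing
    max_step_mm: float = 2.0  # displacement added per iteration, capped
    max_displacement: float = 15.0  # mm, total field magnitude cap
    mask_fraction: float = 0.1  # template mask = voxels > fraction * max


def _downsample(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    sm = _smoothed(vol, float(factor))
    data = sm.data[::factor, ::factor, ::factor]
    aff = vol.grid.affine.copy()
    aff[:3, :3] *= factor
    return Volume(data, Grid(data.shape, aff))


def _upsample_field(disp: np.ndarray, src_grid: Grid, dst_grid: Grid) -> np.ndarray:
    out = np.empty((3, *dst_grid.shape))
    inv = np.linalg.inv(src_grid.affine)
    xyz = dst_grid.world_coordinates().reshape(-1, 3)
    vox = xyz @ inv[:3, :3].T + inv[:3, 3]
    for ax in range(3):
        out[ax] = ndimage.map_coordinates(
            disp[ax], vox.T, order=1, mode="nearest", prefilter=False
        ).reshape(dst_grid.shape)
    return out


def nonlinear_register(
    moving: Volume,
    template: Volume,
    config: NonlinearConfig | None = None,
    init_field: DeformationField | None = None,
    mask: BinaryVOI | None = None,
) -> DeformationField:
    """Estimate a smooth displacement field warping moving onto template.

    The moving image must already be affine-aligned and resampled onto
    the template grid.  Each iteration computes demons forces (with the
    warped image fitted to the template by gain/offset under the mask,
    so the SSD force direction also increases correlation), smooths the
    update fluid-style, composes it with the accumulated field, and
    applies light diffusion smoothing; an iteration is kept only if it
    improves the masked ZNCC and the map stays diffeomorphic, so the
    similarity of the returned field never falls below its starting
    value.  Raises on folding.
    """
    cfg = config or NonlinearConfig()
    if not grids_compatible(moving.grid, template.grid):
        raise ValueError("moving volume must be resampled onto the template grid")
    grid = template.grid
    mask_full = mask.mask if mask is not None else _default_mask(template, cfg.mask_fraction)

    field: np.ndarray | None = None
    field_grid: Grid | None = None
    if init_field is not None:
        field = init_field.displacement.copy()
        field_grid = init_field.grid

    trace = []
    for level in range(cfg.levels):
        factor = 2 ** (cfg.levels - 1 - level)
        mov_l = _downsample(moving, factor)
        tpl_l = _downsample(template, factor)
        m = mov_l.data
        f = tpl_l.data
        g_l = tpl_l.grid
        sp = g_l.spacing
        msk = mask_full[::factor, ::factor, ::factor]
        if field is None:
            u = np.zeros((3, *g_l.shape))
        elif grids_compatible(field_grid, g_l):
            u = field
        else:
            u = _upsample_field(field, field_grid, g_l)

        # keep regularization meaningful on coarse lattices: the fluid
        # kernel never drops below ~1.5 voxels FWHM, the diffusion kernel
        # below ~0.8 voxels, at the level's own spacing
        sigma_update = np.maximum(cfg.update_smoothing_fwhm, 1.5 * sp) / FWHM_PER_SIGMA / sp
        sigma_field = np.maximum(cfg.field_smoothing_fwhm, 0.8 * sp) / FWHM_PER_SIGMA / sp
        grad_f = np.gradient(f, *sp)
        g2 = sum(g * g for g in grad_f)
        kappa = 1.0 / float(np.mean(sp)) ** 2
        lidx = np.indices(g_l.shape, dtype=np.float64)

        def warp_score(u_arr):
            coords = _phi_voxel_coords(u_arr, g_l)
            w = ndimage.map_coordinates(
                m, coords, order=1, mode="constant", cval=0.0, prefilter=False
            ).reshape(g_l.shape)
            return w, _zncc_vals(w[msk], f[msk])

        warped, score = warp_score(u)
        n_iter = cfg.iterations_per_level[min(level, len(cfg.iterations_per_level) - 1)]
        step = 1.0
        for _ in range(n_iter):
            # fit gain/offset of the warped image to the template under the
            # mask: SSD forces then point in the direction that increases
            # correlation, even when subject and template contrast differ
            wm = warped[msk]
            var_w = float(np.var(wm))
            if var_w == 0:
                break
            gain = float(np.cov(wm, f[msk])[0, 1]) / var_w
            offset = float(f[msk].mean()) - gain * float(wm.mean())
            diff = f - (gain * warped + offset)
            denom = g2 + kappa * diff * diff
            with np.errstate(divide="ignore", invalid="ignore"):
                du = np.where(denom > 1e-12, diff / denom, 0.0)[None] * np.stack(grad_f)
            for ax in range(3):
                du[ax] = ndimage.gaussian_filter(du[ax], sigma_update, mode="nearest")
            mag = np.sqrt((du**2).sum(axis=0))
            cap = cfg.max_step_mm * step
            scale_arr = np.where(mag > cap, cap / np.maximum(mag, 1e-12), 1.0)
            du *= scale_arr[None]
            # compositive update: u_new(x) = u(x + du(x)) + du(x), then
            # light diffusion smoothing of the whole field
            dcoords = np.empty((3, int(np.prod(g_l.shape))))
            for ax in range(3):
                dcoords[ax] = (lidx[ax] + du[ax] / sp[ax]).ravel()
            u_trial = np.empty_like(u)
            for ax in range(3):
                u_trial[ax] = ndimage.map_coordinates(
                    u[ax], dcoords, order=1, mode="nearest", prefilter=False
                ).reshape(g_l.shape) + du[ax]
                u_trial[ax] = ndimage.gaussian_filter(u_trial[ax], sigma_field, mode="nearest")
            tot = np.sqrt((u_trial**2).sum(axis=0))
            over = tot > cfg.max_displacement
            if over.any():
                u_trial *= np.where(over, cfg.max_displacement / tot, 1.0)[None]
            w_trial, s_trial = warp_score(u_trial)
            # accept only if the similarity improves AND the map stays
            # diffeomorphic (interior Jacobian bounded away from zero)
            if s_trial > score and _min_jacobian(u_trial, sp) > 0.05:
                u, warped, score = u_trial, w_trial, s_trial
                step = min(step * 1.2, 1.0)
            else:
                step *= 0.5
                if step < 1e-3:
                    break
        trace.append((factor, float(score)))
        field, field_grid = u, g_l

    out = DeformationField(
        field,
        grid,
        meta={
            "trace": trace,
            "field_smoothing_fwhm": cfg.field_smoothing_fwhm,
            "iterations": list(cfg.iterations_per_level),
        },
    )
    out.check_no_folding()
    return out


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def apply_normalization(
    subject: Volume,
    affine: AffineTransform,
    field: DeformationField | None,
) -> Volume:
    """Warp a subject into template space with a single interpolation.

    The nonlinear map and the affine are composed before resampling
    (template world x -> affine(x + u(x)) -> subject world), so the
    subject is interpolated exactly once.
    """
    if field is None:
        raise ValueError("apply_normalization requires a deformation field "
                         "(use DeformationField.zero for affine-only)")
    grid = field.grid
    xyz = grid.world_coordinates().reshape(-1, 3)
    u = field.displacement.reshape(3, -1).T
    src_world = affine(xyz + u)
    inv = np.linalg.inv(subject.grid.affine)
    vox = src_world @ inv[:3, :3].T + inv[:3, 3]
    data = ndimage.map_coordinates(
        subject.data, vox.T, order=1, mode="constant", cval=0.0, prefilter=False
    )
    return Volume(data.reshape(grid.shape), grid)
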