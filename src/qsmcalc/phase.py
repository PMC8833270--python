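"""Phase processing: unwrapping, background-field removal, detrending,
and multi-echo combination.

The chain applied to each echo of the gradient-echo acquisition is

    wrapped phase --Laplacian unwrap--> phase --/(2 pi TE)--> field (Hz)
    --LBV--> --V-SHARP--> --4th-order polynomial detrend--> per-echo local
    field

after which the per-echo local fields are merged into one map by a
T2*-weighted average.  Background fields (from sources outside the region
of interest: air, container walls, bowel gas) are harmonic inside the ROI,
which both removal methods exploit:

* LBV solves the Laplace boundary-value problem for the harmonic component
  matching the total field on the ROI boundary and subtracts it;
* V-SHARP subtracts the spherical-mean value of the field (harmonic
  functions equal their spherical means) using the largest kernel that fits
  inside the ROI at each voxel, then deconvolves the residual high-pass
  filter by truncated k-space division.

The Laplacian unwrapper solves  lap(phi_u) = cos(phi) lap(sin phi)
- sin(phi) lap(cos phi)  with a DCT-diagonalized 7-point Laplacian
(Neumann/mirror boundary), which recovers wraps without path following;
harmonic components of the true phase that the Laplacian cannot see are
deliberately left to the background-removal stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, cg

from .core_io import (
    AcquisitionProtocol,
    Mask,
    ScalarVolume,
    ValidationError,
    VoxelGrid,
)

__all__ = [
    "BackgroundRemovalResult",
    "ConvergenceError",
    "laplacian_unwrap",
    "unwrap_echo_train",
    "lbv_background_removal",
    "vsharp_background_removal",
    "VSharpOperator",
    "poly4_detrend",
    "per_echo_field",
    "t2star_weighted_combine",
    "DEFAULT_VSHARP_RADII_MM",
]

#: Spherical-mean kernel radii: 1 to 25 mm at 2 mm intervals (13 radii).
DEFAULT_VSHARP_RADII_MM = tuple(float(r) for r in range(1, 26, 2))


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance."""


@dataclass
class BackgroundRemovalResult:
    """Local field plus the mask of voxels where the estimate is trusted."""

    local_field: ScalarVolume
    valid_mask: Mask


# ---------------------------------------------------------------------------
# DCT-based discrete Laplacian (Neumann boundary)
# ---------------------------------------------------------------------------

def _dct_eigenvalues(shape, voxel_size_mm) -> np.ndarray:
    """Eigenvalues of the 7-point FD Laplacian under DCT-II (mirror) BCs."""
    lam = np.zeros(shape)
    for ax, (n, h) in enumerate(zip(shape, voxel_size_mm)):
        k = np.arange(n)
        lam_ax = (2.0 * np.cos(np.pi * k / n) - 2.0) / h**2
        sh = [1, 1, 1]
        sh[ax] = n
        lam = lam + lam_ax.reshape(sh)
    return lam


def _dct_laplacian(data: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return sfft.idctn(lam * sfft.dctn(data, type=2, norm="ortho"), type=2, norm="ortho")


def _dct_poisson(rhs: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Solve lap(u) = rhs with Neumann BC; the mean (zero eigenvalue) is 0."""
    spec = sfft.dctn(rhs, type=2, norm="ortho")
    with np.errstate(divide="ignore", invalid="ignore"):
        spec = spec / lam
    spec.flat[0] = 0.0
    return sfft.idctn(spec, type=2, norm="ortho")


def laplacian_unwrap(phase: ScalarVolume, congruent: bool = True) -> ScalarVolume:
    """3D Laplacian-based phase unwrapping.

    Computes the Laplacian of the true phase from sin/cos of the wrapped
    input (both continuous across wraps) and inverts it with a DCT Poisson
    solve (Neumann/mirror boundary, zero mean).  With ``congruent``
    (default) the smooth Poisson estimate is then snapped back to the
    measured phase modulo 2 pi: a global phase offset is removed by the
    circular mean and each voxel's wrap count is taken from the estimate.
    This leaves the result *exactly* congruent to the input and confines
    any estimation error to isolated integer-wrap mistakes where the
    underlying phase is spatially undersampled, instead of letting it
    spread smoothly.  Components of the true phase that are harmonic under
    the discrete Laplacian and exceed pi cannot be recovered by any purely
    Laplacian method; downstream background removal absorbs them.
    """
    if phase.quantity != "phase_rad":
        raise ValidationError("laplacian_unwrap expects a phase_rad volume")
    p = np.asarray(phase.data, dtype=np.float64)
    if not np.all(np.isfinite(p)):
        raise ValidationError("phase contains non-finite values")
    lam = _dct_eigenvalues(p.shape, phase.grid.voxel_size_mm)
    s, c = np.sin(p), np.cos(p)
    rhs = c * _dct_laplacian(s, lam) - s * _dct_laplacian(c, lam)
    est = _dct_poisson(rhs, lam)
    if not congruent:
        return phase.with_data(est)
    delta = est - p
    offset = np.angle(np.exp(1j * delta).mean())
    out = p + offset + 2.0 * np.pi * np.round((delta - offset) / (2.0 * np.pi))
    return phase.with_data(out)


def unwrap_echo_train(
    phases: list[ScalarVolume], te_s: list[float]
) -> list[ScalarVolume]:
    """Unwrap a multi-echo phase train with temporal guidance.

    The first (shortest-TE) echo is unwrapped spatially with the Laplacian
    method — at short TE the voxel-to-voxel phase steps stay below pi even
    next to strong susceptibility sources, so the congruent estimate is
    wrap-exact.  Later echoes are then wrap-corrected against the
    TE-scaled first-echo phase: the signal model has no phase at TE = 0,
    so the true phase is proportional to TE and the scaled early-echo
    phase predicts each later echo to well within half a cycle wherever
    the first echo was unwrapped correctly.  This avoids the wrap-count
    mistakes a purely spatial unwrap makes at long TE, where phase
    gradients near sources exceed pi per voxel.
    """
    if len(phases) != len(te_s):
        raise ValidationError(f"{len(phases)} phase images but {len(te_s)} echo times")
    if any(t <= 0 for t in te_s):
        raise ValidationError("echo times must be positive")
    first = laplacian_unwrap(phases[0])
    out = [first]
    for pha, te in zip(phases[1:], te_s[1:]):
        pred = first.data * (te / te_s[0])
        p = np.asarray(pha.data, dtype=np.float64)
        corrected = p + 2.0 * np.pi * np.round((pred - p) / (2.0 * np.pi))
        out.append(pha.with_data(corrected))
    return out


# ---------------------------------------------------------------------------
# LBV background removal
# ---------------------------------------------------------------------------

def _fd_laplacian(u: np.ndarray, h: tuple[float, float, float]) -> np.ndarray:
    """7-point Laplacian with zero (Dirichlet) padding outside the array."""
    out = np.zeros_like(u)
    for ax in range(3):
        inv_h2 = 1.0 / h[ax] ** 2
        out -= 2.0 * inv_h2 * u
        up = np.roll(u, 1, axis=ax)
        dn = np.roll(u, -1, axis=ax)
        # zero the wrapped faces
        sl = [slice(None)] * 3
        sl[ax] = 0
        up[tuple(sl)] = 0.0
        sl[ax] = -1
        dn[tuple(sl)] = 0.0
        out += inv_h2 * (up + dn)
    return out


def lbv_background_removal(
    total_field: ScalarVolume,
    mask: Mask,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> BackgroundRemovalResult:
    """Background removal by the Laplacian boundary-value method.

    The background field is the harmonic function inside the ROI that
    matches the total field on the ROI boundary shell; it is found by a
    preconditioned conjugate-gradient solve of the interior Laplace
    problem (7-point stencil, DCT Poisson preconditioner on the bounding
    box).  ``valid_mask`` is the ROI eroded by one voxel.
    """
    mask.require_nonempty()
    if not mask.grid.same_geometry(total_field.grid):
        raise ValidationError("mask grid does not match field grid")
    m = mask.data
    interior = ndimage.binary_erosion(m)
    boundary = m & ~interior
    grid = total_field.grid
    h = grid.voxel_size_mm
    f = np.asarray(total_field.data, dtype=np.float64)

    if not interior.any():
        # degenerate thin ROI: nothing trusted after erosion
        local = np.zeros_like(f)
        return BackgroundRemovalResult(
            ScalarVolume(grid, local, "field_Hz"), Mask(grid, interior)
        )

    # crop to the mask bounding box (+1 margin) for solver efficiency
    idx = np.argwhere(m)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, m.shape)
    box = tuple(slice(lo[d], hi[d]) for d in range(3))
    mb, ib, bb = m[box], interior[box], boundary[box]
    fb_box = f[box]
    n_int = int(ib.sum())

    # Dirichlet data: total field on the boundary shell, 0 elsewhere.
    # With u the interior part of the harmonic background, lap(u + g) = 0
    # inside, i.e. (-lap) u = +lap(g) restricted to the interior.
    g = np.where(bb, fb_box, 0.0)
    rhs = _fd_laplacian(g, h)[ib]

    lam = _dct_eigenvalues(mb.shape, h)
    lam_safe = lam.copy()
    lam_safe.flat[0] = -np.min(np.abs(lam[lam != 0]))

    def matvec(x):
        u = np.zeros(mb.shape)
        u[ib] = x
        return -_fd_laplacian(u, h)[ib]

    def precond(x):
        u = np.zeros(mb.shape)
        u[ib] = x
        spec = sfft.dctn(u, type=2, norm="ortho") / (-lam_safe)
        return sfft.idctn(spec, type=2, norm="ortho")[ib]

    A = LinearOperator((n_int, n_int), matvec=matvec, dtype=np.float64)
    M = LinearOperator((n_int, n_int), matvec=precond, dtype=np.float64)
    x0 = fb_box[ib]  # total field is a decent initial harmonic guess
    sol, info = cg(A, rhs, x0=x0, rtol=tol, maxiter=max_iter, M=M)
    if info > 0:
        res = float(np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
        raise ConvergenceError(
            f"LBV conjugate gradient did not reach rtol {tol} in {max_iter} "
            f"iterations (relative residual {res:.3e})"
        )

    background_box = g.copy()
    background_box[ib] = sol
    local = np.zeros_like(f)
    local_box = np.where(mb, fb_box - background_box, 0.0)
    local[box] = local_box
    valid = np.zeros_like(m)
    valid[box] = ib
    local[~valid] = 0.0
    return BackgroundRemovalResult(
        ScalarVolume(grid, local, "field_Hz"), Mask(grid, valid)
    )


# ---------------------------------------------------------------------------
# V-SHARP background removal
# ---------------------------------------------------------------------------

def _sphere_kernel(radius_mm: float, voxel_size_mm) -> np.ndarray:
    """Normalized spherical-mean kernel rasterized on the voxel lattice."""
    half = [max(int(np.floor(radius_mm / v)), 0) for v in voxel_size_mm]
    ax = [np.arange(-hh, hh + 1) * v for hh, v in zip(half, voxel_size_mm)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    ker = (X**2 + Y**2 + Z**2 <= radius_mm**2).astype(np.float64)
    ker[tuple(h for h in half)] = 1.0  # centre voxel always included
    return ker / ker.sum()


class VSharpOperator:
    """Precomputed V-SHARP machinery for one (grid, mask, radii) triple.

    Holds the k-space spherical-mean kernels and the per-radius eroded
    masks so the filter can be applied to many echoes without recomputing
    FFTs of the kernels.
    """

    def __init__(
        self,
        grid: VoxelGrid,
        mask: Mask,
        kernel_radii_mm=DEFAULT_VSHARP_RADII_MM,
        tsvd_threshold: float = 0.05,
    ):
        radii = tuple(float(r) for r in kernel_radii_mm)
        if len(radii) == 0:
            raise ValidationError("kernel_radii_mm must be non-empty")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValidationError("kernel radii must be sorted ascending")
        if tsvd_threshold <= 0:
            raise ValidationError("tsvd_threshold must be positive")
        mask.require_nonempty()
        self.grid = grid
        self.radii = radii
        self.tsvd_threshold = float(tsvd_threshold)
        self.shape = grid.shape

        # radii whose rasterized kernel exceeds the grid can never fit
        radii = tuple(
            r for r in radii
            if all(
                2 * int(np.floor(r / v)) + 1 <= n
                for v, n in zip(grid.voxel_size_mm, grid.shape)
            )
        )
        if not radii:
            raise ValidationError("no V-SHARP kernel fits inside the grid")
        self.radii = radii

        maskf = mask.data.astype(np.float64)
        Fm = sfft.rfftn(maskf)
        self.kernel_ffts = []
        self.fit_masks = []  # kernel fully inside the ROI
        for r in radii:
            ker = _sphere_kernel(r, grid.voxel_size_mm)
            K = np.zeros(self.shape)
            ks = ker.shape
            K[: ks[0], : ks[1], : ks[2]] = ker
            K = np.roll(K, [-(s // 2) for s in ks], axis=(0, 1, 2))
            Fk = sfft.rfftn(K)
            self.kernel_ffts.append(Fk)
            inside = sfft.irfftn(Fm * Fk, s=self.shape)
            self.fit_masks.append((inside >= 1.0 - 1e-6) & mask.data)
        # boundary voxels admit only the trivial (single-voxel) mean when a
        # kernel radius is below the voxel pitch, so always erode >= 1 voxel
        self.valid = self.fit_masks[0] & ndimage.binary_erosion(mask.data)
        if not self.valid.any():
            raise ValidationError(
                "mask vanishes after erosion by the smallest V-SHARP kernel"
            )
        # per-voxel assignment: largest kernel index that fits
        self.assignment = np.full(self.shape, -1, dtype=np.int8)
        for i, fm in enumerate(self.fit_masks):
            self.assignment[fm] = i

    def apply(self, total_field: ScalarVolume) -> BackgroundRemovalResult:
        f = np.asarray(total_field.data, dtype=np.float64)
        Ff = sfft.rfftn(f)
        highpass = np.zeros(self.shape)
        for i, Fk in enumerate(self.kernel_ffts):
            sel = self.assignment == i
            if not sel.any():
                continue
            smv = sfft.irfftn(Ff * Fk, s=self.shape)
            highpass[sel] = f[sel] - smv[sel]
        highpass[~self.valid] = 0.0
        # deconvolve (delta - SMV) using the largest kernel, truncated
        C = 1.0 - self.kernel_ffts[-1]
        Fh = sfft.rfftn(highpass)
        inv = np.where(np.abs(C) > self.tsvd_threshold, Fh / np.where(C == 0, 1.0, C), 0.0)
        local = sfft.irfftn(inv, s=self.shape)
        local = np.where(self.valid, local, 0.0)
        return BackgroundRemovalResult(
            ScalarVolume(self.grid, local, "field_Hz"),
            Mask(self.grid, self.valid.copy()),
        )


def vsharp_background_removal(
    total_field: ScalarVolume,
    mask: Mask,
    kernel_radii_mm=DEFAULT_VSHARP_RADII_MM,
    tsvd_threshold: float = 0.05,
    operator: VSharpOperator | None = None,
) -> BackgroundRemovalResult:
    """Variable-kernel SHARP background removal.

    At each ROI voxel the spherical-mean filter uses the *largest* listed
    kernel that fits entirely inside the ROI (default radii 1-25 mm at
    2 mm steps); the residual (delta - SMV) filter is inverted by truncated
    k-space division.  ``valid_mask`` is the ROI eroded by the smallest
    kernel radius.  Pass a prebuilt :class:`VSharpOperator` to amortize the
    kernel FFTs over multiple echoes.
    """
    if operator is None:
        operator = VSharpOperator(
            total_field.grid, mask, kernel_radii_mm, tsvd_threshold
        )
    return operator.apply(total_field)


# ---------------------------------------------------------------------------
# Polynomial detrending
# ---------------------------------------------------------------------------

def _poly_design(grid: VoxelGrid, mask: np.ndarray, order: int) -> np.ndarray:
    idx = np.argwhere(mask).astype(np.float64)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    u = 2.0 * (idx - lo) / span - 1.0  # normalized to [-1, 1] per axis
    cols = []
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                cols.append(u[:, 0] ** a * u[:, 1] ** b * u[:, 2] ** c)
    return np.stack(cols, axis=1)


def poly4_detrend(field: ScalarVolume, mask: Mask, order: int = 4) -> ScalarVolume:
    """Remove a 3D polynomial trend of total degree <= 4 inside the mask.

    Residual slowly-varying field (imperfect background removal, eddy
    currents) is fitted by ordinary least squares over the mask on
    coordinates normalized to [-1, 1] and subtracted; voxels outside the
    mask are zeroed.
    """
    mask.require_nonempty()
    n_terms = (order + 1) * (order + 2) * (order + 3) // 6
    if mask.count < n_terms:
        raise ValidationError(
            f"mask has {mask.count} voxels; need >= {n_terms} for degree-{order} fit"
        )
    X = _poly_design(field.grid, mask.data, order)
    y = np.asarray(field.data, dtype=np.float64)[mask.data]
    coef, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        raise np.linalg.LinAlgError(
            f"degenerate mask geometry: polynomial design rank {rank} < "
            f"{X.shape[1]} (condition number {cond:.3e})"
        )
    out = np.zeros_like(np.asarray(field.data, dtype=np.float64))
    out[mask.data] = y - X @ coef
    return ScalarVolume(field.grid, out, field.quantity)


# ---------------------------------------------------------------------------
# Field conversion and echo combination
# ---------------------------------------------------------------------------

def per_echo_field(phase_u: ScalarVolume, te_s: float) -> ScalarVolume:
    """Convert unwrapped phase (rad) at one echo to field in Hz: phase/(2 pi TE)."""
    if te_s <= 0:
        raise ValidationError("echo time must be positive")
    return ScalarVolume(phase_u.grid, phase_u.data / (2.0 * np.pi * te_s), "field_Hz")


def t2star_weighted_combine(
    fields: list[ScalarVolume],
    r2star: ScalarVolume,
    protocol: AcquisitionProtocol,
    te_s: list[float] | None = None,
    echo_magnitudes: list[np.ndarray] | None = None,
) -> ScalarVolume:
    """T2*-weighted average of per-echo field maps.

    SNR-optimal weights for phase-derived fields, ``w_i ~ TE_i exp(-TE_i
    R2*)``, normalized to sum 1 per voxel; where all weights underflow the
    first echo's field is used.  ``te_s`` overrides the protocol echo times
    when only a leading subset of echoes is combined.

    When the measured per-echo magnitude images are supplied the empirical
    form ``w_i ~ TE_i |S_i|`` is used instead: identical under pure
    mono-exponential decay (the M0 factor cancels in the normalization)
    but it additionally captures signal loss that the fitted R2* does not,
    notably intravoxel dephasing voids around strong susceptibility
    sources, where the late-echo phase carries no usable field
    information.
    """
    tes = list(te_s) if te_s is not None else list(protocol.te_s)
    if len(fields) != len(tes):
        raise ValidationError(
            f"{len(fields)} field maps but {len(tes)} echo times"
        )
    if np.any(r2star.data < 0):
        raise ValidationError("r2star must be >= 0")
    r2 = np.asarray(r2star.data, dtype=np.float64)
    if echo_magnitudes is not None:
        if len(echo_magnitudes) != len(tes):
            raise ValidationError(
                f"{len(echo_magnitudes)} magnitude images but {len(tes)} echo times"
            )
        weights = np.stack(
            [te * np.abs(np.asarray(m, dtype=np.float64))
             for te, m in zip(tes, echo_magnitudes)],
            axis=0,
        )
    else:
        weights = np.stack([te * np.exp(-te * r2) for te in tes], axis=0)
    total = weights.sum(axis=0)
    dead = total <= 1e-300
    total = np.where(dead, 1.0, total)
    stack = np.stack([np.asarray(f.data, dtype=np.float64) for f in fields], axis=0)
    combined = (weights * stack).sum(axis=0) / total
    combined = np.where(dead, stack[0], combined)
    return ScalarVolume(fields[0].grid, combined, "field_Hz")
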