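"""Dipole inversion: local field (Hz) -> susceptibility map (ppm).

The measured local field is the convolution of the susceptibility
distribution with the unit dipole response, diagonal in k-space:

    f(k) = D(k) chi(k),    D(k) = 1/3 - kz^2/|k|^2,  D(0) = 0.

D vanishes on the magic-angle cone kz^2/|k|^2 = 1/3, so the inverse
problem is ill-posed there and naive inversion produces streaking.  The
approach here is a masked least-squares (LSQR) first pass

    argmin_chi || Wt (F^-1 D F chi - f/(gamma B0 1e-6)) ||_2

followed by a streaking-reduction pass that replaces the k-space content
of the solution on the ill-conditioned cone (|D| below a threshold) with
the content of a spatially smooth prior (the Gaussian-filtered first-pass
map); all frequencies off the cone are left untouched.  No reference
region is subtracted: maps are relative, with zero k-space DC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy.sparse.linalg import LinearOperator, lsqr

from .core_io import (
    AcquisitionProtocol,
    Mask,
    ScalarVolume,
    ValidationError,
    VoxelGrid,
)
from .phantom import _dipole_kernel_freqs

__all__ = ["InversionConfig", "dipole_kernel", "lsqr_invert", "streak_reduction", "invert"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InversionConfig:
    lsqr_tol: float = 1e-4
    lsqr_max_iter: int = 200
    cone_threshold: float = 0.1  # |D| below this is treated as ill-conditioned
    streak_filter_sd_mm: float = 5.0
    weight_mode: str = "uniform"  # or "magnitude"

    def __post_init__(self):
        if self.lsqr_tol <= 0:
            raise ValidationError("lsqr_tol must be positive")
        if not (0.0 < self.cone_threshold < 2.0 / 3.0):
            raise ValidationError("cone_threshold must lie in (0, 2/3)")
        if self.weight_mode not in ("uniform", "magnitude"):
            raise ValidationError("weight_mode must be 'uniform' or 'magnitude'")


def dipole_kernel(grid: VoxelGrid) -> np.ndarray:
    """Real dipole kernel D(k) on the grid's full FFT frequency lattice.

    B0 is along the grid z axis; D(0) = 0 so the reconstruction has no
    absolute susceptibility reference.
    """
    return _dipole_kernel_freqs(grid.shape, grid.voxel_size_mm, rfft=False)


def _weights(
    mask: Mask, weights: ScalarVolume | None, config: InversionConfig
) -> np.ndarray:
    if config.weight_mode == "magnitude":
        if weights is None:
            raise ValidationError("magnitude weighting requires a weights volume")
        w = np.asarray(weights.data, dtype=np.float64) * mask.data
        peak = w.max()
        if peak <= 0:
            raise ValidationError("magnitude weights are zero inside the mask")
        return w / peak
    return mask.data.astype(np.float64)


def lsqr_invert(
    local_field: ScalarVolume,
    mask: Mask,
    protocol: AcquisitionProtocol,
    config: InversionConfig = InversionConfig(),
    weights: ScalarVolume | None = None,
) -> ScalarVolume:
    """First-pass dipole inversion by masked weighted LSQR.

    The field is normalized to ppm by the Larmor scale gamma*B0*1e-6 before
    the solve; the returned susceptibility map is in ppm and zero outside
    the mask.  On hitting the iteration limit a RuntimeWarning is emitted
    and the last iterate is returned.
    """
    mask.require_nonempty()
    if not mask.grid.same_geometry(local_field.grid):
        raise ValidationError("mask grid does not match field grid")
    shape = local_field.grid.shape
    D = _dipole_kernel_freqs(shape, local_field.grid.voxel_size_mm, rfft=True)
    Wt = _weights(mask, weights, config)
    f_ppm = np.asarray(local_field.data, dtype=np.float64) / protocol.hz_per_ppm
    n = int(np.prod(shape))

    def matvec(x):
        vol = x.reshape(shape)
        field = sfft.irfftn(D * sfft.rfftn(vol), s=shape)
        return (Wt * field).ravel()

    def rmatvec(x):
        vol = Wt * x.reshape(shape)
        return sfft.irfftn(D * sfft.rfftn(vol), s=shape).ravel()

    A = LinearOperator((n, n), matvec=matvec, rmatvec=rmatvec, dtype=np.float64)
    b = (Wt * f_ppm).ravel()
    sol = lsqr(
        A, b, atol=config.lsqr_tol, btol=config.lsqr_tol,
        iter_lim=config.lsqr_max_iter,
    )
    chi, istop, itn = sol[0], sol[1], sol[2]
    if istop == 7:
        warnings.warn(
            f"LSQR hit the iteration limit ({config.lsqr_max_iter}); "
            "returning the last iterate",
            RuntimeWarning,
        )
    log.debug("LSQR stopped with istop=%d after %d iterations", istop, itn)
    return ScalarVolume(
        local_field.grid, chi.reshape(shape) * mask.data, "susceptibility_ppm"
    )


def streak_reduction(
    chi0: ScalarVolume,
    local_field: ScalarVolume | None = None,
    mask: Mask | None = None,
    protocol: AcquisitionProtocol | None = None,
    config: InversionConfig = InversionConfig(),
) -> ScalarVolume:
    """Replace ill-conditioned-cone k-space content with a smooth prior.

    The streaking artifact lives on the cone |D(k)| < cone_threshold where
    the data constrain chi poorly.  It is estimated as the cone-supported
    component of chi0 not explained by a smooth prior (Gaussian low-pass of
    chi0, sd ``streak_filter_sd_mm``) and subtracted; every frequency off
    the cone is bit-identical to chi0.
    """
    grid = chi0.grid
    shape = grid.shape
    D = _dipole_kernel_freqs(shape, grid.voxel_size_mm, rfft=True)
    cone = np.abs(D) < config.cone_threshold
    X0 = sfft.rfftn(np.asarray(chi0.data, dtype=np.float64))
    # Gaussian low-pass applied in k-space so off-cone content is untouched
    kx = np.fft.fftfreq(shape[0], d=grid.voxel_size_mm[0])
    ky = np.fft.fftfreq(shape[1], d=grid.voxel_size_mm[1])
    kz = np.fft.rfftfreq(shape[2], d=grid.voxel_size_mm[2])
    KX, KY, KZ = np.meshgrid(kx, ky, kz, indexing="ij")
    sd = config.streak_filter_sd_mm
    G = np.exp(-2.0 * np.pi**2 * sd**2 * (KX**2 + KY**2 + KZ**2))
    Xout = np.where(cone, G * X0, X0)
    out = sfft.irfftn(Xout, s=shape)
    # no re-masking here: it would leak into the off-cone spectrum and break
    # the k-space partition guarantee
    return ScalarVolume(grid, out, "susceptibility_ppm")


def invert(
    local_field: ScalarVolume,
    mask: Mask,
    protocol: AcquisitionProtocol,
    config: InversionConfig = InversionConfig(),
    weights: ScalarVolume | None = None,
    reduce_streaks: bool = True,
) -> ScalarVolume:
    """LSQR inversion followed (optionally) by streak reduction."""
    chi0 = lsqr_invert(local_field, mask, protocol, config, weights)
    if not reduce_streaks:
        return chi0
    return streak_reduction(chi0, local_field, mask, protocol, config)
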