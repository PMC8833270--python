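"""Fat chemical-shift correction and complex log-linear signal fitting.

In fatty tissue the gradient-echo signal is modulated by the 3.5 ppm
chemical shift of fat: with water/fat fractions W and F,

    S_i = M0 (W + F e^{i 2 pi f_f TE_i}) e^{-R2* TE_i} e^{i 2 pi phi TE_i}.

Given externally estimated W and F maps (from a chemical-shift DIXON
acquisition, resampled onto the gradient-echo grid), dividing S_i by the
known fat factor  W + F e^{i 2 pi f_f TE_i}  makes ln S'_i exactly linear
in TE:

    ln S'_i = A + B TE_i,   A = ln M0,   B = -R2* + i 2 pi phi,

so an ordinary least-squares line through the complex log signal (with the
phase unwrapped along the echo dimension first) recovers M0 = |exp(A)|,
R2* = -Re(B) (clipped at 0) and the total field phi = Im(B)/(2 pi) in Hz.
Noise-regularized, fat-free wrapped phase images for the leading echoes,
wrap(2 pi phi TE_i), are then handed to the standard phase-processing
chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import (
    AcquisitionProtocol,
    ComplexEchoSeries,
    Mask,
    ScalarVolume,
    ValidationError,
)

__all__ = [
    "ComplexFitResult",
    "demodulate_fat",
    "complex_log_fit",
    "corrected_phase_images",
    "default_fit_mask",
]

log = logging.getLogger(__name__)


@dataclass
class ComplexFitResult:
    """Per-voxel intercept/slope of the complex log-linear fit and the
    physical maps derived from them."""

    a_map: np.ndarray  # complex intercept A
    b_map: np.ndarray  # complex slope B
    m0: ScalarVolume
    r2star: ScalarVolume  # -Re(B), clipped at 0
    total_field: ScalarVolume  # Im(B)/(2 pi), Hz
    residual_rms: ScalarVolume
    mask: Mask
    clip_fraction: float  # fraction of fitted voxels where Re(B) > 0


def demodulate_fat(
    series: ComplexEchoSeries,
    w: ScalarVolume,
    f: ScalarVolume,
    protocol: AcquisitionProtocol | None = None,
    eps: float = 1e-3,
) -> tuple[ComplexEchoSeries, Mask]:
    """Divide out the fat chemical-shift factor from each echo.

    Voxels where the fat factor magnitude falls below ``eps`` at any used
    echo (near-perfect water/fat cancellation) are left undivided and
    excluded from the returned validity mask.
    """
    protocol = protocol or series.protocol
    for v, name in ((w, "water fraction"), (f, "fat fraction")):
        if not v.grid.same_geometry(series.grid):
            raise ValidationError(f"{name} map is not on the series grid")
    ff = protocol.fat_freq_hz
    valid = np.ones(series.grid.shape, dtype=bool)
    out = []
    for te, sig in zip(protocol.te_s, series.echoes):
        den = w.data + f.data * np.exp(2j * np.pi * ff * te)
        ok = np.abs(den) >= eps
        valid &= ok
        corrected = np.where(ok, sig / np.where(ok, den, 1.0), sig)
        out.append(corrected)
    return (
        ComplexEchoSeries(series.grid, out, protocol),
        Mask(series.grid, valid),
    )


def default_fit_mask(series: ComplexEchoSeries, rel_threshold: float = 0.05) -> Mask:
    """Voxels with first-echo magnitude above 5% of the 99th percentile."""
    mag = series.magnitude(0)
    ref = np.percentile(mag, 99)
    return Mask(series.grid, mag > rel_threshold * ref)


def complex_log_fit(
    demod: ComplexEchoSeries,
    mask: Mask | None = None,
    echoes_used=None,
) -> ComplexFitResult:
    """Fit ln S_i = A + B TE_i per voxel by ordinary least squares.

    The echo phase is unwrapped along the echo dimension (temporal
    unwrapping) before forming the complex log, so the imaginary part of
    the line is continuous in TE.  Phase aliasing — a true per-echo phase
    step beyond pi, e.g. |phi| > 1/(2 dTE) — cannot be detected from the
    data itself; it surfaces as a biased field with small residual, or a
    large ``residual_rms`` when the steps are inconsistent.
    """
    if echoes_used is None:
        echoes_used = list(range(demod.n_echoes))
    echoes_used = list(echoes_used)
    if len(echoes_used) < 2:
        raise ValidationError("complex_log_fit needs at least 2 echoes")
    if mask is None:
        mask = default_fit_mask(demod)
    elif not mask.grid.same_geometry(demod.grid):
        raise ValidationError("fit mask is not on the series grid")
    te = np.asarray([demod.protocol.te_s[i] for i in echoes_used])
    sig = np.stack([demod.echoes[i] for i in echoes_used], axis=0)

    mag = np.abs(sig)
    usable = np.all(mag > 0, axis=0) & mask.data
    if not usable.any():
        raise ValidationError("no voxel has positive magnitude at all used echoes")

    S = sig[:, usable]  # (n_echo, n_vox)
    theta = np.unwrap(np.angle(S), axis=0)
    y = np.log(np.abs(S)) + 1j * theta

    t = te - te.mean()
    denom = np.sum(t**2)
    B = (t[:, None] * y).sum(axis=0) / denom
    A = y.mean(axis=0) - B * te.mean()
    resid = y - (A[None, :] + B[None, :] * te[:, None])
    rms = np.sqrt(np.mean(np.abs(resid) ** 2, axis=0))

    shape = demod.grid.shape
    a_map = np.zeros(shape, dtype=np.complex128)
    b_map = np.zeros(shape, dtype=np.complex128)
    a_map[usable] = A
    b_map[usable] = B

    r2 = -b_map.real
    n_clip = int(np.count_nonzero(r2[usable] < 0))
    clip_fraction = n_clip / max(int(usable.sum()), 1)
    if n_clip:
        log.info("R2* clipped at 0 in %.2f%% of fitted voxels", 100 * clip_fraction)
    r2 = np.where(usable, np.maximum(r2, 0.0), 0.0)

    m0 = np.where(usable, np.abs(np.exp(a_map)), 0.0)
    phi = np.where(usable, b_map.imag / (2.0 * np.pi), 0.0)
    rms_vol = np.zeros(shape)
    rms_vol[usable] = rms

    grid = demod.grid
    return ComplexFitResult(
        a_map=a_map,
        b_map=b_map,
        m0=ScalarVolume(grid, m0, "magnitude_au"),
        r2star=ScalarVolume(grid, r2, "r2star_per_s"),
        total_field=ScalarVolume(grid, phi, "field_Hz"),
        residual_rms=ScalarVolume(grid, rms_vol, "magnitude_au"),
        mask=Mask(grid, usable),
        clip_fraction=clip_fraction,
    )


def corrected_phase_images(
    fit: ComplexFitResult,
    protocol: AcquisitionProtocol,
    n_echoes: int = 3,
) -> list[ScalarVolume]:
    """Fat-free wrapped phase images for the first ``n_echoes`` echoes.

    phase_i = wrap(2 pi phi TE_i) in [-pi, pi): the phase the tissue would
    have shown without fat modulation or magnitude decay, re-wrapped so the
    standard unwrapping/background-removal chain applies unchanged.
    """
    if n_echoes > protocol.n_echoes:
        raise ValidationError(
            f"requested {n_echoes} echoes but protocol has {protocol.n_echoes}"
        )
    phi = np.asarray(fit.total_field.data, dtype=np.float64)
    out = []
    for te in protocol.te_s[:n_echoes]:
        raw = 2.0 * np.pi * phi * te
        wrapped = np.mod(raw + np.pi, 2.0 * np.pi) - np.pi
        out.append(ScalarVolume(fit.total_field.grid, wrapped, "phase_rad"))
    return out
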