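"""Per-voxel CEST Z-spectrum processing and APTw map computation.

The processing chain per voxel is: normalize the saturated signals to the
unsaturated reference (S0), shift the spectral minimum to 0 ppm (B0
correction), integrate the asymmetry of the linearly interpolated spectrum
over the amide band (3.1-3.9 ppm) to get APTw in percent, and optionally
apply fluid suppression, which rescales APTw by (sigma_wm / Z_ref)^2 with
Z_ref the spectrum intensity at -3.5 ppm.  Long-T2 fluid compartments (CSF,
liquefactive necrosis) have a narrow spectral line, hence high Z_ref and a
suppressed APTw_FS.

Scalar functions operate on a single :class:`ZSpectrum`;
:func:`compute_aptw_maps` applies the same chain to a 4D stack with
vectorized NumPy code (identical results, checked in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ZSpectrum",
    "AptwConfig",
    "AptwMaps",
    "normalize_zspectrum",
    "b0_correct",
    "interp_z",
    "aptw",
    "fluid_suppress",
    "compute_aptw_maps",
]

DEFAULT_SIGMA_WM = 0.4  # WM Z(-3.5 ppm) for the default saturation module


@dataclass
class ZSpectrum:
    """A normalized saturation profile Z(offset) = S_sat/S0.

    offsets are in ppm and strictly increasing; z is dimensionless and
    non-negative; b0_shift records the ppm shift applied by B0 correction
    (0 before correction).  uncorrectable is set when B0 correction could
    not locate an interior spectral minimum.
    """

    offsets: np.ndarray
    z: np.ndarray
    b0_shift: float = 0.0
    uncorrectable: bool = False

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, float)
        self.z = np.asarray(self.z, float)
        if self.offsets.ndim != 1 or self.offsets.shape != self.z.shape:
            raise ValueError("offsets and z must be 1-D arrays of equal length")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if not np.all(np.isfinite(self.z)) or np.any(self.z < 0):
            raise ValueError("z values must be finite and >= 0")


@dataclass(frozen=True)
class AptwConfig:
    """Integration bounds, reference offset and fluid-suppression factor."""

    delta_omega_1: float = 3.1  # ppm, lower integration bound
    delta_omega_2: float = 3.9  # ppm, upper integration bound
    ref_offset: float = -3.5  # ppm, Z_ref location
    sigma_wm: float = DEFAULT_SIGMA_WM  # dimensionless

    def __post_init__(self) -> None:
        if not 0 < self.delta_omega_1 < self.delta_omega_2:
            raise ValueError("need 0 < delta_omega_1 < delta_omega_2")
        if not 0 < self.sigma_wm <= 1:
            raise ValueError("sigma_wm must be in (0, 1]")


@dataclass
class AptwMaps:
    """Voxelwise APTw (%), fluid-suppressed APTw (%), and B0 shift (ppm) maps."""

    aptw: np.ndarray
    aptw_fs: np.ndarray
    b0_map: np.ndarray

    def __post_init__(self) -> None:
        if not (self.aptw.shape == self.aptw_fs.shape == self.b0_map.shape):
            raise ValueError("map shapes must agree")


def normalize_zspectrum(s_sat, s0: float, offsets=None) -> ZSpectrum:
    """Normalize per-offset saturated intensities by the unsaturated S0.

    Raises ValueError for non-positive or non-finite S0 (at map level such
    voxels are flagged invalid rather than raising).
    """
    s_sat = np.asarray(s_sat, float)
    if offsets is None:
        raise ValueError("offsets must be provided")
    if not np.isfinite(s0) or s0 <= 0:
        raise ValueError("s0 must be positive and finite")
    if not np.all(np.isfinite(s_sat)) or np.any(s_sat < 0):
        raise ValueError("s_sat must be finite and non-negative")
    return ZSpectrum(offsets=np.asarray(offsets, float), z=s_sat / s0)


def _parabolic_min(offsets: np.ndarray, z: np.ndarray):
    """Sub-sample location of the spectral minimum, or None if degenerate.

    Fits a parabola through the discrete minimum and its two neighbours.
    Returns None when the minimum sits on the axis boundary or the spectrum
    is flat within tolerance.
    """
    if len(offsets) < 5:
        return None
    if np.ptp(z) <= 1e-12 * max(1.0, float(np.max(np.abs(z)))):
        return None
    k = int(np.argmin(z))
    if k == 0 or k == len(z) - 1:
        return None
    x0, x1, x2 = offsets[k - 1], offsets[k], offsets[k + 1]
    y0, y1, y2 = z[k - 1], z[k], z[k + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a <= 0:  # flat or concave triple -- no interior minimum
        return None
    return -b / (2.0 * a)


def b0_correct(spec: ZSpectrum, max_shift: float = 1.0) -> ZSpectrum:
    """Shift the offset axis so the spectral minimum lies at 0 ppm.

    The minimum is located by a parabolic fit through the discrete minimum
    and its two neighbours.  Shifts beyond ``max_shift`` (default 1 ppm), a
    boundary minimum, or a flat spectrum leave the spectrum unshifted with
    ``uncorrectable`` set.
    """
    delta = _parabolic_min(spec.offsets, spec.z)
    if delta is None or abs(delta) > max_shift:
        return replace(spec, b0_shift=0.0, uncorrectable=True)
    return ZSpectrum(offsets=spec.offsets - delta, z=spec.z.copy(), b0_shift=delta)


def interp_z(spec: ZSpectrum, omega: float) -> float:
    """Linearly interpolated spectrum intensity at ``omega`` (no extrapolation)."""
    if omega < spec.offsets[0] or omega > spec.offsets[-1]:
        raise ValueError(f"omega {omega} ppm outside sampled range "
                         f"[{spec.offsets[0]}, {spec.offsets[-1]}]")
    return float(np.interp(omega, spec.offsets, spec.z))


def _integral_linear(offsets: np.ndarray, z: np.ndarray, a: float, b: float) -> float:
    """Exact integral of the piecewise-linear interpolant over [a, b].

    Partial end segments are integrated analytically (trapezoid of the
    interpolated endpoint values), not snapped to knots.
    """
    inner = (offsets > a) & (offsets < b)
    xs = np.concatenate(([a], offsets[inner], [b]))
    zs = np.concatenate(([np.interp(a, offsets, z)], z[inner],
                         [np.interp(b, offsets, z)]))
    return float(np.trapezoid(zs, xs))


def aptw(spec: ZSpectrum, cfg: AptwConfig = AptwConfig()) -> float:
    """APTw in percent: the asymmetry integral over the amide band.

    100 * [int_{-d2}^{-d1} Z dw - int_{d1}^{d2} Z dw] / (d2 - d1), with Z the
    linearly interpolated spectrum.  Expects a B0-corrected spectrum.
    """
    d1, d2 = cfg.delta_omega_1, cfg.delta_omega_2
    if -d2 < spec.offsets[0] or d2 > spec.offsets[-1]:
        raise ValueError("integration bounds outside the sampled offset range")
    neg = _integral_linear(spec.offsets, spec.z, -d2, -d1)
    pos = _integral_linear(spec.offsets, spec.z, d1, d2)
    return 100.0 * (neg - pos) / (d2 - d1)


def fluid_suppress(aptw_value: float, z_ref: float,
                   cfg: AptwConfig = AptwConfig()) -> float:
    """Fluid-suppressed APTw: aptw * sigma_wm^2 / z_ref^2.

    Attenuates voxels whose reference intensity at -3.5 ppm exceeds the
    white-matter value (narrow-line, long-T2 fluid); leaves white-matter-like
    voxels (z_ref == sigma_wm) unchanged.
    """
    if z_ref <= 0:
        raise ValueError("z_ref must be positive")
    return aptw_value * cfg.sigma_wm ** 2 / z_ref ** 2


# ---------------------------------------------------------------------------
# vectorized map-level chain


def _eval_interp_rows(offsets, zmat, x):
    """Rowwise linear interpolation: zmat[v] evaluated at x[v]."""
    n = len(offsets)
    idx = np.clip(np.searchsorted(offsets, x, side="right") - 1, 0, n - 2)
    rows = np.arange(zmat.shape[0])
    z0 = zmat[rows, idx]
    z1 = zmat[rows, idx + 1]
    w = (x - offsets[idx]) / (offsets[idx + 1] - offsets[idx])
    return z0 + w * (z1 - z0)


def _eval_cumint_rows(offsets, zmat, cum, x):
    """Rowwise cumulative integral of the linear interpolant at points x."""
    n = len(offsets)
    idx = np.clip(np.searchsorted(offsets, x, side="right") - 1, 0, n - 2)
    rows = np.arange(zmat.shape[0])
    zx = _eval_interp_rows(offsets, zmat, x)
    return cum[rows, idx] + 0.5 * (zmat[rows, idx] + zx) * (x - offsets[idx])


def compute_aptw_maps(cest_4d: np.ndarray, s0_vol: np.ndarray, mask: np.ndarray,
                      cfg: AptwConfig = AptwConfig(), *,
                      offsets: np.ndarray, apply_fs: bool = True) -> AptwMaps:
    """Run the full APTw chain over a 4D CEST stack.

    cest_4d has shape (x, y, z, n_offsets) matching ``offsets`` (ascending
    ppm); s0_vol and mask are 3-D.  Per masked voxel: normalize -> B0-correct
    -> asymmetry integral -> fluid suppression.  Invalid voxels (S0 <= 0,
    uncorrectable handled as shift 0) and voxels outside the mask are NaN in
    the output maps; uncorrectable voxels additionally carry NaN in the B0
    map but keep their (unshifted) APTw value.
    """
    offsets = np.asarray(offsets, float)
    cest_4d = np.asarray(cest_4d, float)
    if cest_4d.shape[-1] != len(offsets):
        raise ValueError("cest_4d last axis must match the offset list")
    if cest_4d.shape[:3] != s0_vol.shape or s0_vol.shape != mask.shape:
        raise ValueError("volume shapes disagree")
    d1, d2 = cfg.delta_omega_1, cfg.delta_omega_2

    shape = s0_vol.shape
    vmask = mask.astype(bool).ravel()
    s0 = s0_vol.reshape(-1)[vmask]
    sig = cest_4d.reshape(-1, len(offsets))[vmask]

    valid = np.isfinite(s0) & (s0 > 0) & np.all(np.isfinite(sig), axis=1)
    z = np.full_like(sig, np.nan)
    z[valid] = sig[valid] / s0[valid, None]
    z[z < 0] = 0.0

    # --- vectorized parabolic B0 shift
    nv, n = z.shape
    delta = np.zeros(nv)
    uncorr = np.zeros(nv, bool)
    with np.errstate(invalid="ignore"):
        k = np.where(valid, np.nanargmin(np.where(valid[:, None], z, np.inf), axis=1), 0)
    interior = valid & (k > 0) & (k < n - 1) & (np.ptp(z, axis=1) > 1e-12)
    rows = np.arange(nv)
    ki = np.clip(k, 1, n - 2)
    x0, x1, x2 = offsets[ki - 1], offsets[ki], offsets[ki + 1]
    y0 = z[rows, ki - 1]
    y1 = z[rows, ki]
    y2 = z[rows, ki + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
        vert = -b / (2.0 * a)
    ok = interior & (a > 0) & np.isfinite(vert) & (np.abs(vert) <= 1.0)
    delta[ok] = vert[ok]
    uncorr = valid & ~ok

    # --- asymmetry integral of the shifted spectrum.
    # Shifting the axis by -delta is equivalent to integrating the original
    # interpolant over bounds offset by +delta.
    zsafe = np.where(np.isfinite(z), z, 0.0)
    seg = 0.5 * (zsafe[:, 1:] + zsafe[:, :-1]) * np.diff(offsets)[None, :]
    cum = np.concatenate([np.zeros((nv, 1)), np.cumsum(seg, axis=1)], axis=1)

    lo, hi = offsets[0], offsets[-1]
    bounds_ok = valid & (-d2 + delta >= lo) & (d2 + delta <= hi)

    def F(x):
        return _eval_cumint_rows(offsets, zsafe, cum, x)

    i_neg = F(-d1 + delta) - F(-d2 + delta)
    i_pos = F(d2 + delta) - F(d1 + delta)
    aptw_v = 100.0 * (i_neg - i_pos) / (d2 - d1)
    aptw_v[~bounds_ok] = np.nan

    zref = _eval_interp_rows(offsets, zsafe, cfg.ref_offset + delta)
    with np.errstate(invalid="ignore", divide="ignore"):
        fs_v = np.where(zref > 0, aptw_v * cfg.sigma_wm ** 2 / zref ** 2, np.nan)
    if not apply_fs:
        fs_v = aptw_v.copy()

    b0_v = np.where(uncorr, np.nan, delta)
    b0_v = np.where(valid, b0_v, np.nan)

    def unravel(vals):
        out = np.full(int(np.prod(shape)), np.nan)
        out[vmask] = vals
        return out.reshape(shape)

    return AptwMaps(aptw=unravel(aptw_v), aptw_fs=unravel(fs_v), b0_map=unravel(b0_v))
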