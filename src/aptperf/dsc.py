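"""DSC-MRI perfusion quantification.

Signal-to-concentration conversion (Delta R2* from the gradient-echo signal
drop), semi-automatic arterial-input-function (AIF) selection, Boxerman-style
linear leakage correction yielding K2 and leakage-corrected CBV, and
delay-insensitive block-circulant SVD deconvolution for CBF.

All perfusion outputs are relative (arbitrary units): downstream analysis
normalizes tumor values to normal-appearing white matter, so no hematocrit
or density scaling is applied.

Sign convention for K2: positive K2 means T2*-dominant extravasation that
depresses the measured concentration curve (the correction adds signal
back); negative K2 means T1-dominant enhancement.  Both occur in practice
depending on sequence parameters, so K2 is reported signed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DscSeries",
    "ConcCurve",
    "Aif",
    "PerfusionMaps",
    "signal_to_conc",
    "detect_bolus_arrival",
    "select_aif",
    "leakage_correct",
    "cbv",
    "deconvolve_cbf",
    "compute_perfusion_maps",
]


@dataclass
class DscSeries:
    """A 4D dynamic susceptibility contrast acquisition."""

    signal: np.ndarray  # (x, y, z, t)
    tr: float = 1.243  # s
    te: float = 0.029  # s
    baseline_window: tuple | None = None  # (start, stop) frame indices, stop exclusive

    def __post_init__(self) -> None:
        if self.te <= 0 or self.tr <= 0:
            raise ValueError("tr and te must be positive")
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, t)")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.signal.shape[-1]) * self.tr


@dataclass
class ConcCurve:
    """A relative concentration-time curve (Delta R2*, 1/s)."""

    t: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.c = np.asarray(self.c, float)
        if self.t.shape != self.c.shape:
            raise ValueError("t and c must have equal length")


@dataclass
class Aif(ConcCurve):
    """Arterial input function averaged over selected voxels."""

    n_voxels: int = 1


@dataclass
class PerfusionMaps:
    cbf: np.ndarray
    cbv: np.ndarray
    ccbv: np.ndarray
    k2: np.ndarray  # 1/min, signed
    mtt: np.ndarray  # s
    aif: Aif | None = None


def signal_to_conc(voxel_signal, baseline_window, te: float,
                   t: np.ndarray | None = None) -> ConcCurve:
    """Convert a signal time series to Delta R2* = -ln(S/S_pre)/TE.

    S_pre is the mean over the pre-bolus baseline window.  Frames with
    non-positive signal become NaN; a non-positive baseline raises.
    """
    s = np.asarray(voxel_signal, float)
    i0, i1 = baseline_window
    s_pre = float(np.mean(s[i0:i1]))
    if not np.isfinite(s_pre) or s_pre <= 0:
        raise ValueError("non-positive baseline signal")
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(s > 0, -np.log(s / s_pre) / te, np.nan)
    if t is None:
        t = np.arange(len(s), dtype=float)
    return ConcCurve(t=t, c=c)


def detect_bolus_arrival(mean_signal: np.ndarray, min_baseline: int = 5,
                         n_sd: float = 3.0) -> int:
    """First frame where the global-mean signal drops n_sd SDs below its
    running baseline; returns the series length if no bolus is found.

    The baseline window is then (0, arrival - 1) to stay clear of the
    leading edge.
    """
    s = np.asarray(mean_signal, float)
    for i in range(min_baseline, len(s)):
        base = s[:i]
        sd = max(float(np.std(base)), 1e-9 * abs(float(np.mean(base))), 1e-12)
        if s[i] < np.mean(base) - n_sd * sd:
            return i
    return len(s)


def _cumint(t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid integral of c over t, starting at 0."""
    out = np.zeros_like(c)
    out[1:] = np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t))
    return out


def select_aif(conc_4d: np.ndarray, brain_mask: np.ndarray, t: np.ndarray,
               seed_region: np.ndarray | None = None, n_top: int = 10) -> Aif:
    """Semi-automatic AIF selection.

    Candidate voxels (inside ``seed_region`` if given, else the brain mask)
    are screened for a flat baseline and an adequate peak, then ranked by a
    composite score favouring high peak concentration (weight 0.5), early
    arrival (0.25) and a low first moment (0.25).  The top ``n_top`` curves
    are averaged.  The score weights are heuristics standing in for the
    interactive step of clinical software.
    """
    region = seed_region if seed_region is not None else brain_mask
    cand = np.asarray(conc_4d)[np.asarray(region, bool)]
    cand = cand[np.all(np.isfinite(cand), axis=1)]
    if len(cand) < 1:
        raise ValueError("no candidate voxels for AIF selection")

    peaks = cand.max(axis=1)
    peak_idx = cand.argmax(axis=1)
    n_base = max(3, int(0.1 * cand.shape[1]))
    base_sd = cand[:, :n_base].std(axis=1)
    # sanity screens: real bolus peak, quiet baseline
    keep = (peaks > 5.0 * np.maximum(base_sd, 1e-12)) & (peaks > 0)
    if not np.any(keep):
        raise ValueError("no AIF candidate passed sanity screens; "
                         "provide a manual seed_region")
    cand, peaks, peak_idx = cand[keep], peaks[keep], peak_idx[keep]

    pos = np.clip(cand, 0.0, None)
    area = pos.sum(axis=1) + 1e-12
    first_moment = (pos * t[None, :]).sum(axis=1) / area
    arrival = t[peak_idx]

    def zscore(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    score = 0.5 * zscore(peaks) - 0.25 * zscore(arrival) - 0.25 * zscore(first_moment)
    top = np.argsort(score)[::-1][: min(n_top, len(score))]
    return Aif(t=t, c=cand[top].mean(axis=0), n_voxels=len(top))


def leakage_correct(voxel_curve: ConcCurve, ref_curve: ConcCurve):
    """Boxerman linear leakage fit against a non-enhancing reference curve.

    Fits c_voxel(t) ~ K1 * ref(t) - K2 * int_0^t ref, returns
    (k1, k2 [1/min], corrected_curve) with corrected = c + K2 * int ref.
    """
    t = voxel_curve.t
    if not np.array_equal(t, ref_curve.t):
        raise ValueError("voxel and reference curves must share a time axis")
    ref = ref_curve.c
    if float(np.sum(ref ** 2)) <= 0:
        raise ValueError("degenerate (zero-energy) reference curve")
    iref = _cumint(t, ref)
    X = np.column_stack([ref, -iref])
    coef, *_ = np.linalg.lstsq(X, voxel_curve.c, rcond=None)
    k1, k2_per_s = float(coef[0]), float(coef[1])
    corrected = ConcCurve(t=t, c=voxel_curve.c + k2_per_s * iref)
    return k1, k2_per_s * 60.0, corrected


def cbv(voxel_curve: ConcCurve, aif: Aif) -> float:
    """Relative blood volume: ratio of curve to AIF areas (trapezoid)."""
    denom = float(np.trapezoid(aif.c, aif.t))
    if denom <= 0:
        raise ValueError("AIF integral must be positive")
    return float(np.trapezoid(voxel_curve.c, voxel_curve.t)) / denom


def _circulant_inverse(aif_c: np.ndarray, tr: float, threshold: float) -> np.ndarray:
    """Truncated-SVD inverse of the zero-padded block-circulant AIF matrix."""
    n = len(aif_c)
    L = 2 * n
    pad = np.concatenate([aif_c, np.zeros(n)])
    idx = (np.arange(L)[:, None] - np.arange(L)[None, :]) % L
    A = pad[idx] * tr
    u, s, vt = np.linalg.svd(A)
    if s[0] <= 0:
        raise ValueError("AIF is identically zero")
    sinv = np.where(s >= threshold * s[0], 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return (vt.T * sinv) @ u.T


def deconvolve_cbf(voxel_curve: ConcCurve, aif: Aif, tr: float,
                   threshold: float = 0.15):
    """CBF and MTT by delay-insensitive circulant-SVD deconvolution.

    The AIF convolution matrix is made block-circulant by zero-padding to
    twice the series length, so residue functions shifted by (positive or
    negative) bolus delays wrap around instead of being clipped.  Singular
    values below ``threshold`` times the maximum are zeroed.  CBF is the
    peak of the recovered residue function; MTT = CBV / CBF.
    """
    n = len(voxel_curve.c)
    ainv = _circulant_inverse(aif.c, tr, threshold)
    k = ainv @ np.concatenate([voxel_curve.c, np.zeros(n)])
    cbf_val = float(np.max(k))
    if cbf_val <= 0:
        return 0.0, np.nan
    vol = cbv(voxel_curve, aif)
    return cbf_val, vol / cbf_val


def compute_perfusion_maps(series: DscSeries, brain_mask: np.ndarray,
                           enhancing_mask: np.ndarray | None = None,
                           aif_seed: np.ndarray | None = None,
                           svd_threshold: float = 0.15) -> PerfusionMaps:
    """Full DSC pipeline over a 4D series.

    Conversion to Delta R2* -> AIF selection -> per-voxel Boxerman leakage
    fit against the mean non-enhancing brain curve -> CBV / corrected CBV /
    K2 -> circulant-SVD CBF on the corrected curves -> MTT.  Voxels outside
    the brain mask are NaN.
    """
    sig = np.asarray(series.signal, float)
    mask = np.asarray(brain_mask, bool)
    if mask.shape != sig.shape[:3]:
        raise ValueError("mask shape must match the series")
    nt = sig.shape[-1]
    t = series.t

    if series.baseline_window is None:
        arrival = detect_bolus_arrival(sig[mask].mean(axis=0))
        window = (0, max(2, arrival - 1))
    else:
        window = series.baseline_window

    flat = sig.reshape(-1, nt)
    vidx = mask.ravel()
    vox = flat[vidx]
    s_pre = vox[:, window[0]:window[1]].mean(axis=1)
    valid = s_pre > 0
    conc = np.full_like(vox, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc[valid] = -np.log(vox[valid] / s_pre[valid, None]) / series.te
    conc[~np.isfinite(conc)] = np.nan

    conc_4d = np.full(sig.shape, np.nan)
    conc_4d.reshape(-1, nt)[vidx] = conc
    aif = select_aif(conc_4d, mask, t, seed_region=aif_seed)

    # reference: non-enhancing brain, excluding arterial voxels (the AIF
    # seed region), which would otherwise distort the reference shape
    nonenh = mask.copy()
    if enhancing_mask is not None:
        nonenh &= ~np.asarray(enhancing_mask, bool)
    if aif_seed is not None:
        nonenh &= ~np.asarray(aif_seed, bool)
    ref = np.nanmean(conc_4d[nonenh], axis=0)
    iref = _cumint(t, ref)

    # vectorized leakage fit: shared design matrix, per-voxel normal equations
    X = np.column_stack([ref, -iref])
    pinv = np.linalg.pinv(X)
    cfit = np.where(np.isfinite(conc), conc, 0.0)
    coef = pinv @ cfit.T  # (2, nvox)
    k2_per_s = coef[1]
    corrected = cfit + np.outer(k2_per_s, iref)

    aif_area = float(np.trapezoid(aif.c, t))
    if aif_area <= 0:
        raise ValueError("AIF integral must be positive")
    cbv_v = np.trapezoid(cfit, t, axis=1) / aif_area
    ccbv_v = np.trapezoid(corrected, t, axis=1) / aif_area

    ainv = _circulant_inverse(aif.c, series.tr, svd_threshold)
    padded = np.concatenate([corrected, np.zeros_like(corrected)], axis=1)
    residue = padded @ ainv.T
    cbf_v = residue.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt_v = np.where(cbf_v > 0, ccbv_v / cbf_v, np.nan)

    def unravel(vals):
        out = np.full(flat.shape[0], np.nan)
        out[vidx] = vals
        return out.reshape(mask.shape)

    return PerfusionMaps(cbf=unravel(cbf_v), cbv=unravel(cbv_v),
                         ccbv=unravel(ccbv_v), k2=unravel(k2_per_s * 60.0),
                         mtt=unravel(mtt_v), aif=aif)
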