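"""Digital brain phantom and two-group synthetic cohort generator.

Real patient data for the GBM-vs-metastasis comparison are not publicly
deposited, so this module builds labelled digital phantoms with known ground
truth and synthesizes both modalities from physics-based forward models:

* CEST 4D stacks: per-tissue Z-spectra from the Bloch-McConnell simulator,
  broadcast over the label volume, displaced by a smooth B0 offset field and
  degraded with Gaussian noise.
* DSC 4D series: gamma-variate arterial bolus, tissue curves by convolution
  with an exponential residue function (per-tissue relative CBF/CBV and
  delay), a Boxerman-style leakage term in enhancing tissue, converted to
  signal via the gradient-echo Delta R2* relation, plus Gaussian noise.

Group effect sizes default to the enhancing-tumor contrasts the generator is
meant to emulate (relative corrected CBV ~4.3 vs ~2.4, relative CBF ~3.7 vs
~2.3, normalized APTw ~2.0 vs ~1.7 for the GBM-like vs MET-like groups);
these are emulation targets for the simulator, not measured-data claims.

Per-tissue Z-spectra are linear in the amide proton fraction to excellent
approximation over the simulated range, so each tissue template is simulated
once at two anchor fractions and per-subject spectra are interpolated
between them; the anchors are cached across subjects and cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.ndimage import zoom
from scipy.signal import fftconvolve

from .bmsim import (OffsetPlan, SaturationModule, default_saturation,
                    simulate_zspectrum, wm_pools)
from .zspectrum import ZSpectrum, aptw

__all__ = [
    "LABELS",
    "TissueSpec",
    "SubjectTruth",
    "SyntheticSubject",
    "CohortConfig",
    "build_phantom",
    "sample_subject_truth",
    "generate_cest",
    "generate_dsc",
    "generate_subject",
    "generate_cohort",
]

LABELS = {"background": 0, "NAWM": 1, "ET": 2, "necrosis": 3, "edema": 4,
          "artery": 5, "ET_hot": 6}

_ANCHOR_F = (0.002, 0.014)  # amide-fraction anchors for spectrum interpolation


@dataclass(frozen=True)
class TissueSpec:
    """Generating parameters of one tissue class for one subject."""

    label: str
    pools: tuple  # CEST pool set (water first)
    cbf_rel: float = 1.0  # relative to NAWM = 1
    cbv_rel: float = 1.0
    k2: float = 0.0  # 1/min
    delay: float = 0.0  # s, bolus delay
    b0_offset: float = 0.0  # ppm, added to the smooth subject field
    noise_sd: float = 0.0  # fraction of S0 (set from the cohort config)


@dataclass
class SubjectTruth:
    """Everything needed to regenerate or verify one synthetic subject."""

    group: str  # "GBM" or "MET"
    tissues: dict  # label name -> TissueSpec
    seed: int
    spectra: dict = field(default_factory=dict)  # label -> ZSpectrum (acq. grid)
    spectra_ext: dict = field(default_factory=dict)  # label -> ZSpectrum (extended grid)
    has_edema: bool = True
    has_necrosis: bool = True


@dataclass
class SyntheticSubject:
    labels: np.ndarray
    truth: SubjectTruth
    cest_4d: np.ndarray | None = None
    s0: np.ndarray | None = None
    dsc_4d: np.ndarray | None = None


@dataclass(frozen=True)
class GroupEffect:
    """Normal distribution of one per-subject tissue parameter."""

    mean: float
    sd: float
    lo: float = 0.05  # truncation floor

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        return float(max(self.lo, rng.normal(self.mean, self.sd)))


def default_effects() -> dict:
    """Per-group distributions of the drawn enhancing-tumor parameters.

    Means/SDs are the generator's emulation targets for the enhancing-tumor
    region (normalized-to-NAWM scale); K2 is in 1/min and does not differ
    between groups.  ``et_naptw_hot`` is the normalized APTw of a focal
    hot-spot subregion inside ET, emulating the intra-tumor heterogeneity
    that makes the region *maximum* a stronger discriminator than the mean.
    """
    return {
        "GBM": {
            "et_naptw": GroupEffect(2.0, 0.60, lo=0.3),
            "et_naptw_hot": GroupEffect(4.9, 0.40, lo=1.0),
            "et_cbf_rel": GroupEffect(3.7, 1.7, lo=0.5),
            "et_cbv_rel": GroupEffect(4.3, 1.8, lo=0.5),
            "et_k2": GroupEffect(0.04, 0.03, lo=-1.0),
        },
        "MET": {
            "et_naptw": GroupEffect(1.7, 0.74, lo=0.3),
            "et_naptw_hot": GroupEffect(4.4, 0.40, lo=1.0),
            "et_cbf_rel": GroupEffect(2.3, 1.0, lo=0.5),
            "et_cbv_rel": GroupEffect(2.4, 0.86, lo=0.5),
            "et_k2": GroupEffect(0.04, 0.03, lo=-1.0),
        },
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the synthetic cohort."""

    shape: tuple = (64, 64, 24)
    sat: SaturationModule = field(default_factory=default_saturation)
    plan: OffsetPlan = OffsetPlan()
    n_segments: int = 32  # per-pulse segments for phantom spectra
    n_trains: int = 50  # saturation-module repetitions (pseudo-steady state)
    # Effective noise of the (vendor-smoothed) CEST images, as a fraction of
    # S0: calibrated so the region maximum of the APTw map tracks the focal
    # hot spot rather than the voxel-noise extreme over the ROI
    noise_sd_cest: float = 0.005
    noise_sd_dsc: float = 0.02
    b0_amp: float = 0.15  # ppm, amplitude of the smooth B0 field
    s0_scale: float = 1000.0
    # DSC timing / bolus
    tr: float = 1.243  # s
    te: float = 0.029  # s
    n_frames: int = 72
    bolus_arrival: float = 15.0  # s
    bolus_peak: float = 12.0  # peak arterial Delta R2*, 1/s
    bolus_shape: float = 3.0  # gamma-variate shape
    bolus_tp: float = 4.0  # s, time to peak after arrival
    mtt_nawm: float = 4.0  # s
    cbf_nawm: float = 0.12  # relative units; WM Delta-R2* peaks near 4 1/s
    effects: dict | None = None
    # per-tissue bolus delay (s) relative to NAWM
    delays: tuple = (("ET", 1.0), ("edema", 0.5), ("necrosis", 2.0))
    # probability a subject presents edema / necrosis, per group
    p_edema: tuple = (("GBM", 1.0), ("MET", 0.75))
    p_necrosis: tuple = (("GBM", 0.5), ("MET", 0.25))

    def group_effects(self) -> dict:
        return self.effects if self.effects is not None else default_effects()


# ---------------------------------------------------------------------------
# geometry


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def build_phantom(shape=(64, 64, 24), *, tumor_radius_frac: float = 0.28,
                  with_edema: bool = True, with_necrosis: bool = True,
                  seed: int = 0) -> np.ndarray:
    """Concentric-ellipsoid tumor phantom embedded in white matter.

    Necrotic core inside an enhancing-tumor rim inside an edema shell, all
    inside a brain ellipsoid of NAWM, plus a small artery tube; the tumor
    center and radii are jittered reproducibly by ``seed``.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 12:
        raise ValueError("phantom shape too small")
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape, dtype=np.int16)

    center = np.array(shape) / 2.0 - 0.5
    brain_r = np.array(shape) * 0.45
    brain = _ellipsoid(shape, center, brain_r)
    vol[brain] = LABELS["NAWM"]

    r_ed = tumor_radius_frac * min(shape) * rng.uniform(0.85, 1.15)
    if r_ed >= 0.9 * min(brain_r):
        raise ValueError("tumor geometry exceeds the brain volume")
    if r_ed > 0.5:
        off = rng.uniform(-0.12, 0.12, size=3) * np.array(shape)
        tc = center + off
        aniso = rng.uniform(0.8, 1.2, size=3)
        red = r_ed * aniso
        ret = 0.62 * red
        rnec = 0.45 * ret
        if with_edema:
            vol[_ellipsoid(shape, tc, red) & brain] = LABELS["edema"]
        vol[_ellipsoid(shape, tc, ret) & brain] = LABELS["ET"]
        # focal hot spot within the enhancing rim
        direction = rng.standard_normal(3)
        direction /= max(np.linalg.norm(direction), 1e-9)
        hc = tc + direction * 0.55 * ret
        hot = _ellipsoid(shape, hc, 0.40 * ret)
        vol[hot & (vol == LABELS["ET"])] = LABELS["ET_hot"]
        if with_necrosis:
            vol[_ellipsoid(shape, tc, rnec) & brain] = LABELS["necrosis"]

    # artery: a small tube running through-plane near the brain edge
    ax, ay = int(shape[0] * 0.22), int(shape[1] * 0.5)
    xs, ys = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    tube = (xs - ax) ** 2 + (ys - ay) ** 2 <= 1.5 ** 2
    vol[tube[:, :, None] & brain] = LABELS["artery"]
    return vol


# ---------------------------------------------------------------------------
# tissue templates and spectra


def _scale_mt(pools: tuple, factor: float) -> tuple:
    return tuple(replace(p, fraction=p.fraction * factor) if p.name == "mt" else p
                 for p in pools)


def _set_water(pools: tuple, t1: float, t2: float) -> tuple:
    return tuple(replace(p, t1=t1, t2=t2) if p.name == "water" else p for p in pools)


def _set_amide(pools: tuple, f: float) -> tuple:
    return tuple(replace(p, fraction=f) if p.name == "amide" else p for p in pools)


@lru_cache(maxsize=None)
def _phantom_base_pools() -> tuple:
    """Phantom base tissue: water + symmetric semisolid MT + amide.

    The semisolid line is centered on water and the upfield rNOE pool is
    dropped so the asymmetry metric isolates the amide pool; the tissue
    templates below then control contrast through the amide fraction and
    the MT/water parameters.
    """
    pools = [p for p in wm_pools() if p.name != "rnoe"]
    return tuple(replace(p, chemical_shift=0.0) if p.name == "mt" else p
                 for p in pools)


def tissue_templates() -> dict:
    """Per-label CEST pool templates (amide fraction is the free parameter)."""
    base = _phantom_base_pools()
    return {
        "NAWM": base,
        "ET": _scale_mt(_set_water(base, 1.4, 0.09), 0.6),
        "edema": _scale_mt(_set_water(base, 1.6, 0.12), 0.5),
        "necrosis": _scale_mt(_set_water(base, 2.5, 0.40), 0.15),
        "artery": _scale_mt(_set_water(base, 1.65, 0.15), 0.2),
    }


def _extended_plan(plan: OffsetPlan, pad_ppm: float = 1.0) -> OffsetPlan:
    """Offset plan padded beyond the acquisition range for B0 resampling."""
    offs = np.asarray(plan.offsets, float)
    step = float(np.min(np.diff(offs)))
    n = int(np.ceil(pad_ppm / step))
    pre = offs[0] - step * np.arange(n, 0, -1)
    post = offs[-1] + step * np.arange(1, n + 1)
    return OffsetPlan(offsets=tuple(np.concatenate([pre, offs, post])),
                      s0_offset=plan.s0_offset)


@lru_cache(maxsize=None)
def _anchor_spectra(pools: tuple, sat: SaturationModule, plan: OffsetPlan,
                    n_segments: int, n_trains: int):
    """Simulated extended-grid spectra at the two amide-fraction anchors."""
    ext = _extended_plan(plan)
    out = []
    for f in _ANCHOR_F:
        spec = simulate_zspectrum(_set_amide(pools, f), sat, ext, n_segments,
                                  n_trains)
        out.append(spec.z)
    return np.asarray(ext.offsets), out[0], out[1]


def _spectrum_at_fraction(pools, f, sat, plan, n_segments, n_trains) -> ZSpectrum:
    offs, z0, z1 = _anchor_spectra(pools, sat, plan, n_segments, n_trains)
    w = (f - _ANCHOR_F[0]) / (_ANCHOR_F[1] - _ANCHOR_F[0])
    return ZSpectrum(offsets=offs, z=np.clip(z0 + w * (z1 - z0), 0.0, None))


def _acq_subset(spec_ext: ZSpectrum, plan: OffsetPlan) -> ZSpectrum:
    offs = np.asarray(plan.offsets, float)
    idx = np.searchsorted(spec_ext.offsets, offs)
    return ZSpectrum(offsets=offs, z=spec_ext.z[idx])


@lru_cache(maxsize=None)
def _aptw_of_fraction_coeffs(pools: tuple, sat, plan, n_segments, n_trains):
    """APTw (%) as an affine function of amide fraction: returns (a, b)."""
    offs, z0, z1 = _anchor_spectra(pools, sat, plan, n_segments, n_trains)
    a0 = aptw(ZSpectrum(offsets=offs, z=z0))
    a1 = aptw(ZSpectrum(offsets=offs, z=z1))
    b = (a1 - a0) / (_ANCHOR_F[1] - _ANCHOR_F[0])
    return a0 - b * _ANCHOR_F[0], b


def _fraction_for_aptw(pools, target_aptw, sat, plan, n_segments, n_trains) -> float:
    a, b = _aptw_of_fraction_coeffs(pools, sat, plan, n_segments, n_trains)
    if b <= 0:
        raise RuntimeError("amide response slope must be positive")
    return float(np.clip((target_aptw - a) / b, 1e-4, 0.05))


# ---------------------------------------------------------------------------
# subject truth


def sample_subject_truth(group: str, config: CohortConfig, seed: int) -> SubjectTruth:
    """Draw one subject's tissue parameters from the group distributions."""
    if group not in ("GBM", "MET"):
        raise ValueError("group must be 'GBM' or 'MET'")
    rng = np.random.default_rng(seed)
    eff = config.group_effects()[group]
    templates = tissue_templates()
    sat, plan, nseg, ntr = (config.sat, config.plan, config.n_segments,
                            config.n_trains)

    base_f = next(p.fraction for p in wm_pools() if p.name == "amide")
    a0, b0 = _aptw_of_fraction_coeffs(templates["NAWM"], sat, plan, nseg, ntr)
    aptw_nawm = a0 + b0 * base_f

    def frac_for_naptw(label: str, naptw: float) -> float:
        return _fraction_for_aptw(templates[label], naptw * aptw_nawm,
                                  sat, plan, nseg, ntr)

    delays = dict(config.delays)
    et_naptw = eff["et_naptw"].draw(rng)
    et_naptw_hot = max(eff["et_naptw_hot"].draw(rng), et_naptw)
    et_cbf = eff["et_cbf_rel"].draw(rng)
    et_cbv = eff["et_cbv_rel"].draw(rng)
    et_k2 = eff["et_k2"].draw(rng)
    # non-enhancing regions: group-independent draws around literature-like means
    ed_naptw = max(0.2, rng.normal(0.88, 0.25))
    ed_cbf = max(0.2, rng.normal(0.95, 0.3))
    ed_cbv = max(0.2, rng.normal(1.0, 0.3))
    nec_naptw = max(0.05, rng.normal(0.5, 0.3))

    tissues = {
        "NAWM": TissueSpec("NAWM", _set_amide(templates["NAWM"], base_f),
                           cbf_rel=1.0, cbv_rel=1.0, k2=0.0,
                           noise_sd=config.noise_sd_cest),
        "ET": TissueSpec("ET", _set_amide(templates["ET"],
                                          frac_for_naptw("ET", et_naptw)),
                         cbf_rel=et_cbf, cbv_rel=et_cbv, k2=et_k2,
                         delay=delays.get("ET", 0.0),
                         noise_sd=config.noise_sd_cest),
        "edema": TissueSpec("edema", _set_amide(templates["edema"],
                                                frac_for_naptw("edema", ed_naptw)),
                            cbf_rel=ed_cbf, cbv_rel=ed_cbv, k2=0.0,
                            delay=delays.get("edema", 0.0),
                            noise_sd=config.noise_sd_cest),
        "necrosis": TissueSpec("necrosis",
                               _set_amide(templates["necrosis"],
                                          frac_for_naptw("necrosis", nec_naptw)),
                               cbf_rel=0.25, cbv_rel=0.22, k2=0.0,
                               delay=delays.get("necrosis", 0.0),
                               noise_sd=config.noise_sd_cest),
        "artery": TissueSpec("artery", _set_amide(templates["artery"], 2 * base_f),
                             cbf_rel=0.0, cbv_rel=0.0, k2=0.0,
                             noise_sd=config.noise_sd_cest),
    }
    tissues["ET_hot"] = replace(
        tissues["ET"],
        label="ET_hot",
        pools=_set_amide(templates["ET"], frac_for_naptw("ET", et_naptw_hot)))
    groups = dict(config.p_edema)
    has_edema = bool(rng.random() < groups[group])
    has_necrosis = bool(rng.random() < dict(config.p_necrosis)[group])
    truth = SubjectTruth(group=group, tissues=tissues, seed=int(seed),
                         has_edema=has_edema, has_necrosis=has_necrosis)
    for name, spec in tissues.items():
        f = next(p.fraction for p in spec.pools if p.name == "amide")
        tpl = templates["ET" if name == "ET_hot" else name]
        ext = _spectrum_at_fraction(tpl, f, sat, plan, nseg, ntr)
        truth.spectra_ext[name] = ext
        truth.spectra[name] = _acq_subset(ext, plan)
    return truth


# ---------------------------------------------------------------------------
# forward models


def _smooth_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field with roughly +-amplitude range (B0 offset, ppm)."""
    if amplitude == 0:
        return np.zeros(shape)
    coarse = rng.standard_normal((4, 4, 3))
    f = zoom(coarse, [s / c for s, c in zip(shape, coarse.shape)], order=3)
    f = f[: shape[0], : shape[1], : shape[2]]
    peak = np.max(np.abs(f))
    return f * (amplitude / peak) if peak > 0 else f


def generate_cest(truth: SubjectTruth, labels: np.ndarray, config: CohortConfig,
                  rng: np.random.Generator):
    """Synthesize the 4D CEST stack + S0 volume for one subject.

    Returns (cest_4d, s0_vol, b0_field).  Each labelled voxel carries its
    tissue's simulated Z-spectrum resampled at (offset - B0) and scaled to
    signal units, with additive Gaussian noise on both the saturated and the
    unsaturated images.
    """
    offs = np.asarray(config.plan.offsets, float)
    shape = labels.shape
    nvox = labels.size
    n = len(offs)
    b0 = _smooth_field(shape, config.b0_amp, rng)

    z = np.zeros((nvox, n))
    lab_flat = labels.ravel()
    b0_flat = b0.ravel()
    for name, code in LABELS.items():
        if name == "background":
            continue
        sel = lab_flat == code
        if not np.any(sel):
            continue
        spec = truth.spectra_ext[name]
        tb0 = b0_flat[sel] + truth.tissues[name].b0_offset
        query = offs[None, :] - tb0[:, None]
        z[sel] = np.interp(query.ravel(), spec.offsets, spec.z).reshape(-1, n)

    s0_scale = config.s0_scale
    sig = z * s0_scale
    s0_vol = np.where(lab_flat > 0, s0_scale, 0.0)
    if config.noise_sd_cest > 0:
        sd = config.noise_sd_cest * s0_scale
        sig = sig + rng.normal(0.0, sd, sig.shape)
        s0_vol = s0_vol + rng.normal(0.0, sd, s0_vol.shape)
    sig[lab_flat == 0] = 0.0
    return (np.clip(sig, 0.0, None).reshape(*shape, n),
            np.clip(s0_vol, 0.0, None).reshape(shape), b0)


def gamma_variate_aif(t: np.ndarray, arrival: float, peak: float,
                      shape: float, tp: float) -> np.ndarray:
    """Gamma-variate bolus: peak amplitude ``peak`` at ``arrival + tp``."""
    if shape <= 0 or tp <= 0 or peak <= 0:
        raise ValueError("invalid gamma-variate parameters")
    x = np.clip(t - arrival, 0.0, None) / tp
    return peak * x ** shape * np.exp(shape * (1.0 - x))


def generate_dsc(truth: SubjectTruth, labels: np.ndarray, config: CohortConfig,
                 rng: np.random.Generator):
    """Synthesize the 4D DSC signal series for one subject.

    Tissue curves are CBF * (AIF conv exp(-t/MTT)) with per-tissue bolus
    delay; enhancing tissue additionally loses K2 * cumulative integral of
    the NAWM reference curve (the Boxerman leakage term).  Artery voxels
    carry the AIF itself.  Signal: S = S0 * exp(-TE * DeltaR2*) + noise.
    """
    t = np.arange(config.n_frames) * config.tr
    aif_c = gamma_variate_aif(t, config.bolus_arrival, config.bolus_peak,
                              config.bolus_shape, config.bolus_tp)
    # internal oversampling: the kinetic convolution is evaluated on a fine
    # grid and sampled at the frame times, so short mean transit times are
    # not distorted by frame-rate discretization
    oversample = 8
    dt = config.tr / oversample
    t_fine = np.arange(config.n_frames * oversample) * dt

    def tissue_curve(spec: TissueSpec) -> np.ndarray:
        if spec.cbf_rel <= 0:
            return np.zeros_like(t)
        cbf_abs = spec.cbf_rel * config.cbf_nawm
        mtt = config.mtt_nawm * spec.cbv_rel / spec.cbf_rel
        aif_f = gamma_variate_aif(t_fine, config.bolus_arrival + spec.delay,
                                  config.bolus_peak, config.bolus_shape,
                                  config.bolus_tp)
        conv = fftconvolve(aif_f, np.exp(-t_fine / mtt))[: len(t_fine)] * dt
        return cbf_abs * conv[::oversample]

    ref = tissue_curve(truth.tissues["NAWM"])
    iref = np.concatenate([[0.0], np.cumsum(0.5 * (ref[1:] + ref[:-1]) * np.diff(t))])

    curves = {"artery": aif_c}
    for name, spec in truth.tissues.items():
        if name == "artery":
            continue
        c = tissue_curve(spec)
        if spec.k2 != 0.0:
            c = c - (spec.k2 / 60.0) * iref
        curves[name] = c

    shape = labels.shape
    lab_flat = labels.ravel()
    sig = np.zeros((labels.size, config.n_frames))
    s0 = config.s0_scale
    for name, code in LABELS.items():
        if name == "background":
            continue
        sel = lab_flat == code
        if np.any(sel):
            sig[sel] = s0 * np.exp(-config.te * curves[name])[None, :]
    if config.noise_sd_dsc > 0:
        sig = sig + rng.normal(0.0, config.noise_sd_dsc * s0, sig.shape)
    sig[lab_flat == 0] = 0.0
    return np.clip(sig, 0.0, None).reshape(*shape, config.n_frames)


# ---------------------------------------------------------------------------
# cohort assembly


def generate_subject(group: str, config: CohortConfig, seed: int,
                     modalities=("cest", "dsc")) -> SyntheticSubject:
    """Generate one labelled subject with the requested modalities."""
    ss = np.random.SeedSequence(seed)
    s_truth, s_geom, s_cest, s_dsc = [int(c.generate_state(1)[0]) % (2 ** 31)
                                      for c in ss.spawn(4)]
    truth = sample_subject_truth(group, config, s_truth)
    labels = build_phantom(config.shape, with_edema=truth.has_edema,
                           with_necrosis=truth.has_necrosis, seed=s_geom)
    subj = SyntheticSubject(labels=labels, truth=truth)
    if "cest" in modalities:
        cest, s0, _ = generate_cest(truth, labels, config,
                                    np.random.default_rng(s_cest))
        subj.cest_4d, subj.s0 = cest, s0
    if "dsc" in modalities:
        subj.dsc_4d = generate_dsc(truth, labels, config,
                                   np.random.default_rng(s_dsc))
    return subj


def generate_cohort(n_gbm: int = 10, n_met: int = 8,
                    config: CohortConfig = CohortConfig(), master_seed: int = 0,
                    modalities=("cest", "dsc")) -> list:
    """Generate a reproducible two-group cohort (default 10 GBM vs 8 MET)."""
    if n_gbm < 1 or n_met < 1:
        raise ValueError("need at least one subject per group")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_gbm + n_met)
    subjects = []
    for i, child in enumerate(children):
        group = "GBM" if i < n_gbm else "MET"
        seed = int(child.generate_state(1)[0]) % (2 ** 31)
        subjects.append(generate_subject(group, config, seed, modalities))
    return subjects
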