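"""ROI statistics and two-group cohort analysis.

Per-subject: mean/max/SD per region (enhancing tumor, necrosis, edema, the
whole-tumor union, and normal-appearing white matter) for each parameter
map, followed by normalization to the subject's NAWM mean.  K2 is never
normalized: leakage is absent in healthy white matter, so dividing by a
near-zero NAWM mean would produce arbitrarily large values.

Cohort level: two-sided Mann-Whitney U tests (U reported as the smaller of
the two orientations), nonparametric ROC AUC with Hanley-McNeil standard
errors and unclipped 95% confidence intervals, and in-sample binary
logistic-regression combinations of predictors scored by the same AUC.
The AUC orientation is fixed (higher value predicts GBM); values below 0.5
are reported as-is rather than flipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phantom import LABELS

__all__ = [
    "REGIONS",
    "RegionStats",
    "GroupComparison",
    "CombinedModel",
    "extract_region_stats",
    "normalize_to_nawm",
    "mann_whitney",
    "roc_auc",
    "logistic_combine",
    "subject_stats",
    "cohort_report",
]

# stats regions; WT is the union of tumor compartments.  The ET ROI covers
# the whole enhancing rim, including the generator's focal hot spot.
REGIONS = ("WT", "ET", "edema", "necrosis", "NAWM")
REGION_CODES = {
    "ET": ("ET", "ET_hot"),
    "necrosis": ("necrosis",),
    "edema": ("edema",),
    "NAWM": ("NAWM",),
    "WT": ("ET", "ET_hot", "necrosis", "edema"),
}
UNNORMALIZED_PARAMS = ("K2",)


@dataclass
class RegionStats:
    region: str
    parameter: str
    mean: float
    max: float
    sd: float
    n_voxels: int
    is_normalized: bool = False


@dataclass
class GroupComparison:
    parameter: str
    region: str
    statistic_kind: str  # "mean" | "max"
    u: float
    p: float
    auc: float
    auc_se: float
    auc_ci_low: float
    auc_ci_high: float


@dataclass
class CombinedModel:
    predictors: list
    coefficients: np.ndarray
    intercept: float
    fitted_probabilities: np.ndarray
    auc: float
    auc_se: float
    auc_ci_low: float
    auc_ci_high: float
    separation: bool = False


def extract_region_stats(map_3d: np.ndarray, labels: np.ndarray,
                         parameter: str) -> list:
    """Mean/max/SD/N per region over non-missing (finite) voxels.

    Whole tumor (WT) pools the ET, necrosis and edema voxels.  Regions with
    no finite voxels yield no entry (some subjects lack edema or necrosis).
    """
    if map_3d.shape != labels.shape:
        raise ValueError("map and label shapes disagree")
    out = []
    lab = np.asarray(labels)
    for region in REGIONS:
        sel = np.isin(lab, [LABELS[r] for r in REGION_CODES[region]])
        vals = map_3d[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        out.append(RegionStats(region=region, parameter=parameter,
                               mean=float(vals.mean()), max=float(vals.max()),
                               sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                               n_voxels=int(vals.size)))
    return out


def normalize_to_nawm(stats_list: list) -> list:
    """Divide each region's mean and max by the subject's NAWM mean.

    K2 passes through unnormalized.  Raises if stats are already normalized
    or if a parameter's NAWM mean is non-positive.
    """
    if any(s.is_normalized for s in stats_list):
        raise ValueError("stats are already normalized to NAWM")
    nawm = {s.parameter: s.mean for s in stats_list if s.region == "NAWM"}
    out = []
    for s in stats_list:
        if s.parameter in UNNORMALIZED_PARAMS:
            out.append(RegionStats(s.region, s.parameter, s.mean, s.max, s.sd,
                                   s.n_voxels, is_normalized=False))
            continue
        if s.parameter not in nawm:
            raise ValueError(f"no NAWM stats for parameter {s.parameter!r}")
        ref = nawm[s.parameter]
        if ref <= 0:
            raise ValueError(f"non-positive NAWM mean for {s.parameter!r}")
        out.append(RegionStats(s.region, s.parameter, s.mean / ref, s.max / ref,
                               s.sd / ref, s.n_voxels, is_normalized=True))
    return out


def mann_whitney(group_a, group_b, spss_compat: bool = False):
    """Two-sided Mann-Whitney U test; U is the smaller orientation.

    Uses the exact null distribution when n1*n2 <= 400 and the data are
    tie-free, otherwise the tie-corrected normal approximation
    (``spss_compat=True`` forces the approximation).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # fully tied: no evidence either way
        return a.size * b.size / 2.0, 1.0
    ties = len(np.unique(pooled)) < a.size + b.size
    if spss_compat or ties or a.size * b.size > 400:
        method = "asymptotic"
    else:
        method = "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return u, float(min(res.pvalue, 1.0))


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(values, labels, clip_ci: bool = False):
    """Nonparametric AUC with Hanley-McNeil SE and 95% CI.

    ``labels`` is binary with 1 = positive class (GBM); higher values are
    taken to indicate the positive class and the orientation is never
    flipped, so AUC < 0.5 is possible.  The CI is auc +- 1.96*SE, unclipped
    by default (mirroring reports that print upper bounds above 1).
    """
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # pairwise probability that a positive outranks a negative (ties count 1/2)
    pos, neg = v[y == 1], v[y == 0]
    diff = pos[:, None] - neg[None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (n_pos * n_neg))
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    lo, hi = auc - 1.96 * se, auc + 1.96 * se
    if clip_ci:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return auc, se, (lo, hi)


def logistic_combine(predictors: np.ndarray, labels, names=None) -> CombinedModel:
    """Unregularized in-sample logistic regression of a parameter combination.

    Constant predictor columns are dropped with a warning.  Complete
    separation is detected and reported (auc = 1, separation flag) instead
    of returning divergent coefficients.
    """
    X = np.asarray(predictors, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, int)
    if X.shape[0] != len(y):
        raise ValueError("predictor rows must match the number of labels")
    if len(y) < X.shape[1] + 2:
        raise ValueError("need at least n_predictors + 2 observations")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    keep = X.std(axis=0) > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant predictor column(s): {dropped}")
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    if X.shape[1] == 0:
        raise ValueError("no non-constant predictors remain")

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
            params = fit.params
            proba = fit.predict()
            if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
                separation = True
        except Exception:
            separation = True
            params = None

    if separation:
        # a tiny ridge keeps the fitted scores finite and monotone in the
        # separating direction; the AUC is reported as exactly 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, sm.add_constant(X)).fit_regularized(
                alpha=1e-4, disp=0, maxiter=500)
        params = np.asarray(fit.params)
        proba = np.asarray(fit.predict(sm.add_constant(X)))
    proba = np.clip(np.asarray(proba, float), 1e-12, 1 - 1e-12)
    auc, se, (lo, hi) = roc_auc(proba, y)
    if separation:
        se = _hanley_mcneil_se(1.0, int(y.sum()), int((1 - y).sum()))
        auc, lo, hi = 1.0, 1.0, 1.0
    return CombinedModel(predictors=names, coefficients=np.asarray(params[1:]),
                         intercept=float(params[0]), fitted_probabilities=proba,
                         auc=auc, auc_se=se, auc_ci_low=lo, auc_ci_high=hi,
                         separation=separation)


# ---------------------------------------------------------------------------
# cohort assembly


def subject_stats(maps: dict, labels: np.ndarray, normalize: bool = True) -> pd.DataFrame:
    """Region stats for a dict of parameter maps, optionally NAWM-normalized.

    ``maps`` maps parameter names (e.g. "APTw", "cCBV", "K2") to 3-D arrays.
    Returns a tidy DataFrame with one row per region x parameter.
    """
    rows = []
    for param, vol in maps.items():
        stats_list = extract_region_stats(vol, labels, param)
        if normalize:
            stats_list = normalize_to_nawm(stats_list)
        rows.extend(stats_list)
    return pd.DataFrame([vars(s) for s in rows])


DEFAULT_COMBINATIONS = (
    ("nAPTw", "ncCBV"),
    ("nAPTw", "nCBF"),
    ("nAPTw", "K2"),
    ("nAPTw", "ncCBV", "K2"),
)

# display name of each normalized parameter
_NORM_NAME = {"APTw": "nAPTw", "APTw_FS": "nAPTw_FS", "CBF": "nCBF",
              "CBV": "nCBV", "cCBV": "ncCBV", "K2": "K2", "MTT": "nMTT"}


def cohort_report(cohort_df: pd.DataFrame, combinations=DEFAULT_COMBINATIONS,
                  spss_compat: bool = False):
    """Cohort-level statistics tables from per-subject normalized stats.

    ``cohort_df`` needs columns: subject, group ("GBM"/"MET"), region,
    parameter, mean, max.  Returns (group_table, roc_table, combo_table):

    * group_table - per parameter x region x statistic: group means of the
      subject means, group maxima of the subject maxima, SDs, Mann-Whitney
      U and two-sided p (one row per statistic kind);
    * roc_table - per-parameter AUC, Hanley-McNeil SE, p, unclipped 95% CI;
    * combo_table - in-sample logistic combinations in the enhancing-tumor
      region for max and mean statistics.

    Regions absent in a subject are simply omitted from that subject's rows;
    group sizes per cell are reported as n_gbm / n_met.
    """
    df = cohort_df.copy()
    df["display"] = df["parameter"].map(lambda p: _NORM_NAME.get(p, p))
    group_rows, roc_rows = [], []
    for (param, region), cell in df.groupby(["display", "region"], sort=False):
        if region == "NAWM":
            continue
        g = cell[cell.group == "GBM"]
        m = cell[cell.group == "MET"]
        if len(g) == 0 or len(m) == 0:
            continue
        for kind in ("max", "mean"):
            gv, mv = g[kind].to_numpy(), m[kind].to_numpy()
            u, p = mann_whitney(gv, mv, spss_compat=spss_compat)
            group_rows.append({
                "parameter": param, "region": region, "statistic": kind,
                "gbm_mean": g["mean"].mean(), "gbm_max": g["max"].max(),
                "gbm_sd": g["mean"].std(ddof=1) if len(g) > 1 else 0.0,
                "met_mean": m["mean"].mean(), "met_max": m["max"].max(),
                "met_sd": m["mean"].std(ddof=1) if len(m) > 1 else 0.0,
                "n_gbm": len(g), "n_met": len(m), "U": u, "p": p,
            })
            vals = np.concatenate([gv, mv])
            y = np.concatenate([np.ones(len(gv), int), np.zeros(len(mv), int)])
            auc, se, (lo, hi) = roc_auc(vals, y)
            roc_rows.append({
                "statistic": kind, "region": region, "parameter": param,
                "auc": auc, "se": se, "p": p, "ci_low": lo, "ci_high": hi,
                "n_gbm": len(gv), "n_met": len(mv),
            })
    group_table = pd.DataFrame(group_rows)
    roc_table = pd.DataFrame(roc_rows)

    combo_rows = []
    et = df[df.region == "ET"]
    for kind in ("max", "mean"):
        wide = et.pivot_table(index=["subject", "group"], columns="display",
                              values=kind)
        for combo in combinations:
            combo = tuple(combo)
            if not all(c in wide.columns for c in combo):
                continue
            sub = wide.loc[:, list(combo)].dropna()
            y = np.array([1 if g == "GBM" else 0
                          for g in sub.index.get_level_values("group")])
            if y.sum() == 0 or y.sum() == len(y):
                continue
            try:
                model = logistic_combine(sub.to_numpy(), y, names=list(combo))
            except ValueError:  # e.g. all predictors constant
                continue
            combo_rows.append({
                "statistic": kind, "parameters": " + ".join(combo),
                "auc": model.auc, "se": model.auc_se,
                "ci_low": model.auc_ci_low, "ci_high": model.auc_ci_high,
                "separation": model.separation, "n": len(y),
            })
    combo_table = pd.DataFrame(
        combo_rows, columns=["statistic", "parameters", "auc", "se",
                             "ci_low", "ci_high", "separation", "n"])
    return group_table, roc_table, combo_table
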