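"""End-to-end cohort pipeline: synthetic subjects -> parameter maps -> tables.

Glue between the per-modality processing chains and the cohort statistics:
computes APTw/APTw_FS and perfusion maps for each subject, extracts
NAWM-normalized region statistics, and assembles the tidy per-subject
DataFrame consumed by :func:`aptperf.roistats.cohort_report`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dsc import DscSeries, compute_perfusion_maps
from .phantom import LABELS, CohortConfig, SyntheticSubject
from .roistats import cohort_report, subject_stats
from .zspectrum import AptwConfig, compute_aptw_maps

__all__ = ["subject_parameter_maps", "analyze_cohort"]


def subject_parameter_maps(subject: SyntheticSubject, config: CohortConfig,
                           aptw_cfg: AptwConfig = AptwConfig(),
                           svd_threshold: float = 0.15) -> dict:
    """Run the APTw and DSC chains on one subject; returns name -> 3D map."""
    labels = subject.labels
    brain = labels > 0
    maps = {}
    if subject.cest_4d is not None:
        am = compute_aptw_maps(subject.cest_4d, subject.s0, brain, aptw_cfg,
                               offsets=np.asarray(config.plan.offsets))
        maps["APTw"] = am.aptw
        maps["APTw_FS"] = am.aptw_fs
    if subject.dsc_4d is not None:
        series = DscSeries(signal=subject.dsc_4d, tr=config.tr, te=config.te)
        enhancing = labels == LABELS["ET"]
        artery = labels == LABELS["artery"]
        pm = compute_perfusion_maps(series, brain, enhancing_mask=enhancing,
                                    aif_seed=artery, svd_threshold=svd_threshold)
        maps["CBF"] = pm.cbf
        maps["cCBV"] = pm.ccbv
        maps["K2"] = pm.k2
    return maps


def analyze_cohort(subjects: list, config: CohortConfig,
                   aptw_cfg: AptwConfig = AptwConfig(),
                   spss_compat: bool = False):
    """Full analysis of a synthetic cohort.

    Returns (cohort_df, group_table, roc_table, combo_table) where cohort_df
    holds the per-subject NAWM-normalized region statistics.
    """
    rows = []
    for i, subj in enumerate(subjects):
        maps = subject_parameter_maps(subj, config, aptw_cfg)
        # exclude the artery from statistics regions (it is not a ROI)
        stats_labels = np.where(subj.labels == LABELS["artery"], 0, subj.labels)
        df = subject_stats(maps, stats_labels, normalize=True)
        df["subject"] = f"sub-{i:03d}"
        df["group"] = subj.truth.group
        rows.append(df)
    cohort_df = pd.concat(rows, ignore_index=True)
    group_table, roc_table, combo_table = cohort_report(cohort_df,
                                                        spss_compat=spss_compat)
    return cohort_df, group_table, roc_table, combo_table
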