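from dataclasses import replace

import numpy as np
import pytest

from aptperf.bmsim import OffsetPlan, default_saturation, wm_pools
from aptperf.phantom import (CohortConfig, build_phantom, generate_dsc,
                             generate_subject, sample_subject_truth)


@pytest.fixture(scope="session")
def wm():
    return wm_pools()


@pytest.fixture(scope="session")
def sat():
    return default_saturation()


@pytest.fixture(scope="session")
def plan():
    return OffsetPlan()


@pytest.fixture(scope="session")
def clean_config():
    """Small noiseless phantom configuration (CEST fidelity checks)."""
    return CohortConfig(shape=(32, 32, 20), noise_sd_cest=0.0,
                        noise_sd_dsc=0.0, b0_amp=0.0)


@pytest.fixture(scope="session")
def clean_subject(clean_config):
    return generate_subject("GBM", clean_config, seed=11)


@pytest.fixture(scope="session")
def shape_matched():
    """Noiseless shape-matched DSC subject without leakage."""
    return shape_matched_dsc(et_k2=0.0)


def shape_matched_dsc(et_k2: float = 0.0, et_scale: float = 4.0,
                      shape=(32, 32, 20), noise_sd: float = 0.0, seed: int = 5):
    """Noiseless DSC subject whose tissue curves are scalar multiples of NAWM.

    Equal MTT everywhere and zero bolus delays put the data exactly in the
    regime the Boxerman leakage model assumes, so K1/K2 recovery is
    identifiable; ``et_k2`` (1/min) injects leakage into the enhancing rim.
    """
    cfg = CohortConfig(shape=shape, noise_sd_cest=0.0, noise_sd_dsc=noise_sd,
                       b0_amp=0.0)
    truth = sample_subject_truth("GBM", cfg, seed=seed)
    for name, ts in list(truth.tissues.items()):
        if name == "artery":
            continue
        scale = et_scale if name in ("ET", "ET_hot") else 1.0
        k2 = et_k2 if name in ("ET", "ET_hot") else 0.0
        truth.tissues[name] = replace(ts, cbf_rel=scale, cbv_rel=scale,
                                      k2=k2, delay=0.0)
    labels = build_phantom(shape, seed=seed)
    dsc = generate_dsc(truth, labels, cfg, np.random.default_rng(seed + 1))
    return cfg, truth, labels, dsc
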