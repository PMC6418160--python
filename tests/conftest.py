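import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from smokesig import synthdata as sd
from smokesig.synthdata import RawIntensities, SimulationConfig

settings.register_profile(
    "det", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


#: Conditions of the planted-sharing demonstration run: a 500-probe genome,
#: 150 tumour samples, 100 true lung probes of which 40 are shared with a
#: 60-probe blood signature, with effect sizes large enough for the cohort
#: to detect them (the adequately-powered regime).
PLANTED_SIM = dict(
    n_probes=500, n_samples=150, n_true_lung=100, n_true_blood=60, n_shared=40,
    effect_mean=0.15, effect_sd=0.03, blood_effect_mean=0.08, blood_effect_sd=0.02,
    seed=0,
)


@pytest.fixture(scope="session")
def small_annotation():
    return sd.simulate_annotation(400, cross_reactive_frac=0.05, seed=11)


@pytest.fixture(scope="session")
def small_run():
    """One small simulated cohort shared across read-only tests."""
    cfg = SimulationConfig(
        n_probes=300, n_samples=80, n_true_lung=30, n_true_blood=30, n_shared=10, seed=7
    )
    ann = sd.simulate_annotation(cfg.n_probes, cross_reactive_frac=cfg.cross_reactive_frac, seed=1)
    cohort = sd.simulate_cohort(cfg.n_samples, n_plates=cfg.n_plates, seed=2)
    eff = sd.plant_effects(ann, cfg, seed=3)
    raw = sd.simulate_intensities(ann, cohort, eff, cfg, seed=4)
    return cfg, ann, cohort, eff, raw


def make_raw(M, U, neg_totals=None, sample_ids=None, n_oob=50, mu_b=500.0, sigma_b=100.0,
             seed=0):
    """Hand-built RawIntensities for targeted preprocessing tests.

    ``M``/``U`` are probes x samples arrays; negative-control totals can be
    pinned exactly by passing per-sample 1-D arrays (split evenly between
    the two channels).
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    G, n = M.shape
    probes = [f"cg{i:05d}" for i in range(G)]
    samples = sample_ids or [f"s{i}" for i in range(n)]
    rng = np.random.default_rng(seed)
    if neg_totals is None:
        neg_totals = np.maximum(rng.normal(2 * mu_b, np.sqrt(2) * sigma_b, size=(50, n)), 0)
    else:
        neg_totals = np.asarray(neg_totals, dtype=float)
        if neg_totals.ndim == 1:
            neg_totals = np.tile(neg_totals[:, None], (1, n))
    oob = np.maximum(rng.normal(mu_b, sigma_b, size=(n_oob, n)), 0)
    return RawIntensities(
        M=pd.DataFrame(M, index=probes, columns=samples),
        U=pd.DataFrame(U, index=probes, columns=samples),
        oob=pd.DataFrame(oob, columns=samples),
        neg_M=pd.DataFrame(neg_totals / 2, columns=samples),
        neg_U=pd.DataFrame(neg_totals / 2, columns=samples),
    )
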