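import logging

import numpy as np
import pandas as pd
import pytest

from micetrans import synthetic

logging.getLogger("micetrans").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_world():
    cfg = synthetic.WorldConfig(n_mice=12, grid_side=10, n_loggers=25,
                                n_nights=40, n_asv=80, n_genera=10,
                                samples_per_mouse=2, seed=11)
    return synthetic.simulate_world(cfg)


@pytest.fixture(scope="session")
def small_detections(small_world):
    return synthetic.simulate_detections(small_world)


def scripted_detections(rows):
    """Build a detections frame from (individual, logger, iso-timestamp) rows."""
    df = pd.DataFrame(rows, columns=["individual", "logger", "timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def logit_scale_dyads(n_ind=12, reps=2, b0=-0.9, b_sri=0.0, b_ovl=0.0,
                      b_hab=0.0, sd_sample=0.4, sd_indiv=0.4, phi=60.0,
                      seed=0, sex_effects=None):
    """Dyadic dataset with a beta response generated on the logit scale.

    Ground truth for parameter-recovery tests: the response is drawn from
    the exact model the fitter assumes. ``sex_effects`` optionally maps
    sex combo -> additional SRI slope (on top of ``b_sri``).
    """
    from scipy.special import expit

    r = np.random.default_rng(seed)
    n_samp = n_ind * reps
    samp_ind = np.repeat(np.arange(n_ind), reps)
    sex = r.choice(["F", "M"], size=n_ind)
    u = sd_sample * r.standard_normal(n_samp)
    v = sd_indiv * r.standard_normal(n_ind)
    sri_m = r.beta(0.5, 4.0, (n_ind, n_ind))
    ovl_m = r.beta(2.0, 2.0, (n_ind, n_ind))
    hab_m = r.beta(4.0, 4.0, (n_ind, n_ind))
    rows = []
    for i in range(n_samp):
        for j in range(i + 1, n_samp):
            ia, ib = samp_ind[i], samp_ind[j]
            if ia == ib:
                continue
            combo = "".join(sorted(sex[ia] + sex[ib]))
            sri = sri_m[min(ia, ib), max(ia, ib)]
            slope = b_sri + (sex_effects or {}).get(combo, 0.0)
            eta = (b0 + slope * sri
                   + b_ovl * ovl_m[min(ia, ib), max(ia, ib)]
                   + b_hab * hab_m[min(ia, ib), max(ia, ib)]
                   + u[i] + u[j] + v[ia] + v[ib])
            mu = expit(eta)
            rows.append({
                "sample_a": f"s{i}", "sample_b": f"s{j}",
                "indiv_a": f"m{ia}", "indiv_b": f"m{ib}",
                "response": float(r.beta(mu * phi, (1 - mu) * phi)),
                "sri": sri,
                "spatial_overlap": ovl_m[min(ia, ib), max(ia, ib)],
                "habitat_similarity": hab_m[min(ia, ib), max(ia, ib)],
                "sex_combo": combo,
                "sex_similarity": float(sex[ia] == sex[ib]),
                "age_similarity": float(r.random() < 0.5),
                "time_interval_days": float(r.integers(0, 120)),
                "extraction_distance": float(r.uniform(0, 10)),
                "read_depth_difference": float(r.uniform(0, 30000)),
                "plate_similarity": float(r.random() < 0.5),
            })
    return pd.DataFrame(rows)
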