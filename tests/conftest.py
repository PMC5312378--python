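import numpy as np
import pandas as pd
import pytest

from mirsurv import normalize, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_survival_data(rng, n=200, beta_x=0.0, n_cov=2, event_scale=50.0):
    """Small survival dataset with continuous times (no ties) and optional
    planted effect of a standard-normal exposure."""
    x = rng.normal(size=n)
    Z = rng.normal(size=(n, n_cov)) if n_cov else np.empty((n, 0))
    eta = beta_x * x + (0.3 * Z[:, 0] if n_cov else 0.0)
    t_ev = rng.exponential(event_scale * np.exp(-eta))
    cens = np.minimum(rng.exponential(150.0, n), 60.0)
    time = np.maximum(np.minimum(t_ev, cens), 1e-6)
    event = (t_ev <= cens).astype(int)
    return time, event, x, Z


@pytest.fixture
def tiny_km_data():
    # times 1..5; events at 2, 3, 5; censored at 1 and 4
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    events = np.array([0, 1, 1, 0, 1])
    return times, events


@pytest.fixture(scope="session")
def small_study():
    """A small seeded synthetic study shared by read-only tests."""
    cs = simulate.CohortSpec(n_subjects=250, seed=11)
    es = simulate.ExpressionSpec(n_mirnas=40, seed=12)
    ss = simulate.SurvivalSpec(seed=13)
    clinical, carcinoma, normal, truth = simulate.simulate_study(cs, es, ss)
    return clinical, carcinoma, normal, truth


def raw_matrix(rng, n=20, m=50, tissue="carcinoma", zeros_frac=0.2):
    v = rng.lognormal(mean=5.0, sigma=1.0, size=(n, m))
    v[rng.random((n, m)) < zeros_frac] = 0.0
    return normalize.ExpressionMatrix(
        values=pd.DataFrame(
            v,
            index=[f"S{i:03d}" for i in range(n)],
            columns=[f"miR-{j:03d}" for j in range(m)],
        ),
        tissue=tissue,
    )
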