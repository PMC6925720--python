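import numpy as np
import pandas as pd
import pytest

from anaemia_gamm import cohort, synthetic_data as sd


@pytest.fixture(scope="session")
def small_geography():
    cfg = sd.GeographyConfig(districts_per_country=[3, 3, 3, 3],
                             clusters_per_district=2)
    return sd.generate_geography(cfg, seed=10)


@pytest.fixture(scope="session")
def small_dataset():
    """~4000 children, 40 districts, default truth; reused across tests."""
    cfg = sd.GeographyConfig()
    return sd.generate_dataset(cfg, n_children=4000, seed=20)


@pytest.fixture(scope="session")
def tiny_records():
    """400 children in 8 districts, for fast oracle-style fits."""
    cfg = sd.GeographyConfig(districts_per_country=[2, 2, 2, 2],
                             clusters_per_district=2)
    ds = sd.generate_dataset(cfg, n_children=400, seed=30)
    return ds.records


def cox_de_boor(z, knots, degree):
    """Independent brute-force Cox-de Boor recursion (test oracle)."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    t = np.asarray(knots, dtype=float)
    n_basis = len(t) - degree - 1
    B = np.zeros((len(z), len(t) - 1))
    hi = t[-degree - 1]
    for i in range(len(t) - 1):
        B[:, i] = ((z >= t[i]) & (z < t[i + 1])).astype(float)
    # half-open intervals, except the right domain edge closes
    edge = z == hi
    if edge.any():
        B[edge, :] = 0.0
        B[edge, np.searchsorted(t, hi, side="left") - 1] = 1.0
    for k in range(1, degree + 1):
        Bk = np.zeros((len(z), len(t) - k - 1))
        for i in range(len(t) - k - 1):
            left = np.zeros(len(z))
            if t[i + k] > t[i]:
                left = (z - t[i]) / (t[i + k] - t[i]) * B[:, i]
            right = np.zeros(len(z))
            if t[i + k + 1] > t[i + 1]:
                right = (t[i + k + 1] - z) / (t[i + k + 1] - t[i + 1]) * B[:, i + 1]
            Bk[:, i] = left + right
        B = Bk
    return B[:, :n_basis]
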