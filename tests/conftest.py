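"""Shared fixtures: random event tables and an independent product-limit oracle."""

import numpy as np
import pandas as pd
import pytest

import fgmrisk as fr


def brute_force_km(times, events):
    """Textbook product-limit estimator, written independently of the package.

    S(t) = product over distinct event ages u <= t of (1 - d_u / n_u), with
    n_u = #{i : t_i >= u} (persons censored at u stay in the risk set at u).
    """
    times = list(times)
    events = list(events)
    event_ages = sorted({t for t, e in zip(times, events) if e})
    s = []
    for t in range(fr.MAX_AGE + 1):
        prod = 1.0
        for u in (u for u in event_ages if u <= t):
            n_u = sum(1 for ti in times if ti >= u)
            d_u = sum(1 for ti, ei in zip(times, events) if ti == u and ei)
            prod *= 1.0 - d_u / n_u
        s.append(prod)
    return np.array(s)


def random_event_frame(rng, n=None, weighted=False, max_time=fr.MAX_AGE):
    """A random event table: arbitrary event/censor ages, optional weights."""
    n = n if n is not None else int(rng.integers(1, 51))
    times = rng.integers(0, max_time + 1, size=n)
    events = rng.random(n) < rng.uniform(0.2, 0.8)
    weights = rng.uniform(0.2, 5.0, size=n) if weighted else np.ones(n)
    return pd.DataFrame(
        {
            "time": times,
            "event": events,
            "weight": weights,
            "stratum_id": "s1",
            "psu_id": np.arange(n).astype(str),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


@pytest.fixture
def hand_fixture():
    """The five-record worked example: events at 4 and 6, censored 5, 7, 8."""
    return pd.DataFrame(
        {
            "time": [4, 5, 6, 7, 8],
            "event": [True, False, True, False, False],
            "weight": 1.0,
            "stratum_id": "s1",
            "psu_id": ["a", "b", "c", "d", "e"],
        }
    )


@pytest.fixture
def clean_spec():
    """Small synthetic survey spec with misreporting switched off."""
    return fr.SyntheticSpec(
        seed=3,
        n_strata=2,
        clusters_per_stratum=10,
        households_per_cluster=10,
        clusters_sampled_per_stratum=5,
        households_sampled_per_cluster=5,
        heaping_prob=0.0,
        infancy_code_prob=0.0,
    )
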