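"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from cesdemog.data import AGE_ADULT, AGE_JUVENILE, CAPTURE_COLUMNS, CaptureHistorySet, CaptureTable
from cesdemog.simulate import SchemeConfig, SimulationConfig, SpeciesConfig


def capture_row(ring, species="SP", scheme="SC", site="S1", year=2000, visit=1, age=AGE_ADULT):
    return {
        "ring_id": ring,
        "species": species,
        "scheme": scheme,
        "site": site,
        "year": year,
        "visit": visit,
        "age_class": age,
    }


def make_table(rows) -> CaptureTable:
    return CaptureTable(pd.DataFrame(rows, columns=list(CAPTURE_COLUMNS)))


def make_history_set(det_rows, first=None, site_idx=None, site_codes=None, years=None):
    """Build a CaptureHistorySet directly from detection vectors."""
    det = np.array(det_rows, dtype=np.int8)
    n, T = det.shape
    if first is None:
        first = det.argmax(axis=1)
    if site_idx is None:
        site_idx = np.zeros(n, dtype=int)
    if site_codes is None:
        site_codes = sorted({f"S{i}" for i in np.unique(site_idx)})
    if years is None:
        years = np.arange(2000, 2000 + T)
    return CaptureHistorySet(
        species="SP",
        scheme="SC",
        years=np.asarray(years),
        detections=det,
        first=np.asarray(first, dtype=np.int64),
        site_index=np.asarray(site_idx, dtype=np.int64),
        site_codes=list(site_codes),
        ring_ids=[f"r{i}" for i in range(n)],
        multi_site=np.zeros(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# independent CJS oracles (enumeration / direct products, no chi recursion
# shared with the implementation)


def plain_cjs_history_prob(det, phi, p) -> float:
    """Textbook CJS probability of one history, conditional on first capture.

    Computed by summing over all possible death times after the last
    detection (exhaustive, no recursion), so it is independent of the
    implementation's chi bookkeeping.
    """
    det = np.asarray(det)
    T = len(det)
    f = int(det.argmax())
    last = int(T - 1 - det[::-1].argmax())
    prob = 1.0
    for t in range(f, last):
        prob *= phi[t] * (p if det[t + 1] else (1.0 - p))
    # after the last detection: alive-until-death paths, never detected
    total = 0.0
    for death_after in range(last, T):  # survives intervals last..death_after-1
        path = 1.0
        for t in range(last, death_after):
            path *= phi[t] * (1.0 - p)
        if death_after < T - 1:
            path *= 1.0 - phi[death_after]
        total += path
    return prob * total


def transient_cjs_history_prob(det, phi, tau, p) -> float:
    """Mixture transient-CJS probability of one history (enumeration oracle)."""
    det = np.asarray(det)
    f = int(det.argmax())
    resident = plain_cjs_history_prob(det, phi, p)
    if det[f + 1 :].sum() == 0:
        return (1.0 - tau) + tau * resident
    return tau * resident


def enumerate_histories(T, f):
    """All detection vectors of length T with first detection at f."""
    for suffix in itertools.product((0, 1), repeat=T - 1 - f):
        det = [0] * T
        det[f] = 1
        det[f + 1 :] = list(suffix)
        yield det


# ---------------------------------------------------------------------------
# canonical small simulation configs


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """Two schemes, two species: quick but exercises every stage."""
    return SimulationConfig(
        schemes=[
            SchemeConfig("FIN", n_sites=10, n_years=9, mean_temp_c=8.0),
            SchemeConfig("ESP", n_sites=10, n_years=9, mean_temp_c=16.0),
        ],
        species=[
            SpeciesConfig(
                "ACR", phi=0.55, tau=0.7, rho=0.55, mean_new_adults=9,
                migration="long-distance", habitat="reed",
            ),
            SpeciesConfig(
                "PAR", phi=0.5, tau=0.8, rho=0.6, mean_new_adults=9,
                migration="short/resident", habitat="forest",
            ),
            SpeciesConfig(
                "SYL", phi=0.52, tau=0.75, rho=0.5, mean_new_adults=9,
                migration="long-distance", habitat="forest",
            ),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def recovery_scheme_config():
    """The reference single-scheme parameter-recovery design."""
    def factory(seed: int) -> SimulationConfig:
        return SimulationConfig(
            schemes=[SchemeConfig("X", n_sites=30, n_years=12, p_sites=(0.3, 0.6))],
            species=[SpeciesConfig("SP", phi=0.55, tau=0.7, rho=0.55, mean_new_adults=10)],
            seed=seed,
        )

    return factory
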