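"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive algorithms (triple loops, all-pairs
scans) so they stay independent of the vectorized implementations they
check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("ci", derandomize=True)
hypothesis_settings.load_profile("ci")

from isoderep.chem_core import MASS_C, MASS_H, MASS_O, MolecularFormula, reaction_mass_shift
from isoderep.spectra_io import Peak, Spectrum


def brute_force_candidates(neutral_mass, config):
    """Naive triple-loop CHO enumeration inside the tolerance window."""
    tol = neutral_mass * config.tol_ppm * 1e-6
    out = []
    for c in range(1, config.c_max + 1):
        for h in range(0, config.h_max + 1):
            for o in range(0, config.o_max + 1):
                if h > 2 * c + 2:
                    continue
                hc = h / c
                if not (config.hc_range[0] <= hc <= config.hc_range[1]):
                    continue
                if o / c > config.oc_max:
                    continue
                dbe = c - h / 2 + 1
                if dbe < 0:
                    continue
                if config.require_integer_dbe and h % 2:
                    continue
                err = c * MASS_C + h * MASS_H + o * MASS_O - neutral_mass
                if abs(err) <= tol:
                    out.append((abs(err), o, c, MolecularFormula(c=c, h=h, o=o)))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return [f for _, _, _, f in out]


def brute_force_series(spectrum, reaction, tol_mz, k_max):
    """O(n^2 * k_max) all-pairs chain builder, the series-detection oracle.

    Mirrors the contract: chains anchored at the base, nearest peak within
    tolerance (lowest m/z on ties), chain stops at the first missing k, a
    base must have no predecessor at base - delta, singleton chains drop.
    Returns a list of (base_mz, [(k, member_mz), ...]).
    """
    delta = reaction_mass_shift(reaction)
    mz = spectrum.mz

    def nearest(target):
        best_i, best_d = -1, None
        for i, m in enumerate(mz):
            d = abs(m - target)
            if d <= tol_mz and (best_d is None or d < best_d):
                best_i, best_d = i, d
        return best_i

    chains = []
    for b, base in enumerate(mz):
        if nearest(base - delta) >= 0:
            continue  # member of a chain with a lower base
        members = [(0, float(base))]
        for k in range(1, k_max + 1):
            j = nearest(base + k * delta)
            if j < 0:
                break
            members.append((k, float(mz[j])))
        if len(members) > 1:
            chains.append((float(base), members))
    return chains


def random_spectrum(
    rng, n_peaks, mz_range=(100.0, 800.0), planted_chains=0, reaction=None, jitter_sd=5e-5
):
    """Random peaks, optionally with planted chains of a reaction's delta."""
    mzs = list(rng.uniform(*mz_range, size=n_peaks))
    if planted_chains and reaction is not None:
        delta = reaction_mass_shift(reaction)
        for _ in range(planted_chains):
            base = float(rng.uniform(*mz_range))
            length = int(rng.integers(1, 5))
            mzs.append(base)
            for k in range(1, length + 1):
                jit = float(rng.normal(0, jitter_sd)) if jitter_sd else 0.0
                mzs.append(base + k * delta + jit)
    inten = rng.lognormal(10, 1, size=len(mzs))
    return Spectrum.from_peaks("rand", zip(mzs, inten))


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic labeling study (50 compounds, seed 42)."""
    from isoderep.synthetic import generate_mixture, simulate_sample_set

    truth = generate_mixture(50, seed=42)
    study = simulate_sample_set(truth, background_n=500, seed=42)
    return study


@pytest.fixture(scope="session")
def default_pipeline_result(default_study):
    """Detection -> merge -> final filter on the default study."""
    from isoderep.dereplication import detect_exogenous, final_filter, merge_routes

    per_route = {
        route: detect_exogenous(default_study.sample_set, route)
        for route in default_study.sample_set.labeled_admin
    }
    merged = merge_routes(per_route)
    return per_route, merged, final_filter(merged)
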