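"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")

PSM_DEFAULTS = {
    "spectrum_id": "s0", "group": "control", "bio_replicate": 1,
    "tech_replicate": 1, "peptide": "PEPTIDEK", "protein_id": "P1",
    "protein_start": 1, "mod_site": 0, "delta_mass": 0.0,
    "peptide_mass": 900.0, "score": 600.0, "delta_mods_score": 50.0,
    "fdr2d": 0.005, "fdr_uniq2d": 0.005,
}


def make_psms(rows):
    """Build a canonical PSM frame from partial row dicts."""
    from ncaadelta.psmio import CANONICAL_COLUMNS
    full = [{**PSM_DEFAULTS, "spectrum_id": f"s{i}", **r}
            for i, r in enumerate(rows)]
    if not full:
        return pd.DataFrame({c: pd.Series(dtype=type(PSM_DEFAULTS[c]))
                             for c in CANONICAL_COLUMNS})
    return pd.DataFrame(full)[CANONICAL_COLUMNS]


@pytest.fixture(scope="session")
def fitted_default_scenario():
    """One seeded reference-scenario run shared by the slower tests."""
    from ncaadelta import DeltaMassModel, default_scenario
    truth, config, psms = default_scenario(seed=11)
    results = DeltaMassModel(psms).fit(seed=11)
    return truth, config, psms, results


# ---------------------------------------------------------------------------
# Independent oracles (never call the code paths they check)

def grid_gaussian_fit(x, bin_width=0.001, rounds=5, grid=25):
    """Brute-force Gaussian fit: coarse-to-fine grid search minimizing the
    same binned least-squares objective as the production regression."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min() - bin_width, x.max() + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2

    def sse(a, mu, s):
        return np.sum((counts - a * np.exp(-0.5 * ((centers - mu) / s) ** 2)) ** 2)

    a0, mu0, s0 = counts.max(), x.mean(), max(x.std(), bin_width)
    wa, wmu, ws = a0, 4 * s0, 0.9 * s0
    best = (a0, mu0, s0)
    for _ in range(rounds):
        a_g = np.linspace(max(best[0] - wa, 1e-9), best[0] + wa, grid)
        mu_g = np.linspace(best[1] - wmu, best[1] + wmu, grid)
        s_g = np.linspace(max(best[2] - ws, 1e-9), best[2] + ws, grid)
        scores = np.array([[[sse(a, m, s) for s in s_g] for m in mu_g] for a in a_g])
        ia, im, isd = np.unravel_index(np.argmin(scores), scores.shape)
        best = (a_g[ia], mu_g[im], s_g[isd])
        wa /= grid / 2.5
        wmu /= grid / 2.5
        ws /= grid / 2.5
    return best[1], best[2]


def _em_1d(x, k, rng, n_iter=200):
    """Plain 1-D Gaussian-mixture EM, one random start."""
    n = len(x)
    mu = rng.choice(x, size=k, replace=False).astype(float)
    var = np.full(k, max(x.var(), 1e-10))
    w = np.full(k, 1.0 / k)
    for _ in range(n_iter):
        dens = (w / np.sqrt(2 * np.pi * var)
                * np.exp(-0.5 * (x[:, None] - mu) ** 2 / var))
        tot = dens.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1e-300
        resp = dens / tot
        nk = resp.sum(axis=0)
        nk[nk == 0] = 1e-12
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        var = np.maximum(var, 1e-10)
        w = nk / n
    dens = (w / np.sqrt(2 * np.pi * var)
            * np.exp(-0.5 * (x[:, None] - mu) ** 2 / var))
    ll = float(np.log(np.maximum(dens.sum(axis=1), 1e-300)).sum())
    return ll


def brute_force_bic_k(x, k_range=(1, 2, 3), restarts=30, seed=0):
    """Exhaustive mixture-order selection: for each k, best log-likelihood
    over many randomly started EM runs; BIC = -2 LL + (3k - 1) ln n,
    minimized (equivalently the negated value is maximized)."""
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(x)
    bics = []
    for k in k_range:
        ll = max(_em_1d(x, k, rng) for _ in range(restarts))
        bics.append(-2 * ll + (3 * k - 1) * np.log(n))
    return k_range[int(np.argmin(bics))]
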