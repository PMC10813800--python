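"""Windowing, mixture fitting with BIC selection, constraint semantics and
Gaussian peak regression."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_bic_k, grid_gaussian_fit
from ncaadelta.cluster import (ClusterParams, MixtureComponent, SD_FLOOR,
                               WindowFitResult, apply_cluster_constraints,
                               assign_windows, cluster_observations,
                               fit_window_gmm, gaussian_regression)


def obs_frame(deltas, peptide_mass=1500.0, residue="M"):
    deltas = np.asarray(deltas, dtype=float)
    return pd.DataFrame({
        "protein_id": "P1", "protein_position": 5, "residue": residue,
        "delta_mass_raw": deltas, "delta_mass_4dp": np.round(deltas, 4),
        "peptide_mass": peptide_mass, "group": "control",
        "bio_replicate": 1, "tech_replicate": 1,
    })


class TestWindows:
    def test_assignment_and_half_open_boundary(self):
        obs = obs_frame([15.9949, 16.4999, 16.5, -0.5, -200.49, 1000.49])
        out = assign_windows(obs)
        assert list(out["window_n"]) == [16, 16, 17, 0, -200, 1000]

    def test_out_of_range_excluded(self):
        obs = obs_frame([1200.0, 15.9949, -200.51])
        out = assign_windows(obs)
        assert list(out["window_n"]) == [16]


class TestMixtureFit:
    def test_single_gaussian_selects_k1(self):
        rng = np.random.default_rng(42)
        x = rng.normal(15.9949, 0.002, 500)
        fit = fit_window_gmm(x, 16, max_k=5, seed=0)
        assert fit.k_selected == 1
        assert abs(fit.components[0].mean - 15.9949) < 0.0003

    def test_two_well_separated_components(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(42.0106, 0.003, 400),
                            rng.normal(42.0470, 0.003, 400)])
        fit = fit_window_gmm(x, 42, max_k=5, seed=0)
        assert fit.k_selected == 2
        means = sorted(c.mean for c in fit.components)
        assert means[0] == pytest.approx(42.0106, abs=0.001)
        assert means[1] == pytest.approx(42.0470, abs=0.001)

    def test_bic_reported_larger_is_stronger(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(42.0106, 0.003, 400),
                            rng.normal(42.0470, 0.003, 400)])
        fit = fit_window_gmm(x, 42, max_k=3, seed=0)
        assert fit.bic_per_k[fit.k_selected - 1] == max(fit.bic_per_k)

    def test_degenerate_duplicates_floored(self):
        x = np.full(21, 0.9840)
        fit = fit_window_gmm(x, 1, max_k=5, seed=0)
        assert fit.k_selected == 1
        assert fit.components[0].sd == SD_FLOOR

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError):
            fit_window_gmm(np.array([1.0]), 1)

    @pytest.mark.parametrize("case_seed,k_true", [(0, 1), (1, 1), (2, 2),
                                                  (3, 2), (4, 1), (5, 2)])
    def test_selection_agrees_with_brute_force_oracle(self, case_seed, k_true):
        """On small windows (<= 100 obs, k <= 2) the BIC choice matches an
        independent exhaustive EM over k in {1, 2, 3}."""
        rng = np.random.default_rng(100 + case_seed)
        if k_true == 1:
            x = rng.normal(57.0215, 0.004, 90)
        else:
            x = np.concatenate([rng.normal(57.0215, 0.003, 50),
                                rng.normal(57.0800, 0.003, 50)])
        fit = fit_window_gmm(x, 57, max_k=3, seed=0)
        assert fit.k_selected == brute_force_bic_k(x, seed=case_seed)


class TestGaussianRegression:
    def test_recovers_planted_peak(self):
        rng = np.random.default_rng(3)
        x = rng.normal(79.9663, 0.003, 1000)
        peak, sd, r2 = gaussian_regression(x)
        assert r2 > 0.9
        assert abs(peak - 79.9663) < 0.0005
        assert sd == pytest.approx(0.003, rel=0.2)

    def test_uniform_deltas_fit_poorly(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(41.5, 42.5, 500)
        _, _, r2 = gaussian_regression(x)
        assert r2 < 0.5

    def test_single_bin_degenerates_with_floor(self):
        x = np.full(30, 15.9949)
        peak, sd, r2 = gaussian_regression(x)
        assert peak == pytest.approx(15.9949)
        assert sd == SD_FLOOR
        assert r2 == 0.0

    def test_requires_21_members(self):
        with pytest.raises(ValueError):
            gaussian_regression(np.zeros(20))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_grid_search_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        x = rng.normal(42.0106, 0.002 + 0.001 * seed, 400)
        peak, sd, _ = gaussian_regression(x)
        peak_o, sd_o = grid_gaussian_fit(x)
        assert abs(peak - peak_o) < 1e-4
        assert abs(sd - sd_o) < 1e-4


def manual_fit(deltas, groups):
    """Build a WindowFitResult by hand from index groups (no GMM)."""
    comps = []
    for idx in groups:
        idx = np.asarray(idx)
        sub = deltas[idx]
        comps.append(MixtureComponent(
            mean=float(sub.mean()), sd=max(float(sub.std()), SD_FLOOR),
            weight=len(idx) / len(deltas), members=idx))
    n = int(np.floor(deltas.mean() + 0.5))
    return WindowFitResult(window_n=n, k_candidates=[len(groups)],
                           bic_per_k=[0.0], k_selected=len(groups),
                           components=comps)


class TestConstraints:
    def test_size_must_strictly_exceed_20(self):
        rng = np.random.default_rng(11)
        a = rng.normal(42.0106, 0.003, 21)
        b = rng.normal(42.4000, 0.003, 20)
        deltas = np.concatenate([a, b])
        fit = manual_fit(deltas, [np.arange(21), np.arange(21, 41)])
        clusters = apply_cluster_constraints(fit, deltas,
                                             np.full(41, 1500.0), seed=0)
        assert len(clusters) == 1
        assert clusters[0].size == 21

    def test_half_width_must_exceed_1ppm(self):
        rng = np.random.default_rng(12)
        spread = rng.normal(42.0106, 0.003, 40)   # ~2 ppm of 1500 Da
        dupes = np.full(40, 42.4000)              # floored SD ~ 0.007 ppm
        deltas = np.concatenate([spread, dupes])
        fit = manual_fit(deltas, [np.arange(40), np.arange(40, 80)])
        clusters = apply_cluster_constraints(fit, deltas,
                                             np.full(80, 1500.0), seed=0)
        assert len(clusters) == 1
        assert clusters[0].half_width_ppm > 1.0
        assert clusters[0].peak == pytest.approx(42.0106, abs=0.002)

    def test_close_components_merged_and_refit(self):
        rng = np.random.default_rng(13)
        a = rng.normal(42.0106, 0.003, 300)
        b = rng.normal(42.0146, 0.003, 300)   # 0.004 Da apart < 2 x 0.003
        deltas = np.concatenate([a, b])
        fit = manual_fit(deltas, [np.arange(300), np.arange(300, 600)])
        clusters = apply_cluster_constraints(fit, deltas,
                                             np.full(600, 1500.0), seed=0)
        assert len(clusters) == 1
        assert clusters[0].size == 600

    def test_separated_components_not_merged(self):
        rng = np.random.default_rng(14)
        a = rng.normal(42.0106, 0.003, 300)
        b = rng.normal(42.0470, 0.003, 300)   # 12 SD apart
        deltas = np.concatenate([a, b])
        fit = manual_fit(deltas, [np.arange(300), np.arange(300, 600)])
        clusters = apply_cluster_constraints(fit, deltas,
                                             np.full(600, 1500.0), seed=0)
        assert len(clusters) == 2


class TestClusterObservations:
    def test_partition_and_ids(self):
        rng = np.random.default_rng(15)
        obs = pd.concat([
            obs_frame(rng.normal(15.9949, 0.003, 200), residue="M"),
            obs_frame(rng.normal(42.0106, 0.003, 200), residue="K"),
        ], ignore_index=True)
        clusters, report = cluster_observations(obs, seed=0)
        assert [c.cluster_id for c in clusters] == ["C0001", "C0002"]
        all_members = np.concatenate([c.members for c in clusters])
        assert len(all_members) == len(set(all_members))
        assert sum(c.size for c in clusters) <= len(obs)
        assert {c.window_n for c in clusters} == {16, 42}
        assert all(c.dominant_fraction == 1.0 for c in clusters)
        assert set(report["windows"]) == {16, 42}

    def test_row_order_permutation_stability(self):
        rng = np.random.default_rng(16)
        obs = pd.concat([
            obs_frame(rng.normal(15.9949, 0.003, 150)),
            obs_frame(rng.normal(16.1000, 0.003, 150)),
        ], ignore_index=True)
        c1, _ = cluster_observations(obs, seed=0)
        perm = obs.sample(frac=1.0, random_state=99).reset_index(drop=True)
        c2, _ = cluster_observations(perm, seed=0)
        p1 = sorted(c.peak for c in c1)
        p2 = sorted(c.peak for c in c2)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_small_windows_skipped_with_diagnostic(self):
        obs = obs_frame([15.9949] * 5)
        clusters, report = cluster_observations(obs, seed=0)
        assert clusters == []
        assert "skipped" in report["windows"][16]
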