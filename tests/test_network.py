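"""Coexpression network: transform/filter, adjacency, TOM, module detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from venomics import network, simulate
from venomics.exceptions import ValidationError


def _cfg(**kw):
    return network.NetworkConfig(**kw)


class TestTransformAndFilter:
    def test_constant_transcript_dropped(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(3, 1, (20, 6)), columns=[f"s{i}" for i in range(6)],
            index=[f"t{i}" for i in range(20)],
        )
        expr.loc["t0"] = 100.0  # constant -> zero variance
        kept = network.transform_and_filter(expr, _cfg(filter_quantile=1.0))
        assert "t0" not in kept.index

    def test_monotone_transform_preserves_sample_ranks(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(3, 1, (5, 6)), columns=[f"s{i}" for i in range(6)]
        )
        t = network.transform_and_filter(expr, _cfg(filter_quantile=1.0))
        for tid in t.index:
            raw = expr.loc[tid].rank()
            trans = t.loc[tid].rank()
            pd.testing.assert_series_equal(raw, trans)

    def test_planted_high_dispersion_retained_first(self, rng):
        n_bg = 40
        base = rng.lognormal(3, 0.1, (n_bg, 8))
        hot = rng.lognormal(3, 1.5, (4, 8))  # matched mean scale, high dispersion
        expr = pd.DataFrame(
            np.vstack([base, hot]),
            index=[f"bg{i}" for i in range(n_bg)] + [f"hot{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(8)],
        )
        kept = network.transform_and_filter(expr, _cfg(filter_quantile=0.1))
        assert sum(t.startswith("hot") for t in kept.index) >= 3

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        with pytest.raises(ValidationError):
            network.transform_and_filter(expr)


class TestAdjacency:
    def test_power_arithmetic(self):
        # two transcripts with known correlation ~0.9 is fiddly; test the map
        # directly through a constructed correlation of +/-1 and the formula
        samples = [f"s{i}" for i in range(6)]
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        expr = pd.DataFrame(
            [x, -x, x * 2 + 1], index=["up", "down", "up2"], columns=samples
        )
        a = network.adjacency(expr, _cfg(beta=10))
        assert a.loc["up", "down"] == pytest.approx(1.0)  # unsigned: |cor| = 1
        assert a.loc["up", "up2"] == pytest.approx(1.0)
        assert np.allclose(np.diag(a), 0.0)
        signed = network.adjacency(expr, _cfg(beta=10, signed=True))
        assert signed.loc["up", "down"] == pytest.approx(0.0)

    def test_beta_exponent_value(self):
        assert 0.9**10 == pytest.approx(0.34867844)

    def test_adjacency_bounds_and_symmetry(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(15, 10)), columns=[f"s{i}" for i in range(10)]
        )
        a = network.adjacency(expr, _cfg()).to_numpy()
        assert ((a >= 0) & (a <= 1)).all()
        np.testing.assert_allclose(a, a.T)

    def test_increasing_beta_never_increases_adjacency(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(10, 8)), columns=[f"s{i}" for i in range(8)]
        )
        a5 = network.adjacency(expr, _cfg(beta=5)).to_numpy()
        a12 = network.adjacency(expr, _cfg(beta=12)).to_numpy()
        assert (a12 <= a5 + 1e-12).all()

    def test_zero_variance_rejected(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]], columns=list("abcd")
        )
        with pytest.raises(ValidationError):
            network.adjacency(expr, _cfg())


def _tom_brute_force(a):
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.empty_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTopologicalOverlap:
    def test_three_node_hand_example(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = network.topological_overlap(pd.DataFrame(a))
        # (0.25 + 0.5) / (1 + 0.5) = 0.5
        assert tom.iloc[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(tom), 1.0)

    def test_zero_adjacency_gives_zero_overlap(self):
        tom = network.topological_overlap(pd.DataFrame(np.zeros((4, 4))))
        off = tom.to_numpy()[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(10):
            raw = rng.uniform(0, 1, (10, 10))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = network.topological_overlap(pd.DataFrame(a)).to_numpy()
            np.testing.assert_allclose(tom, _tom_brute_force(a), atol=1e-12)
            assert ((tom >= 0) & (tom <= 1 + 1e-12)).all()

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValidationError):
            network.topological_overlap(pd.DataFrame(a))


class TestDetectModules:
    # uncorrelated (orthogonal, zero-mean) block profiles for the unsigned net
    _ORTHOGONAL = np.array([[1.5, 0.0, -1.5], [0.87, -1.73, 0.87]])

    def _planted(self, seed, within=0.95, n_bg=0, patterns=None, signed=False):
        expr, samples, truth = simulate.simulate_coexpression(
            n_modules=2, transcripts_per_module=10, n_background=n_bg,
            within_cor=within, n_samples_per_treatment=4, seed=seed,
            patterns=self._ORTHOGONAL if patterns is None else patterns,
        )
        cfg = _cfg(filter_quantile=1.0, signed=signed)
        t = network.transform_and_filter(expr, cfg)
        tom = network.topological_overlap(network.adjacency(t, cfg))
        return network.detect_modules(tom, cfg), truth, t, samples

    def test_two_uncorrelated_blocks_recovered_exactly(self):
        assign, truth, _, _ = self._planted(seed=3, within=0.99)
        true = pd.Series(truth.modules)[assign.index]
        assert adjusted_rand_score(true, assign) == pytest.approx(1.0)
        assert assign.nunique() == 2

    def test_unsigned_network_coassigns_exact_opposites(self, rng):
        # perfectly anti-correlated rows are indistinguishable to |cor|^beta,
        # so the unsigned network merges them; the signed network splits them
        v = rng.normal(0.0, 1.0, 12)
        up = [v + rng.normal(0, 0.01, 12) for _ in range(6)]
        down = [-v + rng.normal(0, 0.01, 12) for _ in range(6)]
        expr_t = pd.DataFrame(
            np.vstack([up, down]),
            index=[f"u{i}" for i in range(6)] + [f"d{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(12)],
        )
        unsigned = network.detect_modules(
            network.topological_overlap(network.adjacency(expr_t, _cfg())), _cfg()
        )
        assert unsigned.nunique() == 1
        cfg_s = _cfg(signed=True)
        signed = network.detect_modules(
            network.topological_overlap(network.adjacency(expr_t, cfg_s)), cfg_s
        )
        truth = pd.Series([1] * 6 + [2] * 6, index=expr_t.index)
        assert adjusted_rand_score(truth, signed) == pytest.approx(1.0)

    def test_opposite_profile_blocks_separated_by_signed_network(self):
        opposite = np.array([[1.5, 0.0, -1.5], [-1.5, 0.0, 1.5]])
        assign_s, truth_s, _, _ = self._planted(
            seed=5, within=0.99, patterns=opposite, signed=True
        )
        true_s = pd.Series(truth_s.modules)[assign_s.index]
        assert adjusted_rand_score(true_s, assign_s) == pytest.approx(1.0)

    def test_background_only_has_no_structure(self):
        expr, _, truth = simulate.simulate_coexpression(
            n_modules=0, transcripts_per_module=0, n_background=30,
            within_cor=0.0, n_samples_per_treatment=4, seed=9,
        )
        cfg = _cfg(filter_quantile=1.0)
        t = network.transform_and_filter(expr, cfg)
        tom = network.topological_overlap(network.adjacency(t, cfg))
        assign = network.detect_modules(tom, cfg)
        planted = pd.Series(truth.modules)[assign.index]
        ari = adjusted_rand_score(planted, assign)
        assert abs(ari) < 0.2  # no agreement with any labelling

    def test_min_module_size_larger_than_n_backgrounds_everything(self):
        assign, _, _, _ = self._planted(seed=3)
        tom = pd.DataFrame(np.eye(len(assign)), index=assign.index,
                           columns=assign.index)
        all_bg = network.detect_modules(tom, _cfg(min_module_size=1000))
        assert (all_bg == 0).all()

    def test_single_transcript_is_trivially_one_module(self):
        tom = pd.DataFrame([[1.0]], index=["t"], columns=["t"])
        assign = network.detect_modules(tom, _cfg())
        assert assign.tolist() == [1]


class TestModuleProfiles:
    def test_profiles_follow_planted_pattern(self):
        expr, samples, truth = simulate.simulate_coexpression(
            n_modules=1, transcripts_per_module=8, n_background=0,
            within_cor=0.99, n_samples_per_treatment=6, seed=21,
            patterns=np.array([[2.0, 0.0, -2.0]]),
        )
        cfg = _cfg(filter_quantile=1.0)
        t = network.transform_and_filter(expr, cfg)
        assign = pd.Series(1, index=t.index, name="module")
        prof = network.module_profiles(assign, t, samples)
        # planted block is highest in treatment A, lowest in B
        assert prof.loc[1, "A"] > prof.loc[1, "A+B"] > prof.loc[1, "B"]

    def test_missing_treatment_errors(self):
        expr_t = pd.DataFrame(
            [[1.0, 2.0], [2.0, 1.0]], index=["t1", "t2"], columns=["s1", "s2"]
        )
        samples = pd.DataFrame({"sample_id": ["s1"], "venom_type": ["A"]})
        assign = pd.Series([1, 1], index=["t1", "t2"])
        with pytest.raises(ValidationError):
            network.module_profiles(assign, expr_t, samples)

    def test_identical_transcripts_profile_equals_member_means(self):
        samples = pd.DataFrame(
            {"sample_id": ["a1", "a2", "b1", "b2"],
             "venom_type": ["A", "A", "B", "B"]}
        )
        row = [1.0, 3.0, 5.0, 7.0]
        expr_t = pd.DataFrame([row, row], index=["t1", "t2"],
                              columns=samples["sample_id"])
        assign = pd.Series([1, 1], index=["t1", "t2"])
        prof = network.module_profiles(assign, expr_t, samples)
        assert prof.loc[1, "A"] == pytest.approx(2.0)
        assert prof.loc[1, "B"] == pytest.approx(6.0)
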