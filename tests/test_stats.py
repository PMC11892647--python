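"""Rank tests and the four-comparison battery."""

import dataclasses
import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, strategies as st
from scipy.stats import rankdata

from somamorph import (
    SimConfig,
    generate_ganglion_pair,
    mann_whitney,
    raincloud_data,
    records_from_truth,
    records_to_frame,
    run_battery,
    sample_cell_population,
    spearman,
)
from somamorph.phantom import GroundTruthTable


def brute_force_mw(a, b):
    """Independent enumeration oracle: U and P(min-U as extreme) over all
    labelings of the pooled sample."""
    pooled = np.concatenate([a, b])
    n1, n, nn = len(a), len(pooled), len(a) * len(b)
    ranks = rankdata(pooled)
    u_obs = min(
        ranks[:n1].sum() - n1 * (n1 + 1) / 2,
        nn - (ranks[:n1].sum() - n1 * (n1 + 1) / 2),
    )
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        u1 = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        hits += min(u1, nn - u1) <= u_obs + 1e-9
    return u_obs, hits / total


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.exact

    def test_identical_samples_give_central_u(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(a, a)
        assert res.statistic == len(a) ** 2 / 2

    def test_interleaved_samples_match_enumeration_oracle(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        res = mann_whitney(a, b)
        u, p = brute_force_mw(np.array(a), np.array(b))
        assert res.statistic == u
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(1, 12, size=2)
            a, b = rng.normal(size=n1), rng.normal(size=n2)
            from somamorph.stats import _u_from_ranks

            u1, u2 = _u_from_ranks(a, b)
            assert u1 + u2 == pytest.approx(n1 * n2)
            assert 0 <= mann_whitney(a, b).statistic <= n1 * n2

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=8), rng.normal(size=6) + 0.5
        base = mann_whitney(a, b)
        for f in (np.exp, lambda x: x**3, lambda x: np.arctan(x / 3)):
            res = mann_whitney(f(a), f(b))
            assert res.statistic == base.statistic
            assert res.p_value == pytest.approx(base.p_value)

    def test_large_sample_path_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(size=120)
        b = rng.lognormal(0.4, size=150)
        res = mann_whitney(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.statistic == min(ref.statistic, len(a) * len(b) - ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tied_data_uses_corrected_approximation(self):
        a = [1.0, 1.0, 2.0, 2.0, 3.0] * 4
        b = [2.0, 3.0, 3.0, 4.0, 4.0] * 4
        res = mann_whitney(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert not res.exact
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_perfect_inverse_relation(self):
        x = np.arange(10.0)
        res = spearman(x, -2 * x + 5)
        assert res.statistic == -1.0
        assert res.p_value == 0.0

    def test_perfect_agreement_on_permutation(self):
        rng = np.random.default_rng(3)
        x = rng.permutation(np.arange(1.0, 21.0))
        res = spearman(x, x)
        assert res.statistic == 1.0

    def test_tied_data_matches_midrank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([10.0, 9.0, 7.0, 7.0, 5.0, 1.0])
        rs_oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        res = spearman(x, y)
        assert res.statistic == pytest.approx(rs_oracle, abs=1e-12)

    def test_equals_spearman_of_ranks(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = spearman(x, y)
        b = spearman(rankdata(x), rankdata(y))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=100)
        y = 0.3 * x + rng.normal(size=100)
        res = spearman(x, y)
        ref = scipy.stats.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [3.0, 4.0])


class TestBattery:
    def test_emits_four_comparisons_on_phantom(self, measured_reduced):
        _, _, _, _, records, _ = measured_reduced
        summary, tests = run_battery(records)
        assert [t.label for t in tests] == [
            "left_vs_right_volume",
            "dorsal_vs_ventral_volume",
            "superficial_vs_internalized_volume",
            "volume_vs_depth_internalized",
        ]
        assert summary.n_total == 1099
        assert sum(summary.counts_by_depth_class.values()) == summary.n_included

    def test_mirror_exact_pair_gives_central_u(self):
        cfg = dataclasses.replace(
            SimConfig.reduced(), n_cells_left=120, n_cells_right=120, mirror_exact=True
        )
        _, truth = generate_ganglion_pair(cfg, seed=4)
        df = records_to_frame(records_from_truth(truth))
        _, tests = run_battery(df, volume_column="volume_voxel_um3")
        lr = [t for t in tests if t.label == "left_vs_right_volume"][0]
        assert lr.statistic == lr.n1 * lr.n2 / 2

    def test_planted_effects_drive_expected_outcomes(self, sampled_populations):
        """Dorsal>ventral and superficial>internalized reject nearly always;
        the planted depth trend shows a negative Spearman sign."""
        dv_reject = si_reject = neg_rho = lr_reject = 0
        n = len(sampled_populations)
        for cells in sampled_populations:
            truth = GroundTruthTable(rows=cells, config=SimConfig())
            _, tests = run_battery(records_to_frame(records_from_truth(truth)))
            by = {t.label: t for t in tests}
            dv_reject += by["dorsal_vs_ventral_volume"].p_value < 0.05
            si_reject += by["superficial_vs_internalized_volume"].p_value < 0.05
            lr_reject += by["left_vs_right_volume"].p_value < 0.05
            neg_rho += by["volume_vs_depth_internalized"].statistic < 0
        assert dv_reject >= 0.95 * n
        assert si_reject >= 0.95 * n
        assert neg_rho >= 0.95 * n
        assert lr_reject <= 0.10 * n

    def test_null_phantom_keeps_nominal_false_positive_rates(self):
        """With no planted effects all four battery tests should reject at
        roughly the nominal level."""
        # smaller counts: with the full lognormal spread and no depth trend
        # the interior cannot pack 526 cells, and the nominal level does
        # not depend on group size
        cfg = dataclasses.replace(
            SimConfig(),
            dorsal_scale=1.0,
            depth_slope=0.0,
            target_depth_rho=0.0,
            n_cells_left=300,
            n_cells_right=300,
        )
        rejections = {k: 0 for k in (
            "left_vs_right_volume",
            "dorsal_vs_ventral_volume",
            "superficial_vs_internalized_volume",
            "volume_vs_depth_internalized",
        )}
        n_seeds = 200
        for seed in range(n_seeds):
            cells = sample_cell_population(dataclasses.replace(cfg, seed=seed))
            truth = GroundTruthTable(rows=cells, config=cfg)
            _, tests = run_battery(records_to_frame(records_from_truth(truth)))
            for t in tests:
                rejections[t.label] += t.p_value < 0.05
        for label, k in rejections.items():
            assert k / n_seeds <= 0.10, (label, k / n_seeds)

    def test_empty_group_skips_comparison_without_error(self):
        cfg = dataclasses.replace(
            SimConfig.reduced(), n_cells_left=0, n_cells_right=30, internal_fraction=0.0
        )
        _, truth = generate_ganglion_pair(cfg, seed=6)
        df = records_to_frame(records_from_truth(truth))
        _, tests = run_battery(df)
        labels = [t.label for t in tests]
        assert "left_vs_right_volume" not in labels
        assert "volume_vs_depth_internalized" not in labels


class TestRaincloud:
    def test_quartiles_and_density_shapes(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(size=200)
        out = raincloud_data(v)
        assert out["quartiles"]["median"] == pytest.approx(np.median(v))
        assert len(out["kde_x"]) == len(out["kde_density"]) == 128
        assert (out["kde_density"] >= 0).all()
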