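import numpy as np
import pytest

from _oracles import grid_min_residual, one_way_anova_f
from waspmorph.landmark_io import AppendageLengths, LandmarkConfiguration
from waspmorph.symmetry import (
    appendage_asymmetry,
    compare_symmetry,
    reflect_relabel,
    symmetry_score,
)
from waspmorph.synthetic import GeneratorConfig, hybrid_template, sample_head


def _rot(theta):
    return np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])


class TestReflectRelabel:
    def test_symmetric_configuration_is_fixed_point(self, symmetric_config):
        out = reflect_relabel(symmetric_config)
        np.testing.assert_allclose(out.coords, symmetric_config.coords, atol=1e-12)

    def test_involution(self, random_config_factory):
        c = random_config_factory()
        twice = reflect_relabel(reflect_relabel(c))
        np.testing.assert_allclose(twice.coords, c.coords, atol=1e-9)

    def test_displacement_moves_to_partner_label(self, symmetric_config, scheme):
        coords = symmetric_config.coords.copy()
        delta = np.array([0.03, -0.02])
        i = scheme.index("cheek-arc-L")
        j = scheme.index("cheek-arc-R")
        coords[i] += delta
        c = symmetric_config.with_coords(coords)
        out = reflect_relabel(c)
        # the perturbation reappears, mirrored in x, under the right label
        expected = coords[i].copy()
        expected[0] = -expected[0]
        np.testing.assert_allclose(out.coords[j], expected, atol=1e-12)
        # the left label now carries the mirror of the untouched right landmark
        np.testing.assert_allclose(out.coords[i], symmetric_config.coords[i], atol=1e-12)

    def test_preserves_centroid_size_exactly(self, random_config_factory):
        c = random_config_factory()
        assert reflect_relabel(c).centroid_size == pytest.approx(c.centroid_size, rel=1e-14)

    def test_works_in_any_orientation(self, random_config_factory):
        c = random_config_factory()
        moved = c.with_coords(c.coords @ _rot(1.3).T + [4.0, -2.0])
        a = symmetry_score(c)
        b = symmetry_score(moved)
        assert a.d_sym == pytest.approx(b.d_sym, abs=1e-9)


class TestSymmetryScore:
    def test_mirror_symmetric_head_scores_exactly(self, symmetric_config):
        res = symmetry_score(symmetric_config)
        assert res.d_sym == 0.0
        assert res.correlation_pct == 100.0

    def test_matches_rotation_grid_oracle(self, random_config_factory):
        c = random_config_factory(jitter=0.04)
        reflected = reflect_relabel(c)
        res = symmetry_score(c)
        grid = grid_min_residual(c.coords, reflected.coords, allow_scale=True, step=0.001)
        assert abs(res.d_sym - grid) < 1e-6

    def test_invariant_under_similarity_transforms(self, random_config_factory):
        c = random_config_factory()
        base = symmetry_score(c).correlation_pct
        moved = c.with_coords(3.0 * c.coords @ _rot(-0.8).T + [1.0, 9.0])
        assert symmetry_score(moved).correlation_pct == pytest.approx(base, abs=1e-9)

    def test_correlation_bounded_and_monotone(self, symmetric_config, scheme):
        prev_corr = 100.0
        prev_d = 0.0
        for mag in (0.0, 0.05, 0.10, 0.20):
            coords = symmetric_config.coords.copy()
            coords[scheme.index("cheek-arc-L")] += (mag, 0.0)
            res = symmetry_score(symmetric_config.with_coords(coords))
            assert 0.0 <= res.correlation_pct <= 100.0
            assert res.d_sym >= prev_d
            assert res.correlation_pct <= prev_corr
            prev_d, prev_corr = res.d_sym, res.correlation_pct

    def test_wildtype_cohort_more_symmetric_than_hybrid(self):
        cfg = GeneratorConfig(seed=5)
        rng = np.random.default_rng(5)
        hyb = hybrid_template()
        wt_scores = [
            symmetry_score(sample_head(hyb, rng, cfg, f"wt{i}", fa_sd=cfg.fa_sd_wildtype).config).correlation_pct
            for i in range(60)
        ]
        hy_scores = [
            symmetry_score(sample_head(hyb, rng, cfg, f"hy{i}", fa_sd=cfg.fa_sd_hybrid).config).correlation_pct
            for i in range(60)
        ]
        assert np.mean(wt_scores) > np.mean(hy_scores)


class TestCompareSymmetry:
    def _results(self, values, group):
        from waspmorph.symmetry import SymmetryResult

        return [
            SymmetryResult(specimen_id=f"{group}{i}", d_sym=v,
                           correlation_pct=100.0 * np.sqrt(1 - min(v, 1.0)), group=group)
            for i, v in enumerate(values)
        ]

    def test_identical_groups(self):
        a = self._results([0.1, 0.2, 0.3], "a")
        b = self._results([0.1, 0.2, 0.3], "b")
        summary = compare_symmetry({"a": a, "b": b})
        (t,) = summary.tests
        assert t.statistic == pytest.approx(0.0)
        assert t.p_raw == pytest.approx(1.0)

    def test_degenerate_zero_variance_rule(self):
        a = self._results([0.0, 0.0, 0.0], "a")
        b = self._results([1.0, 1.0, 1.0], "b")
        (t,) = compare_symmetry({"a": a, "b": b}).tests
        assert t.p_raw == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            compare_symmetry({"a": self._results([0.1], "a"), "b": self._results([0.1, 0.2], "b")})

    def test_rejection_rate_matches_monte_carlo_power_oracle(self):
        # known mean shift: compare the Welch test's rejection rate against a
        # fresh Monte-Carlo estimate of the same quantity (independent draws)
        rng = np.random.default_rng(77)
        shift, n, alpha, reps = 0.8, 15, 0.05, 400

        def rejection_rate(seed):
            r = np.random.default_rng(seed)
            hits = 0
            for _ in range(reps):
                x = r.normal(0.0, 1.0, n)
                y = r.normal(shift, 1.0, n)
                a = self._results(np.abs(x), "a")
                b = self._results(np.abs(y) + 1.0, "b")  # keep d_sym >= 0, preserve shift
                (t,) = compare_symmetry({"a": a, "b": b}).tests
                hits += t.p_raw < alpha
            return hits / reps

        p1 = rejection_rate(1)
        p2 = rejection_rate(2)
        se = np.sqrt(p1 * (1 - p1) / reps + p2 * (1 - p2) / reps)
        assert abs(p1 - p2) < 2 * max(se, 0.01)


class TestAppendageAsymmetry:
    @staticmethod
    def _lengths(diffs, group, part="T1-leg", base=1.0):
        return [
            AppendageLengths(f"{group}-{i}", part, (base + d,), (base,), group=group)
            for i, d in enumerate(diffs)
        ]

    def test_all_symmetric_yields_null_f(self):
        rows = self._lengths([0.0] * 5, "a") + self._lengths([0.0] * 5, "b")
        table = appendage_asymmetry(rows)
        assert table.loc[0, "F"] == 0.0
        assert table.loc[0, "p"] == 1.0

    def test_identical_distributions_not_significant(self, rng):
        diffs = rng.normal(0, 0.01, 40)
        rows = self._lengths(np.abs(diffs[:20]) + 0.5, "a") + self._lengths(
            np.abs(diffs[20:]) + 0.5, "b"
        )
        table = appendage_asymmetry(rows)
        assert table.loc[0, "p"] > 0.05

    def test_matches_closed_form_anova_oracle(self):
        groups = {
            "g1": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
            "g2": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
            "g3": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0],
        }
        rows = []
        for g, diffs in groups.items():
            rows += self._lengths(diffs, g, base=20.0)
        table = appendage_asymmetry(rows)
        expected_f = one_way_anova_f(list(groups.values()))
        assert table.loc[0, "F"] == pytest.approx(expected_f, rel=1e-12)

    def test_parts_reported_separately(self):
        rows = self._lengths([0.1, 0.2, 0.15], "a") + self._lengths([0.1, 0.2, 0.15], "b")
        rows += self._lengths([0.3, 0.1, 0.2], "a", part="forewing")
        rows += self._lengths([0.25, 0.12, 0.2], "b", part="forewing")
        table = appendage_asymmetry(rows)
        assert set(table["part"]) == {"T1-leg", "forewing"}
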