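import numpy as np
import pandas as pd
import pytest

from dyngrn.stc import (
    anchored_mean_profiles,
    assign_genes_to_profiles,
    build_profile_templates,
    profile_significance,
    significant_templates,
)


class TestTemplateEnumeration:
    @pytest.mark.parametrize("T,cap,expected", [(3, 1, 9), (2, 1, 3), (6, 1, 243)])
    def test_template_counts(self, T, cap, expected):
        pset = build_profile_templates(T, cap)
        assert pset.n_templates == expected
        # distinct transition sequences
        assert len({tuple(t) for t in pset.transitions}) == expected

    def test_lexicographic_and_flat_present(self):
        pset = build_profile_templates(3, 1)
        assert list(pset.transitions[0]) == [-1, -1]
        assert list(pset.transitions[-1]) == [1, 1]
        np.testing.assert_array_equal(pset.templates[pset.flat_index], [0, 0, 0])

    def test_profiles_cumulate_from_zero(self):
        pset = build_profile_templates(4, 2)
        assert (pset.templates[:, 0] == 0).all()
        np.testing.assert_array_equal(
            np.diff(pset.templates, axis=1), pset.transitions
        )

    def test_too_few_timepoints_raises(self):
        with pytest.raises(ValueError):
            build_profile_templates(1)


def profiles_frame(rows, genes=None):
    arr = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes)


class TestAssignment:
    def test_exact_template_match_has_correlation_one(self):
        pset = build_profile_templates(4, 1)
        target = pset.templates[5]
        assert np.ptp(target) > 0
        out = assign_genes_to_profiles(profiles_frame([target]), pset)
        rec = out.assignments.iloc[0]
        assert rec.template_id == 5
        assert rec.correlation == pytest.approx(1.0)

    def test_constant_profile_goes_to_flat(self):
        pset = build_profile_templates(4, 1)
        out = assign_genes_to_profiles(profiles_frame([[0, 0, 0, 0]]), pset)
        assert out.assignments.iloc[0].template_id == pset.flat_index

    def test_tie_breaks_to_lowest_index(self):
        """A profile maximally correlated with several templates at once
        lands on the lowest of the tied template indices."""
        pset = build_profile_templates(4, 1)

        def unit_centered(v):
            c = v - v.mean()
            return c / np.linalg.norm(c)

        # bisector of two template directions correlates equally with both
        prof = unit_centered(pset.templates[0]) + unit_centered(pset.templates[1])
        corr = np.array(
            [
                np.dot(unit_centered(prof), unit_centered(t))
                if np.ptp(t) > 0
                else -np.inf
                for t in pset.templates
            ]
        )
        winners = np.flatnonzero(corr > corr.max() - 1e-12)
        assert len(winners) >= 2  # genuine tie in this geometry
        out = assign_genes_to_profiles(profiles_frame([prof]), pset)
        assert out.assignments.iloc[0].template_id == winners.min()

    def test_length_mismatch_raises(self):
        pset = build_profile_templates(4, 1)
        with pytest.raises(ValueError, match="time points"):
            assign_genes_to_profiles(profiles_frame([[0, 1, 2]]), pset)

    def test_gene_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        pset = build_profile_templates(5, 1)
        prof = rng.standard_normal((20, 5))
        prof[:, 0] = 0
        out = assign_genes_to_profiles(profiles_frame(prof), pset)
        perm = rng.permutation(20)
        out_p = assign_genes_to_profiles(
            profiles_frame(prof[perm], genes=[f"g{i}" for i in perm]), pset
        )
        merged = out.assignments.set_index("gene_id").loc[
            out_p.assignments["gene_id"]
        ]
        np.testing.assert_array_equal(
            merged["template_id"].to_numpy(), out_p.assignments["template_id"].to_numpy()
        )

    def test_anchored_profiles_from_matrix(self, small_matrix):
        prof = anchored_mean_profiles(small_matrix)
        assert (prof.iloc[:, 0].abs() < 1e-12).all()
        assert prof.shape == (3, 3)


class TestSignificance:
    def _assigned(self, profiles, T=4):
        pset = build_profile_templates(T, 1)
        return assign_genes_to_profiles(profiles, pset)

    def test_requires_enough_permutations(self):
        out = self._assigned(profiles_frame([[0, 1, 2, 3]]))
        with pytest.raises(ValueError, match="100"):
            profile_significance(out, n_permutations=50)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        prof = rng.standard_normal((30, 4))
        prof[:, 0] = 0
        out = self._assigned(profiles_frame(prof))
        a = profile_significance(out, 150, seed=4).stats
        b = profile_significance(out, 150, seed=4).stats
        pd.testing.assert_frame_equal(a, b)

    def test_empty_template_has_p_one(self):
        """A template attracting no genes in real or permuted data keeps
        p = 1 (its observed count 0 is always reached)."""
        prof = profiles_frame([[0, 1, 2, 3]] * 5)
        out = profile_significance(self._assigned(prof), 120, seed=0)
        counts = out.stats
        empty = counts[counts.observed == 0]
        assert (empty.p_value == 1.0).all()

    def test_planted_template_is_significant(self):
        """All genes following one rising template (plus small noise) make
        that template's count far beyond any permutation."""
        rng = np.random.default_rng(9)
        base = np.array([0.0, 1.0, 2.0, 3.0])
        prof = base + 0.05 * rng.standard_normal((60, 4))
        prof[:, 0] = 0
        out = profile_significance(self._assigned(profiles_frame(prof)), 200, seed=1)
        assigned_to = out.assignments["template_id"].mode()[0]
        p = out.stats.loc[out.stats.template_id == assigned_to, "p_value"].iloc[0]
        assert p <= 2.0 / 201.0

    def test_observed_counts_sum_to_gene_count(self):
        rng = np.random.default_rng(10)
        prof = rng.standard_normal((40, 4))
        prof[:, 0] = 0
        out = profile_significance(self._assigned(profiles_frame(prof)), 120, seed=2)
        assert out.stats["observed"].sum() == 40

    def test_lower_noise_gives_higher_assignment_correlation(self):
        """Median assignment correlation decreases as profile noise grows."""
        rng = np.random.default_rng(11)
        base = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        pset = build_profile_templates(5, 1)
        medians = []
        for sd in (0.05, 0.5, 2.0):
            prof = base + sd * rng.standard_normal((80, 5))
            prof[:, 0] = 0
            out = assign_genes_to_profiles(profiles_frame(prof), pset)
            medians.append(out.assignments["correlation"].median())
        assert medians[0] > medians[1] > medians[2]

    def test_significant_templates_filter_and_topk(self):
        rng = np.random.default_rng(12)
        prof = rng.standard_normal((50, 4))
        prof[:, 0] = 0
        out = profile_significance(self._assigned(profiles_frame(prof)), 120, seed=3)
        sig = significant_templates(out, p_threshold=0.5, top_k=3)
        assert len(sig) <= 3
        assert (sig.p_value < 0.5).all()
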