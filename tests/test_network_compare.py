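"""Fisher-z differences, the subject-relabeling permutation test, and the region union."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scnkit as sk
from scnkit.errors import ValidationError

from conftest import make_difference_network

RNG = np.random.default_rng(555)


class TestFisherZ:
    def test_closed_forms(self):
        assert sk.fisher_z(0.0) == 0.0
        assert sk.fisher_z(0.5) == pytest.approx(0.5493, abs=5e-5)

    def test_boundary_is_clipped_finite(self):
        z = sk.fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))
        assert sk.fisher_z(-1.0) == -z

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            sk.fisher_z(np.array([0.2, np.nan]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r=st.floats(-0.999, 0.999))
    def test_matches_log_form_and_is_odd(self, r):
        assert sk.fisher_z(r) == pytest.approx(0.5 * np.log((1 + r) / (1 - r)), abs=1e-12)
        assert sk.fisher_z(-r) == -sk.fisher_z(r)


class TestPairLabels:
    def test_study_convention_order(self):
        pairs = sk.comparison_pairs(["HC", "SCH", "BD", "MDD"])
        assert [sk.pair_label(a, b) for a, b in pairs] == [
            "HC-BD", "MDD-BD", "MDD-HC", "SCH-BD", "SCH-HC", "SCH-MDD",
        ]

    def test_pair_count_combinatorics(self):
        assert len(sk.comparison_pairs(["A", "B"])) == 1
        assert len(sk.comparison_pairs(list("ABCDE"))) == 10

    def test_self_comparison_rejected(self):
        with pytest.raises(ValidationError):
            sk.pair_label("A", "A")


def _net_from_r(r, group, names):
    r = np.asarray(r, float)
    np.fill_diagonal(r, 1.0)
    return sk.GroupNetwork(
        group=group, r=r, n_subjects=30, n_covariates=0, region_names=tuple(names)
    )


class TestObservedDifference:
    def test_identical_networks_zero(self):
        r = RNG.uniform(-0.5, 0.5, size=(4, 4))
        r = (r + r.T) / 2
        names = list("abcd")
        dz = sk.observed_difference(_net_from_r(r, "A", names), _net_from_r(r.copy(), "B", names))
        np.testing.assert_array_equal(dz, np.zeros((4, 4)))

    def test_swap_negates(self):
        ra = (lambda m: (m + m.T) / 2)(RNG.uniform(-0.5, 0.5, size=(4, 4)))
        rb = (lambda m: (m + m.T) / 2)(RNG.uniform(-0.5, 0.5, size=(4, 4)))
        names = list("abcd")
        a, b = _net_from_r(ra, "A", names), _net_from_r(rb, "B", names)
        np.testing.assert_allclose(sk.observed_difference(a, b), -sk.observed_difference(b, a))

    def test_closed_form_single_edge(self):
        r0 = np.eye(3)
        r1 = np.eye(3)
        r1[1, 2] = r1[2, 1] = 0.9
        dz = sk.observed_difference(_net_from_r(r1, "A", "xyz"), _net_from_r(r0, "B", "xyz"))
        assert dz[1, 2] == pytest.approx(1.4722, abs=5e-5)  # atanh(0.9)

    def test_region_mismatch_rejected(self):
        a = _net_from_r(np.eye(3), "A", "xyz")
        b = _net_from_r(np.eye(3), "B", "xyw")
        with pytest.raises(ValidationError, match="mismatch"):
            sk.observed_difference(a, b)


@pytest.fixture(scope="module")
def null_pair():
    cfg = sk.SimulationConfig(group_sizes={"P": 25, "Q": 25}, n_regions=6, seed=41)
    parts, vols, _ = sk.generate_cohort(cfg)
    cov = parts.covariates()
    ip, iq = parts.group_indices("P"), parts.group_indices("Q")
    return vols.values[ip], vols.values[iq], cov[ip], cov[iq], vols.region_names


class TestPermutationTest:
    def test_minimum_p_value_is_add_one_bound(self, null_pair):
        va, vb, ca, cb, names = null_pair
        # make regions 0 and 1 near-duplicates in group A only: the edge
        # difference dwarfs anything a relabeling can produce
        va = va.copy()
        va[:, 1] = va[:, 0] + 1e-3 * RNG.standard_normal(len(va))
        d = sk.permutation_test(
            va, vb, ca, cb, region_names=names,
            group_a="Q", group_b="P", n_perm=199, seed=3, alpha=0.05,
        )
        assert d.p_values[0, 1] == 1 / 200
        off = ~np.eye(len(names), dtype=bool)
        assert d.p_values[off].min() >= 1 / 200 - 1e-15

    def test_determinism_and_seed_sensitivity(self, null_pair):
        va, vb, ca, cb, names = null_pair
        kw = dict(region_names=names, group_a="Q", group_b="P", n_perm=149, alpha=0.05)
        d1 = sk.permutation_test(va, vb, ca, cb, seed=7, **kw)
        d2 = sk.permutation_test(va, vb, ca, cb, seed=7, **kw)
        d3 = sk.permutation_test(va, vb, ca, cb, seed=8, **kw)
        np.testing.assert_array_equal(d1.p_values, d2.p_values)
        assert not np.array_equal(d1.p_values, d3.p_values)

    def test_group_swap_symmetry(self, null_pair):
        va, vb, ca, cb, names = null_pair
        kw = dict(region_names=names, n_perm=149, seed=5, alpha=0.05)
        d_qp = sk.permutation_test(va, vb, ca, cb, group_a="Q", group_b="P", **kw)
        d_pq = sk.permutation_test(vb, va, cb, ca, group_a="P", group_b="Q", **kw)
        np.testing.assert_array_equal(d_qp.p_values, d_pq.p_values)
        np.testing.assert_allclose(d_qp.delta_z, -d_pq.delta_z)
        assert d_qp.pair == d_pq.pair == "Q-P"

    def test_unattainable_alpha_recorded_as_warning(self, null_pair):
        va, vb, ca, cb, names = null_pair
        d = sk.permutation_test(
            va, vb, ca, cb, region_names=names, group_a="Q", group_b="P",
            n_perm=199, seed=1, alpha=0.001,
        )
        assert any("unattainable" in w for w in d.warnings)
        assert d.n_significant_edges == 0

    def test_small_n_perm_rejected(self, null_pair):
        va, vb, ca, cb, names = null_pair
        with pytest.raises(ValidationError, match="n_perm"):
            sk.permutation_test(
                va, vb, ca, cb, region_names=names, group_a="Q", group_b="P",
                n_perm=50, seed=1, alpha=0.05,
            )

    def test_planted_large_effect_power(self):
        """A rho 0.8 vs 0.0 edge at n=60/group is flagged in nearly every cohort."""
        hits = 0
        reps = 100
        for rep in range(reps):
            cfg = sk.SimulationConfig(
                seed=7000 + rep, n_regions=6, group_sizes={"A": 60, "B": 60},
                rho_within=0.0, perturbations=(sk.EdgePerturbation("A", 0, 1, 0.8),),
            )
            parts, vols, _ = sk.generate_cohort(cfg)
            cov = parts.covariates()
            ia, ib = parts.group_indices("A"), parts.group_indices("B")
            d = sk.permutation_test(
                vols.values[ia], vols.values[ib], cov[ia], cov[ib],
                region_names=vols.region_names, group_a="A", group_b="B",
                n_perm=999, seed=rep, alpha=0.01,
            )
            hits += bool(d.mask[0, 1])
        assert hits >= 95


class TestRegionUnion:
    def test_all_masks_empty(self):
        names = list("abcd")
        diffs = [make_difference_network(np.zeros((4, 4), bool), names)]
        assert sk.significant_region_union(diffs) == []

    def test_single_edge_union_is_its_endpoints(self):
        names = list("abcd")
        mask = np.zeros((4, 4), bool)
        mask[1, 3] = mask[3, 1] = True
        diffs = [make_difference_network(mask, names)]
        assert sk.significant_region_union(diffs) == ["b", "d"]

    def test_union_preserves_region_order(self):
        names = list("abcde")
        m1 = np.zeros((5, 5), bool); m1[4, 0] = m1[0, 4] = True
        m2 = np.zeros((5, 5), bool); m2[2, 1] = m2[1, 2] = True
        diffs = [
            make_difference_network(m1, names, pair=("B", "A")),
            make_difference_network(m2, names, pair=("C", "A")),
        ]
        assert sk.significant_region_union(diffs) == ["a", "b", "c", "e"]

    def test_mismatched_universe_rejected(self):
        d1 = make_difference_network(np.zeros((3, 3), bool), list("abc"))
        d2 = make_difference_network(np.zeros((3, 3), bool), list("abd"))
        with pytest.raises(ValidationError, match="universe"):
            sk.significant_region_union([d1, d2])
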