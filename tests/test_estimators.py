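"""Estimator core: rarefaction against exhaustive enumeration, coverage,
quorum standardization, squares and split-and-sum."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palaeodiv.binning import assign_single_bin
from palaeodiv.estimators import (
    AbundanceCounts,
    IncidenceFrequencies,
    bootstrap_ci,
    build_abundance,
    build_incidence,
    chao2_undetected,
    coverage_reference,
    estimate_at_quorum,
    expected_coverage,
    extrapolate_size,
    goods_u,
    quorum_sweep,
    rarefy_size,
    split_and_sum,
    squares_estimate,
)
from palaeodiv.occurrences import Environment

from conftest import make_dataset, make_record


def inc_from_matrix(M) -> IncidenceFrequencies:
    counts = {f"t{j}": int(M[:, j].sum()) for j in range(M.shape[1])}
    return IncidenceFrequencies("bin", "genus", M.shape[0], counts)


def enumerate_expected_richness(M, t: int) -> float:
    """Mean distinct-taxon count over all size-t subsets of localities."""
    T = M.shape[0]
    vals = [
        (M[list(sub)].sum(axis=0) > 0).sum()
        for sub in itertools.combinations(range(T), t)
    ]
    return float(np.mean(vals))


@st.composite
def incidence_matrices(draw):
    T = draw(st.integers(min_value=2, max_value=6))
    S = draw(st.integers(min_value=1, max_value=8))
    cols = []
    for _ in range(S):
        col = draw(
            st.lists(st.booleans(), min_size=T, max_size=T).filter(any)
        )
        cols.append(col)
    return np.array(cols, dtype=int).T


class TestRarefactionOracle:
    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(incidence_matrices(), st.data())
    def test_matches_exhaustive_subset_enumeration(self, M, data):
        inc = inc_from_matrix(M)
        t = data.draw(st.integers(min_value=1, max_value=inc.T))
        assert rarefy_size(inc, t) == pytest.approx(
            enumerate_expected_richness(M, t), abs=1e-9
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(incidence_matrices())
    def test_identities_and_monotonicity(self, M):
        inc = inc_from_matrix(M)
        assert rarefy_size(inc, 1) == pytest.approx(inc.u / inc.T, abs=1e-12)
        assert rarefy_size(inc, inc.T) == pytest.approx(inc.s_obs, abs=1e-12)
        curve = [rarefy_size(inc, t) for t in range(1, inc.T + 1)]
        assert all(b >= a - 1e-9 for a, b in zip(curve, curve[1:]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(incidence_matrices())
    def test_coverage_in_unit_interval_and_monotone(self, M):
        inc = inc_from_matrix(M)
        covs = [expected_coverage(inc, t) for t in range(1, 2 * inc.T + 1)]
        assert all(0.0 <= c <= 1.0 for c in covs)
        assert all(b >= a - 1e-9 for a, b in zip(covs, covs[1:]))


class TestWorkedExamples:
    def test_toy_incidence_construction(self, scheme, stages):
        ds = make_dataset(
            [
                make_record(genus="A", species="x", locality_id="L1"),
                make_record(genus="A", species="x", locality_id="L2"),
                make_record(genus="B", species="y", locality_id="L1"),
            ]
        )
        inc = build_incidence(
            ds, assign_single_bin(ds, scheme, stages), "genus"
        )["Serpukhovian"]
        assert (inc.T, inc.counts["A"], inc.counts["B"]) == (2, 2, 1)
        assert (inc.q1, inc.q2, inc.u) == (1, 1, 3)

    def test_within_locality_duplicates_collapse(self, scheme, stages):
        ds = make_dataset(
            [make_record(genus="A", species="x", locality_id="L1"),
             make_record(genus="A", species="x", locality_id="L1")]
        )
        inc = build_incidence(
            ds, assign_single_bin(ds, scheme, stages), "genus"
        )["Serpukhovian"]
        assert inc.counts["A"] == 1

    def test_reference_coverage_toy(self):
        inc = IncidenceFrequencies("b", "genus", 2, {"A": 2, "B": 1})
        assert coverage_reference(inc) == pytest.approx(8.0 / 9.0)

    def test_reference_coverage_no_uniques_is_one(self):
        inc = IncidenceFrequencies("b", "genus", 3, {"A": 3, "B": 2})
        assert coverage_reference(inc) == 1.0

    def test_single_unit_all_unique_degenerate_zero(self):
        inc = IncidenceFrequencies("b", "genus", 1, {"A": 1, "B": 1})
        assert inc.is_degenerate
        assert coverage_reference(inc) == 0.0

    def test_rarefy_toy(self):
        inc = IncidenceFrequencies("b", "genus", 2, {"A": 2, "B": 1})
        assert rarefy_size(inc, 1) == pytest.approx(1.5)
        assert rarefy_size(inc, 2) == pytest.approx(2.0)

    def test_extrapolation_flat_without_uniques(self):
        inc = IncidenceFrequencies("b", "genus", 3, {"A": 3, "B": 2})
        assert extrapolate_size(inc, 3) == pytest.approx(inc.s_obs)

    def test_extrapolation_toy_bias_corrected(self):
        # Y={2,1}: Q1=1, Q2=1 -> Q0_hat=(1/2)*1/2=0.25; S(3)=2+1/6
        inc = IncidenceFrequencies("b", "genus", 2, {"A": 2, "B": 1})
        assert chao2_undetected(inc) == pytest.approx(0.25)
        assert extrapolate_size(inc, 1) == pytest.approx(2.0 + 1.0 / 6.0)

    def test_extrapolation_asymptote_is_chao2(self):
        inc = IncidenceFrequencies(
            "b", "genus", 5, {"A": 5, "B": 1, "C": 1, "D": 2}
        )
        asymptote = extrapolate_size(inc, 10_000, enforce_cap=False)
        assert asymptote == pytest.approx(
            inc.s_obs + chao2_undetected(inc), rel=1e-6
        )

    def test_cap_enforced(self):
        inc = IncidenceFrequencies("b", "genus", 2, {"A": 2, "B": 1})
        with pytest.raises(ValueError, match="2T cap"):
            extrapolate_size(inc, 3)


class TestGoodsU:
    def test_direct_arithmetic(self):
        ab = AbundanceCounts("b", "genus", {"A": 3, "B": 1, "C": 1})
        assert goods_u(ab) == pytest.approx(0.6)

    def test_no_singletons_is_one(self):
        assert goods_u(AbundanceCounts("b", "g", {"A": 2, "B": 3})) == 1.0

    def test_all_singletons_is_zero(self):
        assert goods_u(AbundanceCounts("b", "g", {"A": 1, "B": 1})) == 0.0

    def test_empty_undefined(self):
        assert goods_u(AbundanceCounts("b", "g", {})) is None


class TestQuorumEstimation:
    def test_reference_coverage_quorum_recovers_observed(self):
        inc = IncidenceFrequencies(
            "b", "genus", 6, {"A": 6, "B": 4, "C": 2, "D": 1, "E": 3}
        )
        q = coverage_reference(inc)
        est = estimate_at_quorum(inc, q)
        # within the discretization of one sampling unit
        assert est.estimate == pytest.approx(inc.s_obs, abs=1.0)
        assert est.mode == "interpolated"

    def test_tiny_quorum_bounded_by_mean_unit_richness(self):
        inc = IncidenceFrequencies(
            "b", "genus", 6, {"A": 6, "B": 4, "C": 2, "D": 1, "E": 3}
        )
        est = estimate_at_quorum(inc, 1e-6)
        assert est.estimate <= inc.u / inc.T + 1e-9

    def test_unattainable_quorum_flagged_not_clamped(self):
        inc = IncidenceFrequencies("b", "genus", 2, {"A": 2, "B": 1})
        est = estimate_at_quorum(inc, 0.99)
        assert not est.attainable
        assert est.estimate is None

    def test_estimates_monotone_in_quorum(self):
        inc = IncidenceFrequencies(
            "b", "genus", 8,
            {"A": 8, "B": 5, "C": 3, "D": 2, "E": 1, "F": 1, "G": 4},
        )
        qs = (0.3, 0.4, 0.5, 0.6, 0.7)
        ests = [e.estimate for e in quorum_sweep(inc, qs) if e.attainable]
        assert all(b >= a - 1e-9 for a, b in zip(ests, ests[1:]))

    def test_empty_sweep(self):
        inc = IncidenceFrequencies("b", "genus", 2, {"A": 2})
        assert quorum_sweep(inc, []) == []

    def test_empty_bin_undefined(self):
        inc = IncidenceFrequencies("b", "genus", 0, {})
        est = estimate_at_quorum(inc, 0.5)
        assert not est.attainable


class TestBootstrap:
    INC = IncidenceFrequencies(
        "b", "genus", 12,
        {"A": 12, "B": 8, "C": 5, "D": 3, "E": 2, "F": 1, "G": 1, "H": 4},
    )

    def test_point_estimate_within_interval(self):
        est = estimate_at_quorum(self.INC, 0.5)
        lo, hi = bootstrap_ci(self.INC, 0.5, B=200, seed=42)
        assert lo <= est.estimate <= hi

    def test_same_seed_identical(self):
        assert bootstrap_ci(self.INC, 0.5, B=50, seed=7) == bootstrap_ci(
            self.INC, 0.5, B=50, seed=7
        )

    def test_interval_shrinks_with_more_sampling_units(self):
        rng = np.random.default_rng(11)
        widths = []
        for T in (10, 40):
            y = np.maximum(1, rng.binomial(T, 0.3, size=30))
            inc = IncidenceFrequencies(
                "b", "genus", T, {f"t{i}": int(v) for i, v in enumerate(y)}
            )
            lo, hi = bootstrap_ci(inc, 0.5, B=200, seed=5)
            est = estimate_at_quorum(inc, 0.5).estimate
            widths.append((hi - lo) / est)
        assert widths[1] < widths[0]

    def test_degenerate_input_gives_none(self):
        inc = IncidenceFrequencies("b", "genus", 1, {"A": 1})
        assert bootstrap_ci(inc, 0.5, B=10, seed=0) is None


class TestSquares:
    def test_hand_computed_case(self):
        ab = AbundanceCounts("b", "genus", {"A": 3, "B": 1, "C": 1})
        assert squares_estimate(ab).estimate == pytest.approx(3 + 44.0 / 19.0)

    def test_no_singletons_returns_observed(self):
        ab = AbundanceCounts("b", "genus", {"A": 2, "B": 2, "C": 2})
        assert squares_estimate(ab).estimate == 3.0

    def test_all_singletons_undefined(self):
        est = squares_estimate(AbundanceCounts("b", "g", {"A": 1, "B": 1}))
        assert est.estimate is None and not est.attainable

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.text(alphabet="ABCDEFGHIJ", min_size=1, max_size=3),
            st.integers(min_value=1, max_value=30),
            min_size=1, max_size=10,
        )
    )
    def test_never_below_observed_when_defined(self, counts):
        ab = AbundanceCounts("b", "genus", counts)
        est = squares_estimate(ab)
        if est.estimate is not None:
            assert est.estimate >= ab.s_obs - 1e-9
            assert (est.estimate == pytest.approx(ab.s_obs)) == (ab.s1 == 0)


class TestSplitAndSum:
    def test_disjoint_no_singletons_zero_deviation(self, scheme, stages):
        records = []
        for env, genera in (
            (Environment.MARINE, ("A", "B")),
            (Environment.FRESHWATER, ("C", "D")),
        ):
            for g in genera:
                for loc in ("L1", "L2"):
                    records.append(
                        make_record(genus=g, species="x", locality_id=loc,
                                    environment=env)
                    )
        ds = make_dataset(records)
        table = split_and_sum(ds, assign_single_bin(ds, scheme, stages))
        row = table.iloc[0]
        assert row["deviation"] == pytest.approx(0.0)

    def test_shared_taxa_double_counted(self, scheme, stages):
        records = []
        for env in (Environment.MARINE, Environment.FRESHWATER):
            for g in ("A", "B"):
                for loc in ("L1", "L2"):
                    records.append(
                        make_record(genus=g, species="x",
                                    locality_id=f"{loc}{env.value}",
                                    environment=env)
                    )
        ds = make_dataset(records)
        table = split_and_sum(ds, assign_single_bin(ds, scheme, stages))
        row = table.iloc[0]
        assert row["sum"] == pytest.approx(2 * row["pooled_estimate"])

    def test_empty_subset_flagged(self, scheme, stages):
        ds = make_dataset(
            [make_record(genus=g, species="x", environment=Environment.MARINE)
             for g in ("A", "B")]
        )
        table = split_and_sum(ds, assign_single_bin(ds, scheme, stages))
        assert "freshwater subset empty" in table.iloc[0]["flags"]
        assert table.iloc[0]["freshwater_estimate"] == 0.0

    def test_uneven_environment_split_inflates_sum(self, scheme, stages):
        # 90/10 split of an uneven assemblage: subset extrapolations
        # exceed the pooled estimate
        rng = np.random.default_rng(1)
        from palaeodiv.synthetic import geometric_probabilities

        probs = geometric_probabilities(60, 0.15)
        records = []
        n = 0
        for loc in range(12):
            env = Environment.MARINE if loc < 11 else Environment.FRESHWATER
            for d in rng.choice(60, size=25, p=probs):
                n += 1
                records.append(
                    make_record(genus=f"G{d:03d}", species="x",
                                occurrence_id=f"ss{n:05d}",
                                locality_id=f"L{loc}", environment=env)
                )
        ds = make_dataset(records)
        table = split_and_sum(ds, assign_single_bin(ds, scheme, stages))
        assert table.iloc[0]["deviation"] > 0


class TestHierarchyAtIncidence:
    def test_genus_only_pseudo_taxon_only_where_unsubsumed(self, scheme, stages):
        ds = make_dataset(
            [
                make_record(genus="Elonichthys", species="robisoni",
                            locality_id="L1"),
                make_record(genus="Elonichthys", species=None,
                            locality_id="L1"),
                make_record(genus="Elonichthys", species=None,
                            locality_id="L2"),
            ]
        )
        inc = build_incidence(
            ds, assign_single_bin(ds, scheme, stages), "species"
        )["Serpukhovian"]
        assert inc.counts == {"Elonichthys robisoni": 1, "Elonichthys sp.": 1}

    def test_abundance_drops_subsumed_records(self, scheme, stages):
        ds = make_dataset(
            [
                make_record(genus="Elonichthys", species="robisoni",
                            locality_id="L1"),
                make_record(genus="Elonichthys", species=None,
                            locality_id="L1"),
            ]
        )
        ab = build_abundance(
            ds, assign_single_bin(ds, scheme, stages), "species"
        )["Serpukhovian"]
        assert ab.counts == {"Elonichthys robisoni": 1}
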