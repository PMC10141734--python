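"""Host-breadth classification and origin-class occupancy statistics."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rearingnet.fixtures import (corrected_occupancy_table,
                                 printed_occupancy_percentages,
                                 printed_occupancy_table)
from rearingnet.niche import (BreadthRecordSet, OccupancyTable,
                              breadth_records, cell_binomial_tests,
                              classify_host_breadth, exact_binomial_two_sided,
                              occupancy_gof, occupancy_table, percentage_gof)
from rearingnet.network import build_matrix


class TestHostBreadth:
    @pytest.mark.parametrize("counts,label", [
        ({"F1": 40, "F2": 15, "F3": 5}, "specialist"),
        ({"F1": 40, "F2": 16, "F3": 4}, "generalist"),   # secondary family too big
        ({"F1": 39, "F2": 15, "F3": 6}, "generalist"),   # top below two-thirds
        ({"F1": 17}, "specialist"),                      # single family
        ({"F1": 3, "F2": 1}, "specialist"),              # thresholds inclusive
        ({"F1": 2, "F2": 1}, "generalist"),              # other family above 1/4
    ])
    def test_two_condition_rule(self, counts, label):
        c = classify_host_breadth(BreadthRecordSet("X", counts))
        assert c.label == label

    def test_boundary_is_inclusive(self):
        # exactly two-thirds in the top family, exactly one quarter elsewhere
        c = classify_host_breadth(BreadthRecordSet("X", {"A": 8, "B": 3, "C": 1}))
        assert c.is_specialist
        assert c.top_fraction == pytest.approx(2 / 3)
        assert c.max_other_fraction == pytest.approx(1 / 4)

    def test_strict_mode_reads_remaining_records(self):
        # 15 of the 20 non-top records: allowed by the default reading,
        # excluded when the cap applies to the remainder
        r = BreadthRecordSet("X", {"F1": 40, "F2": 15, "F3": 5})
        assert classify_host_breadth(r).is_specialist
        assert not classify_host_breadth(r, strict=True).is_specialist

    @settings(max_examples=60, derandomize=True)
    @given(st.dictionaries(st.sampled_from("ABCDE"),
                           st.integers(min_value=0, max_value=50), min_size=1),
           st.integers(min_value=1, max_value=7))
    def test_scaling_invariance(self, counts, k):
        if sum(counts.values()) == 0:
            return
        base = classify_host_breadth(BreadthRecordSet("X", counts))
        scaled = classify_host_breadth(
            BreadthRecordSet("X", {f: k * c for f, c in counts.items()}))
        assert base.label == scaled.label

    def test_no_records_rejected(self):
        with pytest.raises(ValueError, match="no breeding records"):
            classify_host_breadth(BreadthRecordSet("X", {}))

    def test_record_units(self, tiny_dataset):
        by_sample = breadth_records(tiny_dataset)
        # fly X colonized T1 once and T2 once -> one record per family
        assert by_sample["X"].family_counts == {"Bromeliaceae": 1, "Musaceae": 1}
        by_individual = breadth_records(tiny_dataset,
                                        record_unit="emerged_individuals")
        assert by_individual["X"].family_counts == {"Bromeliaceae": 30, "Musaceae": 2}


class TestOccupancyTable:
    def test_two_by_two_worked_example(self, tiny_dataset):
        # N fly Y bred on exotic T2, T3; E fly X on T1 (N) and T2 (E)
        m = build_matrix(tiny_dataset)
        t = occupancy_table(m, tiny_dataset.taxa, tiny_dataset.species)
        cells = {(r.fly_origin, r.host_origin): (r.observed, r.possible)
                 for r in t.cells.itertuples(index=False)}
        assert cells == {("N", "N"): (0, 1), ("N", "E"): (2, 2),
                         ("E", "N"): (1, 2), ("E", "E"): (1, 4)}
        assert t.overall_pct == pytest.approx(100 * 4 / 9)

    def test_study_table_overall_occupancy(self):
        t = corrected_occupancy_table()
        assert t.cells["possible"].sum() == 784
        assert round(t.overall_pct, 2) == 18.11

    def test_hybrid_hosts_excluded_by_default(self, tiny_dataset):
        from rearingnet.records import Origin, PlantTaxon, ResourceType
        tiny_dataset.taxa.append(PlantTaxon("T4", "Vitis hybrid", "Vitaceae",
                                            Origin.HYBRID,
                                            ResourceType.FLESHY_FRUIT))
        m = build_matrix(tiny_dataset)
        t = occupancy_table(m, tiny_dataset.taxa, tiny_dataset.species)
        assert t.cells["possible"].sum() == 9  # hybrid adds no block
        with pytest.raises(ValueError, match="hybrid"):
            occupancy_table(m, tiny_dataset.taxa, tiny_dataset.species,
                            exclude_hybrid_hosts=False)

    def test_observed_cannot_exceed_possible(self):
        with pytest.raises(ValueError):
            OccupancyTable.from_counts([5, 0, 0, 0], [4, 10, 10, 10])


class TestGoodnessOfFit:
    def test_printed_percentage_inputs_reproduce_study_statistic(self):
        pcts, overall = printed_occupancy_percentages()
        g = percentage_gof(pcts, overall)
        assert round(g.chi2, 3) == 7.311
        assert g.df == 3
        assert g.p_value > 0.05

    def test_full_precision_percentage_scale(self):
        g = occupancy_gof(corrected_occupancy_table(), scale="percentage")
        assert round(g.chi2, 3) == 7.317

    def test_count_scale_equals_contingency_chi_square(self):
        t = corrected_occupancy_table()
        g = occupancy_gof(t, scale="count")
        O = t.cells["observed"].to_numpy()
        M = t.cells["possible"].to_numpy()
        ref_chi2, ref_p, dof, _ = sps.chi2_contingency(np.array([O, M - O]),
                                                       correction=False)
        assert g.chi2 == pytest.approx(ref_chi2)
        assert g.p_value == pytest.approx(ref_p)
        assert g.df == dof == 3

    def test_uniform_occupancy_gives_zero_on_both_scales(self):
        t = OccupancyTable.from_counts([2, 2, 2, 2], [10, 10, 10, 10])
        for scale in ("count", "percentage"):
            g = occupancy_gof(t, scale=scale)
            assert g.chi2 == 0.0
            assert g.p_value == 1.0

    def test_proportional_occupancy_gives_zero(self):
        t = OccupancyTable.from_counts([1, 2, 3, 4], [10, 20, 30, 40])
        assert occupancy_gof(t).chi2 == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_null_rejected(self):
        t = OccupancyTable.from_counts([0, 0, 0, 0], [5, 5, 5, 5])
        with pytest.raises(ValueError, match="degenerate"):
            occupancy_gof(t)


def binomial_minlike_oracle(k, n, p0: Fraction) -> float:
    """Exact-arithmetic enumeration of the minimum-likelihood p-value."""
    pmf = [comb(n, j) * p0**j * (1 - p0)**(n - j) for j in range(n + 1)]
    return float(sum(pj for pj in pmf if pj <= pmf[k]))


class TestExactBinomial:
    def test_modal_outcome_has_p_one(self):
        assert exact_binomial_two_sided(5, 10, 0.5) == pytest.approx(1.0)

    def test_symmetric_tails_worked_example(self):
        assert exact_binomial_two_sided(0, 4, 0.5) == pytest.approx(0.125)

    @pytest.mark.parametrize("n", [4, 10, 17, 25])
    @pytest.mark.parametrize("p0", [Fraction(1, 2), Fraction(3, 10),
                                    Fraction(142, 784)])
    def test_matches_enumeration_oracle(self, n, p0):
        for k in range(n + 1):
            ours = exact_binomial_two_sided(k, n, float(p0))
            oracle = binomial_minlike_oracle(k, n, p0)
            assert ours == pytest.approx(oracle, abs=1e-9), (k, n, p0)

    @pytest.mark.parametrize("k,n", [(3, 20), (0, 15), (12, 25), (7, 8)])
    def test_matches_scipy_binomtest(self, k, n):
        assert exact_binomial_two_sided(k, n, 0.3) == pytest.approx(
            sps.binomtest(k, n, 0.3).pvalue, rel=1e-9)

    def test_neotropical_exotic_host_cell_is_depleted(self):
        p = exact_binomial_two_sided(15, 168, 142 / 784)
        assert p < 0.01

    def test_p_values_lie_in_unit_interval(self):
        for k in range(11):
            p = exact_binomial_two_sided(k, 10, 0.42)
            assert 0 < p <= 1

    def test_invalid_null_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_two_sided(1, 4, 0.0)
        with pytest.raises(ValueError):
            exact_binomial_two_sided(1, 4, 1.0)


class TestCellBinomials:
    def test_study_table_direction_pattern(self):
        results = cell_binomial_tests(corrected_occupancy_table())
        by_cell = {(r.fly_origin, r.host_origin): r for r in results}
        # exotic hosts: used less than expected by N flies, more by E flies
        ne = by_cell[("N", "E")]
        assert ne.direction == "below" and ne.p_value < 0.01
        ee = by_cell[("E", "E")]
        assert ee.direction == "above" and ee.p_value < 0.05

    def test_direction_consistent_with_sign(self):
        t = OccupancyTable.from_counts([1, 5, 3, 2], [10, 10, 10, 10])
        for r in cell_binomial_tests(t):
            delta = r.k - r.n * r.p0
            if delta > 0:
                assert r.direction == "above"
            elif delta < 0:
                assert r.direction == "below"

    def test_central_method_bounds_minlike(self):
        t = corrected_occupancy_table()
        minlike = {(r.fly_origin, r.host_origin): r.p_value
                   for r in cell_binomial_tests(t)}
        central = {(r.fly_origin, r.host_origin): r.p_value
                   for r in cell_binomial_tests(t, method="central")}
        for cell in minlike:
            assert 0 < central[cell] <= 1
            assert minlike[cell] <= central[cell] + 1e-12


def test_printed_table_kept_verbatim():
    t = printed_occupancy_table()
    assert t.cells["possible"].tolist() == [126, 174, 210, 280]
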