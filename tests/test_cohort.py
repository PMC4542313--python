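import math

import numpy as np
import pandas as pd
import pytest

from archseq.cohort import (
    AgeBinError,
    AgeBinSpec,
    CohortTable,
    SPLICEOSOME_GENES,
    compare_groups,
    min_age_by_class,
    multi_mutation_groups,
    prevalence_by_age,
    project_total_incidence,
    summarize_clones,
)
from archseq.table2 import ClonalMutationRecord


def _cohort(n_per_bin, carriers_per_bin, bins):
    rows, calls = [], []
    sid = 0
    for (lo, hi), n, k in zip(bins.bins, n_per_bin, carriers_per_bin):
        for i in range(n):
            rows.append({"sample_id": f"S{sid}", "age_years": lo + (i % (hi - lo + 1))})
            if i < k:
                calls.append(
                    {"sample_id": f"S{sid}", "gene": "DNMT3A",
                     "hotspot": "DNMT3A R882", "vaf": 0.05, "called": True}
                )
            sid += 1
    return CohortTable(pd.DataFrame(rows), pd.DataFrame(calls))


class TestPrevalence:
    def test_published_bin_arithmetic(self):
        bins = AgeBinSpec(((17, 25), (80, 89)))
        cohort = _cohort([489, 355], [1, 11], bins)
        prev = prevalence_by_age(cohort, bins)
        assert prev.loc[0, "k"] == 1 and prev.loc[0, "n"] == 489
        assert prev.loc[0, "pct"] == 0.2
        assert prev.loc[1, "pct"] == 3.1

    def test_zero_carrier_bin_has_zero_lower_ci(self):
        bins = AgeBinSpec(((40, 49),))
        prev = prevalence_by_age(_cohort([100], [0], bins), bins)
        assert prev.loc[0, "prevalence"] == 0.0
        assert prev.loc[0, "ci_low"] == 0.0
        assert prev.loc[0, "ci_high"] > 0.0

    def test_exact_ci_matches_clopper_pearson_endpoints(self):
        from scipy import stats

        bins = AgeBinSpec(((60, 69),))
        prev = prevalence_by_age(_cohort([200], [6], bins), bins)
        ci = stats.binomtest(6, 200).proportion_ci(confidence_level=0.95, method="exact")
        assert prev.loc[0, "ci_low"] == pytest.approx(float(ci.low))
        assert prev.loc[0, "ci_high"] == pytest.approx(float(ci.high))

    def test_multi_mutation_individual_counted_once(self):
        individuals = pd.DataFrame({"sample_id": ["A", "B"], "age_years": [75, 76]})
        calls = pd.DataFrame(
            {
                "sample_id": ["A", "A", "B"],
                "gene": ["SRSF2", "SF3B1", "DNMT3A"],
                "hotspot": ["SRSF2 P95", "SF3B1 K700", "DNMT3A R882"],
                "vaf": [0.1, 0.05, 0.02],
                "called": [True, True, False],
            }
        )
        prev = prevalence_by_age(CohortTable(individuals, calls), AgeBinSpec(((70, 79),)))
        assert prev.loc[0, "k"] == 1  # A once; B's uncalled row does not count

    def test_class_filter_restricts_numerator(self):
        individuals = pd.DataFrame({"sample_id": ["A", "B"], "age_years": [75, 76]})
        calls = pd.DataFrame(
            {
                "sample_id": ["A", "B"],
                "gene": ["SRSF2", "DNMT3A"],
                "hotspot": ["SRSF2 P95", "DNMT3A R882"],
                "vaf": [0.1, 0.2],
                "called": [True, True],
            }
        )
        cohort = CohortTable(individuals, calls)
        prev = prevalence_by_age(cohort, AgeBinSpec(((70, 79),)), class_filter=SPLICEOSOME_GENES)
        assert prev.loc[0, "k"] == 1

    def test_age_outside_bins_raises_listing_offenders(self):
        bins = AgeBinSpec(((60, 69),))
        cohort = _cohort([10], [0], bins)
        cohort.individuals.loc[0, "age_years"] = 12
        with pytest.raises(AgeBinError, match="12"):
            prevalence_by_age(cohort, bins)

    def test_individual_prevalence_never_exceeds_clone_rate(self, records):
        # clone-level count / n is an upper bound for carrier prevalence
        n = 4067
        carriers = 105
        clones = len(records)
        assert carriers / n <= clones / n


class TestAgeBins:
    def test_default_bins_match_study_layout(self):
        assert AgeBinSpec().labels() == [
            "17-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80-89", "90-98",
        ]

    def test_from_string_round_trip(self):
        spec = AgeBinSpec.from_string("17-25, 26-59, 60-98")
        assert spec.bins == ((17, 25), (26, 59), (60, 98))

    def test_overlapping_bins_rejected(self):
        with pytest.raises(AgeBinError):
            AgeBinSpec(((10, 20), (20, 30)))


class TestCloneSummaries:
    def test_cut_of_100_percent_counts_everything(self, records):
        s = summarize_clones(records, 100.0)
        assert s.at_or_below_cut == s.total == 112

    def test_cut_comparison_is_inclusive(self):
        recs = [
            ClonalMutationRecord("SF3B1", "SF3B1 K700", "p.K700E", 3.0, 80),
            ClonalMutationRecord("SF3B1", "SF3B1 K700", "p.K700E", 3.01, 80),
        ]
        s = summarize_clones(recs, 3.0)
        assert s.at_or_below_cut == 1

    def test_gene_set_restriction(self, records):
        s = summarize_clones(records, 3.0, gene_set={"DNMT3A"})
        assert s.total == 47
        assert 0 < s.at_or_below_cut < 47

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_clones([], 3.0)


class TestMultiMutationGroups:
    def test_fixture_has_six_groups_five_convergent(self, records):
        groups = multi_mutation_groups(records)
        assert len(groups) == 6
        assert sum(g.convergent_spliceosome for g in groups) == 5

    def test_records_without_symbols_give_no_groups(self):
        recs = [ClonalMutationRecord("JAK2", "JAK2 V617", "p.V617F", 5.0, 60)]
        assert multi_mutation_groups(recs) == []


class TestMinAgeByClass:
    def test_spliceosome_minimum_is_seventy(self, records):
        assert min_age_by_class(records, SPLICEOSOME_GENES) == 70

    def test_dnmt3a_minimum_is_twenty_five(self, records):
        assert min_age_by_class(records, {"DNMT3A"}) == 25

    def test_single_record_class(self):
        recs = [ClonalMutationRecord("KIT", "KIT D816", "p.D816V", 2.0, 40)]
        assert min_age_by_class(recs, {"KIT"}) == 40

    def test_empty_class_is_an_error(self, records):
        with pytest.raises(ValueError):
            min_age_by_class(records, {"TP53"})


class TestCompareGroups:
    def test_identical_groups_give_zero_t_unit_p(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_matches_closed_form_welch(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_groups(a, b)
        # independent hand computation of Welch's statistic and df
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t = (ma - mb) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert res.statistic == pytest.approx(t)
        assert res.df == pytest.approx(df)

    def test_one_constant_group_still_defined(self):
        res = compare_groups([5.0, 5.0, 5.0], [1.0, 2.0, 9.0])
        assert math.isfinite(res.statistic) and 0.0 <= res.pvalue <= 1.0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([5.0, 5.0], [5.0, 5.0])
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestProjection:
    def test_ratio_one_is_identity(self):
        for p in (0.0, 0.1, 0.195):
            assert project_total_incidence(p, 1.0)["projected_prevalence"] == pytest.approx(p)

    def test_zero_prevalence_projects_to_zero_in_both_modes(self):
        for mode in ("independent-union", "linear-capped"):
            assert project_total_incidence(0.0, 4.0, mode)["projected_prevalence"] == 0.0

    def test_union_mode_matches_direct_evaluation(self):
        out = project_total_incidence(0.195, 4.0, "independent-union")
        assert out["projected_prevalence"] == pytest.approx(1 - 0.805**4)
        assert out["projected_prevalence"] > 0.195

    def test_monotone_and_bounded_and_modes_agree_to_first_order(self):
        grid = np.linspace(0, 0.5, 11)
        for mode in ("independent-union", "linear-capped"):
            vals_p = [project_total_incidence(p, 3.0, mode)["projected_prevalence"] for p in grid]
            assert all(b >= a for a, b in zip(vals_p, vals_p[1:]))
            assert all(0 <= v <= 1 for v in vals_p)
        rs = [1.0, 2.0, 4.0, 8.0]
        vals_r = [project_total_incidence(0.1, r)["projected_prevalence"] for r in rs]
        assert all(b >= a for a, b in zip(vals_r, vals_r[1:]))
        p = 1e-4
        u = project_total_incidence(p, 5.0, "independent-union")["projected_prevalence"]
        l = project_total_incidence(p, 5.0, "linear-capped")["projected_prevalence"]
        assert u / l == pytest.approx(1.0, abs=1e-3)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            project_total_incidence(0.1, 0.5)
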