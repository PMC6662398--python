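"""Sex-linkage, heterozygosity, shared-polymorphism, and census statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from arcticum import datasets
from arcticum.linkage import (
    LinkageClass,
    LinkageResult,
    UndefinedResultError,
    classify_inversion_linkage,
    extent_of_y_linkage,
    heterozygote_proportion,
    shared_polymorphism_incidence,
    taxon_census,
)
from arcticum.nomenclature import parse_inversion_name
from arcticum.records import Genotype, GenotypeState, LarvaRecord, Sex

IIL6 = parse_inversion_name("IIL-6")


def _male(i, state, inv=IIL6):
    return LarvaRecord(f"m{i}", "s", None, Sex.M, True, [Genotype(inv, state)])


def _female(i, state, inv=IIL6):
    return LarvaRecord(f"f{i}", "s", None, Sex.F, False, [Genotype(inv, state)])


class TestExtentOfYLinkage:
    def test_iil6_census_absolute_linkage(self, iil6_records):
        """112 heterozygous males + 1 triploid carrier over 113 Y-bearing."""
        res = extent_of_y_linkage(iil6_records, IIL6)
        assert res.n_y_bearing == 113
        assert res.y_linkage == 1.0
        assert res.n_female == 93
        assert res.female_carrier_rate == 0.0

    def test_all_standard_males(self):
        recs = [_male(i, GenotypeState.ST_ST) for i in range(10)]
        assert extent_of_y_linkage(recs, IIL6).y_linkage == 0.0

    def test_direct_count(self):
        recs = [_male(i, GenotypeState.ST_I) for i in range(97)]
        recs += [_male(100 + i, GenotypeState.ST_ST) for i in range(3)]
        res = extent_of_y_linkage(recs, IIL6)
        assert res.y_linkage == pytest.approx(0.97)
        assert res.male_fraction_of_carriers == 1.0

    def test_no_y_bearing_scored_is_undefined(self):
        recs = [_female(i, GenotypeState.ST_ST) for i in range(5)]
        with pytest.raises(UndefinedResultError):
            extent_of_y_linkage(recs, IIL6)

    def test_carrier_and_noncarrier_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_car = int(rng.integers(0, 50))
            n_non = int(rng.integers(1, 50))
            recs = [_male(i, GenotypeState.ST_I) for i in range(n_car)]
            recs += [_male(100 + i, GenotypeState.ST_ST) for i in range(n_non)]
            res = extent_of_y_linkage(recs, IIL6)
            non_carrier = 1.0 - res.y_linkage
            assert res.y_linkage + non_carrier == 1.0


class TestClassification:
    def _result(self, y, f):
        return LinkageResult(IIL6, 100, 100, y, f)

    def test_survey_minimum_is_sex_linked(self):
        assert (
            classify_inversion_linkage(self._result(0.967, 0.0))
            is LinkageClass.SEX_LINKED
        )

    def test_equal_rates_autosomal(self):
        assert (
            classify_inversion_linkage(self._result(0.30, 0.31))
            is LinkageClass.AUTOSOMAL
        )

    def test_intermediate_is_ambiguous(self):
        assert (
            classify_inversion_linkage(self._result(0.6, 0.2))
            is LinkageClass.AMBIGUOUS
        )

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_inversion_linkage(self._result(1.0, 0.0), sex_threshold=1.5)


class TestHeterozygoteProportion:
    def _cohort(self, n_het, n_total, taxon="t"):
        recs = []
        for i in range(n_total):
            state = GenotypeState.ST_I if i < n_het else GenotypeState.ST_ST
            recs.append(
                LarvaRecord(f"l{i}", "s", None, Sex.F, False,
                            [Genotype(IIL6, state)], taxon_assignment=taxon)
            )
        return recs

    def test_zero_and_half(self):
        assert heterozygote_proportion(self._cohort(0, 206), "t", IIL6) == (0.0, 206)
        assert heterozygote_proportion(self._cohort(103, 206), "t", IIL6) == (0.5, 206)

    def test_empty_cohort_undefined(self):
        with pytest.raises(UndefinedResultError):
            heterozygote_proportion([], "t", IIL6)

    def test_binomial_sampling_recovery(self):
        """Estimate from a seeded binomial cohort stays within 3 SE of truth."""
        q, n = 0.457, 206
        rng = np.random.default_rng(42)
        n_het = rng.binomial(n, q)
        prop, n_out = heterozygote_proportion(self._cohort(n_het, n), "t", IIL6)
        se = math.sqrt(q * (1 - q) / n)
        assert n_out == n
        assert abs(prop - q) <= 3 * se


class TestSharedPolymorphismIncidence:
    def test_published_incidence(self):
        inc = shared_polymorphism_incidence(datasets.autosomal_polymorphism_table())
        assert inc.per_inversion["IS-1"] == (13, 15)
        assert inc.per_inversion["IL-1"] == (11, 15)
        assert set(inc.taxa_sharing_all) == {
            "S. brevicercum",
            "S. saxosum",
            "S. arcticum s.s.",
            "S. arcticum IIL-9",
            "S. arcticum IIL-79",
        }

    def test_all_zero_column(self):
        table = datasets.autosomal_polymorphism_table().copy()
        table["IIL-99"] = 0.0
        inc = shared_polymorphism_incidence(table)
        assert inc.per_inversion["IIL-99"] == (0, 15)

    def test_monotone_in_positive_rows(self):
        """Appending a positive row never decreases any sharing count."""
        table = datasets.autosomal_polymorphism_table()
        before = shared_polymorphism_incidence(table).per_inversion
        table2 = pd.concat(
            [table, pd.DataFrame([[0.1, 0.1, 0.1]], index=["new"],
                                 columns=table.columns)]
        )
        after = shared_polymorphism_incidence(table2).per_inversion
        for inv in before:
            assert after[inv][0] >= before[inv][0]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            shared_polymorphism_incidence(pd.DataFrame())


class TestTaxonCensus:
    def test_published_catalog(self):
        assert taxon_census(datasets.taxon_catalog()) == {
            "n_total": 31,
            "n_sibling": 9,
            "n_cytotype": 22,
        }
        assert taxon_census(datasets.range_catalog())["n_total"] == 31

    def test_empty_and_sibling_only(self):
        from arcticum.records import Rank, TaxonCatalog, TaxonEntry

        assert taxon_census(TaxonCatalog([])) == {
            "n_total": 0, "n_sibling": 0, "n_cytotype": 0,
        }
        cat = TaxonCatalog(
            [TaxonEntry(f"t{i}", Rank.SIBLING, (IIL6,)) for i in range(3)]
        )
        assert taxon_census(cat) == {"n_total": 3, "n_sibling": 3, "n_cytotype": 0}


def test_y_linkage_estimator_coverage():
    """Across 200 seeded replicates the estimate is within 3 binomial SE of
    the generating linkage in at least 99% of cases."""
    lam, n = 0.98, 400
    se = math.sqrt(lam * (1 - lam) / n)
    hits = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        carriers = rng.random(n) < lam
        recs = [
            _male(i, GenotypeState.ST_I if c else GenotypeState.ST_ST)
            for i, c in enumerate(carriers)
        ]
        est = extent_of_y_linkage(recs, IIL6).y_linkage
        hits += abs(est - lam) <= 3 * se
    assert hits >= 198
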