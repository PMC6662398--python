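"""Breakpoint-sharing enumeration, denominators, and hot-spot profiling."""

import numpy as np
import pytest

from arcticum import datasets
from arcticum.breakpoints import (
    BreakpointCatalog,
    BreakpointEntry,
    comparison_count,
    hotspot_profile,
    load_breakpoint_catalog,
    shared_breakpoint_matrix,
    write_breakpoint_catalog,
)
from arcticum.nomenclature import parse_inversion_name


def _entry(name, prox, dist):
    return BreakpointEntry(parse_inversion_name(name), prox, dist)


class TestComparisonCount:
    @pytest.mark.parametrize(
        "n,convention,expected",
        [
            (30, "paper", 1_800),
            (1, "paper", 2),
            (30, "unordered_pairs", 1_740),
            (2, "unordered_pairs", 4),
        ],
    )
    def test_conventions(self, n, convention, expected):
        assert comparison_count(n, convention) == expected

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            comparison_count(5, "ordered")


class TestSharedBreakpointMatrix:
    def test_planted_distal_share_is_symmetric(self):
        cat = BreakpointCatalog(
            [_entry("IIL-1", 56, 60), _entry("IIL-15", 58, 60),
             _entry("IIL-3", 55, 63)]
        )
        res = shared_breakpoint_matrix(cat)
        assert res.distal_distal.loc["IIL-1", "IIL-15"]
        assert res.distal_distal.loc["IIL-15", "IIL-1"]
        assert res.n_shared == 1
        assert res.sign_matrix("distal_distal").loc["IIL-1", "IIL-15"] == "+"

    def test_all_distinct_labels_share_nothing(self):
        cat = BreakpointCatalog(
            [_entry(f"IIL-{i}", 2 * i, 2 * i + 1) for i in range(1, 6)]
        )
        res = shared_breakpoint_matrix(cat)
        assert res.n_shared == 0
        assert res.percent_shared == 0.0

    def test_self_pairs_never_flagged(self):
        cat = BreakpointCatalog([_entry("IIL-1", 56, 60), _entry("IIL-2", 57, 61)])
        res = shared_breakpoint_matrix(cat)
        for mat in (res.distal_distal, res.proximal_proximal, res.proximal_distal):
            assert not np.diag(mat.to_numpy()).any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        entries = []
        for i in range(15):
            prox = int(rng.integers(1, 12))
            dist = prox + int(rng.integers(1, 8))
            entries.append(_entry(f"IIL-{i + 1}", prox, dist))
        cat = BreakpointCatalog(entries)
        res = shared_breakpoint_matrix(cat)
        expected = 0
        for i in range(15):
            for j in range(15):
                if i < j:
                    expected += entries[i].distal == entries[j].distal
                    expected += entries[i].proximal == entries[j].proximal
                if i != j:
                    expected += entries[i].proximal == entries[j].distal
        assert res.n_shared == expected

    def test_invariant_to_row_order(self):
        entries = [_entry("IIL-1", 56, 60), _entry("IIL-2", 56, 62),
                   _entry("IIL-3", 57, 62), _entry("IIL-4", 58, 63)]
        a = shared_breakpoint_matrix(BreakpointCatalog(entries))
        b = shared_breakpoint_matrix(BreakpointCatalog(entries[::-1]))
        assert a.n_shared == b.n_shared

    def test_symmetric_matrices_under_unordered_convention(self):
        entries = [_entry(f"IIL-{i}", 2 * i, 2 * i + 1) for i in range(1, 7)]
        res = shared_breakpoint_matrix(
            BreakpointCatalog(entries), convention="unordered_pairs"
        )
        for mat in (res.distal_distal, res.proximal_proximal):
            arr = mat.to_numpy()
            assert (arr == arr.T).all()

    def test_tolerance_widens_sharing(self):
        cat = BreakpointCatalog([_entry("IIL-1", 10, 20), _entry("IIL-2", 11, 22)])
        assert shared_breakpoint_matrix(cat).n_shared == 0
        assert shared_breakpoint_matrix(cat, tolerance=1).n_shared == 1

    def test_survey_percent_roundings(self):
        """46 shared of 1,800 comparisons prints as 2.6% (rounded) and 2.55%
        (truncated)."""
        percent = 100.0 * 46 / 1_800
        assert round(percent, 1) == 2.6
        cat = BreakpointCatalog(
            [_entry(f"IIL-{i}", 2 * i, 2 * i + 1) for i in range(1, 31)]
        )
        res = shared_breakpoint_matrix(cat)
        res.n_shared = 46
        assert res.percent_rounded(1) == 2.6
        assert res.percent_truncated(2) == 2.55


def test_published_distal_matrix_reproduced():
    """The published +/- distal-distal matrix for the 11 IIL inversions is
    reproduced from section labels planted to encode its sharing groups."""
    published = datasets.distal_sharing_matrix()
    # groups sharing a distal label: {1,15}, {3,22,6}, {10,68}, {13,16,17,19}
    distal = {"IIL-1": 60, "IIL-15": 60, "IIL-3": 61, "IIL-22": 61, "IIL-6": 61,
              "IIL-10": 62, "IIL-68": 62, "IIL-13": 63, "IIL-16": 63,
              "IIL-17": 63, "IIL-19": 63}
    prox = {name: 10 + i for i, name in enumerate(distal)}
    cat = BreakpointCatalog(
        [_entry(name, prox[name], distal[name]) for name in published.index]
    )
    res = shared_breakpoint_matrix(cat)
    computed = res.sign_matrix("distal_distal")
    assert (computed.loc[published.index, published.columns] == published).all().all()


class TestHotspotProfile:
    def test_simple_counts(self):
        cat = BreakpointCatalog(
            [_entry("IIL-1", 56, 60), _entry("IIL-2", 56, 61),
             _entry("IIL-3", 56, 62)]
        )
        prof = hotspot_profile(cat)
        assert prof.counts[56] == 3
        assert prof.max_sections == [56]

    def test_whole_section_inversion_contributes_flanks(self):
        # an inversion of the entire section 56 breaks at its two flanks
        cat = BreakpointCatalog([_entry("IIL-6", 55, 57)],
                                section_domain=range(55, 72))
        prof = hotspot_profile(cat)
        assert prof.counts[55] == 1 and prof.counts[57] == 1
        assert prof.counts[56] == 0

    def test_uniform_catalog_has_no_extreme_hotspot(self):
        """Labels drawn uniformly stay within the multinomial-simulated range
        of max-min count spread."""
        rng = np.random.default_rng(17)
        sections = np.arange(55, 72)
        entries = []
        for i in range(60):
            a, b = rng.choice(sections, size=2, replace=False)
            entries.append(_entry(f"IIL-{i + 1}", int(min(a, b)), int(max(a, b))))
        prof = hotspot_profile(
            BreakpointCatalog(entries, section_domain=range(55, 72))
        )
        spreads = []
        for _ in range(500):
            counts = rng.multinomial(120, np.ones(17) / 17)
            spreads.append(counts.max() - counts.min())
        observed = prof.counts.max() - prof.counts.min()
        assert observed <= np.quantile(spreads, 0.999)


def test_catalog_validation_and_round_trip(tmp_path):
    with pytest.raises(ValueError, match="must differ"):
        _entry("IIL-1", 56, 56)
    with pytest.raises(ValueError, match="outside domain"):
        BreakpointCatalog([_entry("IIL-1", 56, 99)], section_domain=range(55, 72))
    cat = BreakpointCatalog([_entry("IIL-1", 56, 60), _entry("IIL-2", 57, 61)])
    write_breakpoint_catalog(cat, tmp_path / "bp.csv")
    back = load_breakpoint_catalog(tmp_path / "bp.csv")
    assert back.entries == cat.entries
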