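"""FL/RA statistics, activity classes, and landscape analytics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ligscan as ls
from ligscan.activity import pair_type
from ligscan.reads import CountTable


class TestFractionLigated:
    def test_wild_type_magnitude(self):
        fl, lo, hi, flagged = ls.compute_fraction_ligated(413, 87)
        assert fl == pytest.approx(0.826)
        assert not flagged and lo < fl < hi

    def test_all_unligated(self):
        fl, *_ = ls.compute_fraction_ligated(0, 100)
        assert fl == 0.0

    def test_wilson_interval(self):
        fl, lo, hi, _ = ls.compute_fraction_ligated(75, 25)
        assert fl == 0.75
        assert 0.65 < lo < hi < 0.83

    def test_zero_total_is_missing(self):
        fl, lo, hi, flagged = ls.compute_fraction_ligated(0, 0)
        assert fl is None and flagged

    def test_low_coverage_flag(self):
        *_, flagged = ls.compute_fraction_ligated(5, 5, min_reads=20)
        assert flagged

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ls.compute_fraction_ligated(-1, 5)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=50, derandomize=True)
    def test_interval_brackets_estimate(self, n_lig, n_unlig):
        fl, lo, hi, _ = ls.compute_fraction_ligated(n_lig, n_unlig)
        if fl is not None:
            assert 0 <= lo <= fl <= hi <= 1


class TestRelativeActivity:
    @pytest.mark.parametrize(
        "fl,fl_wt,expected", [(0.826, 0.826, 1.0), (0.413, 0.826, 0.5), (0.0, 0.5, 0.0)]
    )
    def test_ratio(self, fl, fl_wt, expected):
        assert ls.compute_relative_activity(fl, fl_wt) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ls.compute_relative_activity(0.5, 0.0)


class TestClassifyActivity:
    @pytest.mark.parametrize(
        "ra,label",
        [
            (0.02, "inactive"),   # e.g. the ucA bulge variant
            (1.08, "high"),       # e.g. the GA 2-nt bulge variant
            (0.90, "active"),     # boundary: >0.90 is strict
            (0.50, "partial"),
            (0.10, "partial"),    # inactive is the strict RA<0.10 bin
        ],
    )
    def test_boundaries(self, ra, label):
        assert ls.classify_activity(ra) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ls.classify_activity(-0.1)

    @given(st.floats(0, 2), st.floats(0, 2))
    @settings(max_examples=100, derandomize=True)
    def test_monotone(self, ra1, ra2):
        """A larger RA never lands in a lower class."""
        order = {"inactive": 0, "partial": 1, "active": 2, "high": 3}
        lo, hi = sorted([ra1, ra2])
        assert order[ls.classify_activity(hi)] >= order[ls.classify_activity(lo)]


def counts_from(mapping):
    table = CountTable()
    for vid, (n_lig, n_unlig) in mapping.items():
        table.counts[vid] = [n_lig, n_unlig]
    table.reads_in = table.assigned
    return table


class TestActivityTable:
    def test_wild_type_ra_is_exactly_one(self):
        table = counts_from({"WT": [413, 87], "m1": [100, 100]})
        df = ls.activity_table(table)
        assert df.loc["WT", "ra"] == 1.0
        assert df.loc["m1", "ra"] == pytest.approx(0.5 / 0.826, rel=1e-12)

    def test_unusable_wild_type_rejected(self):
        with pytest.raises(ValueError):
            ls.activity_table(counts_from({"WT": [0, 0], "m1": [10, 10]}))


def ra_fixture(library, overrides, default=1.0):
    """variant_id → RA mapping covering the whole library."""
    ra = {rec.variant_id: default for rec in library}
    ra.update(overrides)
    return ra


class TestEffectMap:
    def test_uniform_map(self, minf1_library):
        grid = ls.single_mutant_effect_map(ra_fixture(minf1_library, {}), minf1_library)
        filled = grid.drop(columns="del").to_numpy()
        assert np.nanmin(filled) == np.nanmax(filled) == 1.0

    def test_least_active_lookup(self, sub_library):
        # engineered worst single mutant at (25, C), echoing a G25C-type hit
        ra = ra_fixture(sub_library, {"G25C": 0.29, "U23G": 0.45, "G25U": 0.47})
        grid = ls.single_mutant_effect_map(ra, sub_library)
        assert grid.loc[25, "C"] == 0.29
        row = grid.loc[25].drop("del")
        assert row.min() == 0.29

    def test_positions_confined_to_mutable_span(self, sub_library):
        grid = ls.single_mutant_effect_map(ra_fixture(sub_library, {}), sub_library)
        assert set(grid.index) == set(sub_library.template.mutable_positions)

    def test_wild_type_base_is_gap(self, sub_library):
        grid = ls.single_mutant_effect_map(ra_fixture(sub_library, {}), sub_library)
        wt = sub_library.template.sequence
        for pos in grid.index:
            assert np.isnan(grid.loc[pos, wt[pos - 1]])


class TestDoubleMutantMatrix:
    def test_constant_matrix(self, minf1_library):
        m = ls.double_mutant_matrix(ra_fixture(minf1_library, {}), minf1_library)
        assert set(m.values()) == {1.0}
        assert all(i < j for (i, _, j, _) in m)

    def test_known_fraction_above_threshold(self, minf1_library):
        doubles = [r.variant_id for r in minf1_library.by_class("sub2")]
        ra = ra_fixture(minf1_library, {}, default=0.95)
        for vid in doubles[:100]:
            ra[vid] = 0.05
        m = ls.double_mutant_matrix(ra, minf1_library)
        frac = np.mean([v > 0.90 for v in m.values()])
        assert frac == pytest.approx((len(m) - 100) / len(m))


class TestCompensatoryPairs:
    def rescue_fixture(self, minf1_library):
        return ra_fixture(
            minf1_library,
            {
                "A2C": 0.05, "U14G": 0.05, "A2C/U14G": 0.58,
                "U3A": 0.04, "A13U": 0.06, "U3A/A13U": 0.40,
                "U3G": 0.03, "A13C": 0.05, "U3G/A13C": 0.45,
                # deleterious pair rescued through non-pairing bases (A, G)
                "U10A": 0.02, "G15A": 0.02,
            },
            default=0.02,
        ) | {"U10A/G15A": 0.50, "WT": 1.0}

    def test_reported_rescues(self, minf1_library):
        pairs = ls.detect_compensatory_pairs(self.rescue_fixture(minf1_library),
                                             minf1_library)
        by_id = {(p.mutation_a, p.mutation_b): p for p in pairs}
        assert by_id[("A2C", "U14G")].pair_type == "Watson-Crick"
        assert by_id[("U3A", "A13U")].pair_type == "Watson-Crick"
        assert by_id[("U3G", "A13C")].pair_type == "Watson-Crick"
        assert by_id[("U10A", "G15A")].pair_type == "other"

    def test_no_rescue_gives_empty_list(self, minf1_library):
        ra = ra_fixture(minf1_library, {}, default=0.05)
        assert ls.detect_compensatory_pairs(ra, minf1_library) == []

    def test_order_invariance(self, minf1_library):
        ra = self.rescue_fixture(minf1_library)
        shuffled = dict(reversed(list(ra.items())))
        assert ls.detect_compensatory_pairs(ra, minf1_library) == \
            ls.detect_compensatory_pairs(shuffled, minf1_library)

    @pytest.mark.parametrize(
        "a,b,expected",
        [("U", "A", "Watson-Crick"), ("U", "G", "wobble"), ("A", "G", "other")],
    )
    def test_pair_type_table(self, a, b, expected):
        assert pair_type(a, b) == expected

    def test_inferred_positions(self, minf1_library):
        pairs = ls.detect_compensatory_pairs(self.rescue_fixture(minf1_library),
                                             minf1_library)
        inferred = ls.infer_paired_positions(pairs, min_support=1)
        supported = {(i, j) for i, j, _ in inferred}
        assert (2, 14) in supported and (3, 13) in supported
        assert (10, 15) not in supported  # non-pairing bases excluded
        (support_3_13,) = [n for i, j, n in inferred if (i, j) == (3, 13)]
        assert support_3_13 == 2  # both U3A/A13U and U3G/A13C

    def test_empty_input(self):
        assert ls.infer_paired_positions([]) == []


class TestDeletionToleranceMap:
    def test_uniform_tables(self, minf1_library):
        out = ls.deletion_tolerance_map(ra_fixture(minf1_library, {}), minf1_library)
        assert set(out[1].dropna()) == {1.0}
        diag = [out[2].loc[p, p] for p in out[2].index]
        assert set(x for x in diag if not np.isnan(x)) == {1.0}
        assert out[3]["fraction_above"] == 1.0

    def test_merged_record_fills_all_positions(self, minf1_library):
        # A5del..A9del collapse to one record; its RA must appear at 5..9
        rec = next(
            r for r in minf1_library.by_class("del1") if "A5del" in r.source_labels
        )
        ra = ra_fixture(minf1_library, {rec.variant_id: 0.77})
        out = ls.deletion_tolerance_map(ra, minf1_library, max_order=1)
        for pos in (5, 6, 7, 8, 9):
            assert out[1].loc[pos] == 0.77

    def test_triple_fraction_arithmetic(self, minf1_library):
        triples = [r.variant_id for r in minf1_library.by_class("del3")][:10]
        ra = {vid: (1.0 if i < 4 else 0.2) for i, vid in enumerate(triples)}
        ra["WT"] = 1.0
        out = ls.deletion_tolerance_map(ra, minf1_library, max_order=3)
        assert out[3]["n"] == 10 and out[3]["fraction_above"] == pytest.approx(0.40)
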