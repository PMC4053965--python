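"""Fisher's exact test against enumeration oracles, resampling, and the
unique-event rule."""
import warnings
from fractions import Fraction
from math import factorial

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as hs

from splicewatch import differential as diff
from splicewatch.model import SizingError, SplicedAlignment


def fisher_oracle(a, b, c, d):
    """Exact enumeration over all tables with the observed margins,
    using the column-wise hypergeometric decomposition (independent of
    the implementation's row-wise form)."""
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2

    def choose(m, k):
        return Fraction(factorial(m), factorial(k) * factorial(m - k))

    denom = choose(n, r1)
    probs = {}
    for a2 in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[a2] = choose(c1, a2) * choose(c2, r1 - a2) / denom
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        assert diff.fisher_2x2(((5, 50), (5, 50))) == 1.0

    def test_enumeration_oracle_on_moderate_margins(self):
        table = ((10, 100), (50, 100))
        assert diff.fisher_2x2(table) == pytest.approx(
            fisher_oracle(10, 100, 50, 100), abs=1e-12
        )

    def test_fully_crossed_table_matches_complete_enumeration(self):
        assert diff.fisher_2x2(((0, 10), (10, 0))) == pytest.approx(
            fisher_oracle(0, 10, 10, 0), abs=1e-12
        )

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert diff.fisher_2x2(((0, 0), (5, 7))) == 1.0

    def test_negative_or_fractional_entries_are_rejected(self):
        with pytest.raises(ValueError):
            diff.fisher_2x2(((-1, 2), (3, 4)))

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 120, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            expected = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert diff.fisher_2x2(((a, b), (c, d))) == pytest.approx(
                expected, rel=1e-9, abs=1e-12
            )

    def test_large_table_log_path_matches_scipy(self):
        table = ((900, 2100), (1500, 1700))  # total above the exact-path limit
        expected = scipy.stats.fisher_exact([[900, 2100], [1500, 1700]])[1]
        assert diff.fisher_2x2(table) == pytest.approx(expected, rel=1e-6)

    @settings(derandomize=True, max_examples=150)
    @given(hs.integers(0, 25), hs.integers(0, 25), hs.integers(0, 25), hs.integers(0, 25))
    def test_p_is_invariant_under_row_and_column_swaps(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = diff.fisher_2x2(((a, b), (c, d)))
        assert 0.0 <= p <= 1.0
        assert diff.fisher_2x2(((c, d), (a, b))) == pytest.approx(p, abs=1e-12)
        assert diff.fisher_2x2(((b, a), (d, c))) == pytest.approx(p, abs=1e-12)


def _dummy_alignments(n):
    return [
        SplicedAlignment(f"r{i}", "chr1", ((i * 10, i * 10 + 50),)) for i in range(n)
    ]


class TestResample:
    def test_exact_count_without_duplicates(self):
        lib = _dummy_alignments(5000)
        out = diff.resample(lib, diff.ResampleConfig(1000, seed=1))
        assert len(out) == 1000
        assert len({a.read_id for a in out}) == 1000

    def test_same_seed_gives_identical_subsets(self):
        lib = _dummy_alignments(2000)
        a = diff.resample(lib, diff.ResampleConfig(500, seed=9))
        b = diff.resample(lib, diff.ResampleConfig(500, seed=9))
        assert [x.read_id for x in a] == [x.read_id for x in b]

    def test_full_draw_is_the_identity_permutation(self):
        lib = _dummy_alignments(300)
        out = diff.resample(lib, diff.ResampleConfig(300, seed=4))
        assert out == lib

    def test_oversized_draw_raises(self):
        with pytest.raises(SizingError):
            diff.resample(_dummy_alignments(10), diff.ResampleConfig(11, seed=0))


class TestEventTests:
    def test_unique_event_with_five_reads_is_assigned_zero(self):
        (res,) = diff.test_events(
            [diff.EventCounts("e", alt_a=0, exon_a=200, alt_b=5, exon_b=200)]
        )
        assert res.assigned_zero and res.significant
        assert res.p_value == 0.0 and res.direction == "B_over"

    def test_unique_event_with_four_reads_is_not_significant(self):
        (res,) = diff.test_events(
            [diff.EventCounts("e", alt_a=0, exon_a=200, alt_b=4, exon_b=200)]
        )
        assert not res.assigned_zero and not res.significant

    def test_equal_proportions_are_not_significant(self):
        (res,) = diff.test_events(
            [diff.EventCounts("e", alt_a=30, exon_a=300, alt_b=30, exon_b=300)]
        )
        assert not res.significant and res.direction == "none"

    def test_strong_intron_shift_clears_the_stricter_ir_threshold(self):
        (res,) = diff.test_introns(
            [diff.EventCounts("i", alt_a=0, exon_a=200, alt_b=40, exon_b=200)]
        )
        assert res.significant
        # the same table evaluated without the unique rule is itself < 0.001
        assert fisher_oracle(0, 200, 40, 200) < 0.001

    def test_swapping_conditions_flips_direction_and_preserves_p(self):
        fwd = diff.EventCounts("e", alt_a=3, exon_a=150, alt_b=20, exon_b=160)
        rev = diff.EventCounts("e", alt_a=20, exon_a=160, alt_b=3, exon_b=150)
        (rf,) = diff.test_events([fwd])
        (rr,) = diff.test_events([rev])
        assert rf.p_value == pytest.approx(rr.p_value, abs=1e-12)
        assert {rf.direction, rr.direction} == {"A_over", "B_over"}

    def test_null_resamples_stay_calibrated(self, toy):
        """Comparing two resamples of one library, few events reach p<0.01."""
        from splicewatch import events as ev
        from splicewatch import junctions as jx
        from splicewatch.pipeline import assemble_intron_counts

        half = len(toy.mut_alignments) // 2
        sub_a = diff.resample(toy.mut_alignments, diff.ResampleConfig(half, seed=1))
        sub_b = diff.resample(toy.mut_alignments, diff.ResampleConfig(half, seed=2))
        # pseudo-events: every annotated junction, tested junction-vs-exon
        counts = []
        for sub in (sub_a, sub_b):
            catalog = {j.key: j for j in jx.extract_junctions(sub, toy.annotation)}
            counts.append(catalog)
        exon_reads_a = len(sub_a)  # proxy denominator at equal depth
        exon_reads_b = len(sub_b)
        table = []
        keys = sorted(set(counts[0]) | set(counts[1]))
        for key in keys:
            ja = counts[0][key].read_count if key in counts[0] else 0
            jb = counts[1][key].read_count if key in counts[1] else 0
            table.append(
                diff.EventCounts(str(key), ja, exon_reads_a, jb, exon_reads_b)
            )
        results = diff.test_events(table)
        frac = np.mean([r.significant for r in results])
        assert len(results) >= 100
        assert frac <= 0.02


class TestGlobalComparison:
    def test_identical_catalogs_give_p_one_everywhere(self, toy, toy_catalog):
        from splicewatch import events as ev

        _, filtered = toy_catalog
        catalog = ev.classify_events(filtered, toy.annotation)
        frame = diff.global_comparison(catalog.events, catalog.events, 8000, 8000)
        assert (frame["p_value"] == 1.0).all()
        assert (frame["junction_reads_a"] == frame["junction_reads_b"]).all()

    def test_empty_type_rows_are_present_with_p_one(self):
        frame = diff.global_comparison({}, {}, 1000, 1000)
        assert (frame["p_value"] == 1.0).all()
        assert (frame["junction_reads_a"] == 0).all()


class TestRescueProfile:
    def test_counts_proportional_to_totals_normalise_equal(self):
        frame = diff.profile_rescue(
            {"e1": {"wt": 10, "mut": 20}}, {"wt": 10_000, "mut": 20_000}
        )
        assert frame.loc[0, "wt"] == pytest.approx(frame.loc[0, "mut"])

    def test_identical_groups_give_identical_rows(self):
        frame = diff.profile_rescue(
            {"e1": {"a": 7, "b": 7}, "e2": {"a": 3, "b": 3}},
            {"a": 5000, "b": 5000},
        )
        assert (frame["a"] == frame["b"]).all()

    def test_empty_event_set_is_an_error(self):
        with pytest.raises(ValueError):
            diff.profile_rescue({}, {"a": 1000})
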