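"""ISH calling thresholds, monotonicity, co-localization."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filoplast import (
    ConfigurationError,
    ISHConfig,
    ISHEvent,
    MalformedPileupError,
    PileupOrderError,
    call_ish,
    colocalize,
    intra_vs_inter,
    read_pileup,
    read_pileup_table,
)
from filoplast.pairdiff import PairwiseComparison
from filoplast.sim import PILEUP_COLUMNS


def column(pos=0, ref="A", depth=100, a=None, c=0, g=0, t=0, ins=0, dele=0,
           contig="c1"):
    if a is None:
        a = depth - c - g - t
    return pd.DataFrame(
        [(contig, pos, ref, depth, a, c, g, t, ins, dele)],
        columns=PILEUP_COLUMNS,
    )


def write_lines(tmp_path, lines, name="p.tsv"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadPileup:
    def test_valid_line_parsed_and_converted_to_zero_based(self, tmp_path):
        p = write_lines(tmp_path, ["#comment",
                                   "c1\t100\tA\t100\t74\t26\t0\t0\t0\t0"])
        cols = list(read_pileup(p))
        assert len(cols) == 1
        col = cols[0]
        assert (col.position, col.coverage, col.count_a, col.count_c) \
            == (99, 100, 74, 26)

    def test_depth_allele_sum_mismatch_reported_with_line_number(self, tmp_path):
        p = write_lines(tmp_path, ["c1\t1\tA\t50\t25\t24\t0\t0\t0\t0"])
        with pytest.raises(MalformedPileupError, match="line 1"):
            list(read_pileup(p))
        with pytest.raises(MalformedPileupError):
            read_pileup_table(p)

    def test_out_of_order_positions_rejected(self, tmp_path):
        p = write_lines(tmp_path, ["c1\t5\tA\t10\t10\t0\t0\t0\t0\t0",
                                   "c1\t4\tA\t10\t10\t0\t0\t0\t0\t0"])
        with pytest.raises(PileupOrderError):
            list(read_pileup(p))
        with pytest.raises(PileupOrderError):
            read_pileup_table(p)

    def test_empty_file_empty_stream(self, tmp_path):
        p = write_lines(tmp_path, ["#only a comment"])
        assert list(read_pileup(p)) == []
        assert read_pileup_table(p).empty


class TestCallIsh:
    def test_quarter_frequency_allele_called(self):
        events = call_ish(column(depth=100, c=26))
        assert len(events) == 1
        e = events[0]
        assert (e.event_class, e.consensus_allele, e.variant_allele,
                e.frequency) == ("SNV", "A", "C", 0.26)

    def test_coverage_below_floor_yields_nothing(self):
        assert call_ish(column(depth=99, c=29)) == []

    def test_frequency_just_below_threshold_yields_nothing(self):
        assert call_ish(column(depth=200, c=48, g=2)) == []

    def test_indel_alleles_called_and_suppressible(self):
        col = column(depth=120, ins=40, dele=30)
        classes = {e.event_class for e in call_ish(col)}
        assert classes == {"insertion", "deletion"}
        assert call_ish(col, ISHConfig(count_indels=False)) == []

    def test_consensus_tie_broken_alphabetically(self):
        events = call_ish(column(ref="G", depth=100, a=50, c=50))
        assert len(events) == 1
        assert events[0].consensus_allele == "A"
        assert events[0].variant_allele == "C"

    def test_stream_and_table_paths_agree(self, tmp_path):
        p = write_lines(tmp_path, [
            "c1\t1\tA\t100\t74\t26\t0\t0\t0\t0",
            "c1\t2\tC\t200\t0\t150\t48\t2\t0\t0",
            "c1\t3\tG\t150\t0\t0\t100\t50\t40\t0",
        ])
        a = call_ish(list(read_pileup(p)))
        b = call_ish(read_pileup_table(p))
        assert [(e.position, e.variant_allele, e.frequency) for e in a] \
            == [(e.position, e.variant_allele, e.frequency) for e in b]

    def test_raising_thresholds_never_increases_event_count(self, rng):
        """Monotonicity over a threshold grid on one random pileup."""
        n = 400
        depth = rng.integers(80, 400, size=n)
        alt = rng.binomial(depth, rng.uniform(0.05, 0.5, size=n))
        df = pd.DataFrame({
            "contig": "c1", "pos": np.arange(n), "ref": "A",
            "depth": depth, "countA": depth - alt, "countC": alt,
            "countG": 0, "countT": 0, "countIns": 0, "countDel": 0,
        })
        prev_by_cov = None
        for min_cov in (100, 150, 250):
            counts = []
            prev = None
            for freq in (0.25, 0.3, 0.4, 0.5):
                n_ev = len(call_ish(df, ISHConfig(min_coverage=min_cov,
                                                  min_variant_frequency=freq)))
                if prev is not None:
                    assert n_ev <= prev
                prev = n_ev
                counts.append(n_ev)
            if prev_by_cov is not None:
                assert all(a <= b for a, b in zip(counts, prev_by_cov))
            prev_by_cov = counts

    def test_at_most_three_snv_events_per_column(self):
        # frequency budget: at most floor(1/0.25) - 1 non-consensus bases
        events = call_ish(column(depth=100, a=25, c=25, g=25, t=25))
        assert len([e for e in events if e.event_class == "SNV"]) == 3

    def test_coverage_floor_below_31_rejected(self):
        with pytest.raises(ConfigurationError):
            ISHConfig(min_coverage=30)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(counts=st.lists(st.integers(0, 500), min_size=4, max_size=4),
           ins=st.integers(0, 200), dele=st.integers(0, 200))
    def test_event_frequencies_respect_threshold_and_consensus(
            self, counts, ins, dele):
        """Every emitted event has a non-consensus allele at frequency >=
        0.25 on a column of coverage >= 100; the frequency budget caps the
        event count at 5."""
        depth = sum(counts)
        ins, dele = min(ins, depth), min(dele, depth)
        a, c, g, t = counts
        events = call_ish(column(depth=depth, a=a, c=c, g=g, t=t,
                                 ins=ins, dele=dele))
        if depth < 100:
            assert events == []
            return
        assert len(events) <= 5
        for e in events:
            assert e.frequency >= 0.25
            assert e.variant_allele != e.consensus_allele


def make_event(seg, pos, allele="C", klass="SNV", contig="c1"):
    return ISHEvent(seg, contig, pos, klass, "A", allele, 0.3, 200)


class TestColocalize:
    def test_identical_site_in_all_segments_fully_colocalized(self):
        events = {s: [make_event(s, 10)] for s in (1, 2, 3)}
        summ = colocalize(events)
        assert summ.n_sites_shared_by_all == 1
        assert summ.fraction_colocalized == 1.0
        assert summ.fraction_not_colocalized == 0.0

    def test_disjoint_sites_not_colocalized(self):
        events = {s: [make_event(s, 10 * s)] for s in (1, 2, 3)}
        summ = colocalize(events)
        assert summ.n_sites_shared_by_all == 0
        assert summ.fraction_not_colocalized == 1.0

    def test_allele_must_match_for_sharing(self):
        events = {1: [make_event(1, 10, "C")], 2: [make_event(2, 10, "G")]}
        assert colocalize(events).n_sites_shared_by_all == 0

    def test_zero_event_segment_counts_in_denominator(self):
        events = {1: [make_event(1, 10)], 2: [make_event(2, 10)], 3: []}
        summ = colocalize(events)
        assert summ.n_sites_shared_by_all == 0
        assert summ.n_sites_shared_by_2plus == 1

    def test_shared_count_invariant_under_relabeling(self, rng):
        events = {}
        for s in (1, 2, 3, 4):
            events[s] = [make_event(s, int(p))
                         for p in rng.choice(50, size=20, replace=False)]
        base = colocalize(events)
        shuffled = {s: events[s] for s in (3, 1, 4, 2)}
        perm = colocalize(shuffled)
        assert perm.n_sites_shared_by_all == base.n_sites_shared_by_all
        assert perm.fraction_colocalized == base.fraction_colocalized

    def test_fractions_sum_to_one(self, rng):
        events = {s: [make_event(s, int(p))
                      for p in rng.choice(100, size=30, replace=False)]
                  for s in (1, 2)}
        summ = colocalize(events)
        assert summ.fraction_colocalized + summ.fraction_not_colocalized \
            == pytest.approx(1.0)


class TestIntraVsInter:
    def _cmp(self, ref, qry, snps):
        return PairwiseComparison(reference_id=ref, query_id=qry,
                                  total_snps=snps)

    def test_equal_means_ratio_one(self):
        events = {1: [make_event(1, i) for i in range(10)],
                  2: [make_event(2, i) for i in range(10)]}
        comps = [self._cmp(1, 2, 10), self._cmp(2, 1, 10)]
        rep = intra_vs_inter(events, comps)
        assert rep.ratio == pytest.approx(1.0)

    def test_empty_inputs_marked_empty(self):
        assert intra_vs_inter({}, []).empty

    def test_subset_restricts_both_sides(self):
        events = {1: [make_event(1, 1)], 2: [], 3: [make_event(3, i)
                                                    for i in range(99)]}
        comps = [self._cmp(1, 2, 2), self._cmp(2, 1, 2), self._cmp(1, 3, 50)]
        rep = intra_vs_inter(events, comps, subset={1, 2})
        assert rep.mean_ish_events_per_segment == pytest.approx(0.5)
        assert rep.mean_pairwise_snps == pytest.approx(2.0)
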