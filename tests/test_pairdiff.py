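"""Anchored pairwise comparison, checked against independent oracles."""

from collections import Counter, defaultdict

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from filoplast import (
    Anchor,
    SimulationConfig,
    UndefinedRateError,
    banded_global_align,
    chain_anchors,
    compare_pair,
    find_anchors,
    generate_reference,
    mutate_consensus,
    rate_per_100kbp,
    round_half_up,
)
from filoplast.genome import AnnotatedGenome, ConfigurationError
from filoplast.pairdiff import align_gaps, align_pair, call_variants

from conftest import random_seq


def oracle_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -1
    return al


def brute_force_anchors(q: str, t: str, k: int) -> set[Anchor]:
    """Independent oracle: dictionary of all k-mers, keep those unique in
    both sequences, merge same-diagonal consecutive matches."""
    def index(s):
        d = defaultdict(list)
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if "N" not in w:
                d[w].append(i)
        return d

    qi, ti = index(q), index(t)
    pairs = sorted(
        (qi[w][0], ti[w][0]) for w in qi
        if len(qi[w]) == 1 and w in ti and len(ti[w]) == 1
    )
    by_diag = defaultdict(list)
    for qp, tp in pairs:
        by_diag[tp - qp].append(qp)
    anchors = set()
    for diag, qs in by_diag.items():
        qs.sort()
        start = prev = qs[0]
        for p in qs[1:]:
            if p == prev + 1:
                prev = p
                continue
            anchors.add(Anchor(start, start + diag, prev - start + k))
            start = prev = p
        anchors.add(Anchor(start, start + diag, prev - start + k))
    return anchors


def oracle_variant_counts(a: str, b: str) -> tuple[int, int]:
    """(SNPs, indel columns) from an unbanded global alignment oracle."""
    aln = oracle_aligner().align(a, b)[0]
    snps = indels = 0
    pa = pb = 0
    for (qa, qb), (ta, tb) in zip(*aln.aligned):
        indels += (qa - pa) + (ta - pb)
        snps += sum(1 for x, y in zip(a[qa:qb], b[ta:tb]) if x != y)
        pa, pb = qb, tb
    indels += (len(a) - pa) + (len(b) - pb)
    return snps, indels


def pipeline_variant_counts(a: str, b: str, **kw) -> tuple[int, int]:
    chain = align_pair(a, b, **kw)
    assert chain is not None
    snps = sum(1 for op in chain.transcript if op == "X")
    indels = sum(1 for op in chain.transcript if op in "ID")
    return snps, indels


class TestFindAnchors:
    def test_identical_sequences_one_full_length_anchor(self, rng):
        s = random_seq(rng, 10_000)
        anchors = find_anchors(s, s, k=21)
        assert anchors == [Anchor(0, 0, 10_000)]

    def test_single_substitution_two_flanking_anchors(self, rng):
        s = random_seq(rng, 10_000)
        t = s[:5_000] + ("A" if s[5_000] != "A" else "C") + s[5_001:]
        anchors = find_anchors(s, t, k=21)
        assert len(anchors) == 2
        assert anchors[0] == Anchor(0, 0, 5_000)
        assert anchors[1] == Anchor(5_001, 5_001, 4_999)

    def test_matches_brute_force_oracle_with_planted_substitutions(self, rng):
        q = random_seq(rng, 50_000)
        t = list(q)
        for p in rng.choice(50_000, size=10, replace=False):
            t[p] = "ACGT"[("ACGT".index(t[p]) + 1) % 4]
        t = "".join(t)
        assert set(find_anchors(q, t, k=21)) == brute_force_anchors(q, t, 21)

    def test_n_runs_produce_no_anchors(self):
        assert find_anchors("N" * 100, "N" * 100, k=11) == []

    def test_empty_sequence_empty_list(self):
        assert find_anchors("", "ACGT" * 10, k=11) == []

    def test_invalid_k_rejected(self):
        with pytest.raises(ConfigurationError):
            find_anchors("ACGT", "ACGT", k=20)


class TestChainAnchors:
    def test_colinear_anchors_all_retained(self):
        anchors = [Anchor(0, 0, 50), Anchor(100, 100, 50), Anchor(200, 210, 50)]
        assert chain_anchors(anchors) == anchors

    def test_heavier_anchor_beats_two_light_ones(self):
        anchors = [Anchor(0, 0, 100), Anchor(200, 500, 100), Anchor(300, 200, 400)]
        assert chain_anchors(anchors) == [Anchor(0, 0, 100), Anchor(300, 200, 400)]

    def test_single_anchor_kept(self):
        assert chain_anchors([Anchor(5, 9, 30)]) == [Anchor(5, 9, 30)]

    def test_empty_input_empty_chain(self):
        assert chain_anchors([]) == []

    def test_matches_exhaustive_enumeration_on_nonoverlapping_sets(self, rng):
        """On overlap-free anchor sets the chain equals the best strictly
        increasing non-overlapping subset found by 2^n enumeration."""
        for _ in range(50):
            n = int(rng.integers(1, 9))
            qs = np.cumsum(rng.integers(5, 60, size=n))
            ts = rng.permutation(np.cumsum(rng.integers(5, 60, size=n)))
            ln = rng.integers(1, 5, size=n)
            anchors = [Anchor(int(q), int(t), int(l))
                       for q, t, l in zip(qs, ts, ln)]
            best = 0
            for mask in range(1, 2 ** n):
                sub = sorted((anchors[i] for i in range(n) if mask >> i & 1),
                             key=lambda a: a.qpos)
                ok = all(
                    x.qpos + x.length <= y.qpos and x.tpos + x.length <= y.tpos
                    for x, y in zip(sub, sub[1:])
                )
                if ok:
                    best = max(best, sum(a.length for a in sub))
            chain = chain_anchors(anchors)
            assert sum(a.length for a in chain) == best

    def test_chain_output_is_colinear_and_non_overlapping(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 20))
            anchors = [
                Anchor(int(rng.integers(0, 500)), int(rng.integers(0, 500)),
                       int(rng.integers(5, 40)))
                for _ in range(n)
            ]
            chain = chain_anchors(anchors)
            for x, y in zip(chain, chain[1:]):
                assert x.qpos + x.length <= y.qpos
                assert x.tpos + x.length <= y.tpos


class TestBandedAlignment:
    def test_single_mismatch_transcript(self):
        tr, score = banded_global_align("ACGT", "ACTT")
        assert tr == "==X="
        assert score == 2

    def test_single_deletion_transcript(self):
        # the base present only in the first sequence is one gap column
        tr, _ = banded_global_align("ACGT", "ACT")
        assert Counter(tr)["I"] == 1 and Counter(tr)["X"] == 0

    def test_scores_match_unbanded_oracle_on_random_gap_pairs(self, rng):
        al = oracle_aligner()
        for _ in range(200):
            a = random_seq(rng, int(rng.integers(1, 51)))
            b = random_seq(rng, int(rng.integers(1, 51)))
            _, score = banded_global_align(a, b, band=64)
            assert score == al.score(a, b)

    dna = st.text(alphabet="ACGT", min_size=0, max_size=80)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(a=dna, b=dna)
    def test_transcript_consumes_both_sequences(self, a, b):
        tr, _ = banded_global_align(a, b)
        assert sum(1 for o in tr if o in "=XI") == len(a)
        assert sum(1 for o in tr if o in "=XD") == len(b)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(a=st.text(alphabet="ACGTN", min_size=1, max_size=40),
           b=st.text(alphabet="ACGTN", min_size=1, max_size=40))
    def test_score_never_exceeds_shorter_length(self, a, b):
        _, score = banded_global_align(a, b)
        assert score <= min(len(a), len(b))


class TestCallVariants:
    def _planted_pair(self, rng, n_sub=25, n_del=5, length=100_000):
        cfg = SimulationConfig(genome_length=length, seed=int(rng.integers(1e6)),
                               snp_rate_cds=0, snp_rate_ncds=0,
                               indel_rate_cds=0, indel_rate_ncds=0)
        ref = generate_reference(cfg)
        seq = list(ref.contigs["contig_1"])
        pos = np.sort(rng.choice(length - 100, size=n_sub + n_del,
                                 replace=False) + 50)
        # keep events apart so planted coordinates are alignment-unambiguous
        pos = pos[np.concatenate([[True], np.diff(pos) > 60])]
        subs, dels = pos[:n_sub], pos[n_sub:]
        truth_snp = set()
        for p in subs:
            old = seq[p]
            seq[p] = "ACGT"[("ACGT".index(old) + 2) % 4]
            truth_snp.add(int(p))
        for p in sorted(dels, reverse=True):
            del seq[p]
        qry = AnnotatedGenome(contigs={"contig_1": "".join(seq)},
                              cds_intervals={}, name="planted")
        return ref, qry, truth_snp, {int(d) for d in dels}

    def test_identical_sequences_zero_variants(self, rng):
        s = random_seq(rng, 5_000)
        g = AnnotatedGenome(contigs={"c": s}, name="x")
        chain = align_pair(s, s)
        assert call_variants(chain, g, s, "c") == []

    def test_planted_substitutions_and_deletions_recovered(self, rng):
        ref, qry, truth_snp, truth_del = self._planted_pair(rng)
        chain = align_pair(ref.contigs["contig_1"], qry.contigs["contig_1"])
        calls = call_variants(chain, qry, ref.contigs["contig_1"], "contig_1")
        snps = [v for v in calls if v.variant_class == "SNP"]
        dels = [v for v in calls if v.variant_class == "deletion"]
        assert len(snps) == len(truth_snp) and len(dels) == len(truth_del)
        # SNP coordinates on the query shift by the deletions before them
        del_sorted = np.sort(list(truth_del))
        expect = {int(p - np.searchsorted(del_sorted, p)) for p in truth_snp}
        assert {v.position for v in snps} == expect

    def test_snp_inside_cds_classified_cds(self, rng):
        s = random_seq(rng, 2_000)
        q = s[:1_000] + ("G" if s[1_000] != "G" else "T") + s[1_001:]
        qg = AnnotatedGenome(contigs={"c": q},
                             cds_intervals={"c": [(900, 1_200)]}, name="q")
        chain = align_pair(s, q)
        calls = call_variants(chain, qg, s, "c")
        assert [(v.position, v.variant_class, v.compartment)
                for v in calls] == [(1_000, "SNP", "CDS")]


class TestOracleEquivalence:
    def test_anchored_counts_equal_unbanded_oracle(self, rng):
        """Anchored pipeline and direct unbanded global alignment call the
        same SNP and indel-column counts on near-identical pairs."""
        for _ in range(30):
            L = int(rng.integers(800, 3_000))
            a = random_seq(rng, L)
            b = list(a)
            for _ in range(int(rng.integers(1, 8))):
                p = int(rng.integers(10, len(b) - 10))
                r = rng.random()
                if r < 0.6:
                    b[p] = "ACGT"[("ACGT".index(b[p]) + 1) % 4]
                elif r < 0.8:
                    b.insert(p, "ACGT"[rng.integers(0, 4)])
                else:
                    b.pop(p)
            b = "".join(b)
            assert pipeline_variant_counts(a, b, k=11) \
                == oracle_variant_counts(a, b)


class TestComparePair:
    def test_self_comparison_all_zero(self, small_genome):
        c = compare_pair(small_genome, small_genome)
        assert c.aligned
        assert c.total_snps == c.total_indels == 0
        assert c.snps_per_100kbp == 0.0

    def test_unrelated_sequences_explicit_no_alignment(self, rng):
        a = AnnotatedGenome(contigs={"c": random_seq(rng, 5_000)}, name="a")
        b = AnnotatedGenome(contigs={"c": random_seq(rng, 5_000)}, name="b")
        c = compare_pair(a, b)
        assert not c.aligned

    def test_compartment_conservation_and_snp_symmetry(self):
        cfg = SimulationConfig(genome_length=400_000, seed=5,
                               indel_rate_cds=0, indel_rate_ncds=0)
        ref = generate_reference(cfg)
        s1, _ = mutate_consensus(ref, cfg, 1)
        s2, _ = mutate_consensus(ref, cfg, 2)
        c12 = compare_pair(s1, s2)
        c21 = compare_pair(s2, s1)
        assert c12.snps_cds + c12.snps_ncds == c12.total_snps
        assert c12.indels_cds + c12.indels_ncds == c12.total_indels
        # indel-free complete assemblies: SNP counts direction-independent
        assert c12.total_snps == c21.total_snps


class TestRates:
    @pytest.mark.parametrize("count,denom,expected", [
        (132, 3_217_969, 4.10),
        (86, 3_239_714, 2.65),
        (300, 2_544_604, 11.79),
        (41, 374_878, 10.94),
        (0, 1_000, 0.0),
    ])
    def test_rate_per_100kbp_reported_values(self, count, denom, expected):
        assert round_half_up(rate_per_100kbp(count, denom), 2) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(UndefinedRateError):
            rate_per_100kbp(1, 0)


def test_oversized_gap_flagged_structurally_divergent(rng):
    """A gap above the cap is excluded from calling, not aligned."""
    a = random_seq(rng, 4_000)
    insert = random_seq(rng, 1_200)
    b = a[:2_000] + insert + a[2_000:]
    chain = align_pair(a, b, k=11, gap_cap=1_000)
    assert chain.structurally_divergent
    assert all(op != "D" or True for op in chain.transcript)
    n_called_cols = sum(len(t) for k_, _, _, t in chain.pieces if t)
    assert n_called_cols < len(b)
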