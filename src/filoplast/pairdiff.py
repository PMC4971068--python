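"""Pairwise comparison of near-identical assemblies.

Two near-clonal assemblies are aligned by unique-k-mer anchoring: exact
k-mers that occur exactly once in both sequences are matched, merged into
maximal exact matches, chained colinearly (weighted longest increasing
subsequence), and the short inter-anchor gaps are filled with a banded global
(Gotoh affine) alignment.  Mismatch columns become SNPs and every gap column
becomes one single-nucleotide insertion or deletion event, each classified by
coding-compartment membership on the query assembly, whose total/CDS/nCDS
lengths are also the denominators of all per-100-kbp rates.

Scoring is match +1, mismatch -1, gap open -2, gap extend -1 (a length-L gap
costs 2 + (L - 1)); any scheme consistent with near-identity alignment would
do, and the oracle tests pin the behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .genome import (
    AnnotatedGenome,
    ConfigurationError,
    InternalConsistencyError,
    UndefinedRateError,
)

DEFAULT_K = 21
DEFAULT_BAND = 256
DEFAULT_GAP_CAP = 20_000

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2    # cost of the first gap column
GAP_EXTEND = -1  # cost of each further column in the same gap

_NEG = -(10 ** 9)


class Anchor(NamedTuple):
    """Maximal exact match: ``length`` bases at ``qpos``/``tpos``."""

    qpos: int
    tpos: int
    length: int


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit k-mer codes and a validity mask (no N/other inside window)."""
    b = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(b)
    if n < k:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.uint64)
    bad = (b >= 4)
    invalid = np.zeros(m, dtype=bool)
    for j in range(k):
        codes = (codes << np.uint64(2)) | (b[j:m + j] & np.uint8(3))
        invalid |= bad[j:m + j]
    return codes, ~invalid


def _unique_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes occurring exactly once, with their positions."""
    codes, valid = _kmer_codes(seq, k)
    pos = np.flatnonzero(valid)
    u, idx, cnt = np.unique(codes[valid], return_index=True, return_counts=True)
    once = cnt == 1
    return u[once], pos[idx[once]]


def find_anchors(query: str, target: str, k: int = DEFAULT_K) -> list[Anchor]:
    """Exact k-mer matches unique in both sequences, merged into maximal
    exact matches.  Empty input yields an empty list."""
    if not (11 <= k <= 31 and k % 2 == 1):
        raise ConfigurationError("k must be odd and in [11, 31]")
    if not query or not target:
        return []
    qk, qpos = _unique_kmers(query, k)
    tk, tpos = _unique_kmers(target, k)
    _, qi, ti = np.intersect1d(qk, tk, assume_unique=True, return_indices=True)
    if qi.size == 0:
        return []
    qp, tp = qpos[qi], tpos[ti]
    diag = tp - qp
    order = np.lexsort((qp, diag))
    qp, tp, diag = qp[order], tp[order], diag[order]
    # merge runs of consecutive shared unique k-mers on the same diagonal
    brk = np.flatnonzero((np.diff(diag) != 0) | (np.diff(qp) != 1))
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk, [qp.size - 1]])
    anchors = [
        Anchor(int(qp[s]), int(tp[s]), int(qp[e] - qp[s] + k))
        for s, e in zip(starts, ends)
    ]
    anchors.sort(key=lambda a: (a.qpos, a.tpos))
    return anchors


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def chain_anchors(anchors: list[Anchor]) -> list[Anchor]:
    """Highest-total-aligned-length colinear anchor chain.

    Weighted longest-increasing-subsequence over anchors strictly increasing
    in both coordinates; ties broken by smaller total gap span, then by
    leftmost query coordinate.  Adjacent chained anchors may overlap by a few
    bases when indels fall within k bp of each other (their maximal exact
    matches sit on shifted diagonals); such overlaps are trimmed from the
    front of the later anchor, so the returned chain is always strictly
    non-overlapping, and on overlap-free input it is exactly the maximal
    non-overlapping subset.
    """
    if not anchors:
        return []
    a = sorted(anchors, key=lambda x: (x.qpos, x.tpos))
    n = len(a)
    qs = np.array([x.qpos for x in a], dtype=np.int64)
    ts = np.array([x.tpos for x in a], dtype=np.int64)
    ln = np.array([x.length for x in a], dtype=np.int64)
    qe, te = qs + ln, ts + ln
    score = ln.copy()
    gap = np.zeros(n, dtype=np.int64)   # total gap span of best chain ending here
    prev = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        overlap = np.maximum(
            0, np.maximum(qe[:i] - qs[i], te[:i] - ts[i])
        )
        ok = np.flatnonzero(
            (qs[:i] < qs[i]) & (ts[:i] < ts[i])
            & (qe[:i] < qe[i]) & (te[:i] < te[i])
            & (overlap < ln[i])
        )
        if ok.size == 0:
            continue
        cand_score = score[ok] + ln[i] - overlap[ok]
        cand_gap = gap[ok] + np.maximum(0, qs[i] - qe[ok]) \
            + np.maximum(0, ts[i] - te[ok])
        # maximize score, then minimize gap, then leftmost predecessor
        best = np.lexsort((ok, cand_gap, -cand_score))[0]
        if cand_score[best] > score[i] or (
            cand_score[best] == score[i] and cand_gap[best] < gap[i]
        ):
            score[i] = cand_score[best]
            gap[i] = cand_gap[best]
            prev[i] = ok[best]
    end = int(np.lexsort((qs, gap, -score))[0])
    idx = []
    while end != -1:
        idx.append(end)
        end = int(prev[end])
    idx.reverse()
    chain: list[Anchor] = []
    for j in idx:
        q, t, l = int(qs[j]), int(ts[j]), int(ln[j])
        if chain:
            last = chain[-1]
            o = max(0, last.qpos + last.length - q,
                    last.tpos + last.length - t)
            q, t, l = q + o, t + o, l - o
        chain.append(Anchor(q, t, l))
    return chain


# ---------------------------------------------------------------------------
# banded affine gap alignment
# ---------------------------------------------------------------------------

def banded_global_align(a: str, b: str, band: int = DEFAULT_BAND) -> tuple[str, int]:
    """Global Gotoh alignment of two short sequences within a band.

    Returns (transcript, score); transcript ops are '=' match, 'X' mismatch,
    'I' base present only in ``a``, 'D' base present only in ``b``.  The band
    is widened automatically to cover the length difference.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return "D" * lb, (GAP_OPEN + GAP_EXTEND * (lb - 1) if lb else 0)
    if lb == 0:
        return "I" * la, GAP_OPEN + GAP_EXTEND * (la - 1)
    band = max(band, abs(lb - la) + 1)
    lo = min(0, lb - la) - band          # j - i ranges over [lo, hi]
    hi = max(0, lb - la) + band
    width = hi - lo + 1
    acode = np.frombuffer(a.encode(), dtype=np.uint8)
    bcode = np.frombuffer(b.encode(), dtype=np.uint8)

    # rolling score rows (column index c encodes diagonal j - i - lo);
    # only the int8 pointer matrices are kept for traceback
    ptr = np.zeros((la + 1, width), dtype=np.int8)      # 1=diag 2=E 3=F
    pE = np.zeros((la + 1, width), dtype=np.int8)       # 1 = gap extends left
    pF = np.zeros((la + 1, width), dtype=np.int8)       # 1 = gap extends up

    H = np.full(width, _NEG, dtype=np.int64)
    F = np.full(width, _NEG, dtype=np.int64)
    j0 = np.arange(width) + lo           # j values of row 0
    row0 = (j0 >= 0) & (j0 <= lb)
    H[row0] = np.where(j0[row0] == 0, 0,
                       GAP_OPEN + GAP_EXTEND * (j0[row0] - 1))
    ptr[0, row0 & (j0 > 0)] = 2
    pE[0, row0 & (j0 > 1)] = 1

    neg_half = _NEG // 2
    for i in range(1, la + 1):
        jr = np.arange(width) + i + lo   # j value at each column of row i
        valid = (jr >= 0) & (jr <= lb)
        diag_ok = valid & (jr >= 1)
        # match/mismatch from the previous row, same column index
        sub = np.full(width, _NEG, dtype=np.int64)
        jm1 = np.where(diag_ok, jr - 1, 0)
        sub[diag_ok] = np.where(bcode[jm1[diag_ok]] == acode[i - 1],
                                MATCH, MISMATCH)
        M = np.where(diag_ok & (H > neg_half), H + sub, _NEG)
        # vertical gap (consumes a): from (i-1, j) = column c+1 of prev row
        H_up = np.concatenate([H[1:], [_NEG]])
        F_up = np.concatenate([F[1:], [_NEG]])
        F = np.maximum(H_up + GAP_OPEN, F_up + GAP_EXTEND)
        F[~valid | (np.maximum(H_up, F_up) < neg_half)] = _NEG
        pF[i] = np.where((F > neg_half) & (F_up + GAP_EXTEND >= H_up + GAP_OPEN),
                         1, 0)
        # horizontal gap (consumes b): same-row prefix scan.  A gap is never
        # re-opened directly after another horizontal gap when GAP_OPEN <
        # GAP_EXTEND, so the scan over max(M, F) is exact.
        G = np.maximum(M, F)
        X = np.where(G > neg_half, G - GAP_EXTEND * jr, _NEG)
        P = np.maximum.accumulate(X)
        E = np.full(width, _NEG, dtype=np.int64)
        E[1:] = np.where(P[:-1] > neg_half,
                         P[:-1] + (GAP_OPEN - GAP_EXTEND) + GAP_EXTEND * jr[1:],
                         _NEG)
        E[~valid | (jr < 1)] = _NEG
        H = np.maximum(np.maximum(M, E), F)
        H[~valid] = _NEG
        ptr[i] = np.where(H <= neg_half, 0,
                          np.where(H == M, 1, np.where(H == E, 2, 3)))
        pE[i, 1:] = np.where((E[1:] > neg_half)
                             & (E[1:] == E[:-1] + GAP_EXTEND), 1, 0)

    i, j = la, lb
    score = int(H[j - i - lo])
    if score <= neg_half:
        raise InternalConsistencyError("banded alignment did not reach the end")

    def col(i: int, j: int) -> int:
        return j - i - lo
    ops: list[str] = []
    state = 0  # 0: follow ptr, 2: inside E gap, 3: inside F gap
    while i > 0 or j > 0:
        c = col(i, j)
        s = state or int(ptr[i, c])
        if s == 1:
            ops.append("=" if a[i - 1] == b[j - 1] else "X")
            i, j = i - 1, j - 1
            state = 0
        elif s == 2:
            ops.append("D")
            state = 2 if pE[i, c] else 0
            j -= 1
        else:
            ops.append("I")
            state = 3 if pF[i, c] else 0
            i -= 1
    return "".join(ops[::-1]), score


# ---------------------------------------------------------------------------
# chained alignment assembly
# ---------------------------------------------------------------------------

@dataclass
class AlignmentChain:
    """A complete alignment of one contig pair.

    ``pieces`` is an ordered list of (kind, qlen, tlen, transcript) where kind
    is 'anchor' (transcript all '='), 'gap' (banded alignment transcript) or
    'excluded' (gap above the cap: structurally divergent, no transcript).
    """

    query_name: str
    target_name: str
    query_length: int
    target_length: int
    pieces: list[tuple[str, int, int, str | None]] = field(default_factory=list)
    anchors: list[Anchor] = field(default_factory=list)
    score: int = 0

    @property
    def structurally_divergent(self) -> bool:
        return any(kind == "excluded" for kind, *_ in self.pieces)

    @property
    def transcript(self) -> str:
        """Concatenated transcript (excluded regions contribute nothing)."""
        return "".join(t for _, _, _, t in self.pieces if t is not None)

    def check(self) -> None:
        q = sum(ql for _, ql, _, _ in self.pieces)
        t = sum(tl for _, _, tl, _ in self.pieces)
        if q != self.query_length or t != self.target_length:
            raise InternalConsistencyError(
                f"alignment consumes {q}/{t} of {self.query_length}/"
                f"{self.target_length} bases"
            )
        for kind, ql, tl, tr in self.pieces:
            if tr is None:
                continue
            nq = sum(1 for o in tr if o in "=XI")
            nt = sum(1 for o in tr if o in "=XD")
            if nq != ql or nt != tl:
                raise InternalConsistencyError("transcript/sequence length mismatch")


def align_gaps(
    query: str,
    target: str,
    chain: list[Anchor],
    band: int = DEFAULT_BAND,
    gap_cap: int = DEFAULT_GAP_CAP,
    query_name: str = "query",
    target_name: str = "target",
) -> AlignmentChain:
    """Fill the inter-anchor gaps (and the unanchored ends) of a chain with
    banded global alignments.  Gaps longer than ``gap_cap`` on either side are
    flagged structurally divergent and excluded from variant calling."""
    out = AlignmentChain(query_name, target_name, len(query), len(target),
                         anchors=list(chain))
    pq = pt = 0
    bounds = [(a.qpos, a.tpos, a.length) for a in chain]
    bounds.append((len(query), len(target), 0))
    score = 0
    for qs, ts, ln in bounds:
        gq, gt = query[pq:qs], target[pt:ts]
        if gq or gt:
            if max(len(gq), len(gt)) > gap_cap:
                out.pieces.append(("excluded", len(gq), len(gt), None))
            else:
                tr, sc = banded_global_align(gq, gt, band=band)
                out.pieces.append(("gap", len(gq), len(gt), tr))
                score += sc
        if ln:
            out.pieces.append(("anchor", ln, ln, "=" * ln))
            score += MATCH * ln
        pq, pt = qs + ln, ts + ln
    out.score = score
    out.check()
    return out


def align_pair(query: str, target: str, k: int = DEFAULT_K,
               band: int = DEFAULT_BAND, gap_cap: int = DEFAULT_GAP_CAP,
               query_name: str = "query", target_name: str = "target",
               ) -> AlignmentChain | None:
    """Anchor, chain and gap-align one contig pair; None if unanchorable."""
    chain = chain_anchors(find_anchors(query, target, k=k))
    if not chain:
        return None
    return align_gaps(query, target, chain, band=band, gap_cap=gap_cap,
                      query_name=query_name, target_name=target_name)


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

@dataclass
class VariantCall:
    """One difference between the assemblies, located on the query assembly.

    ``position`` is 0-based on the query contig (for deletions: the query
    base immediately following the deleted reference base).  ``ref`` is the
    reference-assembly allele ('-' for insertions), ``alt`` the query allele
    ('-' for deletions).  Compartment comes from the query annotation.
    """

    contig: str
    position: int
    variant_class: str  # SNP | insertion | deletion
    ref: str
    alt: str
    compartment: str    # CDS | nCDS


def call_variants(
    chain: AlignmentChain,
    query_genome: AnnotatedGenome,
    ref_seq: str,
    query_contig: str,
) -> list[VariantCall]:
    """Walk a complete alignment and emit variant calls.

    Each mismatch column is one SNP; each of the r columns of a gap run is
    one single-nucleotide insertion or deletion event.  Columns containing an
    ambiguous base (N) never produce calls.  Alignment orientation: the chain
    aligned ``ref_seq`` (first/anchoring side) to the query contig sequence.
    """
    qseq = query_genome.contigs[query_contig]
    calls: list[VariantCall] = []
    rp = qp = 0  # reference / query coordinates
    for kind, rlen, qlen, tr in chain.pieces:
        if tr is None:  # excluded region: no calls
            rp += rlen
            qp += qlen
            continue
        for op in tr:
            if op == "=":
                rp += 1
                qp += 1
            elif op == "X":
                rb, qb = ref_seq[rp], qseq[qp]
                if rb != "N" and qb != "N":
                    calls.append(VariantCall(
                        query_contig, qp, "SNP", rb, qb,
                        "CDS" if query_genome.in_cds(query_contig, qp)[0] else "nCDS",
                    ))
                rp += 1
                qp += 1
            elif op == "I":  # base only in reference: deleted from the query
                rb = ref_seq[rp]
                if rb != "N":
                    cpos = min(qp, len(qseq) - 1) if qseq else 0
                    calls.append(VariantCall(
                        query_contig, qp, "deletion", rb, "-",
                        "CDS" if query_genome.in_cds(query_contig, cpos)[0] else "nCDS",
                    ))
                rp += 1
            else:  # 'D': base only in the query: insertion
                qb = qseq[qp]
                if qb != "N":
                    calls.append(VariantCall(
                        query_contig, qp, "insertion", "-", qb,
                        "CDS" if query_genome.in_cds(query_contig, qp)[0] else "nCDS",
                    ))
                qp += 1
    calls.sort(key=lambda v: (v.contig, v.position, v.variant_class, v.alt))
    return calls


# ---------------------------------------------------------------------------
# whole-assembly comparison
# ---------------------------------------------------------------------------

def rate_per_100kbp(count: int, denominator_bp: int) -> float:
    """Events per 100 kbp (full precision; rounding happens at reporting)."""
    if denominator_bp <= 0:
        raise UndefinedRateError("rate denominator must be positive")
    if count < 0:
        raise ConfigurationError("count must be >= 0")
    return 100_000.0 * count / denominator_bp


@dataclass
class PairwiseComparison:
    """Directed variant counts and per-100-kbp rates between two assemblies.

    Rates use the query assembly's total/CDS/nCDS lengths as denominators.
    ``aligned`` is False when no contig pair could be anchored (an explicit
    no-alignment result, distinct from an all-zero comparison).
    """

    reference_id: str
    query_id: str
    aligned: bool = True
    total_snps: int = 0
    total_indels: int = 0
    snps_cds: int = 0
    snps_ncds: int = 0
    indels_cds: int = 0
    indels_ncds: int = 0
    snps_per_100kbp: float = 0.0
    indels_per_100kbp: float = 0.0
    snps_cds_per_100kbp: float = 0.0
    snps_ncds_per_100kbp: float = 0.0
    indels_cds_per_100kbp: float = 0.0
    indels_ncds_per_100kbp: float = 0.0
    structurally_divergent: bool = False
    variants: list[VariantCall] = field(default_factory=list)

    def check(self) -> None:
        if self.snps_cds + self.snps_ncds != self.total_snps:
            raise InternalConsistencyError("SNP compartment counts do not sum")
        if self.indels_cds + self.indels_ncds != self.total_indels:
            raise InternalConsistencyError("indel compartment counts do not sum")


def comparison_from_counts(
    reference_id: str,
    query_id: str,
    query_total_bp: int,
    query_cds_bp: int,
    query_ncds_bp: int,
    total_snps: int,
    total_indels: int,
    snps_cds: int,
    indels_cds: int,
) -> PairwiseComparison:
    """Build a comparison from externally tabulated counts and lengths
    (total = CDS + nCDS per compartment conservation)."""
    cmp_ = PairwiseComparison(
        reference_id=reference_id, query_id=query_id,
        total_snps=total_snps, total_indels=total_indels,
        snps_cds=snps_cds, snps_ncds=total_snps - snps_cds,
        indels_cds=indels_cds, indels_ncds=total_indels - indels_cds,
        snps_per_100kbp=rate_per_100kbp(total_snps, query_total_bp),
        indels_per_100kbp=rate_per_100kbp(total_indels, query_total_bp),
        snps_cds_per_100kbp=rate_per_100kbp(snps_cds, query_cds_bp),
        snps_ncds_per_100kbp=rate_per_100kbp(total_snps - snps_cds, query_ncds_bp),
        indels_cds_per_100kbp=rate_per_100kbp(indels_cds, query_cds_bp),
        indels_ncds_per_100kbp=rate_per_100kbp(total_indels - indels_cds,
                                               query_ncds_bp),
    )
    cmp_.check()
    return cmp_


def _pair_contigs(
    reference: AnnotatedGenome, query: AnnotatedGenome, k: int
) -> list[tuple[str, str]]:
    """Best-reciprocal contig matching by shared unique k-mer counts."""
    rnames = list(reference.contigs)
    qnames = list(query.contigs)
    if len(rnames) == 1 and len(qnames) == 1:
        return [(rnames[0], qnames[0])]
    rsets = {n: _unique_kmers(reference.contigs[n], k)[0] for n in rnames}
    qsets = {n: _unique_kmers(query.contigs[n], k)[0] for n in qnames}
    shared = []
    for rn in rnames:
        for qn in qnames:
            s = np.intersect1d(rsets[rn], qsets[qn], assume_unique=True).size
            if s > 0:
                shared.append((s, rn, qn))
    shared.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_r: set[str] = set()
    used_q: set[str] = set()
    pairs = []
    for _, rn, qn in shared:
        if rn in used_r or qn in used_q:
            continue
        pairs.append((rn, qn))
        used_r.add(rn)
        used_q.add(qn)
    return pairs


def compare_pair(
    reference: AnnotatedGenome,
    query: AnnotatedGenome,
    k: int = DEFAULT_K,
    band: int = DEFAULT_BAND,
    gap_cap: int = DEFAULT_GAP_CAP,
    indel_run_as_one: bool = False,
    keep_variants: bool = True,
) -> PairwiseComparison:
    """Compare two annotated assemblies (one cell block of the
    heterogeneity matrix).

    Aligns best-matching contig pairs, aggregates SNP/indel calls classified
    on the query annotation, and computes the six per-100-kbp rates with the
    query assembly's lengths.  ``indel_run_as_one`` counts a run of r
    consecutive gap columns as one event instead of r (off by default: the
    events analysed here are single-nucleotide indels).
    """
    all_calls: list[VariantCall] = []
    any_chain = False
    divergent = False
    for rname, qname in _pair_contigs(reference, query, k):
        chain = align_pair(
            reference.contigs[rname], query.contigs[qname],
            k=k, band=band, gap_cap=gap_cap,
            query_name=rname, target_name=qname,
        )
        if chain is None:
            continue
        any_chain = True
        divergent |= chain.structurally_divergent
        all_calls.extend(call_variants(chain, query, reference.contigs[rname], qname))
    if not any_chain:
        return PairwiseComparison(reference.name, query.name, aligned=False)

    if indel_run_as_one:
        merged: list[VariantCall] = []
        prev: VariantCall | None = None
        for v in sorted(all_calls,
                        key=lambda v: (v.contig, v.position, v.variant_class)):
            if (prev is not None and v.variant_class in ("insertion", "deletion")
                    and v.variant_class == prev.variant_class
                    and v.contig == prev.contig
                    and v.position - prev.position <= 1):
                prev = v
                continue
            merged.append(v)
            prev = v
        all_calls = merged

    snps = [v for v in all_calls if v.variant_class == "SNP"]
    indels = [v for v in all_calls if v.variant_class != "SNP"]
    snps_cds = sum(1 for v in snps if v.compartment == "CDS")
    indels_cds = sum(1 for v in indels if v.compartment == "CDS")
    out = PairwiseComparison(
        reference_id=reference.name, query_id=query.name,
        total_snps=len(snps), total_indels=len(indels),
        snps_cds=snps_cds, snps_ncds=len(snps) - snps_cds,
        indels_cds=indels_cds, indels_ncds=len(indels) - indels_cds,
        snps_per_100kbp=rate_per_100kbp(len(snps), query.total_length),
        indels_per_100kbp=rate_per_100kbp(len(indels), query.total_length),
        snps_cds_per_100kbp=rate_per_100kbp(snps_cds, query.cds_length),
        snps_ncds_per_100kbp=rate_per_100kbp(len(snps) - snps_cds,
                                             query.ncds_length),
        indels_cds_per_100kbp=rate_per_100kbp(indels_cds, query.cds_length),
        indels_ncds_per_100kbp=rate_per_100kbp(len(indels) - indels_cds,
                                               query.ncds_length),
        structurally_divergent=divergent,
        variants=all_calls if keep_variants else [],
    )
    out.check()
    return out
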