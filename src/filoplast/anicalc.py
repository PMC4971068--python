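"""Fragment-based average nucleotide identity (ANI).

The classic fragment procedure: the query genome is chopped into
consecutive 1,020 bp windows, each fragment is placed at its best location
on the target, and the one-way ANI is the mean percent identity of the
fragments whose best hit passes the 30% identity and 70% alignable-fraction
cutoffs.  Two-way ANI is the arithmetic mean of the two one-way values.
Near-clonal assemblies sit at 99.98-100%.

Placement uses unique-k-mer seeding (as in the pairwise comparison module);
the fragment is then globally aligned against the seeded target window with
edlib, and identity is taken over the aligned columns.  Best hit is the
highest identity x alignable-fraction product, ties resolved to the
leftmost target coordinate.  ANI is averaged per fragment (unweighted);
a trailing window shorter than the fragment length is kept if it is at
least 100 bp.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import edlib
import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, ConfigurationError
from .pairdiff import _unique_kmers

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_SEED_K = 21
_WINDOW_MARGIN = 60


@dataclass
class ANIConfig:
    fragment_length: int = 1020
    min_identity: float = 0.30
    min_alignable_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise ConfigurationError("fragment_length must be >= 100")
        if not 0.0 < self.min_identity <= 1.0:
            raise ConfigurationError("min_identity must be in (0, 1]")
        if not 0.0 < self.min_alignable_fraction <= 1.0:
            raise ConfigurationError("min_alignable_fraction must be in (0, 1]")


class Fragment(NamedTuple):
    contig: str
    start: int
    seq: str


class FragmentHit(NamedTuple):
    identity: float            # percent over the aligned region, 0-100
    alignable_fraction: float  # aligned fragment bases / fragment length
    contig: str | None
    target_start: int


def fragment(genome: AnnotatedGenome, config: ANIConfig | None = None
             ) -> list[Fragment]:
    """Consecutive non-overlapping windows per contig; a trailing window
    shorter than ``fragment_length`` is kept if >= 100 bp."""
    config = config or ANIConfig()
    out: list[Fragment] = []
    for name, seq in genome.contigs.items():
        for start in range(0, len(seq), config.fragment_length):
            piece = seq[start:start + config.fragment_length]
            if len(piece) < config.fragment_length and len(piece) < 100:
                continue
            out.append(Fragment(name, start, piece))
    return out


class TargetIndex:
    """Unique-k-mer lookup over every contig of the target assembly."""

    def __init__(self, genome: AnnotatedGenome, k: int = _SEED_K):
        self.k = k
        self.contigs = genome.contigs
        self.maps: dict[str, dict[int, int]] = {}
        for name, seq in genome.contigs.items():
            codes, pos = _unique_kmers(seq, k)
            self.maps[name] = dict(zip(codes.tolist(), pos.tolist()))


def _cigar_identity(cigar: str) -> tuple[float, int]:
    """Percent identity and total columns from an edlib extended CIGAR."""
    match = cols = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        cols += n
        if op == "=":
            match += n
    return (100.0 * match / cols if cols else 0.0), cols


def best_fragment_hit(
    frag: Fragment | str,
    index: TargetIndex,
    config: ANIConfig | None = None,
) -> FragmentHit:
    """Best placement of one fragment on the indexed target.

    Seeds are the fragment's k-mers that are unique in both fragment and
    target; candidate placements are the most seed-supported diagonals, each
    evaluated by a semi-global edlib alignment of the whole fragment against
    the seeded window.  A fragment with no seed anywhere (e.g. pure N) is
    unalignable: (0, 0).
    """
    seq = frag.seq if isinstance(frag, Fragment) else frag
    flen = len(seq)
    if flen == 0:
        return FragmentHit(0.0, 0.0, None, -1)
    fcodes, fpos = _unique_kmers(seq, index.k)
    candidates: list[tuple[str, int, int]] = []  # (contig, offset, support)
    for cname, kmap in index.maps.items():
        offsets = Counter()
        for code, qp in zip(fcodes.tolist(), fpos.tolist()):
            tp = kmap.get(code)
            if tp is not None:
                offsets[tp - qp] += 1
        for off, support in offsets.most_common(3):
            candidates.append((cname, off, support))
    if not candidates:
        return FragmentHit(0.0, 0.0, None, -1)
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    best: FragmentHit | None = None
    for cname, off, _ in candidates[:3]:
        tseq = index.contigs[cname]
        lo = max(0, off - _WINDOW_MARGIN)
        hi = min(len(tseq), off + flen + _WINDOW_MARGIN)
        window = tseq[lo:hi]
        if not window:
            continue
        res = edlib.align(seq, window, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        ident, _ = _cigar_identity(res["cigar"])
        start = lo + res["locations"][0][0]
        hit = FragmentHit(ident, 1.0, cname, start)
        if best is None or (hit.identity * hit.alignable_fraction,
                            -hit.target_start) > (
                best.identity * best.alignable_fraction, -best.target_start):
            best = hit
    return best if best is not None else FragmentHit(0.0, 0.0, None, -1)


@dataclass
class ANIResult:
    """One-way and two-way ANI between two assemblies (percent)."""

    a_id: str
    b_id: str
    one_way_ani_ab: float | None
    one_way_ani_ba: float | None
    two_way_ani: float | None
    n_fragments_total_ab: int
    n_fragments_retained_ab: int
    n_fragments_total_ba: int
    n_fragments_retained_ba: int
    diagnostic: str = ""


def _one_way(a: AnnotatedGenome, index_b: TargetIndex, config: ANIConfig
             ) -> tuple[float | None, int, int]:
    frags = fragment(a, config)
    identities = []
    for fr in frags:
        hit = best_fragment_hit(fr, index_b, config)
        if (hit.identity >= 100.0 * config.min_identity
                and hit.alignable_fraction >= config.min_alignable_fraction):
            identities.append(hit.identity)
    if not identities:
        return None, len(frags), 0
    return float(np.mean(identities)), len(frags), len(identities)


def compute_ani(
    a: AnnotatedGenome,
    b: AnnotatedGenome,
    config: ANIConfig | None = None,
    index_a: TargetIndex | None = None,
    index_b: TargetIndex | None = None,
) -> ANIResult:
    """Two-way fragment ANI between assemblies ``a`` and ``b``.

    Pre-built :class:`TargetIndex` objects may be passed to amortise
    indexing over many pairs.  If one direction retains no fragments the
    two-way value is undefined (None) with a diagnostic.
    """
    config = config or ANIConfig()
    index_b = index_b or TargetIndex(b)
    index_a = index_a or TargetIndex(a)
    ab, tot_ab, kept_ab = _one_way(a, index_b, config)
    ba, tot_ba, kept_ba = _one_way(b, index_a, config)
    diag = ""
    if ab is None or ba is None:
        missing = []
        if ab is None:
            missing.append(f"{a.name}->{b.name}")
        if ba is None:
            missing.append(f"{b.name}->{a.name}")
        diag = ("no fragments passed the identity/alignable-fraction cutoffs "
                "in direction(s): " + ", ".join(missing))
        two = None
    else:
        two = (ab + ba) / 2.0
    return ANIResult(a.name, b.name, ab, ba, two,
                     tot_ab, kept_ab, tot_ba, kept_ba, diag)


def ani_matrix(
    genomes: dict[str, AnnotatedGenome],
    config: ANIConfig | None = None,
) -> pd.DataFrame:
    """Symmetric two-way ANI matrix over a set of assemblies."""
    config = config or ANIConfig()
    names = list(genomes)
    indexes = {n: TargetIndex(genomes[n]) for n in names}
    mat = pd.DataFrame(np.full((len(names), len(names)), np.nan),
                       index=names, columns=names)
    for n in names:
        mat.loc[n, n] = 100.0
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            r = compute_ani(genomes[na], genomes[nb], config,
                            index_a=indexes[na], index_b=indexes[nb])
            val = np.nan if r.two_way_ani is None else r.two_way_ani
            mat.loc[na, nb] = val
            mat.loc[nb, na] = val
    return mat
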