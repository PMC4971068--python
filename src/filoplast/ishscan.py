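"""Intrasegmental sequence heterogeneity (ISH) calling and co-localization.

Each filament segment's read library, mapped to one common framework
assembly, yields a per-position pileup of allele counts.  In a polyploid,
multicellular segment, positions where a non-consensus allele reaches an
appreciable read frequency reflect heterogeneity among the many genome
copies.  Following the conservative thresholds appropriate for
MDA-amplified Illumina libraries, an ISH event is called where coverage is
at least 100 and a non-consensus allele reaches a variety frequency of at
least 0.25 (both configurable; the coverage floor is never allowed below
31, under which read heterogeneity is not robust).

No strand-bias, base-quality or mapping-quality filters are applied: the
calls reproduce the two stated thresholds only.  Real-data users should
pre-filter their pileups accordingly.

Pileup dialect: tab-separated ``contig pos ref depth countA countC countG
countT countIns countDel`` with 1-based positions and '#' comment lines.
From a sorted BAM it can be produced with standard tooling, e.g.::

    samtools mpileup -aa -f ref.fa -Q 13 sorted.bam | <count alleles per column>

(the allele-count conversion itself is out of scope; any script tabulating
mpileup base strings into the six count columns will do).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .genome import (
    ConfigurationError,
    MalformedPileupError,
    PileupOrderError,
)
from .sim import PILEUP_COLUMNS

BASE_COLS = ["countA", "countC", "countG", "countT"]
BASE_ORDER = "ACGT"  # tie-break order for the consensus (lexicographic)


@dataclass
class ISHConfig:
    """Thresholds of the ISH caller."""

    min_coverage: int = 100
    min_variant_frequency: float = 0.25
    count_indels: bool = True

    def __post_init__(self) -> None:
        if self.min_coverage < 31:
            raise ConfigurationError(
                "min_coverage below 31 is not robust for read heterogeneity"
            )
        if not 0.0 < self.min_variant_frequency <= 0.5:
            raise ConfigurationError(
                "min_variant_frequency must be in (0, 0.5]"
            )


@dataclass
class PileupColumn:
    """Validated per-position allele counts (0-based position)."""

    contig: str
    position: int
    ref: str
    coverage: int
    count_a: int
    count_c: int
    count_g: int
    count_t: int
    count_ins: int
    count_del: int


@dataclass
class ISHEvent:
    """One variant allele exceeding the thresholds at one position."""

    segment: int | str
    contig: str
    position: int           # 0-based framework coordinate
    event_class: str        # SNV | insertion | deletion
    consensus_allele: str
    variant_allele: str     # base, or '+'/'-' for indels
    frequency: float
    coverage: int

    @property
    def site_key(self) -> tuple:
        return (self.contig, self.position, self.event_class,
                self.variant_allele)


# ---------------------------------------------------------------------------
# pileup reading
# ---------------------------------------------------------------------------

def read_pileup_table(path: str | Path) -> pd.DataFrame:
    """Read a pileup TSV into a validated frame with 0-based positions."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=PILEUP_COLUMNS)
    if df.empty:
        return df
    df["pos"] = df["pos"].astype(np.int64) - 1
    base_sum = df[BASE_COLS].sum(axis=1).to_numpy()
    depth = df["depth"].to_numpy()
    bad = np.flatnonzero(base_sum != depth)
    if bad.size:
        raise MalformedPileupError(
            f"{path}: record {bad[0] + 1}: depth {depth[bad[0]]} != "
            f"allele sum {base_sum[bad[0]]}"
        )
    if ((df["countIns"] > df["depth"]) | (df["countDel"] > df["depth"])).any():
        raise MalformedPileupError(f"{path}: indel count exceeds depth")
    if (df[PILEUP_COLUMNS[3:]] < 0).any().any():
        raise MalformedPileupError(f"{path}: negative count")
    for contig, grp in df.groupby("contig", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise PileupOrderError(
                f"{path}: positions out of order on contig {contig!r}"
            )
    return df


def read_pileup(path: str | Path) -> Iterator[PileupColumn]:
    """Stream validated pileup columns (converted to 0-based positions)."""
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(PILEUP_COLUMNS):
                raise MalformedPileupError(
                    f"{path}: line {lineno}: expected "
                    f"{len(PILEUP_COLUMNS)} fields, got {len(fields)}"
                )
            contig, pos, ref = fields[0], int(fields[1]) - 1, fields[2]
            depth, a, c, g, t, ins, dele = (int(x) for x in fields[3:])
            if a + c + g + t != depth:
                raise MalformedPileupError(
                    f"{path}: line {lineno}: depth {depth} != allele sum "
                    f"{a + c + g + t}"
                )
            if ins > depth or dele > depth or min(a, c, g, t, ins, dele) < 0:
                raise MalformedPileupError(
                    f"{path}: line {lineno}: invalid counts"
                )
            if contig in last and pos <= last[contig]:
                raise PileupOrderError(
                    f"{path}: line {lineno}: position not increasing on "
                    f"{contig!r}"
                )
            last[contig] = pos
            yield PileupColumn(contig, pos, ref, depth, a, c, g, t, ins, dele)


def _columns_to_frame(columns: Iterable[PileupColumn]) -> pd.DataFrame:
    rows = [
        (c.contig, c.position, c.ref, c.coverage, c.count_a, c.count_c,
         c.count_g, c.count_t, c.count_ins, c.count_del)
        for c in columns
    ]
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


# ---------------------------------------------------------------------------
# ISH calling
# ---------------------------------------------------------------------------

def call_ish(
    columns: Iterable[PileupColumn] | pd.DataFrame,
    config: ISHConfig | None = None,
    segment: int | str = 0,
) -> list[ISHEvent]:
    """Call ISH events from a pileup.

    For every column with coverage >= ``min_coverage``, the consensus is the
    majority base (ties broken alphabetically) and every non-consensus
    allele — the three other bases, plus the insertion and deletion counts if
    ``count_indels`` — whose count/coverage reaches
    ``min_variant_frequency`` yields one event.  Accepts either a stream of
    :class:`PileupColumn` or a pileup frame (vectorised fast path).
    """
    config = config or ISHConfig()
    df = columns if isinstance(columns, pd.DataFrame) else _columns_to_frame(columns)
    if df.empty:
        return []
    keep = df["depth"].to_numpy() >= config.min_coverage
    df = df.loc[keep]
    if df.empty:
        return []
    counts = df[BASE_COLS].to_numpy(dtype=np.int64)
    cov = df["depth"].to_numpy(dtype=np.int64)
    cons_idx = counts.argmax(axis=1)  # argmax takes the first maximum: A<C<G<T
    contigs = df["contig"].to_numpy()
    positions = df["pos"].to_numpy()
    events: list[ISHEvent] = []
    thr = config.min_variant_frequency
    for b in range(4):
        freq = counts[:, b] / cov
        hit = np.flatnonzero((cons_idx != b) & (freq >= thr))
        for i in hit:
            events.append(ISHEvent(
                segment, str(contigs[i]), int(positions[i]), "SNV",
                BASE_ORDER[cons_idx[i]], BASE_ORDER[b],
                float(freq[i]), int(cov[i]),
            ))
    if config.count_indels:
        for col, klass, allele in (("countIns", "insertion", "+"),
                                   ("countDel", "deletion", "-")):
            c = df[col].to_numpy(dtype=np.int64)
            freq = c / cov
            hit = np.flatnonzero(freq >= thr)
            for i in hit:
                events.append(ISHEvent(
                    segment, str(contigs[i]), int(positions[i]), klass,
                    BASE_ORDER[cons_idx[i]], allele,
                    float(freq[i]), int(cov[i]),
                ))
    events.sort(key=lambda e: (e.contig, e.position, e.event_class,
                               e.variant_allele))
    return events


# ---------------------------------------------------------------------------
# co-localization across segments
# ---------------------------------------------------------------------------

@dataclass
class CoLocalizationSummary:
    """Recurrence of ISH sites across the segment libraries.

    A site is keyed by (contig, position, event class, variant allele);
    insertions are keyed by position only (the pileup dialect stores a
    count, not the inserted sequence).  ``fraction_colocalized`` is the
    shared-by-all site count over the mean per-segment distinct site count,
    the convention that makes a planted co-localized fraction recoverable;
    the fraction of *distinct* sites shared, and the looser present-in->=2
    count, are reported alongside.
    """

    segments: list
    n_events_per_segment: dict
    n_sites_per_segment: dict
    n_distinct_sites: int
    n_sites_shared_by_all: int
    n_sites_shared_by_2plus: int
    fraction_colocalized: float
    fraction_not_colocalized: float
    fraction_distinct_sites_shared_by_all: float
    presence: pd.DataFrame = field(repr=False, default=None)


def colocalize(
    events_by_segment: Mapping[int | str, list[ISHEvent]],
) -> CoLocalizationSummary:
    """Cross-tabulate ISH sites over segments (all on framework coordinates).

    Segments with zero events are allowed and counted in the denominators.
    Output ordering is deterministic (sites sorted by key).
    """
    segments = list(events_by_segment)
    site_sets: dict[int | str, set] = {
        seg: {e.site_key for e in evts} for seg, evts in events_by_segment.items()
    }
    all_sites = sorted(set().union(*site_sets.values())) if site_sets else []
    presence = pd.DataFrame(
        [[int(key in site_sets[seg]) for seg in segments] for key in all_sites],
        columns=segments,
        index=pd.MultiIndex.from_tuples(
            all_sites, names=["contig", "position", "event_class", "allele"],
        ) if all_sites else None,
    )
    n_seg = len(segments)
    row_sums = presence.sum(axis=1).to_numpy() if all_sites else np.zeros(0)
    shared_all = int((row_sums == n_seg).sum()) if n_seg else 0
    shared_2 = int((row_sums >= 2).sum())
    n_sites = {seg: len(site_sets[seg]) for seg in segments}
    mean_sites = float(np.mean(list(n_sites.values()))) if segments else 0.0
    frac = shared_all / mean_sites if mean_sites > 0 else 0.0
    return CoLocalizationSummary(
        segments=segments,
        n_events_per_segment={s: len(e) for s, e in events_by_segment.items()},
        n_sites_per_segment=n_sites,
        n_distinct_sites=len(all_sites),
        n_sites_shared_by_all=shared_all,
        n_sites_shared_by_2plus=shared_2,
        fraction_colocalized=frac,
        fraction_not_colocalized=1.0 - frac,
        fraction_distinct_sites_shared_by_all=(
            shared_all / len(all_sites) if all_sites else 0.0
        ),
        presence=presence,
    )


# ---------------------------------------------------------------------------
# intra- vs inter-segment contrast
# ---------------------------------------------------------------------------

@dataclass
class IntraInterReport:
    """Within-segment (ISH) vs between-segment (consensus SNP) variation."""

    empty: bool
    mean_ish_events_per_segment: float = float("nan")
    mean_pairwise_snps: float = float("nan")
    ratio: float = float("nan")
    n_segments: int = 0
    n_comparisons: int = 0


def intra_vs_inter(
    events_by_segment: Mapping[int | str, list[ISHEvent]],
    comparisons: Iterable,
    subset: set | None = None,
) -> IntraInterReport:
    """Mean ISH events per segment vs mean pairwise consensus SNP count.

    ``subset`` restricts both sides to the named segments (e.g. the four
    well-assembled ones); comparisons must expose reference_id/query_id/
    total_snps and are used off-diagonal only.
    """
    ish_counts = [
        len(evts) for seg, evts in events_by_segment.items()
        if subset is None or seg in subset
    ]
    pair_snps = []
    for c in comparisons:
        if c.reference_id == c.query_id or not getattr(c, "aligned", True):
            continue
        if subset is not None and (
            c.reference_id not in subset or c.query_id not in subset
        ):
            continue
        pair_snps.append(c.total_snps)
    if not ish_counts or not pair_snps:
        return IntraInterReport(empty=True)
    mean_ish = float(np.mean(ish_counts))
    mean_snp = float(np.mean(pair_snps))
    return IntraInterReport(
        empty=False,
        mean_ish_events_per_segment=mean_ish,
        mean_pairwise_snps=mean_snp,
        ratio=mean_ish / mean_snp if mean_snp > 0 else float("inf"),
        n_segments=len(ish_counts),
        n_comparisons=len(pair_snps),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def events_frame(events: list[ISHEvent]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in events])


def write_events(events: list[ISHEvent], path: str | Path) -> None:
    events_frame(events).to_csv(path, sep="\t", index=False)


def write_site_matrix(summary: CoLocalizationSummary, path: str | Path) -> None:
    summary.presence.to_csv(path, sep="\t")
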