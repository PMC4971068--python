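"""Synthetic clonal-filament data generator.

Emulates the study design the analysis modules assume: a single bacterial
filament of ``n_segments`` consecutive multicellular segments, each segment
sequenced independently.  The generator produces

* a random annotated reference genome (~88% coding by default),
* per-segment consensus assemblies that differ from the reference by
  compartment-specific substitution and single-nucleotide indel rates,
* per-segment read pileups over the reference used as the common framework
  sequence, carrying intrasegmental sequence heterogeneity (ISH) — sites where
  a variant allele segregates among the many genome copies of the polyploid
  cells — plus uniform sequencing error,
* exact ground-truth tables for recovery tests.

All randomness flows from ``SimulationConfig.seed`` through fixed per-purpose
sub-streams, so every output is byte-identical across runs with the same
configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, ConfigurationError, CoordinateError

BASES = np.array(["A", "C", "G", "T"])
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# sub-stream tags (mixed with the user seed so segment streams never collide)
_STREAM_REFERENCE = 11
_STREAM_MUTATE = 101
_STREAM_ISH = 202
_STREAM_PILEUP = 303

#: pileup TSV dialect written/read by the package
PILEUP_COLUMNS = [
    "contig", "pos", "ref", "depth",
    "countA", "countC", "countG", "countT", "countIns", "countDel",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic filament.

    Rates are expected events per bp; defaults follow the regime of a
    ~3.2 Mbp, ~88%-coding genome whose segment consensuses differ by a few
    SNPs per 100 kbp (higher in non-coding regions), with a few thousand ISH
    sites per segment, a third of them recurring across all segments.
    """

    genome_length: int = 3_200_000
    gc_fraction: float = 0.40
    coding_fraction_target: float = 0.88
    n_segments: int = 6
    snp_rate_cds: float = 3.6e-5
    snp_rate_ncds: float = 8.5e-5
    indel_rate_cds: float = 2.0e-6
    indel_rate_ncds: float = 3.9e-5
    ish_site_rate: float = 7.0e-4
    ish_freq_low: float = 0.25
    ish_freq_high: float = 0.50
    ish_indel_fraction: float = 0.20
    colocalized_fraction: float = 1.0 / 3.0
    coverage_mean: float = 380.0
    seq_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self
        if c.genome_length < 10_000:
            raise ConfigurationError("genome_length must be >= 10,000 bp")
        if not 0.0 <= c.gc_fraction <= 1.0:
            raise ConfigurationError("gc_fraction must be in [0, 1]")
        if not 0.0 < c.coding_fraction_target < 1.0:
            raise ConfigurationError(
                "coding_fraction_target must be in the open interval (0, 1)"
            )
        if c.n_segments < 1:
            raise ConfigurationError("n_segments must be >= 1")
        for name in ("snp_rate_cds", "snp_rate_ncds", "indel_rate_cds",
                     "indel_rate_ncds", "ish_site_rate"):
            if getattr(c, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        # downstream anchoring assumes near-clonality
        if max(c.snp_rate_cds + c.indel_rate_cds,
               c.snp_rate_ncds + c.indel_rate_ncds) > 0.10:
            raise ConfigurationError(
                "consensus divergence rates imply >10% divergence; the "
                "anchored comparison assumes near-clonal assemblies"
            )
        if not 0.0 <= c.colocalized_fraction <= 1.0:
            raise ConfigurationError("colocalized_fraction must be in [0, 1]")
        if not 0.0 <= c.ish_freq_low <= c.ish_freq_high <= 1.0:
            raise ConfigurationError(
                "need 0 <= ish_freq_low <= ish_freq_high <= 1"
            )
        if not 0.0 <= c.ish_indel_fraction <= 1.0:
            raise ConfigurationError("ish_indel_fraction must be in [0, 1]")
        if c.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be > 0")
        if not 0.0 <= c.seq_error_rate <= 1.0:
            raise ConfigurationError("seq_error_rate must be in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown simulation keys: {sorted(bad)}")
        return cls(**d)


@dataclass
class ConsensusVariant:
    """A planted difference between a segment consensus and the reference."""

    segment: int
    contig: str
    position: int            # 0-based reference coordinate
    segment_position: int    # 0-based coordinate on the segment consensus
    ref: str                 # '-' for insertions
    alt: str                 # '-' for deletions
    variant_class: str       # SNP | insertion | deletion
    compartment: str         # CDS | nCDS


@dataclass
class IshSite:
    """A planted intra-segment heterogeneity site (framework coordinates)."""

    segment: int
    contig: str
    position: int       # 0-based framework coordinate
    alt_allele: str     # A/C/G/T for SNVs, '+' insertion, '-' deletion
    frequency: float
    colocalized: bool


@dataclass
class SimTruth:
    """Ground-truth tables for recovery tests."""

    consensus_variants: list[ConsensusVariant] = field(default_factory=list)
    ish_sites: list[IshSite] = field(default_factory=list)

    def consensus_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(v) for v in self.consensus_variants])

    def ish_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.ish_sites])


def _rng(config: SimulationConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *tags])


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def generate_reference(config: SimulationConfig,
                       contig_name: str = "contig_1") -> AnnotatedGenome:
    """Draw a random annotated reference genome.

    The sequence is i.i.d. at the requested GC fraction.  Gene lengths are
    drawn around a typical bacterial ~950 bp and intergenic gaps are split
    multinomially so the coding fraction hits ``coding_fraction_target``
    exactly (well inside the ±0.02 contract).
    """
    config.validate()
    rng = _rng(config, _STREAM_REFERENCE)
    L = int(config.genome_length)
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=L, p=p)
    seq = "".join(BASES[codes])

    target_cds = int(round(config.coding_fraction_target * L))
    lengths: list[int] = []
    total = 0
    while total < target_cds:
        g = int(np.clip(round(rng.normal(950.0, 230.0)), 150, 3000))
        g = min(g, target_cds - total) or 1
        lengths.append(g)
        total += g
    n_genes = len(lengths)
    gap_total = L - target_cds
    gaps = rng.multinomial(gap_total, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    intervals = []
    pos = 0
    for g, gap in zip(lengths, gaps[:-1]):
        pos += int(gap)
        intervals.append((pos, pos + g))
        pos += g
    return AnnotatedGenome(
        contigs={contig_name: seq},
        cds_intervals={contig_name: np.asarray(intervals, dtype=np.int64)},
        name="reference",
    )


# ---------------------------------------------------------------------------
# consensus mutation
# ---------------------------------------------------------------------------

def _compartment_positions(genome: AnnotatedGenome, contig: str):
    L = len(genome.contigs[contig])
    mask = np.zeros(L, dtype=bool)
    for s, e in genome.cds_intervals.get(contig, []):
        mask[s:e] = True
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def mutate_consensus(
    reference: AnnotatedGenome, config: SimulationConfig, segment_id: int
) -> tuple[AnnotatedGenome, list[ConsensusVariant]]:
    """Derive one segment consensus from the reference.

    Substitutions and single-nucleotide indels are drawn independently and
    uniformly within each compartment at the compartment-specific rates.
    Returns the mutated annotated genome (CDS intervals shifted through the
    indels) and the exact truth records, carrying both reference and segment
    coordinates.
    """
    config.validate()
    if not 1 <= segment_id <= config.n_segments:
        raise ConfigurationError(
            f"segment_id {segment_id} outside [1, {config.n_segments}]"
        )
    rng = _rng(config, _STREAM_MUTATE, int(segment_id))
    out_contigs: dict[str, str] = {}
    out_cds: dict[str, np.ndarray] = {}
    truth: list[ConsensusVariant] = []

    for contig, seq in reference.contigs.items():
        cds_pos, ncds_pos = _compartment_positions(reference, contig)
        events: list[tuple[int, str, str]] = []  # (ref position, kind, compartment)
        for pool, compartment, snp_rate, indel_rate in (
            (cds_pos, "CDS", config.snp_rate_cds, config.indel_rate_cds),
            (ncds_pos, "nCDS", config.snp_rate_ncds, config.indel_rate_ncds),
        ):
            n = len(pool)
            n_snp = rng.binomial(n, min(snp_rate, 1.0)) if n else 0
            n_ind = rng.binomial(n, min(indel_rate, 1.0)) if n else 0
            if n_snp + n_ind == 0:
                continue
            chosen = rng.choice(pool, size=n_snp + n_ind, replace=False)
            for pos in chosen[:n_snp]:
                events.append((int(pos), "SNP", compartment))
            for pos in chosen[n_snp:]:
                kind = "insertion" if rng.random() < 0.5 else "deletion"
                events.append((int(pos), kind, compartment))
        events.sort(key=lambda t: t[0])

        parts: list[str] = []
        contig_truth: list[ConsensusVariant] = []
        prev = 0
        shift = 0  # segment coordinate minus reference coordinate so far
        ref_arr = seq
        for pos, kind, compartment in events:
            parts.append(ref_arr[prev:pos])
            if kind == "SNP":
                ref_base = ref_arr[pos]
                alt = str(rng.choice([b for b in BASES if b != ref_base]))
                parts.append(alt)
                contig_truth.append(ConsensusVariant(
                    segment_id, contig, pos, pos + shift,
                    ref_base, alt, "SNP", compartment))
                prev = pos + 1
            elif kind == "insertion":
                # inserted base follows the reference base at `pos`
                ins = str(rng.choice(BASES))
                parts.append(ref_arr[pos] + ins)
                contig_truth.append(ConsensusVariant(
                    segment_id, contig, pos, pos + shift + 1,
                    "-", ins, "insertion", compartment))
                shift += 1
                prev = pos + 1
            else:  # deletion of the base at `pos`
                contig_truth.append(ConsensusVariant(
                    segment_id, contig, pos, pos + shift,
                    ref_arr[pos], "-", "deletion", compartment))
                shift -= 1
                prev = pos + 1
        parts.append(ref_arr[prev:])
        mutated = "".join(parts)

        ins_pos = np.array(sorted(
            v.position for v in contig_truth if v.variant_class == "insertion"
        ), dtype=np.int64)
        del_pos = np.array(sorted(
            v.position for v in contig_truth if v.variant_class == "deletion"
        ), dtype=np.int64)

        def lift(coord: np.ndarray) -> np.ndarray:
            # events strictly before the coordinate shift it
            return (coord
                    + np.searchsorted(ins_pos, coord, side="left")
                    - np.searchsorted(del_pos, coord, side="left"))

        iv = reference.cds_intervals.get(contig)
        if iv is not None and iv.size:
            new_iv = np.column_stack([lift(iv[:, 0]), lift(iv[:, 1])])
            new_iv = new_iv[new_iv[:, 1] > new_iv[:, 0]]
        else:
            new_iv = np.zeros((0, 2), dtype=np.int64)
        out_contigs[contig] = mutated
        out_cds[contig] = new_iv
        truth.extend(contig_truth)

    genome = AnnotatedGenome(
        contigs=out_contigs, cds_intervals=out_cds,
        name=f"segment_{segment_id}",
    )
    return genome, truth


# ---------------------------------------------------------------------------
# ISH truth and pileups
# ---------------------------------------------------------------------------

def _draw_allele(rng: np.random.Generator, ref_base: str,
                 indel_fraction: float) -> str:
    u = rng.random()
    if u < indel_fraction / 2:
        return "+"
    if u < indel_fraction:
        return "-"
    return str(rng.choice([b for b in BASES if b != ref_base]))


def generate_ish_truth(
    framework: AnnotatedGenome, config: SimulationConfig
) -> dict[int, list[IshSite]]:
    """Plant ISH sites on the framework assembly for every segment.

    A fraction ``colocalized_fraction`` of each segment's sites is drawn from
    one shared set (identical position and variant allele in all segments);
    the rest are private to single segments.  Per-segment variant frequencies
    are uniform in [ish_freq_low, ish_freq_high].
    """
    config.validate()
    rng = _rng(config, _STREAM_ISH)
    boundaries = np.cumsum([len(s) for s in framework.contigs.values()])
    names = list(framework.contigs)
    L = int(boundaries[-1]) if len(boundaries) else 0
    seqcat = "".join(framework.contigs.values())

    def locate(gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(boundaries, gpos, side="right"))
        offset = gpos - (int(boundaries[ci - 1]) if ci else 0)
        return names[ci], offset

    n_shared = rng.poisson(config.colocalized_fraction * config.ish_site_rate * L)
    n_priv = rng.poisson(
        (1 - config.colocalized_fraction) * config.ish_site_rate * L,
        size=config.n_segments,
    )
    total = n_shared + int(n_priv.sum())
    if total > L:
        raise ConfigurationError("ish_site_rate too high for genome length")
    all_pos = rng.choice(L, size=total, replace=False)
    shared_pos = np.sort(all_pos[:n_shared])
    shared_alleles = [
        _draw_allele(rng, seqcat[p], config.ish_indel_fraction)
        for p in shared_pos
    ]
    out: dict[int, list[IshSite]] = {}
    offset = n_shared
    for seg in range(1, config.n_segments + 1):
        sites: list[IshSite] = []
        for p, allele in zip(shared_pos, shared_alleles):
            contig, cpos = locate(int(p))
            f = rng.uniform(config.ish_freq_low, config.ish_freq_high)
            sites.append(IshSite(seg, contig, cpos, allele, float(f), True))
        mine = np.sort(all_pos[offset:offset + int(n_priv[seg - 1])])
        offset += int(n_priv[seg - 1])
        for p in mine:
            contig, cpos = locate(int(p))
            allele = _draw_allele(rng, seqcat[int(p)], config.ish_indel_fraction)
            f = rng.uniform(config.ish_freq_low, config.ish_freq_high)
            sites.append(IshSite(seg, contig, cpos, allele, float(f), False))
        sites.sort(key=lambda s: (s.contig, s.position, s.alt_allele))
        out[seg] = sites
    return out


def simulate_pileup(
    framework: AnnotatedGenome,
    config: SimulationConfig,
    ish_sites: list[IshSite],
    segment_id: int,
) -> pd.DataFrame:
    """Simulate one segment library's per-position pileup over the framework.

    Coverage is Poisson around ``coverage_mean``.  At ISH sites the variant
    read count is Binomial(coverage, true frequency); everywhere else
    non-reference reads arise only from ``seq_error_rate`` (substitution
    errors split evenly over the three alternative bases).  Returns a frame in
    the package pileup dialect with 0-based ``pos`` (written 1-based).
    """
    config.validate()
    rng = _rng(config, _STREAM_PILEUP, int(segment_id))
    frames = []
    for contig, seq in framework.contigs.items():
        L = len(seq)
        ref_codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        base_idx = np.full(256, -1, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            base_idx[ord(b)] = i
        ridx = base_idx[ref_codes]
        cov = rng.poisson(config.coverage_mean, size=L).astype(np.int64)
        counts = np.zeros((L, 4), dtype=np.int64)
        nerr = rng.binomial(cov, config.seq_error_rate)
        err3 = rng.multinomial(nerr, np.full(3, 1.0 / 3.0))
        for r in range(4):
            mask = ridx == r
            if not mask.any():
                continue
            alts = [a for a in range(4) if a != r]
            counts[mask, r] = cov[mask] - nerr[mask]
            for col, a in enumerate(alts):
                counts[mask, a] = err3[mask, col]
        ins = np.zeros(L, dtype=np.int64)
        dele = np.zeros(L, dtype=np.int64)

        for site in ish_sites:
            if site.contig != contig:
                continue
            p = site.position
            if not 0 <= p < L:
                raise CoordinateError(
                    f"ISH truth position {p} outside contig {contig!r}"
                )
            n = int(cov[p])
            altc = int(rng.binomial(n, site.frequency))
            if site.alt_allele == "+":
                ins[p] = altc
            elif site.alt_allele == "-":
                dele[p] = altc
            else:
                a = _BASE_INDEX[site.alt_allele]
                rest = n - altc
                ne = int(rng.binomial(rest, config.seq_error_rate))
                row = np.zeros(4, dtype=np.int64)
                row[a] = altc
                row[ridx[p]] += rest - ne
                if ne:
                    others = [x for x in range(4) if x != ridx[p]]
                    row[others] += rng.multinomial(ne, np.full(3, 1.0 / 3.0))
                counts[p] = row
        frames.append(pd.DataFrame({
            "contig": contig,
            "pos": np.arange(L, dtype=np.int64),
            "ref": list(seq),
            "depth": cov,
            "countA": counts[:, 0],
            "countC": counts[:, 1],
            "countG": counts[:, 2],
            "countT": counts[:, 3],
            "countIns": ins,
            "countDel": dele,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=PILEUP_COLUMNS)


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pileup frame in the package TSV dialect (1-based positions)."""
    out = df.copy()
    out["pos"] = out["pos"] + 1
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PILEUP_COLUMNS) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# whole-filament orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedFilament:
    config: SimulationConfig
    reference: AnnotatedGenome
    segments: dict[int, AnnotatedGenome]
    truth: SimTruth
    pileups: dict[int, pd.DataFrame]


def simulate_filament(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    write_pileups: bool = True,
) -> SimulatedFilament:
    """Generate the full synthetic dataset (and optionally write it out)."""
    reference = generate_reference(config)
    segments: dict[int, AnnotatedGenome] = {}
    truth = SimTruth()
    for seg in range(1, config.n_segments + 1):
        genome, variants = mutate_consensus(reference, config, seg)
        segments[seg] = genome
        truth.consensus_variants.extend(variants)
    ish = generate_ish_truth(reference, config)
    pileups = {}
    for seg in range(1, config.n_segments + 1):
        truth.ish_sites.extend(ish[seg])
        pileups[seg] = simulate_pileup(reference, config, ish[seg], seg)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        reference.write(outdir / "reference.fasta", outdir / "reference.gff3")
        for seg, genome in segments.items():
            genome.write(outdir / f"segment_{seg}.fasta",
                         outdir / f"segment_{seg}.gff3")
        if write_pileups:
            for seg, df in pileups.items():
                write_pileup(df, outdir / f"pileup_segment_{seg}.tsv")
        truth.consensus_frame().to_csv(
            outdir / "truth_consensus_variants.tsv", sep="\t", index=False)
        truth.ish_frame().to_csv(
            outdir / "truth_ish_sites.tsv", sep="\t", index=False)
        config.to_json(outdir / "sim_config.json")
    return SimulatedFilament(config, reference, segments, truth, pileups)
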