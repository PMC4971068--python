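# Methods

`filoplast` quantifies genome plasticity along a clonal, polyploid bacterial
filament on two levels: fixed consensus differences *between* segment
assemblies, and read-level heterogeneity *within* each segment library.
This note documents the models, the parameters that matter, the synthetic
data used to validate the pipeline, and the numerical conventions.

## Pairwise assembly comparison

**Model.** The segments of one filament are near-clonal: assemblies differ
by scattered substitutions and single-nucleotide indels, not by
rearrangements. The aligner is built on that assumption:

1. *Anchoring.* All k-mers (k = 21 by default, odd, 11–31) that occur
   exactly once in **both** sequences are matched; k-mers containing N are
   ignored. Matches on the same diagonal at consecutive offsets merge into
   maximal exact matches. On a ~3 Mbp random-like genome, k = 21 makes
   spurious repeated k-mers vanishingly rare, so anchors tile the genome
   between variant positions.
2. *Chaining.* A weighted longest-increasing-subsequence selects the
   highest-total-length colinear chain; ties prefer the smaller total gap
   span, then the leftmost query coordinate. Anchors may overlap their
   neighbours by a few bases when two indels fall within k bp of each other
   (their maximal exact matches lie on shifted diagonals); the chain DP
   admits such predecessors and trims the overlap from the later anchor, so
   the output chain is always strictly non-overlapping. Without trimming, a
   strictly non-overlapping chain can be forced to discard a multi-kbp
   anchor over a 5 bp conflict, leaving a large spurious gap.
3. *Gap alignment.* Inter-anchor gaps (and unanchored sequence ends) are
   closed with a banded global affine alignment: match +1, mismatch −1,
   gap open −2, gap extend −1 (a length-L gap costs 2 + (L−1)). The band
   (default 256 diagonals each side) widens automatically to cover the gap
   length difference. Any scoring consistent with near-identity alignment
   would serve; the suite pins behaviour against an independent unbanded
   global aligner (Biopython `PairwiseAligner` with identical scores) on
   hundreds of randomized pairs. Gaps longer than a cap (default 20 kbp on
   either side) mark the pair *structurally divergent*; the region is
   excluded from variant calling and reported, because a near-clonality
   aligner has no business interpreting structural differences.

**Variant calling.** Each mismatch column yields one SNP; each of the r
columns of a gap run yields one single-nucleotide insertion or deletion
event (a 2-base deletion counts as 2 events — the events under study are
defined as single-nucleotide; an alternative one-event-per-run mode exists
behind `indel_run_as_one` but is off by default). Columns containing N
never produce calls; denominators are still the full assembly lengths.
Calls carry 0-based positions on the **query** assembly (deletions at the
query base following the deleted one) and a CDS/nCDS compartment from the
query annotation.

**Rates.** Every density is `100 000 × count / L`, where `L` is the query
(column) assembly's total, CDS, or nCDS length. The compartment identity
`cds + ncds = total` holds for counts and lengths by construction.

**Known ambiguity.** Within a homopolymer or short repeat, the placement of
an indel is not unique among co-optimal alignments; counts and classes are
stable, positions may shift within the repeat run. Recovery tests therefore
match SNPs exactly and indels up to such shifts.

## ISH calling and co-localization

A pileup column (contig, 1-based position, reference base, depth, counts
for A/C/G/T/insertion/deletion; tab-separated, `#` comments) is processed
as follows: if coverage (= sum of the four base counts) is below
`min_coverage` (default 100; hard floor 31, below which read heterogeneity
is not considered robust for these libraries) the column is skipped.
Otherwise the consensus is the majority base, ties broken alphabetically
for determinism, and **each** non-consensus allele with
`count / coverage ≥ min_variant_frequency` (default 0.25) yields one event
— so one column can yield at most three SNV events plus the insertion and
deletion alleles. The frequency denominator is the full column coverage.
No strand-bias, base-quality or mapping-quality filtering is applied; users
of real pileups must pre-filter upstream.

Sites are keyed by (contig, position, class, variant allele); insertions by
position only, since the pileup dialect stores a count, not the inserted
sequence. The **co-localized fraction** is the number of sites present in
*all* segments divided by the mean per-segment distinct-site count — the
convention under which a planted co-localized fraction is recovered
unbiasedly; the fraction of distinct sites shared, and the looser
present-in-≥2 count, are reported alongside. `intra_vs_inter` contrasts
mean ISH events per segment with mean pairwise consensus SNPs: within-cell
genome-copy heterogeneity runs an order of magnitude above between-segment
fixed divergence in the regime this package targets.

## Fragment ANI

Goris-style: non-overlapping 1,020 bp windows (a trailing window is kept if
≥ 100 bp), each placed on the target by unique-k-mer seeding (most
seed-supported diagonals, up to three candidates) and aligned semi-globally
with edlib against the seeded window (±60 bp margin). Identity is matched
columns over aligned columns; the best hit maximizes identity × alignable
fraction, ties to the leftmost target coordinate. Fragments pass at ≥ 30%
identity and ≥ 70% alignable fraction; one-way ANI is the unweighted mean
fragment identity, two-way ANI the arithmetic mean of both directions (by
construction symmetric). A direction retaining no fragments makes the
result undefined, reported with a diagnostic rather than as zero. The
levenshtein-scored fragment alignment is deliberate: at near-clonal
divergence, identity is insensitive to the scoring scheme, and the
1,020 bp/30%/70% constants dominate the estimator's behaviour.

## The synthetic filament

The generator emulates the study design the analysis assumes: one
reference genome, six segment consensuses, six pileup libraries on a
common framework.

| parameter | default | meaning / rationale |
|---|---|---|
| `genome_length` | 3,200,000 bp | genome scale of the target organisms |
| `gc_fraction` | 0.40 | typical for the clade; flat base composition |
| `coding_fraction_target` | 0.88 | coding density of the study genomes |
| `n_segments` | 6 | segments of one filament |
| `snp_rate_cds` / `snp_rate_ncds` | 3.6e-5 / 8.5e-5 per bp | per-segment consensus substitution rates vs the reference, reproducing the observed CDS/nCDS densities per 100 kbp |
| `indel_rate_cds` / `indel_rate_ncds` | 2e-6 / 3.9e-5 per bp | single-nt indel rates; indels are depleted in frame-sensitive coding sequence |
| `ish_site_rate` | 7e-4 per bp | ~2,200 ISH sites per 3.2 Mbp segment |
| `ish_freq_low` / `ish_freq_high` | 0.25 / 0.50 | variant-frequency range among genome copies; anchored at the calling threshold |
| `ish_indel_fraction` | 0.20 | share of ISH sites that are indels (split evenly insertion/deletion); the observed event mix is not published, so a modest minority was fixed once |
| `colocalized_fraction` | 1/3 | share of each segment's sites drawn from one set shared by all segments (identical position *and* allele) |
| `coverage_mean` | 380 | Poisson coverage, matching the libraries' 200–470× range |
| `seq_error_rate` | 0.005 | per-base substitution error, split evenly over the three alternative bases |

Design choices where the design was genuinely open:

* Mutation placement is i.i.d. uniform within each compartment — the
  simplest null consistent with the absence of positional structure.
* Consensus mutation rates are defined per segment **relative to the
  reference**; two segments therefore diverge pairwise at twice the
  per-segment rate. Tests of pairwise regimes account for this factor.
* Pileups are simulated on the *reference* as the common framework (the
  role the best assembly plays in a real analysis) and carry only ISH
  heterogeneity plus sequencing error; consensus divergence between
  segments is deliberately not layered into the pileups, keeping the two
  analysis levels independently testable.
* Coverage is Poisson; no amplification-bias or contamination model
  (whole-genome-amplified real libraries violate this — see limitations).
* Randomness flows from a single seed through fixed per-purpose substreams
  (reference / per-segment mutation / ISH truth / per-segment pileup), so
  all outputs are byte-identical for a fixed configuration.
* Insertions are recorded at the reference base they follow, deletions at
  the deleted base; truth tables carry both reference and segment
  coordinates.

**Boundary effects the generator exposes on purpose.** With truth
frequencies drawn up to the defaults' 0.50, binomial read sampling at
coverage ~380 occasionally makes the variant allele the majority — the
caller then (correctly) reports the *reference* allele as the variant —
and frequencies at the 0.25 threshold are missed about half the time.
Recovery and co-localization tests therefore plant frequencies in
[0.30, 0.45], inside the callable band, so that detection rather than
threshold sampling noise is under test; the threshold boundaries
themselves are tested exactly on constructed columns.

**What passing tests do and do not show.** The simulator draws i.i.d.
sequence, uniform mutations, Poisson coverage and uniform errors. Real
MDA-amplified filament libraries have coverage hotspots (>1000×),
repeat-collapsed assembly regions, contaminant contigs and quality-skewed
errors, none of which are modelled. Passing recovery tests validates the
*machinery* (alignment, calling, thresholds, bookkeeping) — not robustness
to those artefacts.

## Numerical conventions

* Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
  and pileups/variant reports (1-based) are converted at the boundary.
* Internal aggregation is full precision; rounding is half-up at
  serialization only: rates to 2 decimals, summary means/sds to 1.
* "±" summaries are sample standard deviations (n − 1); the four-segment
  subset summarizes exactly the 12 ordered off-diagonal pairs, the
  "segments 5–6 involved" subset exactly the 18 ordered pairs with either
  end segment on either side.
* Consensus ties (ISH) and chain ties (pairdiff) have deterministic,
  documented tie-breaks; degenerate inputs (empty pileups, unalignable
  pairs, zero retained ANI fragments, zero-length denominators) produce
  explicit markers or typed errors, never silent zeros.

## Problem sizes used by the test and acceptance runs

Unit tests run at 10–500 kbp; genome-scale recovery (compartment rate
recovery, clonal-pair ANI) runs at 3 Mbp; ISH structure recovery uses six
1 Mbp libraries with ~2,000 sites each; the end-to-end pipeline check uses
a six-segment 1 Mbp filament. These sizes keep the full suite to minutes
on one CPU while leaving every statistical check comfortably powered.

## Limitations

* No rearrangement or inversion detection; structurally divergent regions
  are excluded, not interpreted.
* No repeat resolution: unique-k-mer anchoring leaves genuinely repetitive
  regions to the banded gap aligner or the divergence cap.
* ISH calling reproduces two thresholds only; it is not a genotyper — no
  likelihoods, ploidy estimation, or phasing.
* ANI uses the package's internal placement, not BLAST; values at deep
  divergence (< ~80% identity) are outside the intended regime.
* The simulator's ISH frequency is a free parameter, not derived from a
  genome-copy-number model; within-cell ploidy is unknown for these
  organisms.
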