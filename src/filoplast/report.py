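"""Aggregation, summary statistics and pipeline orchestration.

Builds the per-reference-segment matrix of variant counts and per-100-kbp
rates (one 10-row block per reference segment), computes mean +/- sd rate
summaries over segment subsets, and runs the whole analysis end to end from
a single configuration (simulation block or real input paths).

Conventions: "+/-" values are sample standard deviations (n-1).  Internal
aggregation is full precision; rounding (half-up, rates to 2 decimals,
summary means/sds to 1) is applied only at serialization.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anicalc import ANIConfig, ani_matrix
from .genome import AnnotatedGenome, ConfigurationError
from .ishscan import (
    ISHConfig,
    call_ish,
    colocalize,
    events_frame,
    intra_vs_inter,
    read_pileup_table,
    write_site_matrix,
)
from .pairdiff import PairwiseComparison, compare_pair
from .sim import SimulationConfig, simulate_filament

logger = logging.getLogger("filoplast")

#: matrix rows, in the canonical block order
METRIC_ROWS = [
    "total_snps",
    "snps_per_100kbp",
    "total_indels",
    "indels_per_100kbp",
    "snps_cds",
    "snps_cds_per_100kbp",
    "snps_ncds_per_100kbp",
    "indels_cds",
    "indels_cds_per_100kbp",
    "indels_ncds_per_100kbp",
]
COUNT_ROWS = {"total_snps", "total_indels", "snps_cds", "indels_cds"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention used for reported rates)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def build_matrix(
    comparisons: list[PairwiseComparison],
    segment_order: list,
) -> dict:
    """One metric-by-query-segment block per reference segment.

    Diagonal cells are synthesized as zero (self-comparison); a missing pair
    leaves an explicit NaN gap cell, never a zero.  Values are full
    precision; round at serialization.
    """
    by_pair = {}
    for c in comparisons:
        if getattr(c, "aligned", True):
            by_pair[(c.reference_id, c.query_id)] = c
    blocks: dict = {}
    for ref in segment_order:
        data = np.full((len(METRIC_ROWS), len(segment_order)), np.nan)
        for j, qry in enumerate(segment_order):
            if ref == qry:
                data[:, j] = 0.0
                continue
            c = by_pair.get((ref, qry))
            if c is None:
                continue
            data[:, j] = [getattr(c, m) for m in METRIC_ROWS]
        blocks[ref] = pd.DataFrame(data, index=METRIC_ROWS,
                                   columns=segment_order)
    return blocks


@dataclass
class RateSummary:
    """Mean +/- sd of one rate metric over a subset of ordered pairs."""

    subset_label: str
    metric: str
    n_values: int
    mean: float
    sd: float
    values: list[float]


def summarize_rates(
    matrix: dict,
    subset: set,
    metric: str,
    mode: str = "within",
) -> RateSummary:
    """Collect off-diagonal ordered-pair values and summarize.

    ``mode='within'`` uses pairs with both segments in ``subset`` (12 values
    for a 4-segment subset); ``mode='involving'`` uses every ordered pair
    with at least one side in ``subset`` (18 values for a 2-of-6 subset).
    """
    if not subset:
        raise ConfigurationError("summary subset must be non-empty")
    if metric not in METRIC_ROWS:
        raise ConfigurationError(f"unknown metric {metric!r}")
    segments = list(next(iter(matrix.values())).columns)
    values = []
    for ref, block in matrix.items():
        for qry in segments:
            if ref == qry:
                continue
            if mode == "within":
                if ref not in subset or qry not in subset:
                    continue
            elif mode == "involving":
                if ref not in subset and qry not in subset:
                    continue
            else:
                raise ConfigurationError(f"unknown mode {mode!r}")
            v = block.loc[metric, qry]
            if not np.isnan(v):
                values.append(float(v))
    label = f"segments {sorted(subset)} {'pairwise' if mode == 'within' else 'involved'}"
    arr = np.asarray(values)
    return RateSummary(
        subset_label=label, metric=metric, n_values=len(values),
        mean=float(arr.mean()) if values else float("nan"),
        sd=float(arr.std(ddof=1)) if len(values) > 1 else 0.0,
        values=values,
    )


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def matrix_to_frames(matrix: dict, ndigits: int = 2) -> dict:
    """Rounded copies of the matrix blocks for writing."""
    out = {}
    for ref, block in matrix.items():
        b = block.copy()
        for row in b.index:
            nd = 0 if row in COUNT_ROWS else ndigits
            b.loc[row] = [
                np.nan if np.isnan(v) else round_half_up(v, nd)
                for v in b.loc[row]
            ]
        out[ref] = b
    return out


def write_matrix(matrix: dict, tsv_path: str | Path,
                 json_path: str | Path | None = None) -> None:
    frames = matrix_to_frames(matrix)
    with open(tsv_path, "w") as fh:
        for ref, block in frames.items():
            fh.write(f"# reference segment {ref}\n")
            block.to_csv(fh, sep="\t")
            fh.write("\n")
    if json_path is not None:
        payload = {
            str(ref): {
                m: {str(q): (None if np.isnan(v) else v)
                    for q, v in block.loc[m].items()}
                for m in block.index
            }
            for ref, block in frames.items()
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def _load_inputs(inputs: dict):
    missing = []
    ref_spec = inputs.get("reference") or {}
    for key in ("fasta", "gff3"):
        if key not in ref_spec:
            missing.append(f"inputs.reference.{key}")
    seg_specs = inputs.get("segments") or []
    if not seg_specs:
        missing.append("inputs.segments")
    for i, spec in enumerate(seg_specs):
        for key in ("id", "fasta", "gff3"):
            if key not in spec:
                missing.append(f"inputs.segments[{i}].{key}")
    if missing:
        raise ConfigurationError(
            "incomplete input configuration; missing: " + ", ".join(missing)
        )
    reference = AnnotatedGenome.from_files(
        ref_spec["fasta"], ref_spec["gff3"], name="reference")
    segments, pileups = {}, {}
    for spec in seg_specs:
        sid = spec["id"]
        segments[sid] = AnnotatedGenome.from_files(
            spec["fasta"], spec["gff3"], name=f"segment_{sid}")
        if "pileup" in spec:
            pileups[sid] = read_pileup_table(spec["pileup"])
    return reference, segments, pileups


def run_pipeline(config, outdir: str | Path) -> dict:
    """Run simulate (optional) -> pairwise comparison -> ISH -> ANI ->
    matrices and summaries; returns the run manifest.

    The summary JSON is deterministic for a fixed seed (timestamps live only
    in the manifest)."""
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        if "sim" in cfg:
            sim_cfg = SimulationConfig.from_dict(cfg["sim"])
            logger.info("simulating filament: %s", sim_cfg)
            data = simulate_filament(
                sim_cfg, outdir / "data",
                write_pileups=cfg.get("output", {}).get("write_pileups", False),
            )
            reference, segments, pileups = data.reference, data.segments, data.pileups
        elif "inputs" in cfg:
            reference, segments, pileups = _load_inputs(cfg["inputs"])
        else:
            raise ConfigurationError(
                "configuration needs a 'sim' or an 'inputs' section"
            )

        thresholds = cfg.get("thresholds", {})
        pd_opts = thresholds.get("pairdiff", {})
        ish_cfg = ISHConfig(**thresholds.get("ish", {}))
        ani_cfg = ANIConfig(**thresholds.get("ani", {}))

        seg_ids = list(segments)
        logger.info("comparing %d ordered segment pairs",
                    len(seg_ids) * (len(seg_ids) - 1))
        comparisons = []
        for a in seg_ids:
            for b in seg_ids:
                if a == b:
                    continue
                c = compare_pair(segments[a], segments[b],
                                 keep_variants=True, **pd_opts)
                c.reference_id, c.query_id = a, b
                comparisons.append(c)
        matrix = build_matrix(comparisons, seg_ids)
        write_matrix(matrix, outdir / "comparison_matrix.tsv",
                     outdir / "comparison_matrix.json")
        var_rows = []
        for c in comparisons:
            for v in c.variants:
                var_rows.append((c.reference_id, c.query_id, v.contig,
                                 v.position + 1, v.variant_class, v.ref,
                                 v.alt, v.compartment))
        pd.DataFrame(var_rows, columns=[
            "reference", "query", "contig", "pos", "class", "ref", "alt",
            "compartment",
        ]).to_csv(outdir / "variants.tsv", sep="\t", index=False)

        events_by_segment = {}
        if pileups:
            logger.info("calling ISH events in %d pileups", len(pileups))
            for sid, df in pileups.items():
                events_by_segment[sid] = call_ish(df, ish_cfg, segment=sid)
                events_frame(events_by_segment[sid]).to_csv(
                    outdir / f"ish_events_segment_{sid}.tsv",
                    sep="\t", index=False)
            coloc = colocalize(events_by_segment)
            write_site_matrix(coloc, outdir / "ish_site_matrix.tsv")
        else:
            coloc = None

        subset_cfg = cfg.get("summaries", {}).get("subsets")
        if subset_cfg is None:
            subsets = [(set(seg_ids), "within")]
            first4 = seg_ids[:4]
            if len(seg_ids) > 4:
                subsets.append((set(first4), "within"))
                subsets.append((set(seg_ids[4:]), "involving"))
        else:
            subsets = [(set(s["segments"]), s.get("mode", "within"))
                       for s in subset_cfg]
        rate_metrics = [m for m in METRIC_ROWS if m.endswith("per_100kbp")]
        summaries = [
            summarize_rates(matrix, subset, metric, mode)
            for subset, mode in subsets
            for metric in rate_metrics
        ]

        intra_inter = None
        if events_by_segment:
            intra_inter = intra_vs_inter(events_by_segment, comparisons)

        ani = None
        if cfg.get("run_ani", True):
            logger.info("computing two-way ANI matrix")
            ani = ani_matrix({s: g for s, g in segments.items()}, ani_cfg)
            ani.round(4).to_csv(outdir / "ani_matrix.tsv", sep="\t")

        summary = {
            "segments": [str(s) for s in seg_ids],
            "comparisons": [
                {k: v for k, v in dataclasses.asdict(c).items()
                 if k != "variants"}
                for c in comparisons
            ],
            "rate_summaries": [
                {
                    "subset": s.subset_label, "metric": s.metric,
                    "n_values": s.n_values,
                    "mean": round_half_up(s.mean, 1),
                    "sd": round_half_up(s.sd, 1),
                }
                for s in summaries
            ],
            "colocalization": None if coloc is None else {
                "n_events_per_segment":
                    {str(k): v for k, v in coloc.n_events_per_segment.items()},
                "n_distinct_sites": coloc.n_distinct_sites,
                "n_sites_shared_by_all": coloc.n_sites_shared_by_all,
                "n_sites_shared_by_2plus": coloc.n_sites_shared_by_2plus,
                "fraction_colocalized": coloc.fraction_colocalized,
                "fraction_not_colocalized": coloc.fraction_not_colocalized,
            },
            "intra_vs_inter": None if intra_inter is None or intra_inter.empty
            else {
                "mean_ish_events_per_segment":
                    intra_inter.mean_ish_events_per_segment,
                "mean_pairwise_snps": intra_inter.mean_pairwise_snps,
                "ratio": intra_inter.ratio,
            },
            "ani_two_way": None if ani is None else {
                str(a): {str(b): (None if np.isnan(ani.loc[a, b])
                                  else round(float(ani.loc[a, b]), 4))
                         for b in ani.columns}
                for a in ani.index
            },
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")

        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        manifest = {
            "tool": "filoplast",
            "version": __version__,
            "config_hash": cfg_hash,
            "seed": cfg.get("sim", {}).get("seed"),
            "started": t0,
            "finished": time.time(),
            "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("pipeline finished in %.1f s", time.time() - t0)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
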