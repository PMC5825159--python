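"""End-to-end orchestration: simulate -> call -> consensus -> classify -> scan -> associate.

One reproducible run produces a results bundle on disk: consensus peak BEDs,
overlap classification tables, read-proportion tables, motif hit / central
enrichment / spacing outputs, specific-gene lists, the binding x expression
enrichment matrix, and — because the inputs are simulated with known truth —
a recovery report scoring peak-class precision/recall, spacing mode error and
specificity-call power. Every file is listed in a manifest with sha256
checksums; a rerun with the same seed reproduces the checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import association, expression, motifs, signal
from .intervals import (
    GenomicInterval,
    OverlapClassification,
    PeakSet,
    _overlap_mask,
    classify_overlap,
    consensus_peaks,
    write_bed,
)
from .motifs import MotifPattern, central_enrichment, scan_peaks, spacing_profile
from .signal import ReadSet, call_peaks_window, proportions_table
from .synthetic_data import (
    SimulationConfig,
    SimulationTruth,
    peak_sequences,
    plant_peaks_and_motifs,
    replicate_peaks,
    simulate_expression,
    simulate_genome,
    simulate_reads,
    write_truth,
)

__all__ = ["RunConfig", "ResultsBundle", "run_all", "report", "score_class_recovery"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and paths for one pipeline run; echoed verbatim into the bundle."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: Optional[str] = None
    caller_window_bp: int = 100
    caller_p_merged: float = 1e-7  # stringent tier, merged duplicates
    caller_p_replicate: float = 1e-6  # lenient tier, each duplicate
    consensus_ext_bp: int = 100
    min_overlap_bp: int = 1
    association_window: int = 500_000
    p_adj_threshold: float = 0.01
    fold_threshold: float = 2.0
    central_window: int = 100
    run_expression: bool = True
    #: gene universe for the binding x expression contingency tests:
    #: "all" annotated genes, or "expressed" (mean RPKM > 1)
    enrichment_universe: str = "all"

    def __post_init__(self) -> None:
        if not (0 < self.caller_p_merged < 1 and 0 < self.caller_p_replicate < 1):
            raise ValueError("caller p thresholds must be in (0, 1)")
        if self.consensus_ext_bp <= 0 or self.central_window <= 0:
            raise ValueError("window sizes must be positive")
        if self.association_window <= 0:
            raise ValueError("association window must be positive")
        if self.enrichment_universe not in ("all", "expressed"):
            raise ValueError("enrichment_universe must be 'all' or 'expressed'")

    def echo(self) -> dict:
        d = asdict(self)
        d.pop("outdir", None)  # path choice is not part of the scientific config
        d["sim"]["expression_plan"] = asdict(self.sim.expression_plan)
        d["sim"]["motif_plans"] = [asdict(p) for p in self.sim.motif_plans]
        d["sim"]["germ_layers"] = dict(self.sim.germ_layers)
        d["sim"]["peaks_per_class"] = dict(self.sim.peaks_per_class)
        return d


@dataclass
class ResultsBundle:
    """In-memory results of one run plus the on-disk manifest."""

    config: RunConfig
    outdir: Optional[Path]
    consensus: dict[str, PeakSet]
    classification: OverlapClassification
    proportions: pd.DataFrame
    central: dict[str, dict]
    spacing: dict[str, pd.DataFrame]
    spacing_stats: dict[str, dict]
    specific_calls: Optional[dict[str, pd.DataFrame]]
    enrichment: Optional[pd.DataFrame]
    recovery: dict
    manifest: dict[str, str]  # relative path -> sha256
    truth: Optional[SimulationTruth] = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s done in %.2fs", name, t1 - t0)
    return t1


def run_all(config: RunConfig) -> ResultsBundle:
    """Run the full simulated analysis; see the module docstring for the stages."""
    sim = config.sim
    t = time.perf_counter()
    genome = simulate_genome(sim)
    true_peaks, truth = plant_peaks_and_motifs(genome, sim)
    t = _stage("simulate", t)

    sizes = sim.genome_sizes
    merged_reads: dict[str, ReadSet] = {}
    consensus: dict[str, PeakSet] = {}
    for tissue in sim.tissues:
        reps = [
            simulate_reads(replicate_peaks(truth, tissue, r), sizes, sim, r)
            for r in range(sim.n_replicates)
        ]
        merged = ReadSet.merge(reps, sample=f"{tissue}_merged")
        merged_reads[tissue] = merged
        merged_calls = call_peaks_window(
            merged, sizes, config.caller_window_bp, config.caller_p_merged
        )
        rep_calls = [
            call_peaks_window(r, sizes, config.caller_window_bp, config.caller_p_replicate)
            for r in reps
        ]
        consensus[tissue] = consensus_peaks(
            merged_calls, rep_calls, config.consensus_ext_bp, config.min_overlap_bp
        )
    t = _stage("call+consensus", t)

    classification = classify_overlap(consensus, dict(sim.germ_layers), config.min_overlap_bp)
    t = _stage("classify", t)

    union_regions = _union_intervals(classification)
    proportions = proportions_table(union_regions, list(merged_reads.values()))
    proportions["class"] = classification.union["class"].values
    t = _stage("proportions", t)

    central: dict[str, dict] = {}
    spacing_tables: dict[str, pd.DataFrame] = {}
    spacing_stats: dict[str, dict] = {}
    for plan in sim.motif_plans:
        pattern = MotifPattern(plan.name, plan.pattern)
        pooled_hits: dict[str, list] = {}
        pooled_seqs: dict[str, str] = {}
        for tissue in sim.tissues:
            seqs = peak_sequences(genome, consensus[tissue])
            seqs = {f"{tissue}:{k}": v for k, v in seqs.items()}
            pooled_seqs.update(seqs)
        pooled_hits = scan_peaks(pooled_seqs, pattern)
        res = central_enrichment(
            {k: pooled_hits.get(k, []) for k in pooled_seqs},
            peak_width=2 * config.consensus_ext_bp,
            central_window=config.central_window,
            pattern_length=len(pattern),
        )
        central[plan.name] = res.to_dict()
        if plan.partner_pattern is not None:
            partner = MotifPattern(plan.partner_name, plan.partner_pattern)
            partner_hits = scan_peaks(pooled_seqs, partner)
            prof = spacing_profile(pooled_hits, partner_hits)
            key = f"{plan.name}-{plan.partner_name}"
            spacing_tables[key] = prof.to_dataframe()
            spacing_stats[key] = {
                "median_spacing": prof.median_spacing,
                "mode_spacing": prof.mode_spacing,
                "n_pairs": prof.n_pairs,
                "empty": prof.empty,
            }
    t = _stage("motifs", t)

    specific_calls = None
    enrichment = None
    if config.run_expression:
        em = simulate_expression(truth, sim)
        specific_calls = expression.specific_genes(
            em, config.p_adj_threshold, config.fold_threshold
        )
        specific_sets = {
            organ: set(df.index[df["specific"]]) for organ, df in specific_calls.items()
        }
        bound_sets = {}
        for tissue in sim.tissues:
            assigned = association.assign_peaks_to_genes(
                consensus[tissue], truth.gene_annotation, config.association_window
            )
            bound_sets[tissue] = set(assigned["gene"].dropna())
        universe = set(truth.gene_annotation["gene"])
        if config.enrichment_universe == "expressed":
            rpkms = em.rpkm_matrix()
            universe &= set(rpkms.index[rpkms.mean(axis=1) > 1.0])
            bound_sets = {t: s & universe for t, s in bound_sets.items()}
            specific_sets = {t: s & universe for t, s in specific_sets.items()}
        enrichment = association.specificity_enrichment(bound_sets, specific_sets, universe)
        t = _stage("expression+assoc", t)

    recovery = _recovery_report(config, truth, consensus, classification,
                                spacing_stats, specific_calls, enrichment, proportions)
    t = _stage("recovery", t)

    bundle = ResultsBundle(
        config=config,
        outdir=Path(config.outdir) if config.outdir else None,
        consensus=consensus,
        classification=classification,
        proportions=proportions,
        central=central,
        spacing=spacing_tables,
        spacing_stats=spacing_stats,
        specific_calls=specific_calls,
        enrichment=enrichment,
        recovery=recovery,
        manifest={},
        truth=truth,
    )
    if bundle.outdir is not None:
        _write_bundle(bundle, genome)
        _stage("write", t)
    return bundle


def _union_intervals(classification: OverlapClassification):
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in classification.union.itertuples()
    ]


def _match_truth(regions, truth: SimulationTruth, true_only: bool = True) -> list[Optional[str]]:
    """Match each region to an overlapping planted peak name (None if no overlap)."""
    names = [
        n for n in truth.peak_intervals
        if (n in truth.peak_class_labels) or not true_only
    ]
    planted = [truth.peak_intervals[n] for n in names]
    out = []
    for region in regions:
        hit = None
        for n, iv in zip(names, planted):
            if iv.chrom == region.chrom and region.start < iv.end and iv.start < region.end:
                hit = n
                break
        out.append(hit)
    return out


def score_class_recovery(
    classification: OverlapClassification, truth: SimulationTruth
) -> pd.DataFrame:
    """Per-class precision/recall of the union classification against planted classes.

    Each union region is matched to an overlapping planted peak; precision of
    a class counts matched regions whose planted class agrees, recall counts
    planted peaks recovered with the right class.
    """
    regions = _union_intervals(classification)
    matched = _match_truth(regions, truth)
    predicted = list(classification.union["class"])
    true_classes = truth.peak_class_labels
    classes = sorted(set(true_classes.values()) | set(predicted))
    rows = []
    for cls in classes:
        pred_idx = [i for i, c in enumerate(predicted) if c == cls]
        tp = sum(1 for i in pred_idx if matched[i] is not None and true_classes[matched[i]] == cls)
        n_pred = len(pred_idx)
        n_true = sum(1 for c in true_classes.values() if c == cls)
        recovered = {matched[i] for i in pred_idx if matched[i] is not None
                     and true_classes[matched[i]] == cls}
        rows.append(
            {
                "class": cls,
                "n_predicted": n_pred,
                "n_planted": n_true,
                "precision": tp / n_pred if n_pred else float("nan"),
                "recall": len(recovered) / n_true if n_true else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _recovery_report(config, truth, consensus, classification, spacing_stats,
                     specific_calls, enrichment, proportions) -> dict:
    sim = config.sim
    rec: dict = {"seed": sim.seed}

    # consensus recovery per tissue: planted true peaks found / spurious retained
    per_tissue = {}
    for tissue in sim.tissues:
        true_ivs = [truth.peak_intervals[n] for n, ts in truth.peak_tissues.items()
                    if tissue in ts and n in truth.peak_class_labels]
        spur_ivs = [truth.peak_intervals[n] for n, _ in truth.spurious.get(tissue, [])]
        cons = consensus[tissue].intervals
        found = _overlap_mask(true_ivs, cons) if true_ivs else np.array([], dtype=bool)
        spur = _overlap_mask(spur_ivs, cons) if spur_ivs else np.array([], dtype=bool)
        widths = {iv.width for iv in cons}
        per_tissue[tissue] = {
            "n_consensus": len(cons),
            "n_true_planted": len(true_ivs),
            "recall": float(found.mean()) if len(found) else float("nan"),
            "spurious_retained": int(spur.sum()),
            "widths": sorted(widths),
        }
    rec["consensus"] = per_tissue

    rec["class_recovery"] = score_class_recovery(classification, truth).to_dict("records")

    planted = [s for (_, _, _, s) in truth.planted_spacings]
    rec["spacing"] = {
        "planted_median": float(np.median(planted)) if planted else None,
        "profiles": spacing_stats,
    }

    if specific_calls is not None:
        power_rows = {}
        for organ, df in specific_calls.items():
            planted_genes = truth.specific_genes.get(organ, set())
            called = set(df.index[df["specific"]])
            n_planted = len(planted_genes)
            tp = len(called & planted_genes)
            others = set(df.index) - set().union(*truth.specific_genes.values())
            fp = len(called & others)
            power_rows[organ] = {
                "n_planted": n_planted,
                "recovered": tp,
                "power": tp / n_planted if n_planted else float("nan"),
                "false_calls": fp,
            }
        rec["specificity"] = power_rows

    if enrichment is not None:
        matched = enrichment[enrichment.bind_tissue == enrichment.expr_tissue]
        mismatched = enrichment[enrichment.bind_tissue != enrichment.expr_tissue]
        row_max = (
            enrichment.loc[enrichment.groupby("bind_tissue")["score"].idxmax()]
            .set_index("bind_tissue")["expr_tissue"]
        )
        rec["enrichment"] = {
            "matched_max_p": float(matched["p"].max()),
            "mismatched_min_p": float(mismatched["p"].min()) if len(mismatched) else None,
            "matched_is_row_max": bool((row_max.index == row_max.values).all()),
        }

    # proportions: fraction of tissue-specific union regions whose maximal
    # per-organ read proportion is the planting tissue
    spec_rows = proportions[proportions["class"].str.startswith("specific:")]
    if len(spec_rows):
        organs = [c for c in proportions.columns
                  if c not in ("chrom", "start", "end", "defined", "class")]
        argmax = spec_rows[organs].idxmax(axis=1)
        target = spec_rows["class"].str.split(":", n=1).str[1]
        rec["proportions"] = {
            "n_specific_regions": int(len(spec_rows)),
            "max_in_planting_tissue": float((argmax.values == target.values).mean()),
        }
    return rec


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _write_bundle(bundle: ResultsBundle, genome) -> None:
    outdir = bundle.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for tissue, ps in bundle.consensus.items():
        p = outdir / f"consensus_{tissue}.bed"
        write_bed(ps, p)
        files.append(p)
    p = outdir / "overlap_classes_per_tissue.tsv"
    bundle.classification.per_tissue.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = outdir / "overlap_classes_union.tsv"
    bundle.classification.union.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = outdir / "venn_counts.json"
    p.write_text(json.dumps(_jsonable({
        "union": bundle.classification.union_counts,
        "per_tissue": bundle.classification.per_tissue_counts,
    }), indent=2, sort_keys=True))
    files.append(p)
    p = outdir / "proportions.tsv"
    bundle.proportions.to_csv(p, sep="\t", index=False, float_format="%.6g")
    files.append(p)
    p = outdir / "central_enrichment.json"
    p.write_text(json.dumps(_jsonable(bundle.central), indent=2, sort_keys=True))
    files.append(p)
    for key, df in bundle.spacing.items():
        p = outdir / f"spacing_{key}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        files.append(p)
    if bundle.specific_calls is not None:
        for organ, df in bundle.specific_calls.items():
            p = outdir / f"specific_genes_{organ}.tsv"
            df[df["specific"]].to_csv(p, sep="\t", float_format="%.6g")
            files.append(p)
    if bundle.enrichment is not None:
        p = outdir / "enrichment_matrix.tsv"
        bundle.enrichment.to_csv(p, sep="\t", index=False, float_format="%.6g")
        files.append(p)
    p = outdir / "recovery.json"
    p.write_text(json.dumps(_jsonable(bundle.recovery), indent=2, sort_keys=True))
    files.append(p)
    if bundle.truth is not None:
        truth_files = write_truth(bundle.truth, outdir / "truth")
        files.extend(truth_files.values())
    p = outdir / "config.json"
    p.write_text(json.dumps(_jsonable(bundle.config.echo()), indent=2, sort_keys=True))
    files.append(p)
    manifest = {str(f.relative_to(outdir)): _sha256(f) for f in files}
    bundle.manifest = manifest
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def report(bundle: ResultsBundle) -> str:
    """Human-readable run summary; never mutates the bundle or its files.

    Raises if manifest entries are missing on disk (listing them).
    """
    if bundle.outdir is not None and bundle.manifest:
        missing = [f for f in bundle.manifest if not (bundle.outdir / f).exists()]
        if missing:
            raise FileNotFoundError(f"manifest entries missing from bundle: {missing}")
    lines = ["# crossbind run summary", ""]
    lines.append("## Consensus peaks per tissue")
    for tissue, ps in sorted(bundle.consensus.items()):
        lines.append(f"  {tissue}: {len(ps)} peaks")
    lines.append("")
    lines.append("## Overlap classes (merged-union convention)")
    if bundle.classification.union_counts:
        for cls, n in sorted(bundle.classification.union_counts.items()):
            lines.append(f"  {cls}: {n}")
    else:
        lines.append("  zero peaks in all tissues")
    lines.append("")
    lines.append("## Central motif enrichment")
    for name, res in sorted(bundle.central.items()):
        if res.get("undefined"):
            lines.append(f"  {name}: no peaks with a hit")
        else:
            lines.append(
                f"  {name}: {res['n_central']}/{res['n_peaks_with_hit']} central "
                f"({100 * res['fraction_central']:.1f}%), p = {res['p_value']:.3g}"
            )
    if bundle.spacing_stats:
        lines.append("")
        lines.append("## Motif spacing")
        for key, st in sorted(bundle.spacing_stats.items()):
            if st["empty"]:
                lines.append(f"  {key}: no co-occurring peaks")
            else:
                lines.append(
                    f"  {key}: mode {st['mode_spacing']} bp, median "
                    f"{st['median_spacing']} bp over {st['n_pairs']} pairs"
                )
    if bundle.enrichment is not None:
        lines.append("")
        lines.append("## Binding x expression specificity enrichment")
        for r in bundle.enrichment.itertuples():
            lines.append(
                f"  bind={r.bind_tissue:<12} expr={r.expr_tissue:<12} "
                f"score={r.score:.3g} chi2={r.chi2:.2f} p={r.p:.3g}"
            )
    return "\n".join(lines) + "\n"
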