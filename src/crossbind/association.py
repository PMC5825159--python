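"""Peak-to-gene association and gene-set enrichment statistics.

Peaks are assigned to the gene with the nearest transcription start site,
within a configurable window (default 500 kb). Binding/expression specificity
enrichment is scored per tissue pair with the overlap enrichment score
|A∩B| / (|A|·|B|) and a Yates-corrected chi-squared test on the 2x2 partition
of a gene universe; this is equivalent to a two-proportion test with
continuity correction, so one implementation serves both descriptions.
GO-style per-term fold enrichment is normalized by the same term's fold in the
union of all gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet

__all__ = [
    "ContingencyResult",
    "read_gene_annotation",
    "assign_peaks_to_genes",
    "overlap_enrichment_score",
    "yates_chi2",
    "specificity_enrichment",
    "go_fold_enrichment",
    "normalized_fold",
]


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV: columns gene, chrom, tss, strand. Gene ids must be unique."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    return _validate_annotation(df)


def _validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "chrom", "tss"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    if df.empty:
        raise ValueError("empty gene annotation")
    if df["gene"].duplicated().any():
        raise ValueError("gene ids must be unique")
    if (df["tss"] < 0).any():
        raise ValueError("TSS positions must be >= 0")
    return df


def assign_peaks_to_genes(
    peakset: PeakSet,
    annotation: pd.DataFrame,
    max_dist: int = 500_000,
) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS (by peak-center distance).

    Peaks whose nearest TSS lies farther than `max_dist` stay unassigned
    (gene = NaN). Equidistant TSSs tie-break deterministically to the
    lexicographically smaller gene id. Gene strand does not enter the
    distance. A gene is "bound" iff >=1 peak is assigned to it; the bound set
    is ``set(result["gene"].dropna())``.
    """
    annotation = _validate_annotation(annotation)
    by_chrom = {}
    for chrom, grp in annotation.groupby("chrom"):
        # sort by (tss, gene) so equal-TSS duplicates fall in lexicographic order
        grp = grp.sort_values(["tss", "gene"])
        by_chrom[chrom] = (grp["tss"].to_numpy(), grp["gene"].to_numpy())
    rows = []
    for i, iv in enumerate(peakset):
        center = iv.center
        gene, dist = None, None
        if iv.chrom in by_chrom:
            tss, genes = by_chrom[iv.chrom]
            j = int(np.searchsorted(tss, center))
            cand = [k for k in (j - 1, j) if 0 <= k < len(tss)]
            dists = np.abs(tss[cand] - center)
            best = int(dists.min())
            # all candidates at the minimal distance (handles equal-TSS runs
            # plus the symmetric left/right tie); lexicographic tie-break
            lo, hi = center - best, center + best
            a = int(np.searchsorted(tss, lo, side="left"))
            b = int(np.searchsorted(tss, hi, side="right"))
            tied = [genes[k] for k in range(a, b) if abs(int(tss[k]) - center) == best]
            if tied and best <= max_dist:
                gene, dist = min(tied), best
        rows.append(
            {
                "peak": iv.name if iv.name != "." else f"peak{i}",
                "chrom": iv.chrom,
                "center": center,
                "gene": gene,
                "distance": dist,
            }
        )
    return pd.DataFrame(rows, columns=["peak", "chrom", "center", "gene", "distance"])


def overlap_enrichment_score(set_a: Set, set_b: Set) -> float:
    """Gene-set overlap enrichment score: |A ∩ B| / (|A| * |B|). Symmetric."""
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    return len(set(set_a) & set(set_b)) / (len(set_a) * len(set_b))


def yates_chi2(table) -> tuple[float, float]:
    """Continuity-corrected (Yates) chi-squared test on a 2x2 table.

    statistic = sum over cells of (max(|O-E|-0.5, 0))^2 / E with expectations
    from the margins; p from the chi-squared(1 df) upper tail. The correction
    is floored at zero (as in R's chisq.test/prop.test), so a table with O=E
    everywhere gives statistic 0, p 1. Any zero expected cell is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (obs < 0).any():
        raise ValueError("cell counts must be non-negative")
    total = obs.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValueError("zero expected cell; test undefined")
    corrected = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    statistic = float((corrected**2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 bound x specific partition of the universe with score and Yates chi2."""

    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    p_value: float
    enrichment_score: float


def _contingency(bound: Set, specific: Set, universe: Set) -> ContingencyResult:
    n11 = len(bound & specific)
    n10 = len(bound - specific)
    n01 = len(specific - bound)
    n00 = len(universe) - n11 - n10 - n01
    table = ((n11, n10), (n01, n00))
    statistic, p = yates_chi2(table)
    return ContingencyResult(table, statistic, p, overlap_enrichment_score(bound, specific))


def specificity_enrichment(
    bound_genes: Mapping[str, Set],
    specific_genes: Mapping[str, Set],
    universe: Set,
) -> pd.DataFrame:
    """Enrichment of tissue-specific binding around tissue-specific expression.

    For every (binding tissue, expression tissue) pair, partitions the gene
    universe into bound/not x specific/not, and reports the overlap
    enrichment score and Yates chi-squared p. One row per pair with columns
    bind_tissue, expr_tissue, n11, n10, n01, n00, score, chi2, p.
    """
    universe = set(universe)
    for name, sets in (("bound", bound_genes), ("specific", specific_genes)):
        for tissue, s in sets.items():
            extra = set(s) - universe
            if extra:
                raise ValueError(
                    f"{name} set for {tissue!r} has {len(extra)} genes outside the universe"
                )
    rows = []
    for bt, bset in bound_genes.items():
        for et, eset in specific_genes.items():
            res = _contingency(set(bset), set(eset), universe)
            (n11, n10), (n01, n00) = res.table
            rows.append(
                {
                    "bind_tissue": bt,
                    "expr_tissue": et,
                    "n11": n11,
                    "n10": n10,
                    "n01": n01,
                    "n00": n00,
                    "score": res.enrichment_score,
                    "chi2": res.statistic,
                    "p": res.p_value,
                }
            )
    return pd.DataFrame(rows)


def go_fold_enrichment(
    gene_set: Set,
    term_annotation: Mapping[str, Set],
    universe: Set,
) -> pd.Series:
    """Per-term fold enrichment: (hits/|set|) / (term_size/|universe|).

    Term gene lists are intersected with the universe first. Terms with no
    gene in the universe give NaN.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set) & universe
    if not gene_set:
        raise ValueError("gene set empty (within the universe)")
    folds = {}
    for term, genes in term_annotation.items():
        genes = set(genes) & universe
        if not genes:
            folds[term] = float("nan")
            continue
        hits = len(gene_set & genes)
        folds[term] = (hits / len(gene_set)) / (len(genes) / len(universe))
    return pd.Series(folds, name="fold")


def normalized_fold(
    gene_sets: Mapping[str, Set],
    term_annotation: Mapping[str, Set],
    universe: Set,
) -> pd.DataFrame:
    """Fold enrichment of each term in each set, normalized by the union of all sets.

    normalized(term, set) = fold(term, set) / fold(term, union). Terms with
    zero hits in the union are undefined (NaN) and flagged in the
    ``union_defined`` column rather than dropped.
    """
    union: set = set().union(*(set(s) for s in gene_sets.values()))
    union_fold = go_fold_enrichment(union, term_annotation, universe)
    out = {}
    for name, s in gene_sets.items():
        fold = go_fold_enrichment(s, term_annotation, universe)
        out[f"fold:{name}"] = fold
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"normalized:{name}"] = fold / union_fold.replace(0.0, np.nan)
    df = pd.DataFrame(out)
    df["fold:union"] = union_fold
    df["union_defined"] = union_fold > 0
    return df
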