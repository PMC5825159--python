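"""Expression quantification (RPKM) and organ-specific gene calling.

Organ specificity follows the rule: a gene is specific to an organ iff, against
*every* other organ, it shows adjusted p < 0.01 and fold change > 2. The test
engine is a declared stand-in for a negative-binomial GLM with dispersion
shrinkage: a moderated two-sample t-test on log2(RPKM+1), where the per-gene
pooled variance is shrunk toward a lowess trend over average log expression
(limma-style empirical Bayes, prior df d0=4) before forming the statistic with
df = d + d0. With 2-3 replicates per group an unmoderated test is dominated by
sample-variance noise; the moderation recovers the power a dispersion-shrinking
GLM would have while keeping the thresholds — not the engine — as the contract.
Benjamini-Hochberg correction is applied within each (target organ vs other
organ) comparison family across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "rpkm",
    "specific_genes",
    "most_variable_genes",
    "read_counts_tsv",
    "read_samples_tsv",
]

logger = logging.getLogger(__name__)

#: pseudocount added to mean RPKM before taking ratios, to avoid division by zero
FOLD_PSEUDOCOUNT = 0.1


@dataclass
class ExpressionMatrix:
    """Gene x sample read counts with gene lengths and sample->organ labels."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    gene_lengths: pd.Series  # bp, indexed by gene
    sample_info: pd.DataFrame  # index: sample; columns: organ, replicate

    def __post_init__(self) -> None:
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be > 0")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_info.index)
        if missing:
            raise ValueError(f"samples without organ label: {sorted(missing)}")

    @property
    def organs(self) -> list[str]:
        return sorted(self.sample_info.loc[self.counts.columns, "organ"].unique())

    def samples_of(self, organ: str) -> list[str]:
        info = self.sample_info.loc[self.counts.columns]
        return list(info.index[info["organ"] == organ])

    def rpkm_matrix(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("every sample needs > 0 total reads")
        return rpkm(
            self.counts,
            self.gene_lengths.values[:, None],
            totals.values[None, :],
        )


def rpkm(count, gene_length_bp, library_total):
    """Reads per kilobase of gene model per million mapped reads.

    rpkm = 1e9 * count / (gene_length_bp * library_total). Works elementwise
    on scalars or arrays.
    """
    length = np.asarray(gene_length_bp, dtype=float)
    total = np.asarray(library_total, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be > 0")
    if np.any(total <= 0):
        raise ValueError("library total must be > 0")
    out = 1e9 * np.asarray(count, dtype=float) / (length * total)
    if isinstance(count, pd.DataFrame):
        return pd.DataFrame(out, index=count.index, columns=count.columns)
    if np.isscalar(count):
        return float(out)
    return out


def _moderated_t_pvalues(x: np.ndarray, y: np.ndarray, trend_covariate: np.ndarray,
                         prior_df: float = 4.0) -> np.ndarray:
    """Two-sided p-values of a variance-moderated two-sample t-test, per gene (row).

    The pooled per-gene variance (df d = n1+n2-2) is shrunk toward a lowess
    trend of log variance over the trend covariate (average log expression):
    s~^2 = (d0*s0^2 + d*s^2) / (d0 + d), and the statistic is referred to a
    t distribution with d + d0 degrees of freedom. The lowess fit of
    log(s^2) is bias-corrected by E[log(chi2_d/d)] = digamma(d/2)-log(d/2).
    """
    n1, n2 = x.shape[1], y.shape[1]
    d = n1 + n2 - 2
    diff = x.mean(axis=1) - y.mean(axis=1)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y - y.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d
    log_s2 = np.log(np.maximum(s2, 1e-10))
    fit = lowess(log_s2, trend_covariate, frac=0.4, return_sorted=False)
    s0_sq = np.exp(fit - (digamma(d / 2.0) - np.log(d / 2.0)))
    s2_mod = (prior_df * s0_sq + d * s2) / (prior_df + d)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where(np.isnan(t), 0.0, t)
    return 2.0 * stats.t.sf(np.abs(t), d + prior_df)


def specific_genes(
    em: ExpressionMatrix,
    p_adj_threshold: float = 0.01,
    fold_threshold: float = 2.0,
    prior_df: float = 4.0,
) -> dict[str, pd.DataFrame]:
    """Call organ-specific genes: padj < threshold AND fold > threshold vs every other organ.

    For each (target organ, other organ) pair a per-gene moderated t-test is
    run on log2(RPKM+1) (see :func:`_moderated_t_pvalues`); p-values are
    BH-adjusted across genes within that comparison family. Fold is the ratio
    of mean RPKM (target/other) with a +0.1 pseudocount. Returns one DataFrame
    per organ with columns max_padj, min_fold, specific.
    """
    organs = em.organs
    if len(organs) < 2:
        raise ValueError("need >=2 organs")
    for organ in organs:
        if len(em.samples_of(organ)) < 2:
            raise ValueError(f"organ {organ!r} has <2 replicates; specificity testing impossible")
    logger.info("specificity calling on %d genes, organs=%s (moderated-t/BH stand-in engine)",
                em.counts.shape[0], organs)
    rpkms = em.rpkm_matrix()
    log_rpkm = np.log2(rpkms + 1.0)
    trend = log_rpkm.mean(axis=1).values
    mean_rpkm = {o: rpkms[em.samples_of(o)].mean(axis=1) for o in organs}
    results: dict[str, pd.DataFrame] = {}
    for target in organs:
        x = log_rpkm[em.samples_of(target)].values
        padj_all = []
        fold_all = []
        for other in organs:
            if other == target:
                continue
            y = log_rpkm[em.samples_of(other)].values
            p = _moderated_t_pvalues(x, y, trend, prior_df)
            padj = multipletests(p, method="fdr_bh")[1]
            fold = (mean_rpkm[target] + FOLD_PSEUDOCOUNT) / (mean_rpkm[other] + FOLD_PSEUDOCOUNT)
            padj_all.append(padj)
            fold_all.append(fold.values)
        max_padj = np.max(np.column_stack(padj_all), axis=1)
        min_fold = np.min(np.column_stack(fold_all), axis=1)
        results[target] = pd.DataFrame(
            {
                "max_padj": max_padj,
                "min_fold": min_fold,
                "specific": (max_padj < p_adj_threshold) & (min_fold > fold_threshold),
            },
            index=em.counts.index,
        )
    return results


def most_variable_genes(
    em: ExpressionMatrix,
    rpkm_floor: float = 1.0,
    top_n: int = 500,
) -> list[str]:
    """Top-n genes by variance of log2(RPKM+1) among genes with mean RPKM above the floor."""
    if top_n > em.counts.shape[0]:
        raise ValueError("top_n exceeds gene count")
    rpkms = em.rpkm_matrix()
    expressed = rpkms.index[rpkms.mean(axis=1) > rpkm_floor]
    variances = np.log2(rpkms.loc[expressed] + 1.0).var(axis=1)
    return list(variances.sort_values(ascending=False).index[:top_n])


def read_counts_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    """Counts TSV: columns gene, length, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("gene")
    lengths = df.pop("length")
    return df, lengths


def read_samples_tsv(path) -> pd.DataFrame:
    """Samples TSV: columns sample, organ, replicate."""
    return pd.read_csv(path, sep="\t").set_index("sample")
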