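"""Read-level computations over BED-like mapped reads.

Covers region read counting (bedcov-style, whole-read >=1 bp overlap),
library-size correction to the mean library, per-organ read proportions at a
site, a minimal Poisson sliding-window peak caller used as plumbing for the
two-tier consensus flow, and PCA of a samples x peak-regions affinity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "ReadSet",
    "count_reads",
    "count_reads_many",
    "correct_counts",
    "read_proportions",
    "proportions_table",
    "call_peaks_window",
    "build_affinity_matrix",
    "affinity_pca",
]


@dataclass
class ReadSet:
    """Mapped single-end reads of one sample: fixed-length intervals per chromosome.

    starts[chrom] is a sorted int array of read start positions; every read
    spans [start, start + read_length). library_size is the total read count.
    """

    sample: str
    organ: str
    starts: dict[str, np.ndarray]
    read_length: int = 50

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        self.starts = {c: np.sort(np.asarray(s, dtype=np.int64)) for c, s in self.starts.items()}

    @property
    def library_size(self) -> int:
        return int(sum(len(s) for s in self.starts.values()))

    def to_dataframe(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": c, "start": s, "end": s + self.read_length})
            for c, s in sorted(self.starts.items())
        ]
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample: str, organ: str,
                       read_length: Optional[int] = None) -> "ReadSet":
        if read_length is None:
            lengths = (df["end"] - df["start"]).unique()
            if len(lengths) > 1:
                raise ValueError("reads must have constant length")
            read_length = int(lengths[0]) if len(lengths) else 50
        starts = {c: g["start"].to_numpy() for c, g in df.groupby("chrom")}
        return cls(sample, organ, starts, read_length)

    @classmethod
    def merge(cls, readsets: Sequence["ReadSet"], sample: str = "merged") -> "ReadSet":
        """Pool reads of several libraries (e.g. duplicates) into one set."""
        if not readsets:
            raise ValueError("nothing to merge")
        rl = {r.read_length for r in readsets}
        if len(rl) != 1:
            raise ValueError("read lengths differ between sets")
        chroms = set().union(*(r.starts for r in readsets))
        starts = {
            c: np.concatenate([r.starts.get(c, np.empty(0, dtype=np.int64)) for r in readsets])
            for c in chroms
        }
        return cls(sample, readsets[0].organ, starts, rl.pop())


def count_reads(region: GenomicInterval, readset: ReadSet, mode: str = "overlap") -> int:
    """Number of reads overlapping `region` by >=1 bp (or with 5' end inside it).

    mode='overlap' matches samtools-bedcov-style whole-read-span counting;
    mode='5prime' counts reads whose start lies in [region.start, region.end).
    """
    s = readset.starts.get(region.chrom)
    if s is None or len(s) == 0:
        return 0
    if mode == "overlap":
        lo = np.searchsorted(s, region.start - readset.read_length + 1, side="left")
        hi = np.searchsorted(s, region.end, side="left")
    elif mode == "5prime":
        lo = np.searchsorted(s, region.start, side="left")
        hi = np.searchsorted(s, region.end, side="left")
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    return int(hi - lo)


def count_reads_many(regions: Sequence[GenomicInterval], readset: ReadSet,
                     mode: str = "overlap") -> np.ndarray:
    """Vectorized count_reads over many regions."""
    return np.array([count_reads(r, readset, mode) for r in regions], dtype=np.int64)


def correct_counts(counts: Mapping[str, float], library_sizes: Mapping[str, float]) -> dict[str, float]:
    """Correct raw per-organ counts to the average library size.

    corrected_i = raw_i * mean(library_sizes) / library_size_i — i.e. counts
    rescaled to what a library of average depth would have yielded.
    """
    if set(counts) - set(library_sizes):
        raise ValueError("every organ needs a library size")
    sizes = {o: float(library_sizes[o]) for o in counts}
    if any(v <= 0 for v in sizes.values()):
        raise ValueError("library sizes must be > 0")
    mean_size = float(np.mean(list(sizes.values())))
    return {o: counts[o] * mean_size / sizes[o] for o in counts}


def read_proportions(
    region: GenomicInterval,
    readsets: Sequence[ReadSet],
    mode: str = "overlap",
) -> tuple[dict[str, float], bool]:
    """Per-organ proportion of (library-corrected) reads at a site.

    Returns (proportions, defined). When no organ has any read at the site the
    proportions are NaN and defined=False — the region is flagged, never a
    silent 0/0.
    """
    if len(readsets) < 2:
        raise ValueError("need >=2 organs for proportions")
    raw = {r.organ: float(count_reads(region, r, mode)) for r in readsets}
    sizes = {r.organ: float(r.library_size) for r in readsets}
    corrected = correct_counts(raw, sizes)
    total = sum(corrected.values())
    if total == 0:
        return {o: float("nan") for o in corrected}, False
    return {o: v / total for o, v in corrected.items()}, True


def proportions_table(
    regions: Sequence[GenomicInterval],
    readsets: Sequence[ReadSet],
    mode: str = "overlap",
) -> pd.DataFrame:
    """read_proportions over many regions; one row per region, one column per organ.

    Undefined regions (no reads in any organ) carry NaN proportions and
    defined=False.
    """
    if len(readsets) < 2:
        raise ValueError("need >=2 organs for proportions")
    sizes = {r.organ: float(r.library_size) for r in readsets}
    if any(v <= 0 for v in sizes.values()):
        raise ValueError("library sizes must be > 0")
    mean_size = float(np.mean(list(sizes.values())))
    counts = {r.organ: count_reads_many(regions, r, mode) * (mean_size / sizes[r.organ])
              for r in readsets}
    df = pd.DataFrame(counts, index=pd.RangeIndex(len(regions)))
    total = df.sum(axis=1)
    props = df.div(total, axis=0)
    props.insert(0, "chrom", [r.chrom for r in regions])
    props.insert(1, "start", [r.start for r in regions])
    props.insert(2, "end", [r.end for r in regions])
    props["defined"] = total > 0
    return props


def call_peaks_window(
    readset: ReadSet,
    genome_sizes: Mapping[str, int],
    window_bp: int = 100,
    p_threshold: float = 1e-6,
) -> PeakSet:
    """Minimal Poisson sliding-window peak caller (plumbing, not a SISSRS/MACS clone).

    Tiles each chromosome with non-overlapping windows of `window_bp`, counts
    read 5' starts per window, and calls windows whose count k has upper-tail
    Poisson probability P(X >= k) < p_threshold under a genome-wide uniform
    rate lambda = total_reads / genome_size * window_bp. Adjacent significant
    windows merge into one peak; the max-coverage bp (summit) is recorded in
    the peak name as ``summit:<pos>``.
    """
    if window_bp <= readset.read_length:
        raise ValueError("window_bp must exceed the read length")
    total_reads = readset.library_size
    genome_total = float(sum(genome_sizes.values()))
    if genome_total <= 0:
        raise ValueError("genome size must be positive")
    peaks: list[GenomicInterval] = []
    if total_reads == 0:
        return PeakSet((), tissue=readset.organ)
    lam = total_reads / genome_total * window_bp
    # smallest count k* with sf(k*-1) < p_threshold; guarantees per-window
    # type-I rate <= p_threshold
    k_star = int(stats.poisson.isf(p_threshold, lam)) + 1
    while stats.poisson.sf(k_star - 2, lam) < p_threshold and k_star > 1:
        k_star -= 1
    for chrom, size in genome_sizes.items():
        s = readset.starts.get(chrom)
        if s is None or len(s) == 0:
            continue
        n_windows = int(np.ceil(size / window_bp))
        counts = np.bincount(np.minimum(s // window_bp, n_windows - 1), minlength=n_windows)
        sig = np.flatnonzero(counts >= k_star)
        if sig.size == 0:
            continue
        # merge runs of adjacent significant windows
        breaks = np.flatnonzero(np.diff(sig) > 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [sig.size - 1]])
        for a, b in zip(run_starts, run_ends):
            w0, w1 = int(sig[a]), int(sig[b])
            start = w0 * window_bp
            end = min((w1 + 1) * window_bp, size)
            summit = _summit(s, readset.read_length, start, end)
            peaks.append(GenomicInterval(chrom, start, end, name=f"summit:{summit}"))
    return PeakSet(tuple(peaks), tissue=readset.organ)


def _summit(starts: np.ndarray, read_length: int, start: int, end: int) -> int:
    """Position of maximal read coverage in [start, end) (first bp on ties)."""
    lo = np.searchsorted(starts, start - read_length + 1, side="left")
    hi = np.searchsorted(starts, end, side="left")
    sub = starts[lo:hi]
    cover = np.zeros(end - start + 1, dtype=np.int64)
    a = np.clip(sub - start, 0, end - start)
    b = np.clip(sub + read_length - start, 0, end - start)
    np.add.at(cover, a, 1)
    np.add.at(cover, b, -1)
    coverage = np.cumsum(cover[:-1])
    return start + int(np.argmax(coverage))


def build_affinity_matrix(
    regions: Sequence[GenomicInterval],
    readsets: Sequence[ReadSet],
    correct: bool = True,
) -> pd.DataFrame:
    """Samples x regions matrix of (optionally library-corrected) read counts.

    The region columns are the consensus binding-site intervals; this is the
    binding/affinity matrix used for sample-level ordination.
    """
    labels = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    rows = {rs.sample: count_reads_many(regions, rs).astype(float) for rs in readsets}
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    if correct:
        sizes = np.array([rs.library_size for rs in readsets], dtype=float)
        if np.any(sizes <= 0):
            raise ValueError("library sizes must be > 0")
        mat = mat.mul(sizes.mean() / sizes, axis=0)
    return mat


def affinity_pca(matrix: pd.DataFrame, top_n: Optional[int] = None) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the affinity matrix: log2(x+1), column-centered, SVD.

    Optionally restricts to the top_n most variable regions first. Returns
    (coordinates DataFrame with PC columns, variance-explained fractions
    summing to 1 over the available rank). A matrix with no variance at all is
    rejected.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("need >=3 samples and >=2 regions")
    if (matrix.values < 0).any():
        raise ValueError("affinity matrix must be non-negative")
    x = np.log2(matrix.values + 1.0)
    if top_n is not None and top_n < x.shape[1]:
        order = np.argsort(x.var(axis=0))[::-1][:top_n]
        x = x[:, np.sort(order)]
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("affinity matrix is constant; PCA undefined")
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=matrix.index, columns=cols), pca.explained_variance_ratio_
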