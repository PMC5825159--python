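"""Synthetic multi-tissue ChIP-seq / RNA-seq generator with ground truth.

Emulates a four-tissue embryonic design (two CNS tissues, two endoderm
tissues) in miniature: per-tissue peak sets with tissue-specific,
germ-layer-common and all-common classes; duplicate read libraries as a
uniform Poisson background plus Gaussian pileups over peak midpoints; IUPAC
motif instances planted at controlled offsets from peak centers with partner
motifs at controlled spacings; and a negative-binomial expression matrix in
which organ-specific genes sit next to organ-specific peaks. Every draw is
a deterministic function of the config seed.

The generator also plants *spurious* peaks whose reads appear in only one
replicate library; these are what the replicate-consensus filter must remove.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .intervals import GenomicInterval, PeakSet
from .motifs import IUPAC_CODES, MotifPattern
from .signal import ReadSet

__all__ = [
    "MotifPlan",
    "ExpressionPlan",
    "SimulationConfig",
    "SimulationTruth",
    "derive_rng",
    "simulate_genome",
    "plant_peaks_and_motifs",
    "replicate_peaks",
    "simulate_reads",
    "simulate_expression",
    "write_fasta",
    "write_truth",
    "config_from_file",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: distribution spec: ("fixed", v) | ("uniform", lo, hi) inclusive | ("normal", mu, sigma)
Dist = tuple


def _draw(dist: Dist, rng: np.random.Generator, size: int) -> np.ndarray:
    kind = dist[0]
    if kind == "fixed":
        return np.full(size, int(dist[1]))
    if kind == "uniform":
        return rng.integers(int(dist[1]), int(dist[2]) + 1, size=size)
    if kind == "normal":
        return np.rint(rng.normal(float(dist[1]), float(dist[2]), size=size)).astype(int)
    raise ValueError(f"unknown distribution kind {kind!r}")


@dataclass(frozen=True)
class MotifPlan:
    """One planted motif (center offset from peak center) with an optional partner.

    The partner is planted at a signed start-to-start spacing from the
    primary motif instance.
    """

    name: str = "SOX2"
    pattern: str = "ACAAW"
    offset_dist: Dist = ("uniform", -25, 25)
    partner_name: Optional[str] = None
    partner_pattern: Optional[str] = None
    spacing_dist: Optional[Dist] = None


@dataclass(frozen=True)
class ExpressionPlan:
    """Negative-binomial expression design: organ-specific fold, dispersion, replicates.

    Dispersion is the NB alpha (variance = mu + alpha*mu^2); 0.005 mimics
    clean bulk RNA-seq triplicates of well-expressed genes. Off-target base
    means for planted specific genes are drawn around `specific_base_mean`.
    """

    n_replicates: int = 3
    specific_fold: float = 8.0
    dispersion: float = 0.005
    specific_base_mean: float = 100.0
    #: organ-specific genes beyond the peak-linked ones, drawn from background
    #: genes (specifically expressed but not specifically bound)
    n_specific_extra: int = 40
    background_log_mean: float = np.log(100.0)
    background_log_sd: float = 1.0
    gene_length_range: tuple[int, int] = (500, 5000)


DEFAULT_TISSUES = ("cortex", "spinal_cord", "stomach", "lung")
DEFAULT_GERM_LAYERS = {
    "cortex": "CNS",
    "spinal_cord": "CNS",
    "stomach": "endoderm",
    "lung": "endoderm",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; the seed fully determines all output."""

    genome_length: int = 10_000_000  # bp per chromosome
    n_chromosomes: int = 2
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    germ_layers: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GERM_LAYERS))
    # per-tissue-specific count applies to EACH tissue; common counts are totals
    peaks_per_class: Mapping[str, int] = field(
        default_factory=lambda: {
            "specific": 20,
            "CNS-common": 15,
            "endoderm-common": 15,
            "all-common": 10,
        }
    )
    spurious_per_tissue: int = 10
    peak_width: int = 200
    min_peak_separation: int = 50_000
    reads_per_peak: float = 100.0  # mean fragments per peak per library
    background_rate: float = 0.001  # reads per bp per library
    read_length: int = 50
    n_replicates: int = 2
    motif_plans: tuple[MotifPlan, ...] = (
        MotifPlan("SOX2", "ACAAW", ("uniform", -25, 25), "ZEB1", "CWCACCTG", ("uniform", 10, 14)),
    )
    expression_plan: ExpressionPlan = field(default_factory=ExpressionPlan)
    n_genes: int = 2000
    gene_offset_range: tuple[int, int] = (5_000, 15_000)
    gene_exclusion_bp: int = 25_000  # background genes keep this distance from peak centers
    association_window: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.genome_length < 10 * self.peak_width:
            raise ValueError("genome_length must be >= 10x peak_width")
        if any(v < 0 for v in self.peaks_per_class.values()) or self.spurious_per_tissue < 0:
            raise ValueError("peak counts must be >= 0")
        if self.peak_width <= 0 or self.read_length <= 0:
            raise ValueError("peak_width and read_length must be positive")
        if self.background_rate < 0 or self.reads_per_peak < 0:
            raise ValueError("rates must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need >=1 ChIP replicate")
        for t in self.tissues:
            if t not in self.germ_layers:
                raise ValueError(f"tissue {t!r} lacks a germ-layer assignment")
        for plan in self.motif_plans:
            for pat in (plan.pattern, plan.partner_pattern):
                if pat is not None and len(pat) > self.peak_width:
                    raise ValueError(f"motif {pat!r} longer than peak_width")
        if self.expression_plan.n_replicates < 2:
            raise ValueError("need >=2 expression replicates per organ")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def genome_sizes(self) -> dict[str, int]:
        return {c: self.genome_length for c in self.chrom_names}


def derive_rng(seed: int, *tokens) -> np.random.Generator:
    """Independent named RNG stream from (seed, tokens) via CRC32 hashing.

    Streams are stable under addition of other streams, so e.g. adding a
    replicate never perturbs existing replicates' draws.
    """
    keys = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))


@dataclass
class SimulationTruth:
    """Ground-truth labels for everything planted."""

    peak_intervals: dict[str, GenomicInterval]  # peak name -> interval
    peak_class_labels: dict[str, str]  # peak name -> class (spurious excluded)
    peak_tissues: dict[str, tuple[str, ...]]  # peak name -> tissues carrying it
    spurious: dict[str, list[tuple[str, int]]]  # tissue -> [(peak name, replicate idx)]
    planted_spacings: list[tuple[str, str, str, int]]  # (peak, motif, partner, spacing)
    planted_offsets: list[tuple[str, str, int]]  # (peak, motif, start offset in peak)
    specific_genes: dict[str, set[str]]  # organ -> gene ids
    peak_gene_links: dict[str, str]  # peak name -> gene id
    gene_annotation: pd.DataFrame  # gene, chrom, tss, strand
    config: SimulationConfig

    def class_of(self, name: str) -> Optional[str]:
        return self.peak_class_labels.get(name)


def simulate_genome(config: SimulationConfig) -> dict[str, np.ndarray]:
    """I.i.d. uniform-base chromosomes as uint8 arrays of ACGT byte codes.

    Motif planting mutates these arrays in place later; everything is
    reproducible from the config seed.
    """
    genome = {}
    for chrom in config.chrom_names:
        rng = derive_rng(config.seed, "genome", chrom)
        genome[chrom] = rng.choice(_BASES, size=config.genome_length)
    return genome


def genome_slice(genome: Mapping[str, np.ndarray], chrom: str, start: int, end: int) -> str:
    return genome[chrom][start:end].tobytes().decode("ascii")


def peak_sequences(genome: Mapping[str, np.ndarray], peaks: PeakSet) -> dict[str, str]:
    """Extract per-peak sequences keyed by peak name (falling back to coordinates)."""
    out = {}
    for iv in peaks:
        key = iv.name if iv.name != "." else f"{iv.chrom}:{iv.start}-{iv.end}"
        out[key] = genome_slice(genome, iv.chrom, iv.start, iv.end)
    return out


def _expand_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[ch])) for ch in pattern)


def _place_locations(config: SimulationConfig, n: int, rng: np.random.Generator
                     ) -> list[tuple[str, int]]:
    """n peak-center locations, >= min_peak_separation apart, clear of chrom edges."""
    margin = config.peak_width + config.gene_offset_range[1] + 5_000
    slots: list[tuple[str, int]] = []
    for chrom in config.chrom_names:
        usable = config.genome_length - 2 * margin
        k = usable // config.min_peak_separation
        for j in range(int(k)):
            slots.append((chrom, margin + j * config.min_peak_separation))
    if n > len(slots):
        raise ValueError(
            f"genome too small: {n} peak locations requested, {len(slots)} slots available"
        )
    idx = rng.choice(len(slots), size=n, replace=False)
    # jitter kept small relative to the slot spacing so designated genes
    # (<= gene_offset_range[1] away) are always nearest their own peak
    jitter = rng.integers(0, max(1, config.min_peak_separation // 8), size=n)
    return [(slots[i][0], int(slots[i][1] + j)) for i, j in zip(idx, jitter)]


def plant_peaks_and_motifs(
    genome: dict[str, np.ndarray], config: SimulationConfig
) -> tuple[dict[str, PeakSet], SimulationTruth]:
    """Plant class-structured peaks, motif instances, and the gene annotation.

    Mutates `genome` in place to embed motif instances. Returns the
    per-tissue true PeakSets (spurious peaks excluded) and the full truth.
    Every planted peak carries its primary motif instance at the drawn
    offset; partner instances follow at the drawn spacing. Each non-spurious
    peak gets a designated gene 5-20 kb away; genes at tissue-specific peaks
    are that organ's specific genes. Background genes stay >=
    gene_exclusion_bp from every peak center so nearest-TSS assignment is
    unambiguous.
    """
    for plan in config.motif_plans:
        MotifPattern(plan.name, plan.pattern)  # validates IUPAC
        if plan.partner_pattern is not None:
            MotifPattern(plan.partner_name or "partner", plan.partner_pattern)
            if plan.spacing_dist is None:
                raise ValueError(f"partner {plan.partner_name!r} needs a spacing_dist")

    tissues = list(config.tissues)
    layers = dict(config.germ_layers)
    layer_members = {
        layer: tuple(t for t in tissues if layers[t] == layer)
        for layer in sorted(set(layers[t] for t in tissues))
    }
    # build the location plan: (class label, carrying tissues)
    plan_entries: list[tuple[str, tuple[str, ...]]] = []
    for cls, count in config.peaks_per_class.items():
        if cls == "specific":
            for t in tissues:
                plan_entries += [(f"specific:{t}", (t,))] * count
        elif cls == "all-common":
            plan_entries += [("all-common", tuple(tissues))] * count
        elif cls.endswith("-common"):
            layer = cls[: -len("-common")]
            if layer not in layer_members:
                raise ValueError(f"unknown germ layer in class {cls!r}")
            plan_entries += [(cls, layer_members[layer])] * count
        else:
            raise ValueError(f"unknown peak class {cls!r}")
    n_spurious = config.spurious_per_tissue * len(tissues)

    rng = derive_rng(config.seed, "plant")
    locations = _place_locations(config, len(plan_entries) + n_spurious, rng)
    half = config.peak_width // 2

    peak_intervals: dict[str, GenomicInterval] = {}
    class_labels: dict[str, str] = {}
    peak_tissues: dict[str, tuple[str, ...]] = {}
    spurious: dict[str, list[tuple[str, int]]] = {t: [] for t in tissues}
    per_tissue: dict[str, list[GenomicInterval]] = {t: [] for t in tissues}

    class_codes = {cls: i + 1 for i, cls in enumerate(sorted({c for c, _ in plan_entries}))}
    for i, (cls, carriers) in enumerate(plan_entries):
        chrom, center = locations[i]
        name = f"pk{i:04d}"
        iv = GenomicInterval(chrom, center - half, center + half, name, class_codes[cls])
        peak_intervals[name] = iv
        class_labels[name] = cls
        peak_tissues[name] = carriers
        for t in carriers:
            per_tissue[t].append(iv)
    for j in range(n_spurious):
        chrom, center = locations[len(plan_entries) + j]
        t = tissues[j % len(tissues)]
        rep = (j // len(tissues)) % config.n_replicates
        name = f"sp{j:04d}"
        iv = GenomicInterval(chrom, center - half, center + half, name, 0)
        peak_intervals[name] = iv
        peak_tissues[name] = (t,)
        spurious[t].append((name, rep))

    # motif planting into the genome (true peaks only)
    planted_spacings: list[tuple[str, str, str, int]] = []
    planted_offsets: list[tuple[str, str, int]] = []
    mrng = derive_rng(config.seed, "motifs")
    for name, cls in class_labels.items():
        iv = peak_intervals[name]
        center = iv.center
        for plan in config.motif_plans:
            L = len(plan.pattern)
            offset = int(_draw(plan.offset_dist, mrng, 1)[0])
            start = center + offset - L // 2
            word = _expand_iupac(plan.pattern, mrng)
            _write_word(genome, iv.chrom, start, word, iv)
            planted_offsets.append((name, plan.name, start - iv.start))
            if plan.partner_pattern is not None:
                spacing = int(_draw(plan.spacing_dist, mrng, 1)[0])
                pstart = start + spacing
                pword = _expand_iupac(plan.partner_pattern, mrng)
                _write_word(genome, iv.chrom, pstart, pword, iv)
                planted_spacings.append((name, plan.name, plan.partner_name, spacing))

    # gene annotation: one designated gene per true peak + background genes
    grng = derive_rng(config.seed, "genes")
    gene_rows = []
    specific_genes: dict[str, set[str]] = {t: set() for t in tissues}
    peak_gene_links: dict[str, str] = {}
    for name, cls in class_labels.items():
        iv = peak_intervals[name]
        d = int(grng.integers(config.gene_offset_range[0], config.gene_offset_range[1] + 1))
        sign = int(grng.choice([-1, 1]))
        gene = f"g_{name}"
        gene_rows.append(
            {"gene": gene, "chrom": iv.chrom, "tss": iv.center + sign * d,
             "strand": "+" if sign > 0 else "-"}
        )
        peak_gene_links[name] = gene
        if cls.startswith("specific:"):
            specific_genes[cls.split(":", 1)[1]].add(gene)
    n_background = config.n_genes - len(gene_rows)
    if n_background < 0:
        raise ValueError("n_genes smaller than the number of designated peak genes")
    centers_by_chrom: dict[str, np.ndarray] = {}
    for iv in peak_intervals.values():
        centers_by_chrom.setdefault(iv.chrom, [])
    for iv in peak_intervals.values():
        centers_by_chrom[iv.chrom].append(iv.center)
    centers_by_chrom = {c: np.sort(np.array(v)) for c, v in centers_by_chrom.items()}
    placed = 0
    while placed < n_background:
        m = (n_background - placed) * 2
        chroms = grng.choice(config.n_chromosomes, size=m)
        pos = grng.integers(0, config.genome_length, size=m)
        for ci, p in zip(chroms, pos):
            chrom = config.chrom_names[int(ci)]
            cts = centers_by_chrom.get(chrom)
            if cts is not None and len(cts):
                k = np.searchsorted(cts, p)
                near = min(
                    abs(int(cts[j]) - int(p)) for j in (k - 1, k) if 0 <= j < len(cts)
                )
                if near < config.gene_exclusion_bp:
                    continue
            gene_rows.append(
                {"gene": f"bg{placed:05d}", "chrom": chrom, "tss": int(p), "strand": "+"}
            )
            placed += 1
            if placed == n_background:
                break
    annotation = pd.DataFrame(gene_rows, columns=["gene", "chrom", "tss", "strand"])

    # extra organ-specific genes unlinked to any peak: specifically expressed
    # but not specifically bound, as most DE genes are in real tissue
    n_extra = config.expression_plan.n_specific_extra
    if n_extra > 0:
        bg_ids = [r["gene"] for r in gene_rows if r["gene"].startswith("bg")]
        need = n_extra * len(tissues)
        if need > len(bg_ids):
            raise ValueError("not enough background genes for n_specific_extra")
        chosen = grng.choice(len(bg_ids), size=need, replace=False)
        for j, t in enumerate(tissues):
            specific_genes[t].update(bg_ids[k] for k in chosen[j * n_extra:(j + 1) * n_extra])

    peaksets = {
        t: PeakSet(tuple(per_tissue[t]), tissue=t) for t in tissues
    }
    truth = SimulationTruth(
        peak_intervals=peak_intervals,
        peak_class_labels=class_labels,
        peak_tissues=peak_tissues,
        spurious=spurious,
        planted_spacings=planted_spacings,
        planted_offsets=planted_offsets,
        specific_genes=specific_genes,
        peak_gene_links=peak_gene_links,
        gene_annotation=annotation,
        config=config,
    )
    logger.info(
        "planted %d true peaks (%d classes), %d spurious, %d genes (seed=%d)",
        len(class_labels), len(class_codes), n_spurious, len(annotation), config.seed,
    )
    return peaksets, truth


def _write_word(genome: dict[str, np.ndarray], chrom: str, start: int, word: str,
                peak: GenomicInterval) -> None:
    if start < peak.start or start + len(word) > peak.end:
        raise ValueError(
            f"planted motif [{start}, {start + len(word)}) escapes peak "
            f"[{peak.start}, {peak.end}); narrow the offset/spacing distributions"
        )
    genome[chrom][start:start + len(word)] = np.frombuffer(word.encode(), dtype=np.uint8)


def replicate_peaks(truth: SimulationTruth, tissue: str, replicate: int) -> PeakSet:
    """True peaks of a tissue plus the spurious peaks assigned to this replicate."""
    ivs = [truth.peak_intervals[n] for n, ts in truth.peak_tissues.items()
           if tissue in ts and n in truth.peak_class_labels]
    ivs += [truth.peak_intervals[n] for n, r in truth.spurious.get(tissue, []) if r == replicate]
    return PeakSet(tuple(ivs), tissue=tissue, replicate=str(replicate))


def simulate_reads(
    peaks: PeakSet,
    genome_sizes: Mapping[str, int],
    config: SimulationConfig,
    replicate_id,
    sample: Optional[str] = None,
) -> ReadSet:
    """One read library: uniform Poisson background + Gaussian pileups over peaks.

    Background reads fall anywhere (including inside peaks). Peak fragments
    have their centers drawn Normal(peak midpoint, peak_width/6); the read
    strand is uniform and the 50 bp read covers the corresponding half of the
    fragment. The RNG stream is derived from (seed, tissue, replicate_id).
    """
    if config.background_rate <= 0:
        raise ValueError("background_rate must be > 0")
    rng = derive_rng(config.seed, "reads", peaks.tissue, replicate_id)
    rl = config.read_length
    starts: dict[str, list[np.ndarray]] = {c: [] for c in genome_sizes}
    for chrom, size in genome_sizes.items():
        n_bg = rng.poisson(config.background_rate * size)
        starts[chrom].append(rng.integers(0, max(1, size - rl), size=n_bg))
    sigma = config.peak_width / 6.0
    for iv in peaks:
        n = rng.poisson(config.reads_per_peak)
        if n == 0:
            continue
        centers = rng.normal(iv.center, sigma, size=n)
        strand_minus = rng.random(size=n) < 0.5
        s = np.rint(np.where(strand_minus, centers, centers - rl)).astype(np.int64)
        s = np.clip(s, 0, genome_sizes[iv.chrom] - rl)
        starts[iv.chrom].append(s)
    merged = {c: np.concatenate(v) if v else np.empty(0, dtype=np.int64)
              for c, v in starts.items()}
    name = sample or f"{peaks.tissue}_rep{replicate_id}"
    return ReadSet(name, peaks.tissue, merged, read_length=rl)


def simulate_expression(truth: SimulationTruth, config: SimulationConfig) -> ExpressionMatrix:
    """NB gene x sample counts; organ-specific genes are `specific_fold` higher in their organ.

    Counts are gamma-Poisson with dispersion alpha (variance mu + alpha mu^2).
    Planted specific genes draw their off-target base mean near
    `specific_base_mean`; all other genes draw log-normal base means.
    """
    plan = config.expression_plan
    if plan.n_replicates < 2:
        raise ValueError("need >=2 replicates per organ")
    genes = list(truth.gene_annotation["gene"])
    organs = list(config.tissues)
    rng = derive_rng(config.seed, "expression")
    specific_of = {}
    for organ, gset in truth.specific_genes.items():
        for g in gset:
            specific_of[g] = organ
    base = np.where(
        [g in specific_of for g in genes],
        plan.specific_base_mean * rng.lognormal(0.0, 0.25, size=len(genes)),
        rng.lognormal(plan.background_log_mean, plan.background_log_sd, size=len(genes)),
    )
    lengths = rng.integers(plan.gene_length_range[0], plan.gene_length_range[1] + 1,
                           size=len(genes))
    columns = {}
    sample_rows = []
    for organ in organs:
        mu = base.copy()
        is_mine = np.array([specific_of.get(g) == organ for g in genes])
        mu[is_mine] *= plan.specific_fold
        for r in range(plan.n_replicates):
            srng = derive_rng(config.seed, "expression", organ, r)
            if plan.dispersion > 0:
                lam = srng.gamma(1.0 / plan.dispersion, mu * plan.dispersion)
            else:
                lam = mu
            columns[f"{organ}_r{r + 1}"] = srng.poisson(lam)
            sample_rows.append({"sample": f"{organ}_r{r + 1}", "organ": organ,
                                "replicate": r + 1})
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    info = pd.DataFrame(sample_rows).set_index("sample")
    return ExpressionMatrix(counts, pd.Series(lengths, index=counts.index), info)


def write_fasta(genome: Mapping[str, np.ndarray], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            arr = genome[chrom]
            for i in range(0, len(arr), width):
                fh.write(arr[i:i + width].tobytes().decode("ascii"))
                fh.write("\n")


def read_fasta(path) -> dict[str, np.ndarray]:
    genome: dict[str, list[bytes]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                current = line[1:].split()[0]
                genome[current] = []
            elif line and current is not None:
                genome[current].append(line.encode())
    return {c: np.frombuffer(b"".join(parts), dtype=np.uint8) for c, parts in genome.items()}


def write_truth(truth: SimulationTruth, outdir) -> dict[str, Path]:
    """Write planted peaks (BED6, score=class code), truth tables, and gene annotation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    bed = outdir / "planted_peaks.bed"
    with open(bed, "w") as fh:
        for name, iv in sorted(truth.peak_intervals.items()):
            code = int(iv.score or 0)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{code}\t.\n")
    files["planted_peaks.bed"] = bed
    classes = outdir / "planted_classes.tsv"
    pd.DataFrame(
        [{"peak": n, "class": c, "tissues": ",".join(truth.peak_tissues[n])}
         for n, c in sorted(truth.peak_class_labels.items())]
    ).to_csv(classes, sep="\t", index=False)
    files["planted_classes.tsv"] = classes
    spac = outdir / "planted_spacings.tsv"
    pd.DataFrame(truth.planted_spacings,
                 columns=["peak", "motif", "partner", "spacing"]).to_csv(
        spac, sep="\t", index=False)
    files["planted_spacings.tsv"] = spac
    ann = outdir / "gene_annotation.tsv"
    truth.gene_annotation.to_csv(ann, sep="\t", index=False)
    files["gene_annotation.tsv"] = ann
    spec = outdir / "specific_genes.tsv"
    pd.DataFrame(
        [{"organ": o, "gene": g} for o, gs in sorted(truth.specific_genes.items())
         for g in sorted(gs)]
    ).to_csv(spec, sep="\t", index=False)
    files["specific_genes.tsv"] = spec
    logger.info("truth written to %s (seed=%d)", outdir, truth.config.seed)
    return files


def config_from_file(path) -> SimulationConfig:
    """Load a SimulationConfig from a plain-text key: value (YAML mapping) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must be a flat key-value mapping")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "motif_plans" in data:
        data["motif_plans"] = tuple(
            MotifPlan(**{**p, "offset_dist": tuple(p.get("offset_dist", ("fixed", 0))),
                         "spacing_dist": tuple(p["spacing_dist"]) if p.get("spacing_dist") else None})
            for p in data["motif_plans"]
        )
    if "expression_plan" in data:
        ep = dict(data["expression_plan"])
        if "gene_length_range" in ep:
            ep["gene_length_range"] = tuple(ep["gene_length_range"])
        data["expression_plan"] = ExpressionPlan(**ep)
    for key in ("tissues",):
        if key in data:
            data[key] = tuple(data[key])
    if "gene_offset_range" in data:
        data["gene_offset_range"] = tuple(data["gene_offset_range"])
    return SimulationConfig(**data)
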