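# Methods

This note documents the models, defaults and numerical choices behind
`crossbind`, and what the simulation-based validation does and does not show
about real data.

## Coordinate and overlap conventions

All intervals are 0-based half-open throughout the library; BED is itself
0-based half-open, so no conversion happens at I/O. Overlap means ≥1 shared
base by default (`min_overlap_bp` is configurable everywhere it matters);
abutting half-open intervals do not overlap. Peak centers are
`floor((start+end)/2)`, and "center ± e" produces `[c−e, c+e)` of width
exactly `2e` — the half-open floor convention resolves the inherent ambiguity
of "±e bp" between widths `2e` and `2e+1`, and is applied consistently
(consensus peaks are exactly 200 bp except when clipped at a chromosome
start, which the simulator's placement margins make impossible in tests).

## Two-tier consensus peak calling

The plumbing caller tiles the genome with non-overlapping windows (default
100 bp, which must exceed the 50 bp read length), counts read 5′ starts per
window, and calls windows whose count exceeds the upper-tail Poisson
threshold at `p` under a genome-wide uniform rate λ = reads/bp × window.
Adjacent significant windows merge; the maximum-coverage bp is recorded as
the summit. There is no local background, duplicate filtering, or
strand-shift model — published callers own that territory; this caller
exists so the *consensus logic* can be exercised end to end on simulated
reads.

The two-tier flow mirrors standard practice with duplicate ChIP libraries:
call once on the pooled duplicates at a stringent threshold (default
p = 1e-7) and once per replicate at a lenient one (default p = 1e-6), then
keep pooled calls supported by every replicate and standardize to
center ± 100 bp. The replicate threshold is deliberately strict in absolute
terms: at the simulation's background (0.001 reads/bp, λ = 0.1 per window)
the discrete Poisson threshold admits a false window only ~3×10⁻⁸ of the
time, so the expected number of background windows that could rescue a
single-replicate spurious peak through the consensus filter is ~0.03 per
library — the filter's specificity is then a property of the design rather
than luck. An optional exclusion set drops pooled calls in known
high-background regions; none ships by default.

## Overlap classification (Venn logic)

Each peak is labeled by the exact set of tissues whose peak sets it overlaps;
the label set maps to `specific:<tissue>` (own tissue only), `<layer>-common`
(all overlapping tissues in one germ layer), `both-germ-layers` (spans
layers, not every tissue), or `all-common` (every tissue). Because overlap
counts are not symmetric between sets of different sizes, counts are reported
both per reference tissue and on the merged union of all tissues (one merged
region = one countable unit); the union convention is the headline number.
Union regions are maximal ≥1 bp-overlap runs, so a chain of pairwise
overlapping peaks merges into one region even if its ends do not overlap
each other.

## Motif scanning and statistics

Motifs are short IUPAC consensi (e.g. SOX2 `ACAAW`, ZEB1 `CWCACCTG`, OTX1
`TAATCCCC`, FOXA1 `GTAAAYA`). Scanning compiles each code position to an
explicit `[ACGT…]` class inside a zero-width lookahead so overlapping
occurrences are all reported; minus-strand hits come from scanning the
reverse-complement pattern and are reported with the + strand coordinate of
the match span. An `N` in the scanned sequence matches nothing — including a
pattern `N` — because an unknown base cannot support a motif call. There is
no PWM scoring and no de novo discovery; the scanner is exact by
construction and is tested for set equality against an independent
window-by-window oracle.

**Central enrichment** reduces each peak to its best hit (match center
nearest the peak center) and tests the count of central best hits against
Bin(n, p0), p0 = window/(W−L+1), upper tail. This fixed-window binomial is a
deliberate simplification of likelihood-ratio window-scanning tools: it
keeps the same monotone relationship ("more central hits → smaller p") with
an exactly calibrated null, which the suite verifies (type-I at α = 0.05
stays in [0.03, 0.07] under uniform placement; the discrete binomial makes
it slightly conservative). Best-hit selection concentrates multi-hit peaks
toward the center, so the null calibration statement applies to one-hit
peaks; planted-signal detection is tested separately.

**Spacing** is start-to-start on the + strand axis by default, with the
convention (`start`/`center`) and a strand-aware orientation mode exposed as
flags, since reasonable conventions differ. All (A,B) pairs in a peak are
counted, not just nearest pairs. The histogram's rolling mean is centered,
window 5, truncated at the support edges; the mode breaks ties toward the
smaller spacing; the median is the plain sample median of all pair spacings.
Empty profiles (no co-occurring peak) are returned flagged, never silently
as zeros.

## Read-level statistics

Region read counting uses whole-read-span ≥1 bp overlap (bedcov-style), with
a 5′-end-in-region mode behind a flag. Library correction rescales each
organ's count by mean(library sizes)/size; per-organ proportions divide
corrected counts by their sum at the site and are therefore invariant under
uniform rescaling of all libraries. Sites with no reads anywhere are flagged
undefined rather than reported as 0/0. The affinity matrix (samples ×
consensus regions, corrected counts) is ordinated by PCA on log2(x+1) with
column centering and full SVD; log2(x+1) is a pragmatic variance-stabilizer
for count data, and the top-N most-variable-region filter defaults to "all".

## Expression: RPKM and the specificity rule

RPKM = 10⁹·count/(length·total). A gene is organ-specific iff against
*every* other organ it shows BH-adjusted p < 0.01 and fold change > 2 (ratio
of mean RPKM with a +0.1 pseudocount; the raw ratio, not a shrunken
log-fold-change, which is documented as a modeling choice). The test engine
is a stand-in for a negative-binomial GLM with dispersion shrinkage: a
two-sample t on log2(RPKM+1) whose pooled per-gene variance (df d = n₁+n₂−2)
is shrunk toward a lowess trend over average log expression,
s̃² = (d₀s₀² + d s²)/(d₀+d) with prior df d₀ = 4, referred to t(d+d₀). The
lowess fit of log s² is bias-corrected by E[log(χ²_d/d)] = ψ(d/2) − log(d/2).
An unmoderated test at n = 3 per group is dominated by sample-variance noise
and cannot reach the power a dispersion-shrinking GLM has at these
thresholds; the moderation is the standard small-sample remedy and the
thresholds — not the engine — are the contract. BH runs within each (target
organ vs other organ) family across genes. The fold gate makes the null
false-call rate effectively zero, well inside the α bound the suite asserts.

## Peak–gene association and enrichment

Each peak is assigned to the single gene with the nearest TSS (peak-center
to TSS distance; gene strand ignored), unassigned beyond 500 kb; equidistant
ties break to the lexicographically smaller gene id so runs are
deterministic. This single-nearest rule is a documented simplification of
multi-gene regulatory-domain schemes; the window is configurable. A gene is
"bound" iff ≥1 peak is assigned to it.

The binding × expression contingency test partitions a gene universe
(default: all annotated genes; optionally genes with mean RPKM > 1) into
bound/not × specific/not and applies the Yates-corrected chi-squared,
`Σ(max(|O−E|−½,0))²/E` on 1 df. The floor on the correction matches R's
`chisq.test`/`prop.test` behavior; a popular Python implementation instead
moves observations 0.5 toward expectation and can overshoot when |O−E| < ½,
which is why the statistic is authored here and checked against a hand
oracle. The correction makes the test conservative at small expected counts
— exactly the regime of the mismatched tissue pairs — and negligible at
large counts, where the suite verifies p-value uniformity under an unlinked
null (balanced-margin tables, overlap drawn from its exact hypergeometric
law). The enrichment score |A∩B|/(|A|·|B|) is reported alongside; GO-style
fold enrichment is (hits/|set|)/(term/|universe|) with per-term
normalization by the union of all sets, and terms with no union hits are
flagged undefined.

## The simulator: what it emulates, and what it does not

Defaults model a four-tissue, two-germ-layer embryonic design in miniature:

- **Genome** — 2 chromosomes × 10 Mb of i.i.d. uniform bases. Real genomes
  have repeats, GC structure and mappability bias; none are modeled, so
  motif background rates are slightly lower than in real DNA.
- **Peaks** — 20 specific per tissue, 15 + 15 layer-common, 10 all-common,
  all 200 bp, centers ≥ 50 kb apart (placement on a jittered grid). Plus 10
  spurious peaks per tissue whose reads appear in one replicate only — the
  negative control for the consensus filter.
- **Reads** — 50 bp single-end; uniform Poisson background at 0.001
  reads/bp per library (background may fall inside peaks); per peak,
  Poisson(100) fragments per library with centers Normal(midpoint, width/6)
  so the caller sees a summit; strand uniform. No PCR duplicates, no
  sequencing error, no fragment-length model.
- **Motifs** — a SOX2 `ACAAW` instance per true peak with its center offset
  uniform ±25 bp from the peak center, and a ZEB1 `CWCACCTG` partner at a
  start-to-start spacing uniform in 10–14 bp. Planting writes the expansion
  into the genome, so scans also encounter chance background occurrences —
  spacing histograms therefore contain a realistic background pedestal.
- **Genes** — 2000 genes; each true peak gets a designated gene 5–15 kb
  away, and background genes stay ≥25 kb from every peak center, so
  nearest-TSS assignment is structurally unambiguous and mismatched
  (binding, expression) tissue pairs are exactly null rather than slightly
  depleted. Genes at tissue-specific peaks are that organ's specific genes;
  40 additional unlinked specific genes per organ model the majority of DE
  genes that are not specifically bound.
- **Expression** — gamma-Poisson (NB) counts, dispersion 0.005 (clean bulk
  triplicates of well-expressed genes), organ-specific fold 8, off-target
  base mean ~100 counts, triplicate libraries, gene lengths uniform
  0.5–5 kb.

Every stream derives from `(seed, name…)` via CRC32-keyed `SeedSequence`, so
output is bit-reproducible and adding a replicate never perturbs existing
ones. Problem sizes (20 Mb genome, 160 peak locations, 2000 genes, 1000-null
calibrations) were chosen so the complete validation runs comfortably on a
laptop while keeping every statistical check well-powered.

Passing on this simulator demonstrates correctness of the *logic and the
statistics* — it does not demonstrate robustness to crosslinking artifacts,
blacklist regions, mappability holes, batch effects, or contaminating cell
populations, none of which are generated.

## Degenerate inputs and tie-breaks (summary)

Empty replicate list, zero library size, genome of length 0, organs with a
single replicate, empty gene sets/universe, zero expected contingency cells,
and invalid IUPAC characters all raise with specific messages; empty peak
sets, no-hit peaks, no co-occurring motif pairs, and no-read regions return
flagged empty/undefined results instead of raising. Mode ties → smallest
spacing; nearest-gene ties → smallest gene id; summit ties → leftmost bp.
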