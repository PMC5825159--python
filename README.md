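# crossbind

Comparative multi-tissue transcription-factor ChIP-seq / RNA-seq analysis:
replicate-consensus peak construction, cross-tissue binding-site overlap
classification, IUPAC consensus-motif scanning with central-enrichment and
spacing statistics, peak-to-gene association, and binding × expression
specificity enrichment — together with a ground-truthed synthetic-data
generator that plants exactly the structure these analyses assume.

## Who this is for

A transcription factor such as SOX2 is active in progenitor cells of several
organs from different germ layers (e.g. cortex and spinal cord from the
neuroectoderm; stomach and lung/esophagus from the endoderm). Given duplicate
ChIP-seq libraries per tissue and replicate RNA-seq per organ, the questions
are: where does the factor bind in each tissue, how much of that binding is
tissue-specific versus germ-layer-common versus universal, which partner-motif
arrangements distinguish the specific sites, and is tissue-specific binding
enriched near tissue-specifically expressed genes? `crossbind` implements that
entire analysis chain as a reusable, tested library with a thin CLI, and ships
a simulator so every stage can be validated against known ground truth.

## The statistics at the core

- **Consensus peaks.** Peaks called from the merged duplicates (stringent
  threshold) are kept only if they overlap (≥1 bp) a peak called in *every*
  individual replicate (lenient threshold); each survivor is standardized to
  its center ±100 bp, so all consensus peaks are exactly 200 bp.
- **Overlap classes.** Each peak (or merged-union region) is labeled by the
  set of tissues binding it: `specific:<tissue>`, `<layer>-common`,
  `both-germ-layers`, or `all-common` — the multi-set Venn logic.
- **Central enrichment.** Per peak, the best motif hit is the one whose match
  center is nearest the peak center; with *n* peaks carrying a hit and *k*
  best hits inside a central window of *w* bp, the p-value is the upper
  binomial tail `P(X ≥ k), X ~ Bin(n, p0)`, `p0 = w/(W − L + 1)` for peak
  width *W* and motif length *L*.
- **Motif spacing.** For two motifs co-occurring in a peak, every hit pair
  contributes a signed start-to-start distance; the histogram is reported with
  a centered 5-bp rolling mean, its median, and its mode.
- **RPKM and organ specificity.** `rpkm = 10⁹ · count / (length · total)`.
  A gene is organ-specific iff, against *every* other organ, adjusted
  p < 0.01 (BH within each pairwise comparison family) *and* fold change of
  mean RPKM > 2. The test engine is a declared stand-in for an NB GLM: a
  moderated t-test on log2(RPKM+1) with lowess-trend variance shrinkage.
- **Enrichment score and test.** For gene sets A, B in a universe of N genes:
  `score = |A∩B| / (|A|·|B|)`, significance from the Yates
  continuity-corrected chi-squared on the 2×2 partition of the universe
  (equivalent to a two-proportion test with continuity correction),
  `X² = Σ (max(|O−E|−½, 0))² / E` on 1 df.
- **GO-style fold enrichment.** `fold = (hits/|set|)/(term/|universe|)`,
  normalized per term by the same fold computed on the union of all sets.

## Worked example

Run the whole pipeline on the default simulation (4 tissues, 2 germ layers,
20 tissue-specific + 15 CNS-common + 15 endoderm-common + 10 all-common
planted peaks, 10 single-replicate spurious peaks per tissue, SOX2 `ACAAW`
motifs planted near peak centers with a ZEB1 `CWCACCTG` partner 10–14 bp
downstream, and a negative-binomial expression matrix with 60 specific genes
per organ):

```python
from crossbind import pipeline
bundle = pipeline.run_all(pipeline.RunConfig(outdir="results/demo"))
print(pipeline.report(bundle))
```

prints (seed 0):

```
## Consensus peaks per tissue
  cortex: 45 peaks
  lung: 45 peaks
  spinal_cord: 45 peaks
  stomach: 45 peaks

## Overlap classes (merged-union convention)
  CNS-common: 15
  all-common: 10
  endoderm-common: 15
  specific:cortex: 20
  ...

## Central motif enrichment
  SOX2: 160/180 central (88.9%), p = 2.2e-27

## Motif spacing
  SOX2-ZEB1: mode 10 bp, median 12.0 bp over 288 pairs

## Binding x expression specificity enrichment
  bind=cortex       expr=cortex       score=0.00741 chi2=257.35 p=6.48e-58
  bind=cortex       expr=lung         score=0 chi2=0.56 p=0.452
  ...
```

Reading this: every tissue recovers its 45 planted peaks (20 specific plus
its share of the common classes) at exactly 200 bp; the spurious
single-replicate peaks are all removed by the consensus filter; the planted
overlap classes are recovered exactly on the union convention; the planted
SOX2 motif is centrally enriched (88.9% of best hits within the central
100 bp, binomial p ≈ 1e-27); the SOX2–ZEB1 spacing mode/median sit in the
planted 10–14 bp band; and only matched (binding tissue = expression tissue)
pairs are significant in the enrichment matrix — mismatched pairs stay at
chance.

The same stages are available as CLI subcommands on files
(`crossbind simulate | callpeaks | consensus | venn | proportions | scan |
central | spacing | express | assoc | pca | run-all | report`); see
`crossbind --help`.

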