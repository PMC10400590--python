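# Methods

This note documents the models behind `dropmet`, the parameters that
matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was open.

## Droplet-experiment model

Cell loading is Poisson: with `N` input cells assigned uniformly to
`round(N/λ)` droplets, occupancy is Binomial(N, 1/n) ≈ Poisson(λ).
The default λ = −ln 0.9 makes 10% of droplets non-empty, with
P(exactly two cells) = 0.4995%.  Droplet counts use V = (π/6)d³ with
lengths in μm, volumes in pL and flows in μl/min; only the aqueous
(dispersed) phase counts toward droplet volume.  Bead pairing applies
two independent Bernoulli thinnings — bead occupancy (default 0.07)
and fusion efficiency (default 0.80) — so the expected barcoded-cell
yield is `n_pairings × P(≥1 cell) × occupancy × efficiency`.  Beads
fused with empty droplets, and unfused beads, become noise barcodes
that still appear in the library with background reads.

## Synthetic genomes and methylomes

Genomes are i.i.d. base draws at a set GC fraction (default 0.42),
several contigs plus one fully unmethylated spike-in contig (default
48 kb, phage-sized) used for conversion-rate QC.  Two-species genomes
tag contigs alternately, giving disjoint per-species contig sets.

Methylomes are bimodal over CpGs: a CpG pair (both strands share the
state) is methylated with local probability w and carries per-read
methylation probability 0.97 when methylated, 0.02 otherwise; non-CpG
cytosines get a flat probability equal to the global mCH target.  The
methylated fraction w is not i.i.d. across the genome: each 50 kb
window receives a Gaussian offset with a component shared by all cell
types (sd 0.03; conserved domain structure) and a component drawn per
type (sd 0.04; regional cell-type identity).  The type-specific
component is what survives normalization by the global level and
drives clustering — with i.i.d. CpG states the between-type bin
signal would be smaller than counting noise at realistic depth, which
does not match how real cell types separate on binned methylomes.
Per-pair state draws use one shared uniform across types ("nested"
draws), so types specified identically realise identical methylomes
and types with close targets share most of their methylome.  After
planting DMRs and domain noise, a small number of CpG pairs outside
any DMR are flipped to bring the realised genome-wide mean probability
back onto the global mCG target (enforced to ±0.01; validated at
construction).

Type-specific DMRs are disjoint intervals (default 8 per type, 2 kb)
in which the owning type's CpG probabilities drop by `dmr_depth`
(default 0.4, floored at zero) — hypomethylation marks identity, as
with neuron-type CG-DMRs.

Targets default to the three cell-line-like global mCG levels 50.5%,
68.2% and 63.0% with ~1% mCH.

## Read simulation

Fragments are truncated-normal in length (mean 300 bp, sd 80, minimum
150 bp — emulating size selection that removes <150 bp fragments).
Each fragment is sequenced from one strand of the bisulfite-converted
template (R2 reads the template, R1 its complement, so R1 requires the
complementary-strand alignment mode).  Unmethylated cytosines convert
with probability 0.99 by default; methylated cytosines never convert.
PCR duplicates: each emitted read after a cell's first is, with
probability `duplication_rate` (default 0.1), a re-emission of an
existing fragment with the same converted template (conversion
precedes amplification) and fresh sequencing errors, so the expected
unique fraction is 1 − duplication_rate.  Sequencing errors are
uniform substitutions (default 1e-3) applied after conversion,
including over the barcode (handled downstream by Hamming-1
correction).  Per-cell depth is lognormal around `reads_per_cell`
(sigma 0.35), reproducing the depth unevenness that spreads real
clusters.  Noise barcodes receive Poisson-distributed background reads
(default mean 3% of cell depth), half adapter-dimer-like and half
base-shuffled genomic, so they demultiplex but fail alignment — the
property the cell caller relies on.

A second sampler (`sample_cell_allc`) skips base space: it places
unique reads (one strand, fixed span, default 100 bp) on the genome
and draws per-site calls `mc ~ Binomial(cov, p·c + (1−p)(1−c)·…)`,
i.e. the exact marginal of the read-level path after perfect alignment
and deduplication, with conversion failure folded in as
`p_eff = p·conversion + (1 − conversion)`.  Clustering- and DMR-scale
studies use this sampler; base-level fidelity (barcode extraction,
orientation handling, error tolerance, duplicate collapse) is
exercised by the read-level path at smaller scale.  What the generator
does **not** emulate: polymerase and coverage bias, chimeric reads,
quality-score structure, CNVs, and context-dependent conversion
resistance — so passing benchmarks demonstrate the pipeline's
statistical machinery, not robustness to those artifacts.

## Alignment

The aligner is a deliberately small three-letter seed-and-extend:
references are indexed fully C→T and G→A converted (k = 24 seeds at
every position, two seed offsets per read), candidates are scored by
substitution count over the full read length (no indels — the
simulator emits none and co-linear toy fragments don't need banding),
and a hit is reported only if strictly better than the runner-up and
within `max_edit = 3`.  Ties are ambiguous and count as unmapped.
Mapping efficiency is uniquely-aligned mates over submitted mates,
R1 and R2 counted separately.  Large-genome scalability is a
non-goal; the seed table is an exact in-memory hash.

## Methylation calling

Duplicates collapse on (barcode, contig, start, end, orientation
mode); the representative is lowest edit distance, then read id, so
the result is order-independent.  Unique reads are counted per mate
(R1 and R2 of one fragment are two records).  At reference C (top
strand; OT/CTOT alignments) a read C is methylated, T unmethylated;
at reference G (bottom strand; OB/CTOB) the informative pair is G/A
in forward coordinates.  Other read bases — sequencing errors — are
ignored entirely rather than counted into coverage, which avoids
biasing rates.  CpG rows are per strand (allc convention); a
strand-collapse utility backs CpG counting and per-CpG testing.  The
spike contig is excluded from all genome-wide levels and feature
matrices; its pooled 1 − mc/cov is the conversion-rate estimate,
withheld below 1000 calls.  The saturation curve is the exact
subsampling-without-replacement expectation
E[unique at d] = Σ_f (1 − C(N−m_f, d)/C(N, d)), computed in log space.

## Cell calling

EM for the univariate normal mixture uses quantile initialisation
(deterministic), tolerance 1e-8 on the log-likelihood, 500 iterations
maximum, variance floor 1e-6, and asserts monotone likelihood.  k is
chosen by BIC over {2, 3, 4} by default (k = 1 may be offered).  The
cutoff is μ − σ of the highest-mean component; efficiency exactly at
the cutoff passes.  The fit is to raw efficiency values (the
kernel-density detour some workflows take adds nothing at these sample
sizes).  One consequence worth stating plainly: when the fit recovers
the cell component accurately, the μ − σ rule retains Φ(1) ≈ 84% of
true cells by construction — precision is essentially perfect, recall
is not, and that trade-off is the rule's purpose.  Species purity uses
uniquely aligned reads as the denominator and calls pure only when a
fraction strictly exceeds the threshold (default 0.90).

## Clustering and annotation

Bin values are pooled Σmc/Σcov per cell per fixed-width bin (defaults:
100 kb, ≥20 covered sites per bin, bins kept when non-missing in ≥50%
of cells).  Missing bins stay missing until normalization, which
divides each cell's row by that cell's global level and imputes
missing entries with the neutral value 1.0 — zero-filling would
encode coverage, not biology.  PCA centres but does not scale bins
(levels are already on one scale; unit-variance scaling would inflate
noisy bins); n_pcs defaults to 50 and is lowered with a warning when
cells or bins are fewer.  The kNN graph (k = 15, Euclidean in PC
space, undirected union) feeds igraph's Louvain at resolution 1.0,
seeded for determinism.  UMAP is presentation-only.

Cluster annotation merges member-cell allc tables per cluster,
computes pooled CG levels over each named DMR set, divides by the
cluster's global mCG (without this, clusters with different global
levels swamp the set-specific signal and the z-scores measure global
methylation instead of identity), z-scores across clusters within each
set (sample sd), and labels each cluster with its minimum-z set when
that z < −1; otherwise no-call.  Labels attach to membership sets and
are invariant to cluster id permutation.  Note that modularity
clustering always partitions a kNN graph — even of a homogeneous
population — so "no structure" manifests as partitions that fail to
reproduce across seeds, not as a single cluster.

## DMR calling

Pseudobulks are exact per-site count sums.  The caller tests each
strand-collapsed CpG (coverage ≥5 in both groups) with a
two-proportion z-test on counts pooled over a 300 bp window centred on
the CpG; windowed counts borrow strength from neighbours the way
smoothing-based callers do — at 30× single-CpG coverage the
unsmoothed test has ~50% power at a 0.4 difference and clips true
regions.  Smoothing correlates neighbouring tests, so the BH step
(q ≤ 0.05) controls the FDR approximately; the null simulations in the
test-suite confirm ≤1 false region in ≥9/10 seeds at these defaults.
BH-significant CpGs within 500 bp merge into seed regions (≥3
significant CpGs required), which then grow outward over consecutive
nominally significant (p < 0.05), same-direction CpGs — two-stage
region growth in the bumphunter tradition.  Region rates and the
reported difference always come from raw, unsmoothed counts;
zero-information sites (rate 0 or 1 in both groups) are skipped; the
reported q is the minimum member q.  All thresholds are parameters;
`smooth_window=0` and a tiny `extend_p` recover the bare per-CpG
procedure.  Gene annotation assigns at most one gene per region:
promoter (TSS ± 2 kb) beats gene-body overlap beats nearest TSS, ties
broken by TSS distance then name.

## Pipeline, determinism and problem sizes

The orchestrator derives stage seeds from one master seed via a CRC of
the stage name through `SeedSequence`, writes plain-text intermediates
(FASTA/FASTQ/TSV), skips stages whose outputs exist, and echoes every
parameter into the JSON run report.  Benchmarks run at desk scale by
design: toy genomes of 0.25–6 Mb, tens to low hundreds of cells,
800–15,000 reads per cell.  The clustering and global-level benchmarks
use the fragment-level sampler (90 cells × 15k unique reads on a 6 Mb
genome; annotation stability over 10 seeds at 45 cells); the
conversion benchmark runs the full FASTQ → alignment → allc path.
These sizes recover the simulated targets comfortably (per-cluster
global mCG to within ~0.6 points, ARI 1.0, conversion to ~0.1 point in
the seeded acceptance runs) while keeping the whole suite and the
acceptance script within minutes on one CPU.

## Known limitations

- The aligner is exact-alphabet, substitution-only and holds the seed
  table in memory: suitable for megabase toy genomes only.
- CH is one class (no CHG/CHH split).
- The DMR caller's FDR under smoothing is approximate and the caller
  is two-group only.
- The simulator's noise-barcode model (adapter dimers + shuffled
  genomic) is a stylised stand-in for ambient DNA; real ambient reads
  partially align, which would compress the mapping-efficiency
  separation the cell caller sees.
- Doublet barcodes are simulated and recorded but no methylome-based
  doublet detector is provided (the species-mixing rule is the only
  doublet probe).
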