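# Methods

## The O/E estimator and its N correction

For a dinucleotide xy, the per-gene observed/expected ratio is

    O/E(xy) = (d_xy / W) / ((m_x / L_eff) · (m_y / L_eff))

with `d_xy` the number of adjacent windows equal to xy among the `W` windows
whose two bases are both in {A,C,G,T}, and `m_x` the count of base x among
the `L_eff` non-N positions. Windows spanning an N contribute to neither
numerator nor `W`; Ns are likewise excluded from the mononucleotide
frequencies. With no Ns present this is the textbook estimator up to the
L/(L−1) window factor; no small-sample length correction is applied, and
that choice is fixed here so results are reproducible. Values above 3 are
retained everywhere; truncation at 3.0 happens only in the plotting helper.

The ratio is undefined — recorded as NaN with a reason code, never an
exception — when `W = 0`, when `m_x` or `m_y` is 0, or when
`L_eff < min_length`. The default `min_length` is 100 non-N bases, chosen
because EST unigene sets of interest bottom out near 100 bp; shorter
fragments give O/E estimates too noisy to pool.

Percent identity of pre-aligned pairs drops columns gapped in both
sequences, compares all others, and rounds to one decimal (half away from
zero); clone-census percentages round to the nearest integer the same way.

## Mixture model and the unimodality test

Gene classification uses a two-component normal mixture fitted to the
defined CpG O/E values by EM: quantile initialization (means at the
25th/75th percentiles), 10 restarts jittered from the seed with an
epsilon-split safeguard restart that guarantees the k=2 likelihood
dominates k=1, relative log-likelihood tolerance 1e-8, variance floor 1e-6,
and an iteration cap of 300. The cap was set after observing the well-known
component-merging crawl of EM on single-population data: past a few hundred
iterations the likelihood changes by amounts irrelevant to any downstream
quantity, while the bootstrap test below would otherwise take hours. The
cap applies identically to observed and bootstrap refits, so the test
statistic and its null distribution are computed under the same procedure.

Departure from unimodality is tested with a parametric-bootstrap likelihood
ratio: LRT = 2(ℓ₂ − ℓ₁), null distribution from refitting both models to
datasets simulated from the fitted single Gaussian, and
p = (1 + #{boot ≥ obs}) / (B + 1). Mixture-order LRTs have no chi-square
null, hence the bootstrap.

Three guards make the test honest on realistic O/E pools, all standard in
the commingling-analysis tradition:

1. **Yeo-Johnson transform** (λ by normal MLE) applied before testing.
   O/E ratios of short genes are right-skewed, and skewness is the classic
   mimic of a second component; power-transforming first is the established
   cure. A monotone transform cannot merge genuine modes, so power against
   real bimodality survives (the planted two-population case gives
   LRT ≈ 325, p = 0.005).
2. **Common component variance.** Genes of different lengths carry
   different O/E sampling variance; a free-variance fit absorbs the
   resulting excess kurtosis as spurious bimodality. The common-variance
   fit responds to separated means, the signal of interest.
3. **Minimum mixing proportion 5%.** Without it the likelihood rewards a
   degenerate 1–2%-weight component parked on the tail; a gene *population*
   must hold a non-negligible share of genes. The constrained M-step clips
   the weight into [0.05, 0.95], which is the box-constrained maximizer,
   so EM monotonicity is preserved.

Without these guards the test rejects on essentially every
single-population synthetic dataset with realistic length spread
(LRT ≈ 60 from a 1.6%-weight tail component); with them the null rejection
rate is at the nominal level while planted bimodality is detected with
large margins. `equal_var=False`, `min_weight=0` and `transform=None`
expose the unguarded variants.

Classification is done on the raw O/E scale, where component means are
interpretable: each gene's posterior membership in the lower-mean component
labels it low (posterior ≥ 0.5, ties to low) or high; the class boundary is
the posterior-0.5 crossing between the means, found by bisection to 1e-10.

## Enrichment

For each GO term with at least `min_term_size = 2` annotated background
genes, a 2×2 table compares the gene class against the background of all
annotated genes (genes without annotations never enter any margin; a gene
counts once per term). The base statistic is the one-sided hypergeometric
tail P(X ≥ hits); the EASE score removes one gene from the overlap before
taking the tail, so singleton overlaps can never look significant, and is
always ≥ the unmodified Fisher probability. Benjamini–Hochberg step-up
adjustment (via statsmodels) runs across the tested terms within each
class; low and high classes are tested separately against the shared
background. No GO-hierarchy propagation is performed — terms are tested as
annotated. A `top` option trims the sorted output for presentation only.

## In-silico digest

Molecules are linear, coordinates 0-based, cuts are inter-base indices.
Every exact forward-strand CCGG (self-reverse-complementary, so one scan
suffices; Ns abolish a match) cuts at start+1 unless blocked. HpaII is
blocked when the internal C is methylated on either strand (forward
position start+1, reverse partner start+2); MspI is modelled as fully
insensitive to internal-C methylation — its reported sensitivity to
outer-C methylation in some genomes is a documented simplification not
modelled here. The high-molecular-weight fraction is mass-weighted
(share of total base pairs in fragments ≥ threshold), mirroring staining
intensity on a gel; the methylation signal is hmw(HpaII) − hmw(MspI).
There is no principled default threshold — gel resolution is not a number —
so it is a required argument (the CLI defaults to 1000 bp for convenience).

## The simulator: what it emulates and what it does not

Sequence evolution is a discrete-round approximation, not a continuous-time
chain: per round each site mutates to a uniform different base with
probability `base_rate`, and the C of every CpG (plus its reverse-strand G
partner) takes an additional targeted transition (C→T / G→A) with
probability `base_rate · (cpg_multiplier − 1)`. Writing the extra channel
with multiplier − 1 makes multiplier 1 an *exact* null — no CpG-specific
pressure — while the total targeted rate scales as
`base_rate · cpg_multiplier`; only the direction and dose-dependence of CpG
depletion matter to the analysis. CpG context is re-evaluated every round
so newly created CpGs become hypermutable; deamination wins when both
channels fire at one site; Ns are inert; no indels (O/E is
alignment-free).

Unigene sets draw lengths from a log-normal law (median ≈ 450 bp,
mean ≈ 598 bp, clipped to [101, 4278]) emulating EST unigene collections,
GC content 0.45 as typical of insect transcriptomes. The two-population
defaults — base rate 0.01 over 10 rounds with multipliers 7.3 (methylated
class) and 1.8 (unmethylated class) — were fixed once from a calibration
sweep so the class means land near 0.4 and 0.9, the canonical separation
for a historically methylated transcriptome; they are simulation knobs, not
biological estimates. Annotation planting assigns each background term with
probability 0.05 per gene and the enriched term to methylated-class genes
at factor × 0.05.

What the simulator does **not** model: EST positional biases within
transcripts, codon structure, indels, phylogenetic correlation between
genes, and partial-digestion kinetics. Passing tests therefore demonstrate
that the pipeline recovers planted signal under an idealized mutational
mechanism — not that any particular real transcriptome is methylated.

## Problem sizes and numerical choices in the test suite

The suite runs the headline analysis at n = 2000 genes (bootstrap B = 199
for the single planted run, B = 99 for multi-seed rate estimates), type-I
calibration at n = 500 over 25 deterministic replicates, the GpC control on
a 600-gene set, and oracle equivalences on 1000 random sequences — sizes
chosen to keep the full suite at a few minutes on one CPU while leaving the
statistical margins wide (observed planted LRT ≈ 325 versus bootstrap null
values below ~10). All stochastic operations take explicit seeds and are
bit-reproducible; derived seeds stay below 2³¹.

## Known limitations

- CpG O/E is an indirect, historical signal; present-day methylation can
  differ, and O/E of EST-derived sequence inherits EST coverage biases.
- The mixture model assumes two normal components on the raw scale; heavy
  asymmetry within a class biases the boundary.
- The EASE/BH pipeline treats GO terms as opaque, independent labels; the
  GO DAG induces dependence the correction ignores.
- The digest model is all-or-nothing per site (no partial digestion) and
  ignores MspI outer-C sensitivity.
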