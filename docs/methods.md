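# Methods

## The read-loss model of the in vitro cleavage assay

The simulator emulates an experiment in which total RNA is incubated with
recombinant IRE1 (or mock-treated), poly(A)-selected, and sequenced in
replicate.  IRE1 cleaves a substrate 3′ of the guanine of a CUGCAG consensus
held in a hairpin loop.  Because only the 3′ cleavage product retains the
poly(A) tail, library preparation discards the 5′ fragment entirely: in a
treated sample, a transcript cleaved with efficiency ε loses fraction ε of
its coverage over every position 5′ of the cut, and none 3′ of it.  A
`carryover` knob (default 0) admits partial retention of the 5′ fragment,
scaling the retained 5′ coverage to (1 − ε) + ε·carryover.

Expected counts for bin *i* of gene *g* in sample *j* are

```
mock:   μ = s_j · λ_g · π_gi
ire1:   μ = s_j · λ_g · π_gi · [f_i (1 − ε_g) + (1 − f_i)]
```

where s_j is the library size factor, λ_g the gene abundance, π_gi the
within-gene bin weight (proportional to bin length), and f_i the fraction of
the bin lying 5′ of the (3′-most) cleavage position.  Counts are negative
binomial with variance μ + αμ²; α = 0 degenerates to Poisson.

Defaults, chosen to mimic a bulk poly(A) RNA-seq replicate experiment:

| parameter | default | rationale |
| --- | --- | --- |
| replicates | 3 mock vs 3 IRE1-treated | the assay design being emulated |
| dispersion α | 0.05 | typical bulk RNA-seq replicate noise |
| gene abundance λ | log-normal(meanlog 4, sdlog 1) | realistic dynamic range |
| library sizes | log-normal(0, 0.1), geometric mean 1 | mild depth variation |
| depth | 10⁶ expected reads/sample | desk-scale stand-in for 26–32 M reads |
| exons per gene | 4–8, one isoform | enough bins for a step profile |
| exon length | 80–200 nt | human internal exons centre near 120–150 nt |
| planted hairpin | 6 G–C stem, loop `ACUGCAG` | perfect-complement XBP1-like stem-loop |

Hairpins are planted by substitution (never insertion), keeping transcript
coordinates stable; the recorded ground-truth cleavage position is the
coordinate of the guanine at consensus position 3 (CUG↓CAG).  Cleavage
efficiency ε is a free simulation parameter — the assay's real efficiency is
not measurable from published material — and the parameter-recovery studies
use ε = 0.9.

What the simulator does **not** model: read-level errors, fragment-length
effects, isoform switching, multi-isoform genes (multi-isoform inputs are
exercised only in the flattening tests), positional coverage bias.  Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not performance on any particular real library.

## Flattening and coordinates

Transcript exons are flattened into disjoint counting bins: every exon
boundary of any overlapping transcript splits the axis, and each atomic
interval covered by at least one exon becomes a bin carrying its set of
member genes.  Bins with ≥ 2 genes are flagged ambiguous; they remain in the
count matrix but are excluded from testing and selection (flag-and-exclude,
rather than merging overlapping genes into aggregates).  Genomic intervals
are 0-based half-open internally (GTF I/O converts from 1-based inclusive);
transcript coordinates are 1-based with position 1 at the 5′ end, matching
how cleavage sites are cited in the RIDD literature.  Transcript FASTA is
written U→T and converted back on read.

## The differential exon-usage test

Each unambiguous bin of a ≥ 2-bin gene is contrasted against the sum of the
gene's other bins.  For the 2 × n_samples observations (bin, rest), negative
binomial means are fit with per-sample intercepts and a part (bin-vs-rest)
effect; the alternative adds a condition × part interaction.  LR = 2(ℓ₁ − ℓ₀)
is referred to χ² with 1 df.  Numerical notes:

- Per-sample intercepts absorb sequencing depth, so the test is invariant to
  size factors; median-of-ratios size factors (geometric-mean reference,
  normalised to geometric mean 1) are used for usage fractions and count
  fold changes.
- With α = 0 the Poisson MLEs are closed-form (iterative-proportional-fitting
  solution) and the LR equals the G test of independence on the collapsed
  2 × 2 (part × condition) table — used as an exact oracle.
- With α > 0 the likelihood is maximised by L-BFGS with analytic gradients,
  warm-started from the Poisson solution; the dispersion is a plug-in shared
  by both fits (standard LR practice).
- Dispersion: per-bin method-of-moments on normalised counts within each
  condition, α̂ = max(0, (s² − μ̄)/μ̄²), averaged over conditions and shrunk
  halfway toward the gene-wise mean.  The truncation at 0 and the shrinkage
  make the plug-in slightly conservative on null data (observed type-I
  fractions ~0.03–0.04 at nominal 0.05, inside the 99 % binomial band).
- Degenerate inputs: all-zero bins get p = 1; usages of 0 or 1 trigger a
  0.5 pseudocount on counts; single-bin genes are flagged untestable.

**Two fold changes.**  The *selection* fold change is the usage odds ratio
r = [u₁/(1−u₁)]/[u₀/(1−u₀)] reported in the signed convention with |FC| ≥ 1
(FC < 0 ⇔ usage lower in IRE1-treated); selection keeps FDR < 0.05 and
FC < −2 with strict inequalities.  The *profile* fold change (`count_fc`) is
the plain treated/mock ratio of normalised bin counts in the same signed
convention.  The distinction matters: after 5′ cleavage, 3′ bins keep their
coverage (count_fc ≈ ±1) but their *usage* rises, because the rest of the
gene shrank.  Depletion profiles and the change-point stage therefore use
count_fc, whose 3′ segment is genuinely flat, while candidate ranking uses
the usage FC, which isolates within-transcript redistribution from
whole-gene expression shifts.

## Change-point localization and XBP1-like classification

The per-gene profile of log2 count fold changes (bins ordered 5′→3′) is
segmented at the k ∈ [1, n) minimising the two-segment residual sum of
squares; ties (improvements ≤ 1e-12) resolve toward the smallest k, reading
the boundary as the *first* transition from depleted to unaffected.  A gene
is XBP1-like when

- depth_delta = mean(5′ segment) − mean(3′ segment) ≤ −1.0 log2,
- ≥ 50 % of 5′-segment bins are individually significant (FDR < 0.05), and
- the clearly-3′ bins average within ±0.5 log2 of zero.

The bin immediately 3′ of the boundary is excluded from the third clause
(when the 3′ segment has ≥ 2 bins): the bin straddling the cut is *expected*
to be partially depleted, and judging flatness on it would reject genuine
cleavage signatures.  Uniformly shifted profiles fail the flatness clause,
separating cleavage from whole-transcript downregulation.

The change-point has one-bin resolution, so the cleavage search window is
centred on a refined sub-bin estimate: with r = 2^(mean 5′ log2 FC)
estimating the retained fraction, a boundary bin with observed scale
2^v has 5′ fraction f = (1 − 2^v)/(1 − r); accumulating f·length over the two
boundary bins places the cut inside the straddling bin.  The window is the
refined position ± 100 nt (configurable), clipped to the transcript; an
unrefined mode uses the raw bin junction.

## Hairpin model and energy score

Within each window, every CUGCAG match is folded by exhaustive enumeration
of hairpins (loop_start, loop_len, stem_len): stems are runs of consecutive
Watson–Crick or G·U pairs (min 4), loops span 4–12 unpaired bases and must
contain the scissile guanine, all within ±30 nt of the match.  The energy is
a deliberately simple additive score — G–C −3, A–U −2, G·U −1, +0.5 per loop
nucleotide beyond 4 — not a thermodynamic model: it is deterministic,
exactly re-derivable from the reported structure, and sufficient to rank
hairpins.  The minimum-energy hairpin per match is reported (ties: shortest
loop, then 5′-most).  Calls are sorted by energy; nearby calls on one
transcript (≤ 200 nt) group into multi-site targets, accommodating
substrates with two adjacent cleavage sites.  Background specificity is
assessed on dinucleotide-shuffled window sequences (Altschul–Erickson
shuffling, seeded).  Full minimum-free-energy folding, pseudoknots, and
relaxed consensus variants are out of scope.

## Validation statistics

- **qPCR**: per replicate ΔCt = Ct_target − Ct_reference, expression
  2^−ΔCt, summarised mean ± SD.  Invariant to common Ct shifts.
- **Decay calls**: decay is a two-sided Welch t-test on replicate ΔCt
  (inducer vs control; the test choice is this package's, stated here
  because significance conventions vary); rescue by the IRE1 inhibitor is
  met when the inhibitor condition is not significantly below control *or*
  recovers ≥ 75 % of control expression — partial rescue counts.  A call is
  IRE1-dependent when decay is significant and rescue is met.
- **Half-life**: least squares of ln(level) on time after normalising to
  t = 0; t½ = ln 2 / k, with non-decaying series reported as ∞.
- **Synergy**: the median-effect line log(fa/fu) = m·log D − m·log Dm is fit
  by OLS on the logit–log scale (boundary fa values dropped);
  CI = d₁/Dx₁ + d₂/Dx₂ with Dx_i = Dm_i·(fa/(1−fa))^(1/m_i).  The mutually
  exclusive form is the default (the nonexclusive cross term is a flag), and
  a sham single-drug combination gives CI = 1 to machine precision.

## Problem sizes used in the test suite

The parameter-recovery study runs 200 genes with 20 planted targets
(ε = 0.9, depth 10⁶, α = 0.05, 3 vs 3); the null study runs 100 genes
(~600 bins) with no targets.  These sizes give stable rates (recovery,
change-point accuracy, exact-coordinate calls, shuffled-control background,
type-I error) while keeping a full suite run in seconds.
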