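# Methods

This note documents the statistical procedures implemented in
`metscreen`, the generative models behind its synthetic data, the
parameter defaults and why they were chosen, and the limits of what the
synthetic benchmarks can show about real screens.

## Barcode deconvolution

Reads are matched against the barcode library by windowed Hamming
distance: for each read, the minimum distance to every barcode over all
allowed offsets is computed; the read is assigned to the single barcode
attaining the global minimum when that minimum is ≤ `max_mismatch`,
flagged *ambiguous* when two or more distinct barcodes attain it, and
*unassigned* otherwise. Ties between offsets of the same barcode do not
affect counting; the leftmost minimal offset is the match site. The
counter refuses tolerances with 2·m + 1 greater than the library's
minimum pairwise distance (overridable), because same-offset collisions
then become possible by construction. Read conservation
(assigned + unassigned + ambiguous = total) holds for every sample and
is asserted by the test suite. A deliberately naive pure-Python
exhaustive scan (`metscreen.evaluation.exhaustive_scan_reference`)
serves as an independent cross-check; the two paths agree read for read
on error-containing simulated data.

Relative abundance is the plain ratio of a barcode's count to the total
library count in the sample — no pseudocount, since the downstream
statistic is a ratio of ratios and the detection floor handles
low-count noise. Samples with zero assigned reads are flagged failed
and excluded. Enrichment divides sample abundance by the
replicate-averaged input abundance of the sample's pool; clones with
zero input abundance are dropouts (flagged, never infinite).

### Hit rules and edge policy

* SQ rule: threshold 100× on the abundance ratio, mouse-level
  positivity from any SQ core, hit when ≥ 1 mouse is positive; the
  %-positive-mice summary uses mice with > 2 analyzable cores as its
  denominator. The rule text is attached to the output table's
  metadata so alternative readings remain auditable.
* Exactly 100× counts as a hit (≥). Ratios are continuous, so edge
  behavior must simply be fixed and documented; inclusive was chosen.
* Metastasis rule: *positively enriched* means enrichment strictly
  above 1.0 **and** abundance ≥ the detection floor (default 0.01 of
  sample reads, configurable) — the floor suppresses calls driven by
  sequencing noise on near-absent clones. A hit needs ≥ 2 positive
  metastasis samples spanning ≥ 2 mice within one pool cohort.

## Screen simulator

The generator emulates the screen design it is meant to test: pools of
20 clones (19 candidates + 1 shared control) injected into cohorts of
10 mice, quadruplicate input sequencing, triplicate tumor cores, and a
Poisson number of metastasis lesions per mouse (mean 2).

* **Input**: per-pool composition ~ Dirichlet(α = 20). Pools are mixed
  from equal cell numbers per clone, so the input is near-even with a
  realistic ~20% CV from pipetting and culture variation.
* **SQ tumors**: composition ∝ input × growth fitness × lognormal
  mouse-level noise (σ = 0.5), renormalized. Planted drivers carry a
  5× fitness multiplier.
* **Metastases** are clonally bottlenecked: each lesion draws 1–3
  founding cells with replacement, with probability ∝ tumor abundance ×
  metastatic seeding weight, and its composition is a Dirichlet over
  the distinct founders. Drivers carry seeding weight 500; everything
  else weight 1. The large ratio encodes the biology the rule exploits:
  the parental line is essentially non-metastatic, so lesions are
  dominated by one or a few driver clones and passenger appearances are
  rare hitchhiking events. Founders are drawn *with* replacement —
  drawing without replacement would force every multi-founder lesion to
  contain a distinct extra (usually passenger) clone, a sampling
  artifact rather than biology.
* **Sequencing**: counts are multinomial draws per sample; FASTQ
  emission adds configurable flanks around the barcode and a uniform 1%
  per-base substitution error. Count tables are the pre-error
  multinomial truth; the FASTQ path is exercised separately and its
  decoded composition is χ²-consistent with the intended one.

Under these defaults no clone typically reaches the 100× SQ dominance
threshold — that threshold selects extreme clonal takeover, which a 5×
fitness advantage with σ = 0.5 growth noise rarely produces. It is
reachable (heavier noise or fitness produces such events) but not
trivially passed, which is the intended calibration.

What the simulator does **not** model: multi-gene interactions within
pools, PCR amplification bias and chimeras, sequencing quality-score
structure, in vivo clonal dynamics over time, or mouse-to-mouse
differences in lesion count beyond Poisson. Passing the recovery
benchmarks therefore shows the *rules and plumbing* are correct under
the stated model, not that real screens achieve these sensitivities.

## Candidate selection statistics

Expression values are log2(x + 1)-transformed before testing; base 2 is
the field convention and the +1 offset keeps zeros finite. The paired
test is the textbook paired t on per-pair log2 differences; the
unpaired test is the pooled-variance (homoscedastic) two-sided t.
Fold changes are geometric-mean ratios (2^mean log2 difference).
Passing requires raw p < 0.01 **and** linear fold change strictly
greater than 1.5 in either direction; the strict inequality follows the
selection rule's "> 1.5" phrasing, so an exact 1.5-fold gene does not
pass. No multiple-testing correction enters the selection filter
(candidate selection is a recall-oriented screen-building step); BH
q-values are reported as an informational column. Genes with zero
variance get p = 1 and a QC flag rather than an error, so pipelines
never abort on degenerate genes; in the unpaired case, zero variance
with unequal means is infinite evidence (p = 0) instead.

Amplification recurrence is inclusive on both cut-offs (ratio ≥ 1.5,
fraction ≥ 5%), matching the "1.5-fold across ≥ 5%" convention; 8 of
154 samples (5.19%) qualifies, 7 of 154 (4.55%) does not. The
triangulation is pure set algebra — (up in A ∩ up in B ∩ amplified) ∪
(amplified ∩ validated missense) — with orthology applied to the
mouse-derived sets first. One-to-many orthology expands to all targets
and many-to-one collapses with OR semantics, maximizing recall;
unmapped genes are dropped with a logged warning. Probe-level
collapsing is out of scope: sets intersect at gene-symbol level.

## Signature scoring

The transcriptome and protein (RPPA-style) readouts share one engine.
Grubbs outlier filtering is iterative two-sided single-removal:
G = max|x − mean|/sd against the critical value
(n−1)/√n · √(t²/(n−2+t²)) with t = t(α/2n, n−2); at most one point is
removed (default), only for groups with n ≥ 4, at α = 0.05. Under a
simulated null the removal rate is ≈ α (slightly conservative), as the
test intends. Over-representation uses the hypergeometric upper tail
P(X ≥ k) (one-sided Fisher) with each set intersected with the universe
first and BH FDR across all tested sets. The default universe is the
set of genes present on the input matrix; a query equal to the universe
is degenerate (every p = 1) and flagged rather than refused.

## BRET analysis

BRET ratio = I535/L460; net BRET subtracts the matched per-replicate
donor-only ratio (falling back to the plate-wide donor mean when a
replicate lacks donor wells). Negative net BRET values are retained in
fitting — truncation at zero would bias the plateau downward.

The one-site fit minimizes least squares for y = B·x/(K + x) with both
parameters bounded positive, deterministic initialization (B₀ = max y;
K₀ = x at half-max by linear interpolation along the sorted curve) and
no random restarts. Fits whose K lands more than 10⁴-fold outside the
sampled x range are flagged non-identifiable (flat titrations end up
here) and excluded from scoring. The AUC uses the closed form
B·(x_max − K·ln(1 + x_max/K)), verified against adaptive quadrature to
1e-9 relative.

FOC_AUC compares mean replicate AUCs over a shared range
x_max = min(max observed x of pair, of control), avoiding extrapolation
of the control curve. The t-test is an unpaired two-tailed Student test
on replicate-level AUCs; testing per-plate FOC values instead would
require plate pairing information the long-format input does not carry.
With fewer than two replicates per condition the FOC is reported
without a p-value or hit call.

## Problem sizes and determinism

The benchmark sizes — 10,000 reads for oracle equivalence, 20
study-scale screens for driver recovery, 10,000 null genes for type-I
error, 100 noisy titrations for fit recovery — were chosen as the
smallest sizes at which the measured rates are stable to well within
the asserted margins; everything regenerates in well under a minute.
All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning; identical seeds give bit-identical
libraries, count tables, reads, matrices and titrations, which the
suite asserts by running every generator twice.
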