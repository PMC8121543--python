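# Methods

This note documents the models implemented in `clampscan`, the defaults
that matter, and the choices made where the design was genuinely open.

## The selection model and the fitness estimator

The phage-propagation assay is modeled as one multiplicative round of
selection on variant frequencies. An NNS saturation library (32 codons per
mutagenized position: any two bases followed by C or G, encoding all 20
amino acids plus the single stop TAG) is assembled into an input pool as a
wild-type spike plus a symmetric Dirichlet over the variants:

- `wt_input_fraction` (default 0.38): mutagenic PCR also produces
  perfect-match product, so the wild-type gene dominates real input pools
  at roughly this share.
- `dirichlet_concentration` (default 1.0): a flat Dirichlet reproduces the
  long low-count tail seen in real libraries; large values give the
  near-equimolar pools of a focused, balanced library.

Selection multiplies each variant's frequency by `10**F_true`, after which
both populations are multinomially resampled at the requested depths
(default 10⁶ reads each). Replicates share the library composition (they
model repeated transfections of one plasmid pool) and are resampled
independently. Stop-codon variants default to F_true = −3: truncating an
essential ATPase is treated as near-complete loss of function; the value
is a modeling choice, exposed as `stop_fitness`. Compounding over multiple
infection waves is available (`waves`) but off by default — a single
multiplicative round reproduces the estimator's behavior and the extra
waves only rescale F_true.

The estimator is the log10 enrichment ratio relative to wild type.
Frequencies are counts over the sample total, so the totals cancel and F
is invariant to sequencing-depth scaling; swapping input and output
negates every F. Zero counts are handled with a pseudocount (default 0.5
added to variant and wild-type counts in both samples), which keeps
dropout scores finite while shifting variants with ≥50 counts by less
than 0.01. Variants with input counts below 50 are flagged `low_input`;
parameter-recovery guarantees (r > 0.95, MAE < 0.1 at depth 10⁶) are
stated for variants above that coverage.

Amino-acid scores are unweighted means of F over synonymous codons. The
wild-type residue's cell averages the WT-synonymous codons *other than*
the reference codon (0 when the reference codon is the only synonym), so
it measures synonymous-substitution effects rather than restating the
zero point. A position's mean mutational effect averages the 19
non-wild-type amino acids; stop codons are excluded by default because
they conflate truncation with missense (a toggle is exposed — under stop
inclusion the sensitive set can shift by a residue or two). The sensitive
flag uses mean ≤ θ with θ = −1.6 by default; effect categories are severe
(F < −1), moderate/neutral (−1 ≤ F ≤ +1, boundaries inclusive), and gain
(F > +1).

## Read processing

Amplicons come from a fixed, known locus, so reads are located by exact
anchor sequences flanking the mutagenized region (default 15 nt) rather
than by gapped alignment — bit-exact and fast, at the cost of rejecting
reads whose anchors are corrupted. Pair merging scores every candidate
overlap (≥ `min_overlap`) as matches minus mismatches, requires the
mismatch fraction within `max_mismatch_frac` (default 0.25), and resolves
disagreements by base quality, with ties becoming N. Variant calling is
codon-by-codon: zero differing codons is wild type, exactly one is a
variant, two or more are rejected (`multi_codon`), length mismatches are
rejected (`indel_or_length`), and an N inside a differing codon rejects
the read (`ambiguous_base`) while N elsewhere is tolerated. In
double-mutant mode a required background codon must be present
(`background_absent` otherwise); a background-only read is tabulated as
the screen's reference class, so fitness in a suppressor screen is
measured relative to the background mutant. The suppressor intersection
keeps variants that exceed the gain threshold in *both* independent
trials, ranked by the weaker score — a guard against random mutations
arising during either selection.

One identifiability limit: a library member whose NNS codon equals the
wild-type codon yields reads indistinguishable from wild type, so
sequence-level counting can only observe the merged class.
`collapse_reference_variants` performs that merge for comparisons between
simulated tables and called-back counts.

## Conservation and the ROC

Per-column conservation over a homolog alignment is information content
in bits: log2(20) minus the Shannon entropy of the gap-excluded,
renormalized amino-acid frequencies; logo stack heights are frequency ×
bits. Columns gapped in the reference row are dropped; columns with more
than half gaps are flagged low-confidence. No sequence weighting or
small-sample entropy correction is applied by default (with ~1000
sequences the bias term is negligible; both are exposed).

The consensus-substitution analysis looks up the fitness of the
evolutionarily most likely substitution: the alignment runner-up where the
wild type *is* the consensus, the consensus itself where it is not; the
chosen residue is therefore never the wild type. Positions above a
conservation quantile (default 0.9) are excluded because the runner-up at
near-invariant columns is noise.

The ROC is deliberately unusual and implemented exactly as defined: the
predictor is *fixed* (conserved = bits ≥ t, with t a required parameter),
and the *ground-truth* fitness cutoff is swept over all observed
per-position mean effects. TPR is the fraction of sensitive positions
that are conserved; FPR the fraction of insensitive positions that are
conserved; cutoffs where either class is empty are skipped, and AUC is
the trapezoid over FPR-sorted points anchored at (0,0) and (1,1). This
construction makes AUC(labels) + AUC(inverted labels) = 1 exactly. A
conventional ROC (sweep the conservation score against a fixed
sensitivity labeling) is available as `mode="conventional"`.

## Contact graphs and bridge residues

Contacts default to minimum heavy-atom inter-residue distance ≤ 4.5 Å, a
standard van-der-Waals proxy; a representative-point scheme (CA or
centroid) is available. The cutoff is exposed because "contiguous" has no
unique numeric definition: contiguity and bridge conclusions should be
reported as functions of it. Coordinates are read from PDB/mmCIF with
author chain ids and residue numbers taken verbatim. A sensitivity
profile position expands to the same residue number in each ATPase chain
of the complex. Components of the induced subgraph describe contiguity;
bridge residues are its articulation vertices (removal increases the
component count), computed per component and verified in tests against a
remove-and-recount brute force. `threshold_scan` traces set size,
component count, and the bridge set from the most stringent θ upward, so
the trace shows where new bridges appear as the sensitive definition is
broadened.

## Trajectory correlation networks

Trajectories are frames × residues × 3 reference points (typically
mass-weighted residue centers of mass from an optional atom layer), with
plain-text TSV and multi-frame interchange supported. Frames are
superposed by least-squares rigid (Kabsch) alignment over a selection —
aligning only the domain of interest avoids spurious correlations from
rigid-body motion, and an explicit common reference allows several
trajectories to share one frame.

Linear correlation is the normalized covariance of 3-D positional
fluctuations, c_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩). The generalized
correlation estimates mutual information I between displacement-vector
pairs with the Kraskov k-nearest-neighbor estimator (k = 6, max-norm) and
maps it to r_MI = √(1 − exp(−2I/3)) ∈ [0, 1]; for isotropic Gaussian
motion with per-axis correlation ρ this equals |ρ|, making the two
measures directly comparable. The diagonal is 1 by convention (self-MI
diverges). Because the estimator's finite-sample null is not exactly zero
and the sqrt map folds its fluctuations upward, the default subtracts the
mean MI of three frame-shuffled surrogates before mapping
(`null_shuffles=0` restores the raw estimate); the remaining null noise
is tamed by the default analysis mode of averaging matrices over several
(typically four) trajectories, which is also how multi-trajectory results
are reported. Cross-subunit values are obtained by aligning pairs of
blocks and stitching the resulting matrices over the block-diagonal
within-subunit values.

Network edges require contact in ≥ 35% of frames (geometric proxy:
residue-center distance ≤ 6.5 Å, or heavy-atom ≤ 4.5 Å with an atom
layer — a distance gate replaces chemistry-aware contact typing, which
the edge rule does not need) *and* correlation above the kind-specific
threshold (0.35 linear, 0.5 generalized — the two statistics have
different null distributions), and sequence-adjacent residues (same
chain, |Δresidue| = 1) are excluded because their correlation is
dominated by the covalent link.

## Poisson infection bookkeeping

At multiplicity of infection λ, per-cell phage counts are Poisson:
p_k = e^(−λ) λ^k / k!. At λ = 0.001 over 10⁹ cells this gives ~10⁶
infected cells and fewer than 500 multiply-infected ones — the regime in
which each selected genome reports on a single variant.

## What the synthetic generator does and does not emulate

It reproduces the features the estimator and its QC respond to: the
wild-type-dominated input skew with a low-count tail, multiplicative
selection in log10 units, multinomial sequencing noise, replicate
structure, substitution sequencing error, and (for trajectories)
block-correlated isotropic Gaussian motion. It does not model PCR bias or
chimeras, recombination efficiency, burst-size variation, infection-wave
stochasticity, quality-score structure, indel errors, or anharmonic /
multi-state protein dynamics. Passing tests therefore demonstrate that
the estimators recover ground truth under the stated statistical model,
not that real libraries are free of the unmodeled effects.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: 10-position
libraries (320 variants) at sequencing depths of 10⁶–10⁷, two-residue
trajectories of 4000 frames, and random graphs up to 200 nodes — sizes at
which the statistical claims (estimator recovery r > 0.95, MAE < 0.1;
generalized-vs-linear agreement within 0.05; ROC calibration at
0.5 ± 0.1 under permutation) are comfortably testable. All stochastic
operations take explicit seeds; there is no global random state.
Degenerate inputs raise rather than guess: zero wild-type counts with a
zero pseudocount, zero-variance residues, collinear superposition
selections, empty alignment columns, and single-class ROC labelings are
all errors. Ties are deterministic: consensus/runner-up ties break
alphabetically, merge-overlap ties prefer the higher score then the
longer overlap, and disagreeing equal-quality overlap bases become N.

## Known limitations

- The fitness estimator is the plain enrichment ratio; no shrinkage or
  error model is fit, so low-coverage variants are flagged rather than
  corrected.
- Anchor-based calling cannot rescue reads with corrupted flanks and
  never attempts gapped alignment; indel variants are rejected, not
  called.
- The contact-graph contiguity and bridge conclusions depend on the
  distance cutoff; they should be swept, not quoted at a single value.
- The k-NN mutual-information estimator is biased low for strongly
  dependent, low-noise signals (a deterministic linear coupling reads as
  ~0.96 rather than 1.0 at 2000 frames).
- Structure parsing takes the first model of a file and ignores altloc
  bookkeeping beyond gemmi's defaults.
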