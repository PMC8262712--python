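# Methods

## Charge model

Net charge is the sum of Henderson–Hasselbalch protonation fractions over
the nine ionizable groups (alpha-amino, alpha-carboxyl, and the C, D, E,
H, K, R, Y side chains). Basic groups (alpha-amino, H, K, R) contribute
`+n/(1+10^(pH−pKa))`, acidic groups (alpha-carboxyl, C, D, E, Y)
contribute `−n/(1+10^(pKa−pH))`. Assumptions: every input chain has free
termini; cysteines are always titratable (no disulfide modelling); `X`
(unknown residue) carries no ionizable group; no ionic-strength,
temperature or structural (burial/salt-bridge) corrections; and no
post-translational modifications — phosphorylation or N-terminal
acetylation would shift the true pI in ways a sequence-only model cannot
see.

Because the charge is strictly decreasing in pH, the isoelectric point is
the unique root of `Q` on [0, 14] and is found by bisection (tolerance
1e-3 pH, at most 100 iterations). Bisection was chosen over
gradient-based root finding because monotonicity makes it exact, robust
to the plateaus `Q` exhibits far from any pKa, and trivially verifiable
against a grid search — the test suite checks agreement with an
exhaustive 1e-4-step grid argmin of |Q| to 2e-3 across all registered
sets.

The registry ships 19 published pKa sets as a versioned JSON resource.
A set may omit a side chain (the simplified Patrickios set treats C, H
and Y as non-titratable). Two sets are position-aware: Bjellqvist (the
ExPASy convention: alpha-amino pKa depends on the N-terminal residue
identity; Asp/Glu side chains shift when C-terminal) and ProMoST
(per-residue alpha-group pKa at both termini and terminal-context
overrides for all seven side chains). For order-free sets the pI depends
only on the ionizable composition, and a vectorized bisection over a
composition-count matrix evaluates thousands of sequences in one pass.

## pKa-set fitting

A nine-value pKa vector is fitted to a pI-labelled dataset by minimising
the RMSE (MAE optional) between bisection pI and the experimental labels.
The optimizer is scipy differential evolution with an absolute population
of 50, realised as a seeded Latin-hypercube initial population of shape
(50, 9) — scipy's own `popsize` is a per-dimension multiplier, so an
explicit init is the only way to honour an absolute population count.
Remaining evolution parameters are scipy defaults (best1bin, tol 0.01,
final L-BFGS-B polish); the generation cap defaults to 300. Search bounds
default to ±2 pH around the EMBOSS values per group, which keeps the
search inside the biochemically plausible range and the problem
identifiable. Basin-hopping with a truncated-Newton local step is kept as
an alternative strategy flag for comparison. Every run records its seed,
bounds, best vector and a monotone best-objective trace.

Identifiability caveat: a group contributes to the objective only through
sequences that contain it, and groups whose pKa sits far from every
record's pI region are weakly constrained. The recovery tests therefore
assert tight recovery (≤0.3 pH) only for groups present in at least half
the records.

## Feature construction

- **One-hot encoding**: fixed 22-symbol column order — the 20 standard
  residues alphabetically, then X, then the padding symbol. Peptides are
  right-padded to 60 positions (padding rows are hot on the pad column,
  keeping every row exactly one-hot); proteins are right-truncated to
  1000.
- **Property scales**: ~20 canonical scales (Kyte–Doolittle hydropathy,
  Hopp–Woods hydrophilicity, Zimmerman bulkiness/polarity, Chou–Fasman
  propensities, residue volume/mass, charge indicators, ...) ship as a
  JSON resource; the standard AAindex1 flat file (H/I record lines) can
  be loaded for the full catalogue. Scales are reduced to one feature per
  sequence (mean over residues — length-invariant) and ranked by the
  regression F-statistic and by mutual information; at most 10 scales are
  kept per criterion and the ranked union is returned. Constant scales
  are flagged unusable and excluded.
- **kmer windows**: odd sizes 3–15 centred on an ionizable residue (or on
  position 1/L in terminus mode), padded with `-` past the chain ends.
  Window encodings concatenate the flattened one-hot window, per-scale
  (centre value, window mean) pairs, and a nine-way site-type one-hot.
- **Peptide tensor (60×22×4)**: channel 0 one-hot sequence; channel 1
  per-residue values of the selected scales, one scale per column;
  channel 2 the nine ionizable-group counts broadcast down columns 0–8;
  channel 3 a base-method pI prediction broadcast down column 0. Scalars
  are broadcast over dedicated column blocks (zero elsewhere) so each
  1D feature occupies a fixed, documented location.
- **Base-method vectors**: the 19 registry methods in sorted-name order;
  an unknown method name is an error, never a silent NaN.

## Trainable models

All neural components run on a compact numpy layer stack (`isopoint.nn`):
dense layers (selu/elu/relu), inverted dropout, depthwise-separable 2D
convolution (per-channel spatial filter + 1×1 channel mixing), average
pooling, mini-batch Adam on MSE, a 0.2 validation split, and early
stopping with best-weight restoration. Backpropagation is verified
against central finite differences in the test suite. Everything is
seeded: same architecture + seed ⇒ identical initial weights and
identical training trajectory.

**SVR stacking (protein pI).** An RBF-kernel SVR over the 19 base-method
pI predictions, with C ∈ {0.1, 1, 10, 100} and gamma ∈ {1e-3, 1e-2,
1e-1, 1} grid-searched by 5-fold CV; the epsilon tube is 0.05 (narrower
than sklearn's 0.1 — pI labels are meaningful to ~0.01 pH and a 0.1 tube
alone floors the RMSE near 0.06). Held-out RMSE is reported from
out-of-fold predictions. Inputs are restricted to pI-space ([0, 14])
features by default; heterogeneous extras such as length or mass sit on
different scales, distort the RBF geometry and are rejected unless
explicitly allowed.

**Peptide convnet.** Fixed layer sequence sepconv → avgpool → sepconv →
avgpool → flatten → dense(256) → dense(64) → dense(16) → scalar, selu
activations, dropout 0.2 after each hidden dense layer. The first kernel
is 5×22: it spans all 22 symbol columns and slides along the sequence
with a five-residue window, collapsing the symbol axis so subsequent
layers are effectively 1-D over sequence position. Defaults: Adam lr
3e-3, batch 16, ≤200 epochs, patience 10. The small-batch/raised-lr
choice reflects the small-sample regime this model is trained in here (a
few hundred peptides ⇒ few optimizer steps per epoch); both are
configurable. Inputs are standardized per channel and labels to zero
mean/unit variance, restored at prediction; predictions are clipped to
[0, 14] with clip events logged.

**kmer pKa ensemble.** Nine members — one MLP (three dense layers
separated by dropout) per odd kmer size 3–15, plus two extra size-9
members with different seeds — each consuming the encoded window for its
size. Labels are first centred by the per-site-type mean (an
alpha-carboxyl sits near 2.5, a Lys amine near 10.5; centring lets the
networks and the stacker spend all capacity on the local sequence-context
signal instead of spanning that 8-pH gap, and it is what makes the rare
terminus sites predictable at all). Members are trained on standardized
residuals; an RBF-SVR stacker is fitted on out-of-fold member residual
predictions (members and the per-type centring are refitted inside each
of 5 folds, so no site ever stacks its own label). Final prediction =
stacker(member residuals) + type mean, clipped to [0, 14]. A per-type
accuracy report is emitted from out-of-fold stacker predictions; types
with fewer than 5 examples are excluded with a warning. Sequence-only
pKa prediction is intended for proteins (>50 residues); the CLI warns
below that length rather than refusing.

## Evaluation

Datasets are clustered by exact identity (same sequence for pI data, same
sequence+position for pKa data) with duplicate labels averaged, then
split 75/25 with a seeded permutation. Metrics: RMSE, MAE, squared
Pearson correlation, coefficient of determination (reported separately —
it can go negative for methods worse than the mean predictor), and the
outlier count at a threshold of 0.5 pH (proteins, pKa) or 0.25 pH
(peptides), using a strict `>` at the boundary. Cross-validation pools
metrics over concatenated out-of-fold predictions. The benchmark harness
ranks methods by RMSE ascending with a deterministic name tie-break; a
method failing on any sequence is marked invalid without affecting the
others.

## Synthetic data

The generator emulates the shape of experimental datasets while keeping
the generative truth known. Sequences are drawn from a composition that
up-weights the seven ionizable residues ×2 (so short peptides carry
charge signal); peptide lengths are uniform on 6–24 (mean ~15, matching
isoelectric-focusing peptide data), protein-like lengths for pKa data
uniform on 30–80. pI labels are the hidden set's bisection pI plus
Gaussian noise; pKa labels are the hidden per-group base value plus a
linear context effect — coefficients 0.06/0.05/0.04 at neighbour
distances 1/2/3, applied to the composition-centred Kyte–Doolittle
hydropathy of each neighbour (centring keeps per-type label means equal
to the base values) — plus Gaussian noise. The default label noise is
0.2 pH, approximating the run-to-run spread of experimental pI/pKa
measurements. Labels are clipped to (0, 14) with the clip count recorded
(<1% under defaults).

What the generator does **not** emulate: structural effects (burial,
salt bridges, hydrogen-bond networks) that dominate real pKa shifts,
PTMs, measurement bias of isoelectric focusing, non-Gaussian label error,
and the compositional biases of real proteomes. Passing recovery tests
therefore demonstrates that the machinery can extract the signal it was
designed for, not that real-data accuracy will match.

## Problem sizes and numerical choices

Experiments run at: 500 noiseless peptides for differential-evolution
recovery; 300 peptides × 3 seeds for stacking skill; 200 peptides for
convnet trainability; 60 protein-like sequences (~1900 ionizable sites,
75/25 split) for the pKa ensemble; 100 random peptides × all 19 sets for
the grid-oracle check (30 in the acceptance script). These sizes give
stable statistics while keeping a full run in minutes on one CPU.

Tie-breaks and degenerate inputs: zero-variance labels make correlation
undefined (reported as NaN with a warning) and are rejected for SVR
training; empty datasets, inverted bounds, even kmer sizes,
non-ionizable centres and out-of-range positions are errors; a
non-finite training loss aborts with a diagnostic rather than returning
a silently broken model.

## Known limitations

- The two optimized registry sets for the protein/peptide tasks are
  transcriptions from the method's public standalone distribution; their
  provenance is weaker than the literature sets, and users fitting their
  own data should prefer `optimize_pka_set`.
- pI reported to 3 decimals (below experimental resolution, above solver
  tolerance); predictions outside [0, 14] are clipped, which can mask a
  badly extrapolating model — clip events are logged for that reason.
- The pKa models are sequence-only by design; structure-based effects
  are out of scope.
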