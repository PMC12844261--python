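# Methods

## Scope and model form

`envqsar` treats molecular descriptors as given inputs: no structure parsing,
no descriptor computation. Three properties are modelled on the log10 scale
— soil–water partition normalised to organic carbon (log Koc), fish
bioconcentration (log BCF), and the unbound brain-to-plasma ratio
(log Kp,uu) — each by a fixed-coefficient linear equation shipped as a
package constant, plus the machinery to re-derive such equations from a
reference dataset. The linear form assumes additive, non-interacting
descriptor effects over the training domain; the tree and network ensembles
exist precisely to probe what that assumption leaves on the table.

## Fixed predictors and classifiers

The four built-in equations store their published coefficients and standard
errors verbatim; evaluation is a pure dot product and raises per compound
when a term is missing (descriptors are never imputed — silent imputation
would corrupt predictions invisibly).

Threshold semantics are deliberately exact and documented at the boundary:

* **Soil mobility (EPA bands).** The printed class table uses touching
  ranges ("1–2", "2–3"); we resolve them as lower-inclusive half-open
  intervals, so log Koc = 2.0 is "moderately mobile". Any deterministic
  convention would do; this one keeps the class a monotone step function.
* **Bioaccumulation.** Strict inequality at the cut-off; default 3.3 (the
  conservative of the two regulatory values), 3.7 selectable, anything else
  accepted with a warning. The threshold used is recorded in the result.
* **Brain exposure.** high > −0.3; moderate (−0.52, −0.3]; low (−2, −0.52];
  very_low ≤ −2. The −0.52…−0.3 band is a range of literature cut-offs for
  "penetrates easily", so it is kept as its own category rather than
  collapsed to a single number.
* **Caco-2.** permeable ≥ −5.15; borderline [−5.5, −5.15); impaired < −5.5.
  The borderline band's upper edge is the usual permeability cut-off; its
  lower edge of −5.5 marks the scores reported alongside clearly impaired
  transport. Whether these predicted scores are log10 cm/s is left opaque —
  the cut-offs are applied to the scores as given.
* **Drug-likeness.** The Moriguchi-logP/molecular-weight crude limits
  (MLOGP > 4.15, MW > 500) merged with the classical H-bond rules
  (nHA > 10, nHD > 5); at most one violation keeps a compound drug-like.
  Absent nHA/nHD are *skipped and recorded*, never assumed zero, so a
  two-descriptor table yields a two-rule check, visibly.

**PAMPA sign convention.** Some sources print the effective permeability as
`Pe = C·ln(1 − f)`, which is negative for any non-trivial acceptor fraction
f. We implement the standard convention `Pe = −C·ln(1 − f)` so that Pe is
non-negative, strictly increasing in f, and divergent as the acceptor
approaches equilibrium.

## Model development stages

**Collinearity screen.** Tolerance between two candidates is 1 − r² on the
training rows; pairs below 0.1 (|r| ≳ 0.949) are collinear. One member of
each flagged pair is dropped: the one less correlated (in absolute value)
with the response, ties dropping the later candidate in input order —
deterministic and favouring the more informative member. Zero-variance
candidates are degenerate and dropped with a warning.

**Forward stepwise MLR.** Pure forward selection from the intercept-only
model: each step enters the candidate with the largest partial F if its
p-value is below `p_enter = 0.05`; no removal step. The entry criterion and
threshold were an open choice (commercial packages vary between F-to-enter
values and p-values); partial-F at 0.05 is the textbook default and is
exposed as a parameter. Ties break on larger F, then input order. A
rank-deficient design at any step aborts with a diagnostic naming the
offending candidate — a screen failure upstream, not something to paper
over. The final model is refit by OLS for coefficient standard errors.

**Q².** "Cross-validated R²" is read as leave-one-out PRESS-based Q²
(`1 − PRESS/TSS`), the most common usage in QSAR validation; k-fold variants
exist but introduce a partition choice. PRESS is computed through the exact
OLS hat-matrix identity `e_i/(1 − h_ii)` — algebraically equal to refitting
n times, at a fraction of the cost; the test suite checks this equality
against a literal n-refit loop to 1e-10. Rows with leverage ≈ 1 make the
left-out refit singular and raise, naming the row.

**Boosted trees.** Squared-error gradient boosting; defaults
`n_trees=200, depth=3, learning_rate=0.05` — shallow trees and a small
learning rate, standard for tabular regression of this size; all exposed.
Impurity importances are rescaled so the maximum is exactly 1, the
convention for reporting relative descriptor importance.

**Network ensemble.** A reduced automated search: by default 50
single-hidden-layer perceptrons (hidden size uniform on 2–12, activation
drawn from identity / logistic / tanh) trained with L-BFGS and sum-of-squares
loss on standardised inputs; the 5 with the highest validation-set Pearson
correlation are retained and averaged at prediction. 50 nets keeps a laptop
run in seconds while exercising the same retain-best-by-validation logic as
a wide search; width is a parameter. Exponential activations and entropy
losses are not offered — the former is not a supported perceptron activation
in the underlying library and the latter is irrelevant to regression. A
candidate network that fails to train (or emits non-finite predictions) is
discarded with a log entry, never fatally. All sampling is driven by one
seed; there is no global random state anywhere in the package.

**Global sensitivity analysis.** The importance of an input is the ratio of
the model's residual sum of squares with that input *ablated* to the full
model's. Ablation semantics were open (the originating implementation is
proprietary): we substitute the variable's training mean without refitting,
which matches the "model without the variable" description while keeping a
single fitted model and making the score exactly 1 whenever the model
ignores the variable. Scores ≤ 1 mean the model does no worse without the
input; a zero full-model SSR yields infinite sentinels with a warning.

**Protocol.** `run_protocol` chains screen → stepwise MLR (with Q² and test
RMSE) → boosted trees (for log Kp,uu the candidate pool additionally
includes logVDss) → network ensemble on the stepwise-selected variables →
GSA of the ensemble. Identical seeds give byte-identical bundle summaries.

## Synthetic data

The generator emulates the study conditions: train/test sizes 500/132
(log Koc), 400/156 (log BCF), 60/14 (log Kp,uu); descriptor marginals are
independent uniforms over realistic ranges (counts as integer uniforms,
probabilities on [0, 1], log P spanning −2.2 to +9.9 — the lipophilicity
range of the bioconcentration reference compounds); responses are the
built-in equation plus Normal(0, σ) noise with σ = 0.4 log units (0.3 for
log Kp,uu, whose response range is narrower), chosen to put training R² in
the high 0.8s–low 0.9s typical of such fits.

What the generator does **not** emulate: the joint correlation structure of
real descriptors (real descriptor panels are strongly inter-correlated; here
columns are independent unless a `collinear_spec` injects a target
correlation through a Gaussian copula that preserves the marginal ranges),
chemical realisability (a sampled vector need not correspond to any
molecule), and family-specific distributions beyond simple additive offsets
in the synthetic drug panel. Consequently, passing tests demonstrate the
*algorithms* are correct — selection, estimation, validation, ranking — not
that the models generalise to real chemistry, which only the original
reference data could show.

The synthetic drug panel draws a five-family mix (benzimidazole-,
organophosphate-, pyrethroid-, salicylanilide- and sulfonamide-like) with
additive log P / log D / log S offsets reflecting each family's broad
character (salicylanilides and pyrethroids lipophilic and poorly soluble,
sulfonamides polar), so family-summary orderings are exercised end to end.

## Numerical choices and degenerate inputs

* All logs are base 10; unicode minus signs and dashes in input files are
  normalised to ASCII on read, and numeric CSV round trips are lossless
  (shortest-repr formatting).
* Derived-ratio descriptors (Dense = MW/Vol, Flex = nRot/nRig) are checked
  against their constituents at 1e-9 when all are present.
* Undefined Pearson correlations (zero-variance vectors) are NaN sentinels,
  never silently dropped; consensus statistics exclude (and flag) compounds
  missing any model's prediction.
* The applicability domain is per-descriptor range coverage only — the
  reference comparison is a range overlap, so leverage- or distance-based
  domains are out of scope.
* Hat-matrix leverages are computed via QR; the stepwise scan uses
  `lstsq` residuals with an explicit rank check.

## Problem sizes in the test suite

Unit and property tests run at small n (tens to hundreds of rows).
Stochastic recovery of each published equation's coefficients is checked
over 100 seeds at the original split sizes; the pure-noise selection rate
over 300 seeds at n = 100; the full protocol (including the network
ensemble) runs once per property at reduced search width (6–10 nets),
with the stepwise-only recovery carrying the multi-seed load. These sizes
are the package's own desk-scale choices and are parameters, not limits.

## Known limitations

* The published coefficients are taken as ground truth; no re-derivation
  from the original reference compilations is attempted (they are not
  redistributable), so real-data predictive performance is inherited from
  the source equations, not re-validated here.
* Quantitative intestinal-absorption modelling is out of scope: HIA enters
  only as an input percentage with a 30% cut-off.
* The stepwise procedure inherits the usual caveats of forward selection
  (greedy, order-dependent under near-ties, post-selection SEs are
  optimistic); the 2-SE recovery checks quantify this on synthetic data.
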