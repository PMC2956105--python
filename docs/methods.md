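# Methods

This note records the models implemented, the conventions chosen where the
source material left them open, and what the synthetic-data tests do and do
not demonstrate.

## Dataset and endpoint

The packaged dataset holds 82 ER ligands (2-arylnaphthalenes and
2-arylquinolines designed around the genistein scaffold) with competitive
radioligand-binding pIC50 values against both receptor subtypes, stored at
their printed 2-decimal precision. Two printing artifacts were repaired at
packaging time — whitespace and a typographic minus inside one nitro-group
SMILES, and one garbled row label — and every SMILES was canonicalized with
RDKit. The loader re-validates the fixture on every call (record count,
unique identifiers, parsable connected molecules, pIC50 within the assay
range, selectivity present exactly when the two affinities differ).

The selectivity index is

    S = log10((IC50α − IC50β) / IC50β) = log10(10^Δ − 1),   Δ = pIC50β − pIC50α,

defined only for Δ > 0. Equal affinities yield "undefined" rather than a
sentinel (−∞), matching the exclusion of the one equal-affinity compound
(81 compounds carry S). Note the literal algebra: S = 1 corresponds to an
11-fold IC50 ratio, although the statistic is often described as "10-fold
at S = 1"; the equation, not the prose gloss, is implemented. Matching the
printed table uses round-half-away-from-zero at 2 decimals; the residual
|computed − printed| ≤ 0.01 across all 81 compounds is fully explained by
the 2-decimal rounding of the pIC50 inputs.

## Descriptors

All descriptors are computed from first principles against their
literature definitions; every family is verified, on molecules of ≤ 6
heavy atoms, against an independent brute-force oracle (explicit loops,
own BFS distances) to 1e-10. Conventions the source did not state:

* **Graphs.** Topological families (JGI, BEH/BEL, EEig) use the
  hydrogen-depleted graph; information content uses the hydrogen-included
  graph; 3D families use all atoms of the conformer. These follow the
  standard descriptor literature.
* **Conformer.** One ETKDG embedding with a fixed seed (default 20100920)
  followed by MMFF94 minimization (UFF fallback). Identical seeds give
  identical coordinates; embedding failures are isolated per compound and
  reported, and such compounds are excluded from the matrix rather than
  carrying NaN.
* **Atomic properties.** Carbon-relative mass, van der Waals volume,
  Sanderson electronegativity and polarizability per element ship in
  `data/atom_properties.csv` (standard tabulations; vdW volumes from Bondi
  radii). Carbon is exactly 1 in every scheme.
* **Burden matrix.** Diagonal: carbon-relative property; bonded
  off-diagonal: bond order/10 with aromatic = 0.15; non-bonded fill 0.001.
* **Edge-adjacency weights.** Edge degree `x` = (deg i − 1) + (deg j − 1);
  resonance `r` per bond type 1.0 / 1.5 / 2.0 / 3.0 (single / aromatic /
  double / triple); dipole `d` = absolute Sanderson-electronegativity
  difference of the endpoints. The `r` and `d` constants are package
  conventions — the original values were never published.
* **RDF.** Gaussian smoothing β = 100 Å⁻²; the grid radius is index/10 Å.
* **MLOGP.** The Moriguchi 13-term regression (intercept −1.041) with
  documented structural interpretations for the indicator terms: PRX counts
  N/O pairs at topological distance 1 (weight 2) and 2 (weight 1) with a −1
  correction per carboxyl/amide group; UB counts non-nitro double and
  triple bonds on the Kekulized graph; POL counts polar substituents on
  aromatic atoms (N/O/S/halogen first atoms, or carbons multiply bonded to
  N/O); HB is an ortho donor/acceptor flag on aromatic rings; elements
  outside {C H N O S P halogens} are rejected. BLTA96 = 0.90·MLOGP + 1.07,
  a baseline-toxicity affine transform whose constants live in module
  config; only its perfect correlation with MLOGP matters for modeling.
* **Pruning.** Columns that are constant, have zero standard deviation, or
  are near-constant (> 95% identical values) are flagged with their reason
  and excluded from the active matrix.

Exact numeric agreement with proprietary descriptor software is *not* a
goal: conformers and unstated conventions differ. The package promises
definition-faithful values, which is why refitting the published equations
on self-computed descriptors is the honest reproduction route (below).

## Map-based splitting

A Kohonen map (5×5 for the affinity endpoints, 4×4 for selectivity)
clusters autoscaled descriptor vectors. Training uses the deterministic
*batch* update — per epoch, every prototype becomes the
Gaussian-neighborhood weighted mean of the data, with the radius decaying
exponentially from max(shape)/2 to 0.5 over 100 epochs — followed by a
short zero-radius (Lloyd) refinement. The batch variant was chosen over
the online rule because it is reproducible without an update-order
convention and, for a single-cell map, converges exactly to the data mean;
if the smoothing phase ever ends above the random-init quantization error,
the Lloyd-refined initial codebook is used instead, so the trained map is
never worse than its starting point.

Splitting is distance-ranked per occupied cell: nearest members to the
prototype go to training, farthest to test, with largest-remainder per-cell
quotas adjusted so the global training count equals round(fraction·n); at
61/82 this reproduces the study's 61/21 design exactly. Single-member
cells go to training, and every multi-member cell keeps at least one
training compound. The neural-network validation set is a seeded uniform
2:1 carve-out of the training ids (41/20 at n = 61).

## Models

**Stepwise MLR.** Forward entry / backward removal on partial-F p-values
(defaults: enter 0.05, remove 0.10 — the original thresholds are unstated),
OLS refits via statsmodels at every step. Two guards make the search
terminate in all regimes: entry stops once the fit is numerically perfect
(the p-values of further candidates are 0/0 noise), and a repeated-model
check breaks entry/removal ping-pong cycles. Descriptors enter unscaled,
consistent with the raw-scale magnitudes of the published coefficients.
The three published equations are packaged verbatim (the equation spelling
"BELTA96" is accepted as an alias of BLTA96) and evaluated exactly
linearly; `refit_published_form` re-estimates their coefficients on
self-computed descriptors and reports the achieved statistics next to the
originally reported ones, flagging R² deviations above 0.15 as
informational only.

**PLS.** Classical NIPALS with deflation (tolerance 1e-12), autoscaling
(n−1 standard deviations) inside the fit, weight-vector sign fixed by a
positive first nonzero element. Factor count is chosen to maximize
external Q² on the map-based split, ties toward fewer factors. VIP uses
the per-factor explained y-variance, so ΣVIP² = p exactly. Outlier
flagging combines standardized prediction residuals (default cutoff 2.5)
with latent-space leverage above 3·(factors)/n — the rule is a package
choice intended to make outlier handling reproducible; the original work
states no rule. Known limitation: with a single response, argmax-Q² factor
selection does *not* reliably recover the planted rank of noisy low-rank
data — PLS1 compresses multi-factor signal into fewer score directions,
and at low noise the Q² differences beyond the true rank are sign-random
epsilons. The selection rule is still the stated one; the recovery
property is exact (and tested) in the noiseless construction, and under
noise the selected model is tested for predictive skill instead.

**BRNN.** Two-layer network (tanh hidden, linear output) trained by
Levenberg–Marquardt on F(ω) = β·E_D + α·E_W, with Nguyen–Widrow hidden
initialization on inputs mapped to [−1, 1] and an internally standardized
response. After every accepted LM cycle the evidence framework re-estimates
γ = N_w − α·tr(H⁻¹), α = γ/2E_W, β = (n − γ)/2E_D on the Gauss–Newton
Hessian H = β·JᵀJ + α·I; training stops when the log evidence stops
improving (patience 8) or at max_epochs (200). All weights including
biases share the single α class. α and β are clipped to [1e-8, 1e8] and γ
to [0, N_w] for numerical safety. `noise_precision` reports β on the raw
response scale (β/σ_y²) so it can be compared with a known noise variance.
Because a single training depends on its start, predictions are averaged
over independently seeded repeats (50 by default, seeds derived from one
master seed and kept below 2³¹); individual failed repeats are dropped and
at least 80% must succeed. Architecture defaults per endpoint: 5 hidden
units with 5 (α), 11 (β) and 14 (selectivity) input principal components —
the selectivity count truncates to the 11 available core descriptors with
a warning.

**Metrics.** R² = 1 − RSS/TSS; SEE = √(RSS/(n−p−1));
F = (SSreg/p)/(RSS/(n−p−1)); external Q² = 1 − PRESS/Σ(y_te − ȳ_train)²;
SEP = √(PRESS/n_te); LOO Q²cv = 1 − PRESS/TSS. Every cross-validated
denominator is anchored at the training mean, one definition everywhere,
so predicting the training mean scores exactly zero. Because
neural-network results in this field are often quoted as correlation-style
R, the squared Pearson correlation is emitted alongside as `r2_corr`.

## Synthetic generators and what the tests show

The generators are pure functions of their arguments (seed included) and
mirror the study scale by default (n ≈ 82, p ≈ 11):

* `gen_linear` — standard-normal columns with optional shared-factor
  collinearity and y = Xβ + ε; exercises stepwise recovery (exact at zero
  noise) and the false-entry rate on pure noise (≈ alpha_enter per
  candidate, mean ≈ 1 entry per run with 20 decoys at 0.05).
* `gen_latent` — X = TPᵀ + E with orthonormal T and P and singular values
  linspace(1, 0.5, r)·√n, y loading on every factor with magnitude in
  [0.5, 1.5]; the noiseless spectrum is exactly the planted profile.
* `gen_nonlinear` — sine, smooth-XOR and saturating surfaces with the
  oracle function returned; the sine target (n = 200, σ = 0.1) is the BRNN
  recovery condition, and the XOR surface separates the network from any
  linear probe.
* `gen_clusters` — Gaussian mixtures for map training and splitting tests.

Passing these tests shows the estimators recover the structures they
assume, at small-n scales, under Gaussian noise. It does not show that
real descriptor matrices satisfy those assumptions: real descriptors are
heavy-tailed, discretely valued (counts), and collinear in blocks, and the
map-based split is not an i.i.d. sample. The fixture-based pipeline tests
cover the real-data path end to end, but their fit statistics are
descriptor-implementation-specific (see above).

## Numerical choices and degenerate inputs

Ties in per-cell split ranking break by compound index; NIPALS declares
non-convergence after 10,000 iterations; PCA components carry a
largest-element-positive sign convention; eigen-decompositions of
symmetric matrices use `eigvalsh`; the molecular influence matrix uses a
pseudoinverse so planar and linear molecules (coordinate rank < 3) are
handled; a GETAWAY lag beyond the topological diameter returns 0 (empty
sum); constant columns are rejected by the autoscaler with the offending
column named (they should have been pruned upstream).
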