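# Methods

This note documents the models, numerical choices and calibrations behind
`ddrensemble`, and what the synthetic test battery does and does not show
about real data.

## The modelling problem

A DEER experiment on a doubly spin-labelled protein yields, after
inversion, a distance distribution P(r) between the two nitroxide labels.
For a disordered domain each distribution is broad (σ of several tens of
percent of the mean), and a single distribution constrains the ensemble
only weakly. The pipeline therefore treats a *set* of distributions for
M site pairs as "distribution restraints" on a conformer ensemble: a raw
pool of conformers consistent with coarse (Gaussian) summaries of the
restraints is generated by Monte-Carlo sampling, and populations on that
pool are then fitted against the full distributions. Weak order is read
off the refined ensemble as systematic deviation of segment statistics
from random-coil scaling.

## Distance distributions

Distributions are discretized on a uniform grid, 0.5 Å spacing and
10–120 Å by default, and normalized by the **discrete sum** (Σp = 1, not
the trapezoid rule) because the overlap metric

    o = Σ_r min{P₁(r), P₂(r)}

is defined on unit-sum vectors. For unit-sum vectors, o = 1 − TV, one
minus the total-variation distance; it is symmetric, bounded in [0, 1]
and equals 1 only for identical vectors. When two distributions live on
different grids, the *predicted* one is resampled (linear interpolation
of per-Å density, then renormalization) onto the experimental grid, so
experimental band metadata is never touched. Files use the 4-column
whitespace format (distance in nm, density, lower band, upper band);
distances are Å everywhere in memory.

Two parametric shapes are provided:

* **Gaussian** — mean ⟨r⟩ and width, with σ_r = Γ_FWHM/√(8 ln 2) held as
  an exact identity between the two width fields.
* **SAW-ν** — the closed-form end-to-end distribution of a self-avoiding
  walk, P(x) ∝ x^(2+g) exp(−βx^δ) with x = r/a, δ = 1/(1−ν) and
  g = (γ−1)/ν, γ = 1.1615 the 3D SAW susceptibility exponent
  (configurable). The two free constants (a, β) are fixed by unit
  normalization and by the second-moment condition ⟨r²⟩ = R². The density
  is skewed with the steeper flank toward short distances; skewness grows
  as ν decreases toward the poor-solvent value 1/3.

Least-squares fits of both shapes to tabulated densities use bounded
nonlinear least squares with five starting points; ties are broken by
lower RMSD, then lower ν. Fit RMSDs are quoted on unit-maximum scaled
densities by default (`rmsd_convention="unit_sum"` switches to the
unit-sum vectors); the unit-max convention is the one on which RMSD
values of order 0.1–0.2 arise for typical coil-section fits. The ν search
box is (0.2, 0.95): fits of nearly symmetric distributions run to
unphysically high exponents (> 0.6), which is itself diagnostic — such
data cannot discriminate SAW-ν from Gaussian shapes.

## DEER forward model and inversion

The kernel follows the two-pathway form with exponential background (a
homogeneous 3D distribution of remote labels); stretched-exponential
backgrounds are out of scope. The elementary kernel K₀ is evaluated with
the Fresnel-integral closed form of the powder average,
K₀ = [cos φ·C(κ) + sin φ·S(κ)]/κ with κ = √(6φ/π), φ = ω_dd·t, which the
test suite checks against a stratified Monte-Carlo orientation average
at 10⁶ orientations (agreement < 10⁻³).

Parametric inversion fits the distribution parameters jointly with
(Λ₀, λ₁, k) — and optionally (λ₂, T₀₂), fitted within bounds anchored
near the end of the trace — by multi-start trust-region least squares.
Multi-Gaussian component counts are selected over 1..n_max by AIC or BIC
computed from the residual sum of squares. Non-convergence is flagged on
the result object, never silent.

Tikhonov inversion solves min ‖KP − F‖² + α²‖LP‖² with P ≥ 0 (stacked
nonnegative least squares), where F is the background- and
unmodulated-amplitude-corrected signal and L is the plain second-difference
operator. Criterion-based α selection evaluates a log-spaced grid
(10⁻³–10³, 25 points): AIC/BIC use effective degrees of freedom equal to
the trace of the influence matrix of the unconstrained regularized
solution; the residual method applies the discrepancy principle against
the trace's noise estimate (second-difference estimator if none given).
Absolute α values are convention-dependent (they scale with the grid and
the operator normalization), so criterion-selected α is the default and a
fixed α is accepted as a number.

## Conformer sampling

Chains are grown residue by residue with ideal bond geometry (N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, trans ω = 180°), giving a CA–CA
virtual bond of 3.804 Å. Torsions (φ, ψ) are drawn jointly from
residue-class coil densities discretized on a 10° grid with in-bin
jitter. The shipped library approximates residue-specific coil
statistics by Gaussian basin mixtures for five classes {generic,
glycine, proline, pre-proline, β-branched (Ile/Val/Thr)}; basin
locations are the canonical coil basins (PPII, extended β, α_R, α_L,
plus mirror basins for glycine). The basin weights were calibrated
once so that unrestrained 100-residue low-complexity ensembles
reproduce the established coil-library reference behaviour — segment
scaling R_k ≈ 5.2·k^0.57 Å and a 20-residue section end-to-end
distribution near (27, 8–9) Å — and are fixed; any library object
implementing `sample(class, rng)` can be substituted for the shipped
one. Self-avoidance is enforced at the CA level (CA–CA < 4.0 Å for
|i−j| ≥ 3 rejected; CA vs anchor heavy atoms < 3.5 Å), with up to 50
torsion redraws per residue before the chain restarts. Side chains are
not built; the enlarged CA clash radius stands in for side-chain
excluded volume.

Restraint rejection: as soon as both sites of a restraint have backbone
coordinates, the mean label position is predicted and the distance is
scored with the max-normalized Gaussian p = exp(−(d−⟨r⟩)²/(2s²)),
s = √2·σ_r. The running product over evaluated restraints must stay
≥ 0.75 or the conformer is discarded and restarted. The max-normalized
form (p = 1 at the mean) was chosen over a tail integral so that the
0.75 threshold applies to a product of quantities each equal to 1 for a
perfectly satisfied restraint; the threshold is applied to the product,
not per restraint. Early rejection concentrates compute on the
restraint-consistent region; the restart budget (default 2000) converts
a geometrically unsatisfiable restraint set into an explicit sampling
failure report. Anchored sampling fixes an N-terminal stretch to the
anchor model's coordinates and distributes conformers round-robin over
multiple anchor models. The entire Monte-Carlo stream is a pure
function of the seed.

## Spin-label surrogate

A full rotamer-library treatment predicts per-site clouds of ~100
rotamers; the pipeline needs only (i) the mean label position per site
(for sampling-time restraint scoring) and (ii) the pair broadening of
distance distributions (for fitting). The surrogate therefore has two
parameters: the mean position sits `radial_offset` from CA along the
ideal tetrahedral pseudo-CB direction (built from the N/CA/C frame,
110.5° to both CA→N and CA→C, L-chirality; CA fallback where the frame
is missing), and the ensemble histogram of mean-label distances is
convolved with a Gaussian of width σ_conv = √2·`sigma_label` (the
pairwise combination of two independent per-site spreads). A plug-in
returning per-site position clouds can replace the surrogate.

Defaults are radial_offset = 8.3 Å and sigma_label = 3.9 Å
(σ_conv ≈ 5.5 Å), calibrated once so that a coil section whose CA–CA
distribution is ≈(27.0, 8.2) Å at 20-residue separation maps to a
label–label distribution ≈(29.7, 10.8) Å — a mean shift of +2.7 Å and a
width ratio of 1.32. Note that the geometric offset itself already
broadens the mean-position distance distribution, which is why σ_conv is
smaller than the naive √(10.8²−8.2²) ≈ 7 Å deconvolution estimate. The
surrogate is site- and conformer-independent, a documented approximation:
real rotamer distributions vary with local environment.

## Population fitting

The objective ō = (∏ o_m)^{1/M} is maximized as Σ log o_m over the
probability simplex. Each o_m(p) = Σ_r min{(A_m p)_r, b_m(r)} is concave
(a sum of minima of linear functions), so the log objective is concave
and the global optimum is attainable; overlaps are floored at 10⁻⁶
inside the log. The solver is projected (sub)gradient ascent with a
doubling/backtracking monotone line search, warm-started from stacked
nonnegative least squares on the first block and from the previous
block's solution afterwards. Per-conformer distribution columns A_m are
built on each restraint's experimental grid (triangular binning of the
label distance, Gaussian broadening, unit-sum normalization).

Conformers are admitted in generation order in blocks (default 100):
fit, prune conformers below `prune_frac` (default 1%) of the most
populated one, admit the next block, re-fit. When fewer than 10% of the
nominal block size are free for admission the block grows by 50%; when
the retained count later drops the block resets to its nominal value. A
final re-fit follows the last prune. The objective is monotone across
block iterations up to the (bounded) mass removed by pruning. Duplicate
conformers make populations non-identifiable individually; only their
sum is constrained, which is the documented contract.

## Weak-order analytics

All ensemble averages are population-weighted. Segment statistics use
⟨R²_ij⟩, the mean-square CA–CA distance of residue pair (i, j), and its
square root RMS(i, j). The scaling law b·k^ν is fitted in linear space
by nonlinear least squares to *all* pair points (one point per pair, no
per-k averaging), seeded from a log-space linear fit. The deviation
matrix ΔL_ij = RMS(i,j) − mean_k{RMS} has an exact per-k zero sum by
construction; negative blocks mark compacted segments. The ensemble
width Γ is the population-weighted RMS of pairwise CA RMSDs after
optimal (Kabsch) superposition; a single conformer has Γ = 0 by
convention. Radii of gyration are CA-only and combined over conformers
in quadrature, √(Σ pᵢ R²_g,i), consistent with the RMS conventions
elsewhere (an arithmetic-mean option exists).

## Jack-knife validation

For n_r restraints, n_r additional modelling runs each leave one
restraint out (no replacement), re-generate a raw ensemble, re-fit
populations, and predict the omitted distribution; each run's seed is
spawned deterministically from the master seed. A left-out overlap far
below the rest flags an inconsistent restraint (e.g. a conformation-
biasing label); the flag rule, overlap < median − 2·MAD, is this
package's operational choice for what is otherwise a visual judgement.
Sub-runs use equal conformer targets by default. The union of all
leave-one-out ensembles (populations scaled by 1/n_ensembles,
renormalized) is a basis of conformers each consistent with at least
n_r − 1 restraints; a final fit of all restraints on this enlarged basis
does not do worse than the initial fit and is usually better.

## Synthetic ground truth

The generators emulate the inputs of a real study with known answers:
freely jointed CA chains (step 3.8 Å) are the analytic coil null
(R_k = 3.8√k, ν = 1/2, ΔL = 0 in expectation); weak order is injected by
geometrically rescaling the displacement vectors inside a designated
segment (compaction factor) or by mixing extended and compacted
populations — geometric rescaling keeps the ground truth analytic and
the tests fast, at the price of unphysical local bond lengths inside the
compacted segment. Simulated restraints are forward-modelled label
distributions (optional multiplicative bin noise, then renormalization)
on a grid extended down to 0.5 Å so that no synthetic support is
truncated; simulated traces add white Gaussian noise to the exact
forward model. Every generator is a pure function of (arguments, seed).

What passing synthetic tests shows: the inversion, sampling, fitting,
analytics and validation machinery is internally consistent and
recovers known ensembles and parameters under the stated noise. What it
does not show: that the coil surrogate library matches any particular
protein's local conformational preferences, that the two-parameter
label surrogate matches a real rotamer ensemble at a specific site, or
that experimental background separation artifacts are handled — those
require real traces.

## Problem sizes and determinism

Default study conditions are 100-residue chains with raw ensembles of
1,000–2,500 conformers for reference-state statistics (the acceptance
script uses 1,200), 2,000 freely jointed conformers for the ideal-chain
check, and a 40-residue, 5-restraint synthetic system with ~50–300
conformers per run for recovery and jack-knife demonstrations — sizes
chosen so the whole battery runs on a single desktop CPU in minutes
while keeping stochastic estimates inside their tolerance bands. All
randomness flows through seeded NumPy generators; identical seeds give
bit-identical ensembles, fits and reports.

## Known limitations

* The coil library is a five-class basin surrogate, not a per-residue
  statistical compilation; sequence effects beyond the five classes are
  absent. Its reference-state SAW-ν fit exponent for 20-residue sections
  (~0.67) is somewhat lower than values obtained with per-residue coil
  libraries (~0.78), though both lie in the "unphysically high,
  shape-indiscriminable" regime that motivates Gaussian restraints.
* Backbone-only models; side-chain packing and label accessibility are
  not modelled.
* Fitting targets distance distributions, not primary traces; model bias
  of the chosen inversion propagates into the restraints (mitigated, as
  recommended, by comparing several inversion routes).
* Ensemble width Γ is O(n²) in conformers with a Kabsch superposition
  per pair; it is intended for refined (≤ a few hundred conformer)
  ensembles.
* Restraints lying entirely inside a fixed anchor are not re-scored
  during sampling (they are constants of the anchor model).
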