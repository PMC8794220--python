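# Methods

## Model and assumptions

The package treats the ensemble of chain fragments buried inside globular
proteins as a realization of a dense polymer melt. Under the Flory theorem,
such fragments follow ideal-chain statistics: the end-to-end distance `R`
at sequence separation `m` is Maxwell distributed,
`M_m(R, b) = 4πR²(3/(2πb²m))^{3/2} exp(−3R²/(2b²m))`, with the Kuhn length
`b` as the single scale. Burial is enforced combinatorially, not
geometrically: a fragment is kept iff `m < N^{2/3}` (strict), with `N` the
residue count of its (break-split) chain — equivalently, only chains with
`N > m^{3/2}` contribute at separation `m`. A lower bound `m ≥ 30` removes
the regime where secondary-structure rigidity dominates, which is visible
as a non-zero tangent–tangent correlation below `m ≈ 30` with an
anti-correlation dip near `m = 13`.

The observed density `E_m(R, w)` (Gaussian KDE) is compared to the fitted
reference by Boltzmann inversion, `V_m(R) = −ln(E_m/M_m)` in units of
`k_B T = 1`. The partition-function ratio of the underlying free-energy
difference is independent of `R` and dropped, so every potential carries an
additive-constant gauge; all comparisons against known injected potentials
subtract the mean over the common support. The pairwise total score
`V_tot = Σ_{i<j} V_{|j−i|}(R_ij)` neglects correlations between pairs and is
exact only for the reference ensemble itself.

`m` denotes the sequence separation `|j − i|` of the fragment's terminal
residues (a fragment spans `m + 1` residues). This is the only convention
under which per-separation potentials compose into the total score.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| collection range | 30 ≤ m ≤ 90 | Gaussian regime with possibly non-uniform `b(m)` |
| Flory (plateau) range | 70 ≤ m ≤ 90 | uniform Kuhn length; `b*` is the unweighted mean of `b(m)` |
| globularity cut `k` | 3 | discard chains with log-residual > 3 sd from `R_g = aN^{1/3}` |
| CV separations | {42, 48, 60, 64, 66, 72, 78, 84, 92} | where 5-fold bandwidth CV is run |
| bandwidth grid | 40 log-spaced values, 0.01–10 Å | search space for CV |
| distance grid | 0–30 Å, 0.1 Å steps | shared evaluation grid for all levels and `m` |
| support threshold | 5 expected counts / 0.1 Å bin | masks log-of-noise; `V` is NaN below it |
| seq-dep minimum count | 50 fragments per `m` | separations below it are dropped from the pair average |

Kuhn-length estimation uses the closed-form MLE `b̂ = sqrt(mean(R²)/m)`
(the likelihood equation solves exactly), with Fisher uncertainty
`σ_b = b̂/sqrt(6n)`; a numerical likelihood maximization exists only as an
independent oracle in the tests. The plateau uncertainty is the propagated
`sqrt(Σσ_b²)/k` over the 21 per-`m` fits.

## Numerical choices

* **KDE evaluation.** The kernel sum is computed exactly (chunked
  log-sum-exp) up to 2·10⁶ sample–query pairs; beyond that a fine-grid
  binned convolution is used (`scipy.ndimage.gaussian_filter1d`, bin width
  ≤ w/8, truncation 9σ), whose error is orders of magnitude below every
  tolerance in use (checked against the exact path in the tests). No
  boundary correction is applied at R = 0: with distances of several Å and
  w ≪ R the leaked mass is negligible and is monitored by the
  normalization tests.
* **Bandwidth model.** `w = a·n^s` is fitted by minimizing the RMSD in
  linear `w` (a log-space fit is available as an option). The power law is
  only identifiable when the CV sample sizes span a real range; the
  pipeline falls back to the mean CV bandwidth when they span less than a
  factor 1.5, which is the typical situation for small uniform synthetic
  corpora.
* **Globularity fit.** Residuals of `R_g = aN^{1/3}` are measured in log
  space (the natural space of a power law), the cut is a single pass, and
  `a` is not re-fitted after pruning. The fit is scale-covariant, so the
  discard set is invariant under rescaling all `R_g`.
* **Minima.** Candidates are strict local minima of the average curve after
  a 3-point moving average; position and depth are refined by a parabola
  through the three raw grid values. A minimum is reported only when its
  topographic prominence reaches the across-`m` spread at that point —
  minima indistinguishable from curve-to-curve noise are suppressed (exact
  synthetic curves have zero spread, so nothing is suppressed there).
  Shallow minima of comparable size to the spread may legitimately be
  missed.
* **Short-range repulsion.** `ln V` is fitted linearly in `ln R` from the
  smallest defined grid point to the first grid point where `V` drops below
  1 k_B T. The fitted exponent is sensitive to this window; the default
  merely tracks "the repulsive part" and callers can pass an explicit
  window.
* **Ties and degenerate inputs.** Alternate locations resolve to highest
  occupancy, first-listed on ties; multi-model files use model 1 only;
  degenerate CV samples (all values equal) return the smallest grid
  bandwidth with a warning; an all-empty fragment collection warns rather
  than fails.

## Synthetic ground truth

The generators realize exactly the statistical structure the method
assumes, which is what makes the test suite conclusive about the
*machinery*:

* `generate_gaussian_chain` draws independent isotropic Gaussian steps with
  per-component sd `b/√3`, so `E[R²] = b²m` exactly and fragment distances
  are Maxwell — the null in which the derived potential must vanish.
* `generate_confined_globule` rejects steps leaving a sphere of radius
  `2.2·N^{1/3}` Å (a protein-like prefactor), producing compact-globule
  `R_g ∝ N^{1/3}` scaling for the pruning stage.
* `sample_reweighted_maxwell` draws from `∝ M_m(R,b)·e^{−U(R)}` by
  rejection, so Boltzmann inversion can be checked against a known `U`.
  The standard injected well is Gaussian with depth 1 k_B T, centre 10 Å,
  sd 2 Å: wide enough that the CV-selected bandwidth (≈0.6 Å at n = 10⁵)
  resolves it. A well much narrower than the bandwidth is *not*
  recoverable by this estimator — that is a property of fixed-bandwidth
  KDE inversion, not of the implementation.

What the synthetic data do **not** emulate: excluded volume (unless the
hard-core flag is set), secondary structure and local stiffness, side-chain
geometry (synthetic traces are CA-only), sequence composition bias, and
experimental artefacts (missing atoms, alt-locs appear only in hand-built
test fixtures). Passing tests therefore demonstrate correctness of the
estimators and pipeline under the model's own assumptions; the physical
content of potentials derived from real structures rests on the Flory-
regime diagnostics (`b(m)` plateau, `ν ≈ 1/2`) that the pipeline reports.

## Problem sizes

Statistical checks run at the sizes where their tolerances are meaningful
and stable: 10⁵ reference draws per separation for the null-potential and
well-recovery calibrations, 200 replicates of 10⁴ draws for the Fisher
uncertainty, 2000 chains of 1000 residues for the thermal exponent, 500
confined globules plus 20 planted rods for the pruning check, and 3·10⁶
draws for the KDE sup-norm consistency bound (at 10⁵ the sup-norm noise of
a CV-bandwidth KDE exceeds the 1% target — the bound is a function of `n`,
not of implementation quality).

## Known limitations

* Burial is purely the `m < N^{2/3}` criterion; no solvent accessibility is
  computed.
* The KDE bandwidth depends on `n` only, per the `w = a·n^s` model; the
  optimal bandwidth also varies with the distribution scale (∝ √m), which
  the model ignores by construction.
* Whether fragment "length" counts residues or bonds shifts per-`m` counts
  by one; comparisons of `n(m)` tables across conventions should allow for
  that.
* Sequence-dependent potentials need large corpora: with the default
  minimum of 50 fragments per separation, rare pairs drop most separations
  and the broad average becomes noisy.
* Re-running a pipeline configuration is byte-reproducible only within a
  fixed software environment (floating-point determinism).
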