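# Methods

## Data model

A `SpectraDataset` holds an `n_samples x n_channels` absorbance matrix, a
strictly increasing wavelength axis in nm, and a per-sample target vector.
Channel indexing is 0-based internally; reports give both the channel index
and the nm value. Interchange is plain CSV (optional `sample_id` column,
one numeric column per wavelength, a `target` column); no spectral
pretreatment (SNV, derivatives, MSC) is applied anywhere — the selection
operates on raw absorbance.

## Cost function

For a candidate mask m the cost is the root-mean-square error of k-fold
cross-validation (RMSECV) of a PLS1 regression restricted to the selected
channels:

RMSECV(m) = sqrt( (1/n) Σᵢ (yᵢ − ŷ₋f(i)(xᵢ))² ),

where ŷ₋f(i) is the prediction of the model trained with sample i's fold
held out. Defaults: 2 latent variables, 5 folds. PLS is fitted by NIPALS
with mean-centering and no scaling; the implementation is deliberately
minimal because it sits in the optimizer's inner loop (tens of thousands of
evaluations per experiment) — it agrees with sklearn's `PLSRegression` to
machine precision and with ordinary least squares at full rank, both of
which serve as independent oracles in the test suite.

Numerical/degenerate-input choices:

* The fold assignment is drawn once per optimizer run from the run's seed
  and shared by every individual and iteration, so costs are comparable
  across the swarm.
* An all-zero mask receives a finite sentinel cost (1e10) and can never
  become the food source.
* When a mask selects fewer channels than the requested latent variables,
  the latent count is clamped to `min(n_latent, n_selected, n_train − 1)`
  rather than erroring, so the optimizer can traverse sparse masks.
* NIPALS deflation stops early when the residual X'y covariance vanishes
  (rank-deficient selections); a zero-variance target is an error.

`explained_variance_components` (PCA via scikit-learn) reports cumulative
explained-variance fractions of the absorbance matrix, as a sanity check of
the 2-latent-variable default on new data.

## Swarm dynamics

Positions are binary; steps are real. The five strategy terms and the step
update follow the standard dragonfly model (see the README for the
formulas), with these resolved design points:

* **Neighborhood**: every other dragonfly is a neighbor. The continuous
  algorithm grows a neighborhood radius over iterations, but no formula for
  it is standard; the released binary reference code uses the whole swarm,
  and so does this package. The radius mechanism is intentionally not
  implemented.
* **Food/enemy**: best/worst-so-far masks over *all* evaluations in the
  run, which makes the best-cost trace non-increasing by construction.
* **Binary update**: the "−X" of the position-update rule is read as the
  bit complement (1−x), the established binary-swarm interpretation; a sign
  flip is meaningless on {0,1}.
* **Enemy term**: Eᵢ = X⁻ + X, a sum, exactly as the model is printed, even
  though its geometric meaning as "distraction" is unclear.
* **Step clamp**: ΔX is clamped elementwise to [−6, 6] (configurable) so
  the transfer function stays responsive; the model itself does not bound
  ΔX.
* **Schedules**: γ (one per factor) and f are drawn once per iteration and
  shared by the swarm, matching the scalar schedule traces of the model;
  per-dragonfly draws would also be defensible but are not used.
* **Initialization**: each bit Bernoulli(0.5); initial steps zero.
* **Stopping**: maximum iterations by default; an absolute-error tolerance
  on successive best costs is available (`stop_tol`).
* **RNG**: one seeded `numpy` generator per run, consumed in a fixed order
  (initial bits, then per iteration the three γ draws and f, then the flip
  draws), so runs are bit-reproducible from the seed.
* **Lévy flight**: implemented with the printed 0.10 prefactor (exposed as
  a parameter; the canonical continuous-domain reference uses 0.01) and
  unit-tested, but not wired into the binary run loop: with a whole-swarm
  neighborhood the "no neighbors" trigger never fires, and the
  multiplicative position update is not binary-valid. It is kept for a
  future continuous mode.
* If an update leaves every mask in the population empty, those individuals
  are re-randomized and a warning is logged.

Defaults mirror common practice for this optimizer family: 50 iterations,
10 dragonflies.

## Frameworks and evaluation

`select_multi` derives R per-run seeds deterministically from a master seed
(distinct yet reproducible), runs the optimizer R times on the full data,
tallies votes per channel, and keeps channels with votes/R ≥ vp
(inclusive at the boundary; default vp = 0.65, the midpoint of the
commonly recommended 60–70% band). An empty final mask at high vp is
reported as empty with a warning — never silently relaxed; the tally is
always returned so a lower vp can be chosen.

`select_ensemble` differs only in drawing a bootstrap subset per run:
n indices sampled with replacement, deduplicated (≈63.2% of distinct
samples survive on average), with a fresh fold assignment sized to the
subset. Final masks from both voting frameworks are evaluated by
RMSECV/R² on the **full** dataset so all frameworks are compared on the
same footing; `select_single` evaluates its best mask on the run's own
folds (its food cost). How the original protocol assigned evaluation folds
is not stated; both a shared-folds and a per-repeat-folds variant were
examined and the qualitative conclusions below do not depend on the choice.

`stability_report` summarizes repeated invocations: mean and standard
deviation of final-mask RMSECV (the primary stability index), per-channel
selection frequency, and mean pairwise Jaccard similarity of the final
masks (an additional diagnostic beyond the mean/std index).
`grid_experiment` sweeps (max_iter × swarm size) cells with repeated
seeded single runs.

## Synthetic data

The generator emulates a benchtop NIR calibration study: unit-amplitude
Gaussian absorption bands (the simplest smooth NIR-like profile), linear
mixing by per-sample concentrations drawn U(0.2, 1), additive i.i.d.
Gaussian noise on absorbance (sd 0.005) and target (sd 0.05), and a target
that is a linear combination of the concentrations of the designated
informative components. The default fixture is 60 samples × 401 channels
(900–1700 nm at 2 nm), four bands at 1050/1220/1420/1600 nm with widths
30/45/35/50 nm, two of them informative with coefficients 1.0 and 0.6.
The noise levels were set so the full-spectrum calibration quality matches
the regime typical of published gasoline NIR work (RMSECV/σ_y ≈ 0.25,
cross-validated R² ≈ 0.93). Ground truth marks every channel within one
band width of an informative center (window multiplier adjustable).

What the generator does **not** emulate: scatter and baseline drift,
instrument nonlinearity, wavelength-correlated noise, and the rough,
chemistry-driven cost landscape of real spectra. Consequently, passing
tests demonstrate correct mechanics and qualitative behavior (recovery of
informative regions, voting monotonicity, budget effects), not
field performance on real spectra.

## Known limitations

* At desk-scale budgets (≈250–500 cost evaluations) the swarm only mildly
  enriches informative channels; best masks remain large (~half the
  channels). On the smooth, highly redundant synthetic fixture this has a
  measurable consequence: repeated single runs produce large masks with
  uniformly similar RMSECV, while vote aggregation compresses
  near-chance per-channel frequencies into much smaller masks whose RMSECV
  varies *more* across repeats. The variance-reduction benefit of voting
  therefore does not reproduce on this fixture, although voting does
  improve the mean RMSECV and ensemble and multi remain within a few
  percent of each other. On data with sharper, localized information the
  ordering is expected to revert.
* The problem sizes used in the test suite (25-iteration budgets,
  10 repeats) are the package's default desk-scale study conditions; the
  library itself has no such limits.
* Single-target (PLS1) calibration only; no independent-test-set RMSEP; no
  interval-based selection methods.
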