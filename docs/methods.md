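# Methods

## Model

Let X be a contact count with mean μ and intensity-dependent noise
sd[X] = h(μ). For any smooth monotone g, a first-order Taylor expansion
gives Var[g(X)] ≈ g′(μ)² h(μ)². Requiring Var[g(X)] = C² yields the
differential equation g′(μ) = C / h(μ), hence the variance-stabilizing
transform

```
t(x) = ∫₀ˣ C / h(u) du .
```

Known special cases used as oracles throughout the test suite:

* h(μ) = √μ (Poisson) → t(x) = 2C√x (Anscombe, up to the +3/8 shift);
* h(μ) = √(μ + αμ²) (negative binomial) →
  t(x) = (2C/√α)·ln(√(αx) + √(1 + αx)).

`hicvst` does not assume either law; it estimates h from data.

## Estimating h from two replicates

Two biological replicates M1, M2 measure the same underlying map with
independent noise. Each shared matrix cell contributes a row
(base, aux) = (M1[i,j], M2[i,j]). The procedure:

1. **Pairing** (`build_base_aux`). By default only cells that are nonzero
   in at least one replicate enter (`zero_policy="union_nonzero"`); Hi-C
   maps are dominated by structural and sampling zeros that would
   otherwise swamp the low-intensity bins. `all_pairs` is available for
   dense inputs. Multiple chromosome pairs can be pooled; an optional
   `symmetrize` flag averages the curves learned with the base/aux roles
   swapped.
2. **Sort and bin** (`sort_and_bin`). Rows are stably sorted by the base
   value and cut into B = ⌈BP/s⌉ consecutive bins of `s` rows (last bin
   takes the remainder).
3. **Moments** (`estimate_moments`). Per bin: mean and population stdev
   (divisor = the bin's actual row count) of the **aux** column only.
   Since base and aux noise are independent, the aux spread inside a bin
   estimates the measurement noise at that intensity. The computation is
   two-pass (mean first, then squared deviations) to avoid the
   catastrophic cancellation of the one-pass E[x²]−E[x]² form on
   near-constant bins.
4. **Curve fit** (`fit_mean_sd_curve`). A cubic smoothing spline is fit
   through the (μ_b, σ_b) points with smoothing chosen by generalized
   cross-validation. The fit runs on the arcsinh(μ) axis with bin-count
   weights: the abscissae span several orders of magnitude and the sparse
   far tail would otherwise destabilize the spline. The curve is clipped
   below at `floor_eps` (default `max(1e-8, 0.01 × median σ_b)`) and
   extended as a constant outside the support.
5. **Integration** (`derive_transform`). t is tabulated on the
   asinh-spaced grid x_k = sinh(k·asinh(x_max)/N), k = 0..N (dense near
   zero where the transform curves hardest). The cumulative trapezoid
   rule is applied after the substitution u = w²: count-noise laws have
   h ~ √u near zero, where the raw integrand C/h has an integrable
   singularity the plain rule cannot resolve, while the substituted
   integrand 2wC/h(w²) is flat. The first grid cell uses the midpoint
   rule, which is exact both for square-root laws and for curves held
   constant below their support. Evaluation between knots is
   piecewise-linear (hence exactly monotone); beyond x_max the final
   segment's slope extrapolates.

`rescale_log_converge` optionally post-composes an affine map a·t + b
fitted by least squares to ln(x) over the upper half of the grid, for
workflows that expect log-scale values at high counts; it changes neither
ranks nor variance stability (VI is affine-invariant).

## Parameter defaults and why

* **s (rows per bin) = 10, auto-shrunk so that at least 50 bins exist.**
  The per-bin aux stdev estimates noise **plus** the spread of true means
  within the bin. That second term is bias, grows with bin width, and no
  amount of spline smoothing removes it — smoothing only averages the
  bias in. Small bins undersmooth (noisy σ_b), but the second-stage
  spline absorbs that noise; wide bins produce a bias nothing downstream
  can undo. With s = 10 the learned curve tracks the underlying law
  closely and transformed per-bin stdevs come out at 1.0 ± 0.05 across
  seeds; with s in the thousands they undershoot by ~30%.
* **C = 1**: unit target stdev.
* **n_grid = 1000**: the substituted trapezoid rule is then accurate to
  ~1e-5 relative against the NB closed forms.
* **floor_eps**: keeps 1/h integrable when a bin has zero spread; scaled
  to the data (1% of the median σ_b) so the floor only engages below the
  measured noise scale.

## The synthetic generator

`simulate_pair` draws two conditionally independent replicates of one
λ-field:

```
λ_ij = L · (|i−j| + 1)^(−γ) · b_i · b_j        (intra; inter omits decay)
X_ij ~ NB(mean λ_ij, Var λ + αλ²)   (Poisson when α = 0)
```

with log-normal per-bin biases b_i (sd `bias_sd`) and a fraction
`sparsity_p` of structural zeros shared by both replicates (unmappable
bins are zero in both). Defaults: 400 bins of 50 kb, L = 50, γ = 1,
α = 0.2, bias_sd = 0.3, sparsity_p = 0.05 — sized to run end-to-end in
seconds. The generator emulates marginal count statistics and distance
decay only; it deliberately contains no TADs, loops, or compartments,
which are irrelevant to variance stabilization.

## Diagnostics

`variance_instability` re-bins a transformed pair exactly as during
learning and reports VI = sd(σ′_b)/mean(σ′_b), the coefficient of
variation of per-bin stdevs: 0 means identical spread at every intensity.
VI is exactly invariant under positive affine maps of the signal, so it
compares transforms with different output scales fairly. The report also
carries mean σ′_b (calibration against C) and the least-squares slope of
σ′_b on μ′_b (residual trend).

## Limitations

* **Small-count bias.** Binning by the noisy base replicate mixes cells
  with different true means; the aux spread then exceeds the pure noise
  sd, by up to ~√2 where the within-bin mean spread matches the noise.
  The effect is strongest at low counts under `union_nonzero` (the
  truncation also makes the mean–stdev relation non-functional there) and
  shrinks as counts grow. Consequence: learned transforms mildly
  over-stabilize the lowest intensities; the unit-variance calibration
  (mean σ′ ≈ 1.0, |trend| < 0.05) still holds.
* Values transformed with the log-converge rescaling can be negative
  (b < 0); contact-matrix containers enforce non-negative values, so that
  variant is meant for downstream arrays, not for re-ingestion.
* Single resolution only; no `.mcool` pyramids, no read-level input, and
  no matrix balancing — balanced matrices are accepted as input (`.cool`
  weight column) but ICE/KR themselves are out of scope.
* The two replicates must share binning and chromosome naming; cells are
  paired strictly by (i, j).
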