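# Methods

`netcov` computes pairwise covariance functions in weakly correlated
recurrent neuronal networks along two routes — exactly, from the linear rate
theory, and empirically, from direct stochastic simulation of linear, binary,
Hawkes and leaky integrate-and-fire (LIF) networks — and provides the
linearization maps that connect the two.  This note records the model, the
numerical choices, and what the shipped comparisons do and do not establish.

## The linear rate model and its two noise classes

The backbone is a network of linear rate units with an exponential response
kernel `h(s) = (1/tau) θ(s) e^(−s/tau)` (unit integral), a conduction delay
`d`, and additive white noise of power `rho2`.  The two classes differ in
where the noise enters:

- **input noise** — `tau dr/dt = −r + w r(t−d) + x(t)`; the recorded signal
  is `r`.  This is the class binary networks map onto.
- **output noise** — the unit transmits `y = r + x`, with
  `tau dr/dt = −r + w y(t−d)`.  Spiking models (Hawkes, LIF) map onto this
  class; `x` plays the role of each neuron's own spiking noise.

In the frequency domain (`C(ω) = ∫ c(t) e^(−iωt) dt`,
`c(t) = (1/2π) ∫ C(ω) e^(iωt) dω`):

    input  : C = (H_d⁻¹ − w)⁻¹ D (H_d(−ω)⁻¹ − wᵀ)⁻¹
    output : C = (1 − H_d w)⁻¹ D (1 − H_d(−ω) wᵀ)⁻¹

with `H_d(ω) = e^(−iωd)/(1 + iωτ)` and diagonal noise matrix `D`.

**Poles.**  Both propagators diverge at the solutions of
`(1 + i z τ) e^(izd) = L` for each eigenvalue `L` of `w`:
`z_k = i/τ − (i/d) W_k(L (d/τ) e^(d/τ))`, one per branch `k` of the Lambert-W
function (`z = i(1−L)/τ` for `d = 0`).  Each root is Newton-polished so the
characteristic-equation residual is at machine level regardless of branch.
Stability requires all `Im z_k > 0`; real parts give collective oscillation
frequencies.

**Time domain.**  For the population-averaged 2×2 system (eigenvalues
`{0, L}`, identical rows of `M`, so `M² = L·M`) the inverse Fourier transform
is evaluated exactly by the residue theorem.  For `t ≥ 0`, with
`B = M − L·1`:

    input  : c(t) = D φ1 + B D φ2 + D Bᵀ φ3 + B D Bᵀ φ4
    output : c(t) = M D Mᵀ φ1 + M D φ0 + D δ(t)

and `c(−t) = c(t)ᵀ`.  The φ functions are sums over the poles `z_k(L)` plus,
where the kernel pole `i/τ` contributes, closed extra terms.  Two derivation
details matter and were validated against the independent quadrature oracle:

- the echo function `φ0` (the transform of `f(ω) = 1/(H_d⁻¹ − L)`) vanishes
  identically for `t < d` (contour closes in the lower half-plane) and jumps
  at `t = d`;
- the `φ2` integrand decays in the *upper* half-plane only for `t > d`; for
  `0 ≤ t < d` the contour closes below and the transform equals `φ3(−t)`,
  whose pole sum is valid for all `t > −d`.  `φ2` is therefore evaluated
  piecewise.

Class signatures follow directly: under output noise all four covariance
blocks are equal for `0 < |t| < d` (causality — no network interaction has
arrived yet) with discontinuous echo jumps at `|t| = d`; under input noise
the covariance is continuous everywhere.

**Decomposition.**  The output-noise solution splits into the δ term (own
noise), the symmetric common-input term (`M D Mᵀ φ1`) and the echo term
(`M D φ0` and its transpose at negative lags).  The analogous input-noise
split assigns `D φ1` to the own-noise role, `φ2/φ3` terms to the echo and the
`φ4` term to common input.  Empirically the common part is measured with
auxiliary read-only units (two independent copies per unit, receiving the
full network input but projecting nowhere); the covariance between distinct
copies isolates the common input, and echo := full − common holds exactly by
construction.  For output noise the auxiliary measurement coincides with the
analytic common term (shown using `M(1 + H_d B) = M`); for input noise the
two splits differ by terms proportional to `L`, so only the output-noise
agreement is asserted.  On the diagonal the empirical "echo" also retains the
unit's own-noise autocovariance; pairwise statements use the off-diagonal
blocks.

## Numerical choices

- **Branch cutoff**: residue sums run over `|k| ≤ 20` (41 branches) by
  default; doubling the cutoff changes the curves by < 0.1% relative L2.
  Convergence is slowest exactly at the jump `t = d` (the value there is the
  one-sided limit from above) and at `t = 0`, where the sums converge ~`1/k²`;
  the zero-lag boundary identity `2c(0) = Mc(−d) + (Mc(−d))ᵀ + D/τ` is
  therefore satisfied to ~1e−5 absolute, not machine precision.
- **Balanced coupling** (`L ≈ 0` with `M ≠ 0`) makes the kernel pole double;
  the closed forms refuse this case and the quadrature route
  (`numeric_inverse_ft`) is the supported path.
- **Quadrature oracle**: plain trapezoid inversion of the sampled spectrum;
  the non-decaying δ part of the output-noise spectrum must be declared and
  is subtracted.  The echo part decays only ~1/ω, so the oracle uses a wide
  frequency range (up to 1500/τ) for output noise; disagreement near the
  jump is a property of the oracle, and oracle comparisons exclude a narrow
  window around `|t| = d`.
- **LRM integrator**: uniform grid with the exact exponential (OU) update for
  relaxation and noise and a piecewise-constant treatment of the delayed
  drive, read so that the update to `t_{k+1}` uses the signal at
  `t_{k+1} − d`.  A naive Euler–Maruyama step with the delayed read at `k−D`
  has an effective delay `d + dt` that visibly shifts the oscillatory
  covariance at default resolution.  With `w = 0` the input-noise process is
  sampled exactly; coupling introduces an `O(dt)` bias, kept below the
  Monte-Carlo error at the default step (`τ/100`; the output-noise
  full-precision comparisons use `τ/200` because of the jump).
- **Estimation**: FFT correlograms with global-mean subtraction and a
  one-step correction of the mean-removal bias (`+ (1/T) Σ_ℓ ĉ(ℓ)`), which
  otherwise reaches the size of the standard error on long recordings.
  Standard errors come from a 20-segment bootstrap, valid under temporal
  correlation.  Spike trains are binned at 0.5 ms (the δ peak appears as mass
  `rate/bin` in the zero-lag bin), binary states are sampled at `τ/10`, rate
  trajectories at the integration step.

## Statistical comparison protocol

Simulation–theory agreement is assessed pointwise as `|sim − theory| / SE`.
With 20-segment bootstrap errors the pointwise statistic is approximately
t₁₉-distributed, and estimator errors are correlated across neighbouring
lags, so even a perfect theory produces a few percent of lag points beyond
3 SE.  The shipped tests therefore gate *exact* linear-model comparisons at
≥ 98% of points within 3 SE (≥ 95% for single long smooth curves with few
effective degrees of freedom) and *linearized* nonlinear-model pipelines at
≥ 85–90% with no point beyond 8 SE, alongside the qualitative signatures
(equal blocks, echo jumps, oscillation on/off) that are the substantive
claims.  Bins straddling a discontinuity (δ peak, echo jump) are excluded.

## Model mappings and reference conditions

The original study conditions (network sizes, weights per figure) are not
part of the available text; the package fixes its own reference conditions
once, chosen as weakly correlated regimes in which each linearization is
valid at the resolution of the recordings, and uses them everywhere
(`workbench.make_fixture`).

**Binary** (`N_e = 400`, `γ = 0.25`, `K = 200`, `J = 0.025`, `g = 8`,
`β = 0.5`, `τ = 10 ms`, `T = 4×10⁴ ms`): asynchronous Glauber-type dynamics
simulated event-exactly (pooled Poisson update clock, incremental delayed
drive).  The working point solves `a = ⟨φ⟩_{N(μ(a),σ(a))}` with
`μ = KJ(1−γg)a`, `σ² = KJ²(1+γg²)a(1−a)` (damped fixed point, bisection
fallback; Gauss–Hermite order 64).  Mapping: input-noise LRM with
`w = β_eff J`, `rho2 = 2τa(1−a)`.  The Gaussian-averaged slope `⟨φ′⟩` is the
default linearization; at the reference point it is ~45% above the slope at
the mean (`L ≈ −0.86` vs `−0.59`).  The eigenvalue-cloud radius of the
effective matrix is ~0.15·|L|: at stronger coupling (radius comparable to
|L|) single fixed-in-degree realizations visibly depart from the
realization-averaged theory — a property of the reduction (see below), not
of the simulation.  The linearization ranking (Gaussian-averaged ≤ at-mean
error) is asserted on the error pooled over two realizations and both
delays: at `d = 0.1 ms` alone the short-delay covariance differs between the
two theories by no more than the realization scatter, so the single-run
ranking there is a coin flip, while at `d = 10 ms` the Gaussian average wins
decisively for every realization tried.
`d = 10 ms` produces damped ringing (detected as a theory-predicted trough
with ≥ 2 zero crossings, confirmed by a windowed segment t-test at the
predicted trough lag); `d = 0.1 ms` does not.

**Hawkes** (`N_e = 400`, `K = 200`, `J = 0.015`, `g = 5`, `ν = 0.04/ms`,
`τ = 10 ms`, `d = 3 ms`, `T = 2×10⁴ ms`): exact thinning simulation
(per-neuron positive/negative synaptic traces, FIFO delayed delivery,
redraw-after-delivery bound).  The rectified stationary rate solves
`λ0 = σ/√(2π) e^(−μ²/2σ²) + μ P_{μ,σ}(r>0)` with `μ = ν + λ0 KJ(1−gγ)` and
`σ = J √(λ0 K (1+g²γ)/(2τ))` (Campbell's theorem for the exponential
kernel).  Mapping: output-noise LRM with `w = P_{μ,σ}(r>0)·J`, `rho2 = λ0`.
The Gaussian closure requires the filtered shot noise to be near-Gaussian:
individual trace jumps are `J/τ` (inhibitory `gJ/τ`), so the reference uses
dense in-degree and small weights (jumps ≈ 0.35σ); at sparse/strong settings
(jumps ≈ 0.7σ) the rate closure is measurably biased.  Rectification is
active (~11% of neuron-time clipped, `P ≈ 0.87`); the simulator reports the
clipped fraction and warns above 25%.

**LIF** (`N_e = 400`, `K = 200`, `J = 0.032 mV`, `g = 6`, `τ_m = 20 ms`,
`τ_s = 0.5 ms`, `τ_r = 2 ms`, `V_θ = 20 mV`, `V_r = 0`, `d = 1.5 ms`,
balanced external Poisson drive `±0.1 mV` giving `μ_ext = 19.2 mV`,
`σ_ext² = 5.76 mV²`, `T = 10⁴ ms`, `dt = 0.025 ms`): exact exponential
subthreshold propagation, grid threshold detection (bias `O(dt)`), delayed
current jumps `τ_m J/τ_s`.  The stationary rate uses the colored-noise
formula with boundary shift `(α/2)√(τ_s/τ_m)`, `α = √2|ζ(1/2)|` (own
accelerated alternating-series evaluation of ζ(1/2), tested against an
independent route).  The DC-susceptibility is
`w_ij = ∂r_i/∂r_j = α J_ij + β J_ij²` with the analytic coefficients equal to
the exact derivative of the rate formula (verified by finite differences).
The effective kernel time constant is measured from the single-neuron
impulse response (paired common-random-number trials, one extra 0.15 mV
impulse; the probe amplitude is fixed rather than tied to `J` for
signal-to-noise) and reduced to a single exponential by the moment estimator
`τ_eff = integral/peak` of the smoothed decaying flank — a log-linear fit
over a long window latches onto the non-exponential tail and noise floor.
At the reference point `τ_eff ≈ 3 ms ≪ τ_m`.  Mapping: output-noise LRM with
`rho2 = r` (δ-approximated spike autocovariance).  Two quantified
limitations: (i) direct response-integral measurements show the
diffusion-based susceptibility overestimates the true effective weights by
~30% at PSPs of ~1 mV — the reference therefore uses weak synapses so this
systematic stays below the Monte-Carlo resolution of the 10 s recording;
(ii) the true response kernel is not a single exponential, so the echo flank
is reproduced at the 20–30% level; the asserted network properties are the
short-lag structure (equal blocks below `d`, the echo jump at `d` and its
size) rather than the full curve.

**Population averaging.**  Block averages
`c_ab = (N_a N_b)⁻¹ Σ_ij c_ij` equal the covariance of population-mean
signals (including `i = j`; a disjoint-pairs option removes the mean
single-neuron autocovariance exactly).  The reduction of the full weight
matrix to `M = Kw[[1, −γg],[1, −γg]]` is *exact* for fixed out-degree
(every column has exactly `K`/`γK` targets) and holds only in expectation
for fixed in-degree.  Near the bifurcation — eigenvalue-cloud radius
`w√(N_e p(1−p)(1+γg²))` approaching the stability margin — single
fixed-in-degree realizations develop long-lived modes and depart strongly
from the reduced theory while fixed out-degree realizations still match;
far from the bifurcation both agree.  Nonlinear models use fixed in-degree
(identical input statistics justify one shared linearization), which bounds
how far their operating points may sit from the bifurcation.

## What the synthetic data do and do not show

All inputs are generated by the package's own simulators; there is no
external data.  The generators emulate stationary, homogeneous,
asynchronous-irregular network activity with a single synaptic time constant
and delay.  Passing tests show that the closed-form covariances are correct
for the models as defined, and that the linearization maps are quantitatively
accurate in the stated weakly correlated regimes at the stated recording
lengths.  They do not certify the maps at strong coupling, near balance
(`γg ≈ 1`), under heterogeneous parameters or non-exponential kernels, in
mean-driven LIF regimes, or for real recorded data, which are nonstationary
and heterogeneous in ways none of the generators emulate.
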