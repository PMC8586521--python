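# Methods

This note documents the models, numerical choices and limitations of
`poreblock`. It is written for users who want to know *what* is computed and
*why the defaults are what they are*, in the package's own terms.

## 1. Ion hopping in the selectivity filter (`ionflux`)

Permeation is modelled as a continuous-time Markov chain over five filter
configurations arranged in a cycle ("soft knock-on": K+ ions separated by
water molecules hop between binding-site arrangements). States 1 and 2 have
the inner sites S2 and S4 empty; states 3–5 carry ions in both, so the site
occupancies follow from the stationary distribution as

    P(S4) = P3 + P4 + P5,        P(S2) = P(S4) by construction.

Each directed transition i→j has a rate

    k_ij(V) = k0_ij · a_coupled · exp(δ_ij · F·V / (R·T)),

with `k0_ij` the rate at 0 mV and unit activity, `δ_ij` a signed electrical
distance, and `a_coupled` the K+ activity on the coupled membrane side
(cytosolic for entry into the cavity via 1→2, external for entry from the
outside via 5→4). Voltage is referenced to the cytosolic side; the external
side is grounded. The per-edge translocated charges q = δ_fwd − δ_rev sum to
1 around the cycle, so the cycle affinity at voltage V is exactly F·V/(R·T)
— at +100 mV, 3.8922 — and vanishes at 0 mV for a detailed-balanced set.

**Stationary solve.** P solves P·Q = 0, ΣP = 1, computed by least squares on
the row-scaled generator with an explicit normalization row. Before solving,
the strongly connected components of the positive-rate graph are checked:
more than one *closed* class raises an error that lists the classes rather
than silently picking a vector. Transient states (e.g. state 2 of the
blocked scheme) are handled naturally and get probability 0.

**Blocking.** A cavity-bound quaternary-ammonium blocker occupies the place
of the cavity ion, so `apply_block` zeroes k(1→2), k(2→1) and k(3→2) and
leaves everything else untouched. This opens the cycle: micro-reversibility
no longer constrains the stationary state at nonzero voltage, which is
exactly what reshapes the voltage dependence of P(S4) in the blocked
channel. At 0 mV with detailed balance, cutting edges of a reversible chain
cannot change the relative weights of the surviving states — a property the
test suite asserts exactly.

**Default parameter set.** The shipped `kcv_like_scheme()` is a synthetic
stand-in, not a fitted set: rate constants of order 10^8–10^9 s⁻¹ (single-ion
transit on the 10-ns scale, stationary currents of a few pA at ±160 mV),
activity coefficient 0.77 for KCl (100 mM ↔ 77 mM activity), and electrical
distances chosen so that the blocked-channel P(S4) rises monotonically from
≈0.34 at −160 mV to ≈0.97 at +160 mV. One rate (k23) is derived from the
detailed-balance product constraint instead of being quoted, so
micro-reversibility at 0 mV holds to machine precision by construction. Any
real parameter set can be supplied as a YAML/JSON scheme file and flows
through the identical machinery.

## 2. Blocker release (`blockrelease`)

Release of the blocker is a barrier crossing whose height depends on whether
S4 holds an ion. Weighting the empty-S4 and occupied-S4 scenarios by
P(S4, V) gives

    koff(V) = a·(1 − P(S4)) + c·P(S4) = a + b·P(S4),   b = c − a,

with `a`, `c` (equivalently `a`, `b`) voltage-independent: all voltage
dependence of release enters through the filter occupancy. The ion-induced
barrier change is

    ΔΔG = −ln(1 + b/a)   [kT],

convertible to kJ/mol with R·T (298.15 K by default; configurable). Absolute
barrier heights and the attempt prefactor are not identifiable from koff
data and are deliberately not represented.

**Fitting.** `fit_release` regresses koff on P(S4) by least squares.
Options: unweighted (default — the model is linear in P(S4) and this is the
simplest defensible loss), `inverse_square` (fixed 1/koff² weights), and
`relative` (iteratively reweighted 1/fitted², two reweighting passes).
For lognormally dispersed rate constants the relative loss is the
appropriate one, and unlike weighting by the noisy observations themselves
it does not bias the slope. Parameter covariance comes from the usual
weighted-least-squares formula with residual variance on n−2 degrees of
freedom; confidence bands are delta-method (t-quantile) bands for the mean
response. A fitted intercept can come out non-positive under heavy noise;
the model object represents such estimates faithfully and the ΔΔG
computation raises a domain error instead of silently clamping.

**Prediction under new conditions.** Because a and b are properties of the
blocker–ion interaction, a fit obtained in symmetric solutions predicts
asymmetric ones by recomputing P(S4, V) with the blocked scheme under the new
activities and reusing (a, b) with their covariance.

**Energetics bookkeeping.** `release_energy_cycle` combines four excess
chemical potentials and a direct blocker–ion interaction energy,

    μex(ch+K) − μex(ch+blocker+K) − [μex(ch) − μex(ch+blocker)] − ΔE,

and `voltage_energy` converts z·F·V to kJ/mol (≈9.65 kJ/mol for one charge
across 100 mV) — the scale argument for neglecting the direct action of the
field on the blocker.

**Pooling.** Per-channel rate constants are pooled per voltage with
geometric mean and geometric SD (lognormal-consistent); groups measured at
different blocker concentrations merge, since release does not depend on
blocker concentration.

## 3. Synthetic recordings (`simchan`)

The generator emulates planar-bilayer single-channel recordings:

* **Gating model:** states O (conducting, I_true), F/M/S (intrinsic closed
  states with fast/medium/slow dwells) and B (blocked), with B connected
  only to O and kOB = konO·[blocker].
* **Defaults** (frozen; chosen once as typical for a small viral K+ channel
  at room temperature): kOF = 1.5e3, kFO = 6e4, kOM = 40, kMO = 1.2e3,
  kOS = 1.5, kSO = 15 s⁻¹ (open probability ≈0.86), konO = 2e8 M⁻¹s⁻¹,
  conductance 55 pS (I_true = 8.8 pA at +160 mV), baseline noise SD 0.8 pA,
  1-kHz 4-pole Bessel filter, 5-kHz sampling. Fixture grids span ±160 mV
  and blocker concentrations 0.05–5 mM.
* **Simulation:** exact stochastic simulation (exponential dwells, embedded
  jump chain) in compiled (numba) kernels; event sequences tile the duration
  exactly and all randomness derives from explicit seeds
  (`SeedSequence`-split into gating and noise streams). A state with zero
  exit rate raises by default; rendering contexts may instead hold it for
  the remaining duration.
* **Rendering:** the ideal piecewise-constant current is integrated
  area-preservingly onto an oversampled grid (default 20× the sampling
  rate), filtered, decimated, and overlaid with white Gaussian noise at the
  sampling rate. Sub-bin dwells therefore contribute their exact area even
  when mean dwell times (µs) are far below the oversample interval — the
  regime that produces excess noise.
* **Filter discretization:** the analog 4-pole Bessel prototype (−3 dB at
  fc, unit DC gain) is discretized by zero-order hold at the oversampled
  rate. For a piecewise-constant input this reproduces the analog jump
  response exactly at sample instants; a bilinear transform was measured to
  leave a rise-time error of ~1.4 % of the jump amplitude at 20×
  oversampling, above the 1 % fidelity this package promises.

What the generator does **not** emulate: baseline drift, mains hum,
capacitive transients, amplifier nonlinearity, multi-channel membranes, or
any colored noise beyond the filtered signal itself (baseline noise is white
at the output). Passing tests therefore demonstrate correctness of the
analysis chain under the stated idealizations, not robustness to every
artifact of real recordings.

## 4. Amplitude-histogram analysis (`betafit`)

Blocking far above the filter bandwidth leaves no resolvable events, only a
shifted, broadened open-channel peak ("excess noise", the beta-distribution
regime). Hidden rates are recovered by matched simulation:

* **Objective:** Pearson χ² between the measured histogram and a histogram
  simulated with identical filter/noise settings, with adjacent bins pooled
  (on the measured counts, once per fit) to at least 5 counts. Common random
  numbers — one fixed seed per fit — make the objective a deterministic
  function of the parameters; two evaluations at the same point are
  bit-identical.
* **Search:** Nelder–Mead over log-transformed rates (I_true linear), with
  optional restarts from perturbed starts; non-convergence is flagged, not
  raised. Default bins: half the baseline noise SD.
* **Fit window:** when the intrinsic closed states are held fixed, the mass
  of the closed peak differs between the measured and the simulated
  realization purely by the randomness of slow gating, which adds noise to
  the objective without carrying blocking information. `open_peak_window`
  restricts the fit to the open-peak region (0.4·I_true to I_true + 4 noise
  SDs); this measurably sharpens short-trace fits.
* **Identifiability:** for rates far above the bandwidth, the open peak is
  close to Gaussian — two moments. Its position fixes kBO/(kBO+kOB) given
  I_true, its excess width fixes the total speed. I_true itself is therefore
  determined from a blocker-free control recording at the same voltage
  first, then held fixed (the default free mask remains kOB, kBO, I_true for
  generic use). `blocking_rate_init` converts the apparent-current ratio
  into starting values. Measured single-trace accuracy at 60 s within the
  detectable window (≈7e3–7e5 s⁻¹): median kBO error of a few percent,
  seed-to-seed scatter ~9 %; errors grow toward the edges of the window.
* **Assembly:** fitted kBO values are pooled per voltage across blocker
  concentrations into a koff(V) dataset; a diagnostic reports the spread of
  kBO between concentration groups at shared voltages and the collapse of
  kOB/[blocker] onto konO.

## 5. Pipeline and problem sizes

`run_pipeline` chains generation → control fits (I_true) → blocker fits
(kOB, kBO) → koff pooling → release fit → ΔΔG → asymmetric prediction, all
from one explicit seed; reruns are byte-identical. The shipped demo
configuration uses four voltages, one blocker concentration and 10-s traces
so a full run takes about a minute; the test suite uses 60-s traces where
recovery accuracy is the claim, and 3-s traces where only the contract
(completion, determinism, file formats) is under test. Trace ground truth in
the pipeline uses kBO(V) = a + b·P(S4, V) with the blocked-scheme occupancy,
closing the loop between the generator and the release model.

## 6. Known limitations

* The shipped hopping parameters are a stand-in; quantitative conclusions
  about a real channel require its fitted rate constants in a scheme file.
* The χ²-of-simulated-histogram objective is stochastic across CRN seeds;
  parameter uncertainty of histogram fits is not reported (only objective
  and restart diagnostics). Bootstrapping over CRN seeds would provide it.
* Blocker *binding* kinetics are represented only through the bilinear
  kOB = konO·[blocker]; no state-dependent binding beyond the open state.
* The energetics helpers do arithmetic on externally supplied excess
  chemical potentials; no solvation model is computed here.
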