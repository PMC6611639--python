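# Methods

## Model

The package models a community of *Bacillus subtilis* strains, each
producing and sensing a chemical variant of the ComX quorum-sensing
(QS) peptide, as a fully connected single-layer network. For strain
*i* with signal concentration `c_i` (nM), cell density `n_i`
(cells/mL) and a LacZ reporter `L` in the tester strain:

```
C_eff,i = max(0, sum_j w_ij c_j)                     (effective signal)
H_i(c)  = c^m / (c^m + theta_i^m)                    (Hill activation)
dL/dt   = rho_L n_i (f_i H_i(C_eff,i) + 1) - gamma_L L
dc_i/dt = rho_c n_i (f_i H_i(C_eff,i) + 1) - gamma_c c_i
dn_i/dt = mu_i n_i (1 - n_tot / s)
```

The crosstalk weight `w_ij` scales the contribution of strain *j*'s
signal to strain *i*'s activation; self-weights are 1 by definition and
a net-inhibitory weighted sum is clamped to zero (a receptor cannot
sense less than no signal). Production of both reporter and signal has
a basal rate (the `+ 1`) multiplied `(f + 1)`-fold at full activation.
Growth is logistic against a carrying capacity `s` shared by all
strains in a culture.

### Numerical scheme

The equations are integrated with explicit forward Euler at a fixed
step of `dt = 1 min`; the discrete update *is* the model contract, so
no adaptive integrator is used. Two consequences are load-bearing and
exploited throughout:

1. **Exact fold change at constant signal.** For a tester held at a
   constant effective concentration with `L(0) = 0`, the discrete
   recurrence for `L` is linear in the production boost, so the
   final-time fold change relative to the no-signal baseline equals
   `f·H(C_eff) + 1` exactly (to rounding), at every `dt`. The
   activation threshold (the fold change at `C_eff = theta`) is
   therefore `f/2 + 1`, and a tester is ON exactly when
   `C_eff >= theta`. The landscape and community modules use a
   vectorised implementation of this constant-signal readout
   (`fold_change_at`); the full simulator reproduces it bit-for-bit
   (tested).
2. **Accuracy.** At `dt = 1 min` the logistic growth curve matches the
   closed-form solution to ~1e-7 relative error at the 10 h endpoint;
   pointwise mid-exponential error is ~0.3–0.8% (first-order Euler) and
   falls linearly with `dt`. Halving `dt` changes all final states of
   the default coculture scenario by < 0.5% (acceptance-tested).
   Non-finite states abort integration with `IntegrationError` naming
   the variable and time.

### Units and conversions

* Signal concentrations in nM; supernatant stocks are taken to carry
  30 nM of signal. A volume `x` µl loaded into a 200 µl assay well
  contributes `30·x/200` nM, so the standard 0–25 µl grid spans
  0–3.75 nM.
* Tester assays start at `n0 = 1e8 cells/mL` and grow to the shared
  capacity `s = 1e9` within the 10 h assay; producer cocultures start
  at `1e6 cells/mL` per strain in a 3 mL tube.
* A perturbation bolus of `v` µl of supernatant into a culture of
  volume `V` mL adds `30 · (v/1000) / (V + v/1000)` nM instantaneously
  (200 µl into 3 mL ≈ 1.875 nM); the added signal then decays like any
  other.
* Coculture supernatants are assayed at a 150/200 dilution, and tester
  fold changes are normalised by each strain's activation threshold;
  normalised fold ≥ 1 counts as QS ON.

## Parameters

Strain-specific parameters of the packaged five-strain community
(labels A–E):

| strain | f | theta (nM) |
| --- | --- | --- |
| A | 5.955 | 1.393 |
| B | 4.083 | 1.633 |
| C | 24.839 | 1.364 |
| D | 8.345 | 1.394 |
| E | 6.951 | 1.815 |

Shared rate constants are package defaults, not strain-resolved
measurements:

* `m = 2` (Hill coefficient), `gamma_L = 0.01 /min`,
  `gamma_c = 0.005 /min`, `rho_L = 1e-9` (reporter units·mL/cell/min).
* `rho_c = 3.0e-11 nM·mL/cell/min` is **calibrated**, not measured: it
  is chosen so that a lone producer strain growing from 1e6 cells/mL
  accumulates ≈30 nM of signal by the 10 h harvest (simulated
  31.7 nM), matching the stock concentration attributed to
  stationary-phase supernatant.
* `mu = 1.5 /h` is a package choice within the range of *B. subtilis*
  growth in rich media; it brings cultures to stationary phase ~2 h
  before the 10 h harvest. Slower growth (e.g. 0.7 /h) leaves
  cocultures at ~half capacity at harvest, far from the regime the
  protocol describes.

### The packaged crosstalk matrix

`fig3d_signs()` returns the community weight matrix. Only one
off-diagonal entry is pinned to a measured interval midpoint — signal A
acting on strain C, `w_CA = 0.445`. The remaining off-diagonal entries
are package-chosen values that satisfy the qualitative interaction
structure of the community (C excited by A, strongly inhibited by B and
D, weakly by E; E responsive only to its own signal; mutual
A-excites/B-inhibited asymmetry between A and B; C inhibiting B while
promoting A). They were additionally screened so that the dynamic
scenarios below behave qualitatively correctly; they are **not**
measured values, and quantitative outcomes that depend on them (e.g.
the exact critical ratio) are fixture-conditional.

## Analysis stages

1. **Dose-response fitting** (`dose_response`). `(f, theta)` are fit by
   minimising the RMSE between measured and simulated fold changes over
   the dose grid. The objective is evaluated on a 5×5 log-spaced grid
   (`f ∈ [0.5, 100]`, `theta ∈ [0.05, 30]`) and the best three grid
   points are polished with Nelder–Mead in log-parameter space, making
   the fit deterministic. Flat curves raise `NonIdentifiableError`.
   Noiseless round trips recover the table above to ~1e-13; with
   additive noise of sd `0.1·f` on the fold changes, the mean over 20
   replicate fits recovers `(f, theta)` within a few percent
   (individual replicates can deviate by ~25% in theta).
2. **Weight extraction** (`landscape`). A pairwise activation landscape
   records ON/OFF over a (cognate volume × interactor volume) grid. A
   candidate weight `w` predicts a landscape; all `w` in a scan range
   (default `[-3, 3]`, step 0.001) whose prediction matches the
   observation exactly form the compatible interval. Because the
   constant-signal fold change is strictly monotone in `C_eff`, each
   grid cell constrains `w` by a half-line with critical value
   `w_crit = (c* - c_cog)/c_int`; the default `"boundary"` method
   intersects these half-lines analytically (upper endpoint open),
   while `"direct"` simulates every scanned landscape and agrees to
   within one scan step (tested). With `max_mismatch > 0` a tolerant
   scan handles noisy landscapes. Refining the grid from 6×6 to 26×26
   weakly tightens the interval.
3. **Community states** (`community`). Each strain's bit in the binary
   state string is computed from an independent tester simulation at
   the clamped weighted sum of the mixture concentrations, mirroring
   parallel single-tester measurements. `transition_scan` ramps one
   signal's volume and counts state transitions.
4. **Coculture dynamics** (`dynamics`). All strains produce signal;
   outcomes are read out by applying the harvested supernatant
   (diluted 150/200) to fresh testers. With the packaged fixture: a 1:1
   A/B coculture activates both strains; above a finite critical
   inoculation ratio (≈1.1 with these weights) strain A's inhibitory
   signal out-races strain B's QS ignition and B stays OFF while A is
   ON at every ratio. An early bolus of strain-C supernatant (inhibitory
   to B) blocks B permanently; past a switch time (~7 h here) the
   ignition has already happened and the same bolus is ineffective —
   the OFF→ON pattern over perturbation time shows a single monotone
   switch.
5. **Synthetic data** (`synth`). All analysis inputs can be generated
   from the forward model with known ground truth: plate-reader-style
   fluorescence-per-cell traces (with seeded Gaussian noise), noisy
   dose-response curves, bit-flipped landscapes and random communities.
   The early-trace slope readout (`lacz_rate`) agrees with the
   endpoint fold change within 5% (tested).

## Synthetic-data scope

No experimental data ships with the package. Every fixture and test
input is generated programmatically by `qscrosstalk.synth` or the
forward model itself; "recovery" results therefore validate internal
consistency of the inference stages against the forward model, not
agreement with wet-lab measurements.

## Limitations

* The shared rate constants (`rho_c`, `gamma_c`, `mu`, …) are
  calibrated or assumed, not fit; absolute signal concentrations and
  any quantity depending on kinetic ratios (critical inoculation
  ratio, perturbation switch time) are fixture-conditional.
* With `gamma_c = 0.005 /min` (signal relaxation time ≈ 200 min, needed
  for perturbations to persist into the ignition window), coculture
  signal concentrations are still 20–40% below their fixed points at
  the 10 h harvest; quantitative "steady-state" claims at 10 h are not
  made. On a 30–40 h horizon the signals settle to within ~0.1%.
* The binary community state treats testers independently; it ignores
  any higher-order (non-additive) signal integration.
* Forward Euler at `dt = 1 min` has first-order pointwise error
  (~0.5% mid-exponential); final-time quantities converge much faster.
  Use a smaller `dt` for trajectory-resolved comparisons.
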