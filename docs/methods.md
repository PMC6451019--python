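# Methods

## The circuit model

A basiconic sensillum houses two olfactory receptor neurons (ORNs) whose
sensory dendrites share a small lymph cavity. An auxiliary cell keeps the
lymph at a positive transepithelial potential and is modeled as a battery
`E_A` behind a reference resistance `R_A`; each ORN is a somatic battery
`E_i` behind its somatic input resistance `R_in,i`, in series with an
odorant-gated dendritic resistance `R_d,i`. Kirchhoff's laws for the three
branches sharing the lymph node give

```
V_A = E_A + I_A R_A
V_A = E_i + I_i R_i ,   R_i = R_in,i + R_d,i   (i = 1, 2)
0   = I_A + I_1 + I_2
V_m,i = E_i + R_in,i I_i
```

The model is purely resistive: it describes the steady state under
sustained stimulation, so capacitive currents are zero and no spiking
dynamics are represented. The local field potential (LFP) is the deflection
of `V_A` from its pre-stimulus value, reported as an absolute value
(activation makes `V_A` more negative).

All resistances are stored pre-divided by `R_A` (`R_A = 1`), so the
resistivities `rho_s` and `rho_d0` carry units of um² and currents are in
mV per unit `R_A` (arbitrary units). Voltages are unaffected by this
rescaling.

Two solution routes are implemented and cross-checked everywhere: a direct
assembly of the 4x4 linear system, and the closed form obtained by
collapsing the two neuronal branches into a Thevenin equivalent
(`E_T = (E_1 R_2 + E_2 R_1)/(R_1+R_2)`, `R_T = R_1 R_2/(R_1+R_2)`). They
agree to better than 1e-9 relative over randomized parameter sweeps.

## Morphometry-dependent resistances

- Somatic input resistance: `R_in = rho_s / A_s` — inversely proportional
  to soma surface area, so the larger "A" neuron has the lower input
  resistance.
- Dendritic resistance: `R_d = rho_d0 / (A_d (1 + g))`, where `g` is the
  activation-induced conductance gain. This is the lumped
  (short-electrotonic-length) limit of the cable formula
  `R_d = sqrt(r_m r_a) coth(L sqrt(r_a/r_m))`, which is provided as a
  validation utility; for electrotonic length `l <= 0.3` the lumped value
  is accurate to better than `l²/2` relative.
- Outer dendrites reconstructed volumetrically are converted to surface
  areas as cylinders: `A = 2 sqrt(pi V L)`.

## Odorant activation

Receptor activation follows a Hill function of concentration. Writing the
dilution as `od = c0 10^x` and the half-activation point as
`K_od = c0 10^k_od`, the activated fraction is
`1 / (1 + 10^{n (k_od - x)})` — the prefactor `c0` cancels exactly, so
`k_od` is a pure log10 dilution and `c0` is fixed to 1. The conductance
gain is `g = g_max * fraction`, with `g_max` the product of the basal
resistivity and the maximal induced conductivity. "Saturating" responses
use the infinite-concentration limit (fraction = 1) rather than the largest
tested dilution. The logistic form is evaluated through `scipy.special.expit`
for numerical stability at extreme exponents; `x = ±inf` is accepted as the
no-odorant / saturation limit, while NaN inputs are rejected.

## Resting-state calibration

The somatic batteries are not free: they are chosen so that, with zero
activation, both neurons rest at `V_0 = -60 mV`. The canonical computation
solves the six-equation linear system (four circuit equations plus
`V_m1 = V_m2 = V_0`) for `(V_A, I_A, I_1, I_2, E_1, E_2)` directly. The
closed-form expressions through the intermediates `xi_0` (branch asymmetry)
and `Theta_0` (driving-force rescale) are evaluated as a cross-check; any
disagreement beyond 1e-6 mV raises an internal calibration error. This
guards against sign-convention drift between the two derivations.

With the default parameter table the resting transepithelial potential is
negative (about -31 mV for ab4, -19 mV for ab5), whereas measured
transepithelial potentials are conventionally reported positive; the model
is implemented as specified and only relative field changes (the LFP)
enter any comparison with data.

## Ephaptic relations and the spike/LFP-ratio constraint

While one neuron's dendritic resistance changes, the neighbor's branch
resistance is constant, so both membrane-potential changes are exactly
linear in the field change: for ORN1 stimulated,
`dV_m1 = -dV_A R_in1 (1 + 1/R_2)` and `dV_m2 = dV_A R_in2 / R_2`. The
stimulated neuron depolarizes as the field drops; the neighbor follows the
field and hyperpolarizes.

The ratio of the two depolarization-per-LFP slopes,
`r = R_in2 (1 + 1/R_1,0) / (R_in1 (1 + 1/R_2,0))` with basal resistances,
is used as a proxy for the measured spike/LFP slope ratio. For sensilla
without measured dendritic surfaces the relation is inverted: given `r` and
the smaller neuron's `A_d2`, the larger neuron's dendritic surface follows
as `A_d1 = rho_d0 / (R_1,0 - R_in1)` with
`R_1,0 = R_2,0 / (r kappa + R_2,0 (r kappa - 1))`, `kappa = R_in1/R_in2`.
Ratios implying `R_1,0 <= R_in1` are rejected as non-physical.

## Default parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `E_A` | auxiliary-cell battery | 77 | mV |
| `V_0` | ORN resting potential (always fixed) | -60 | mV |
| `rho_s` | soma membrane resistivity (R_A-rescaled) | 30 | um² |
| `rho_d0` | basal dendritic resistivity (R_A-rescaled) | 17 | um² |
| `n` | Hill coefficient | 0.7 | — |
| `g_max` | maximal conductance gain | 10 | — |

Per-sensillum morphometry and sensitivities (ab3, ab4, ab5) ship in
`ephaptic/data/default_params.yaml`; ab5's dendritic surfaces are marked as
measured, ab3/ab4's as fitted.

## Simulation conventions

- "50% background activation" of the neighbor means activation fraction
  0.5, i.e. `g = 0.5 g_max`, held constant while the other neuron's
  concentration is swept. (The alternative reading — 50% of the saturating
  LFP — differs because the LFP is nonlinear in `g`; the g-fraction
  convention was adopted and is easy to vary through
  `dose_response(..., background_fraction=...)`.)
- Under a background, responses are re-zeroed at the background-only steady
  state.
- The default dilution grid is -10 to 0 in 0.25 log10 steps, covering all
  tabulated sensitivities.
- The mixture linearity deficit is
  `(|dV_A(x1)| + |dV_A(x2)|) - |dV_A(x1, x2 jointly)|`; it is nonnegative
  for this passive circuit and quantifies the competition of the two
  transduction currents for the shared field.

## Fitting

`global_fit` minimizes the sum of squared differences between model |LFP|
and the replicate-mean measurements, simultaneously over all sensilla in
the dataset, using multistart trust-region-reflective least squares
(`scipy.optimize.least_squares`). Structure:

- shared constants (`E_A, rho_s, rho_d0, n, g_max`) are common to all
  sensilla; `V_0` is always fixed;
- each neuron has its own `k_od`;
- ratio-mode sensilla (ab3, ab4) fit `A_d2` and the slope ratio `r`
  (bounded to (1, 5] by default), with `A_d1` computed from `r` — so the
  returned `A_d1`/`r` pair satisfies the slope-ratio relation exactly;
- measured-mode sensilla (ab5) keep both dendritic surfaces fixed.

Defaults: 32 seeded, jittered starts; unweighted residuals (inverse-s.e.m.
weighting is available; the measurement protocol does not prescribe one).
Infeasible parameter sets (calibration failure, non-physical implied
dendrite area) yield a large finite penalty so the optimizer can retreat.
Convergence tolerances are tight (1e-12) so that restarting from a returned
optimum does not improve the objective by more than 1e-8 relative.

**Identifiability.** The LFP curves constrain the shared constants only
weakly: `E_A`, `rho_s`, `rho_d0` and `g_max` trade off along a near-flat
ridge, and with all five free even a three-sensillum fit can drift far
along that ridge at no cost in residual. A fit of a single sensillum with
all shared constants free is flagged as under-determined in the result.
For parameter-recovery experiments the package therefore uses its
"fixed-common" mode — shared constants held at the generator's values,
freeing each `k_od` and the ratio-mode dendritic surfaces — which is also
the mode that reproduces the reference simulations exactly from the default
table. Recovery claims in the test suite apply to this mode only.

The empirical Hill fit (`hill_fit`) and the ordinary least-squares line fit
(`linear_fit`, slope = spike/LFP ratio) are provided for working with
measured dose-response curves and spike-vs-LFP point clouds; both reject
degenerate inputs (flat responses, constant abscissa) instead of returning
meaningless estimates.

## Synthetic data

`generate` emulates the structure of measured LFP dose-response tables:
per sensillum and neuron, the noiseless model response at each dilution of
a 10^-8..10^-2 decade grid, replicated 9 times (matching typical replicate
counts for paired-ORN recordings) with additive i.i.d. Gaussian noise,
default 0.5 mV — chosen to mimic the error-bar scale of published curves.
The noise is homoscedastic and untruncated (rare negative values are left
in; the fits average over them). Real measurement noise is likely
heteroscedastic (larger near the plateau) and temporally correlated across
a dilution series measured in one animal; the generator represents neither,
so recovery results bound estimation error under idealized noise only.
Seeding: one master seed spawns per-run child seeds (kept below 2^31), so
every experiment is reproducible from a single integer.

`recovery_experiment` repeats generate-then-fit over independent seeds and
reports per-parameter median signed error (bias) and median absolute error
(for areas, also relative versions). Problem sizes used by the shipped
experiment: 3 sensilla x 2 neurons x 7 dilutions x 9 replicates, 20 seeds,
4 starts per fit — about 3 s total; measured recovery is k_od median
|error| < 0.03 log10 units and dendritic areas within ~2.5%.

## Numerical choices

- Closed-form vs direct solves cross-checked at 1e-9 relative; resting
  calibration closed forms at 1e-6 mV (internal errors, not warnings).
- Degenerate inputs (non-positive areas, negative gains, NaN dilutions)
  raise typed errors eagerly rather than propagating NaN.
- The Hill fit's initial point: plateau at the data maximum, midpoint at
  the first abscissa reaching half-maximum, Hill coefficient 1.
- CSV outputs carry a schema-version comment line and explicit units in
  column headers; parameter YAML round-trips byte-identically.

## Limitations

- Steady-state only: no response kinetics, adaptation, or spike generation.
- Exactly two ORNs per sensillum; sensilla housing four neurons are out of
  scope.
- The spike/LFP ratio enters only as a geometric constraint, not as a
  spiking model.
- Coeloconic sensilla (unbranched dendrites) are known not to share a
  common parameter set with the basiconic ones modeled here; the default
  table applies to ab3/ab4/ab5.
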