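# Methods

This note documents the models, conventions and numerical choices
behind the package, in the spirit of a model-description appendix: what
is simulated, what is fitted, which knobs matter, and what the synthetic
experiments do and do not demonstrate about real data.

## The measuring cycle

The automated device runs a fixed loop: pull the discharge tube down to
a partial vacuum (default 40 kPa absolute, reached essentially
instantaneously), log absolute pressure during the extraction phase
(default 60 s at 2 Hz), vent for 5 s, wait until the next cycle
(default every 15 min — also the minimum interval that lets the
sample's gas re-equilibrate with the atmosphere between cycles). If
the pressure climbs back to the restart threshold (default 90 kPa,
a sign of an undersized tube or a severe leak) the pump re-evacuates
mid-measurement; that sample is recorded clipped at the threshold with
a pump-event mark, and the affected cycle is excluded from analysis
because its extraction interval is no longer well defined.

Only the extraction phase appears in the log; venting and waiting carry
no information the analysis uses. The log dialect is one CSV row per
sample (`measurement_id, datetime, elapsed_s, pressure_kPa,
pump_event`). The real firmware's on-card column layout is not
standardised; this dialect is the repository's own convention, used by
both the simulator and the parser.

## Simulator physics

The sample is a gas reservoir at atmospheric pressure whose size tracks
embolism. With water potential Ψ (MPa, ≤ 0) the embolised fraction of
the vulnerable conduit volume is the generative sigmoid

    f(Ψ) = 1 / (1 + exp(a·(Ψ − Ψ50))),

and the gas space the tube can draw on in a cycle starting at time t is

    V_s(t) = v_dead + f(Ψ(t)) · v_emb_max,

where `v_dead` (cut-open conduits plus permanently gas-filled spaces)
sets a non-zero minimum discharge and `v_emb_max` is the embolisable
gas space at atmospheric pressure. Within a cycle, tube pressure
relaxes first-order toward the isothermal two-reservoir mass-balance
equilibrium

    p_eq = (p_i·V_t + P_atm·V_s) / (V_t + V_s),
    dp/dt = k·(p_eq − p) + leak,

solved in closed form (a shifted exponential). This kinetics is a
simulator convention — the simplest model consistent with gas
extraction from embolised conduits being fast relative to the
measurement — not a measured law of the instrument. Between cycles the
sample's gas fully replenishes from the atmosphere.

Defaults, chosen once as realistic study conditions:

| parameter | default | rationale |
|---|---|---|
| Ψ50 (true) | −3.0 MPa | mid-range angiosperm drought resistance |
| a (true) | 2.0 MPa⁻¹ | moderate curve steepness |
| v_emb_max | 400 µL | terminal-branch scale gas space |
| v_dead | 40 µL | ~10% open-conduit fraction |
| k | 0.1 s⁻¹ | ≈78% of extractable gas within the 15-s analysis window; extraction fast but not instantaneous, so the recommended 15-s endpoint carries most of the signal |
| sensor noise | 0.05 kPa (1 sd/sample) | consumer absolute-pressure sensor class |
| Ψ schedule | −0.5 → −6.5 MPa over 10 h, linear | bench dehydration spanning both plateaus in 40 cycles |
| tube volume | 2.6 mL (tests/examples) | matches the worked ideal-gas example |

Two consequences worth knowing. First, the measured discharge is
proportional to V_s/(V_t+V_s), a mildly saturating function of the true
gas space; after PGD normalisation this warps the curve slightly and
biases the fitted Ψ50 by about +0.07 MPa (less negative) and the slope
by ~2% at the defaults. That bias is a property of the *measurement*,
not a fitting artefact, and stays well inside the recovery tolerances
asserted in the tests. Second, with additive Gaussian sensor noise and
window-averaged endpoints, per-cycle discharge noise is ≈1 µL against a
~120 µL dynamic range, so single experiments are informative.

The blocked-tube leak test (`simulate_leak_test`) deserves a caveat:
real leaking systems show discharge readings that drift downward
regularly, cycle after cycle. A stationary within-cycle leak term
cannot produce a cross-cycle trend, so the generator emulates the
documented signature directly through a per-cycle fractional decline.
It is a phenomenological fixture for the verdict logic, not a physical
leak model. The first blocked cycle reads near zero, as in real runs.

## Analysis chain

1. **Segmentation** — log rows group by `measurement_id` into traces;
   malformed rows are skipped with line-numbered warnings (strict mode
   aborts) because field SD-card data are messy.
2. **Endpoints** — p_i and p_f are means over ±0.5 s windows at t_i = 2 s
   (skipping the pump transient) and t_f = 15 s (the extraction length
   that best isolates gas from embolised conduits; longer windows pick
   up gas from sap and radial diffusion). Window means beat single
   samples against sensor noise; windows must not overlap. Cycles are
   flagged (and excluded) for mid-interval pump restarts, truncation,
   or a starting pressure >5 kPa off the vacuum target.
3. **Gas discharge** — ideal gas law per cycle; temperature is one
   constant per experiment (the device logs no temperature channel — a
   known limitation, worth ~0.3%/K in moles).
4. **Ψ on the measurement grid** — the sparse Ψ record (pressure
   chamber or psychrometer; headers `date`, `hour`, `psy`) is linearly
   interpolated every 15 min between first and last observation, never
   extrapolated; each cycle pairs with the nearest grid value within
   7.5 min, otherwise it is dropped and counted.
5. **Plateaus** — GDmin is the mean of the first 3 cycles. GDmax is
   the mean of the longest terminal window with relative range ≤5%
   spanning ≥4 cycles. No such window ⇒ `plateau_ok = False`: the
   experiment stopped too early, GDmax falls back to the overall
   maximum, and everything downstream is flagged unreliable (the
   classic premature-stop failure, where Ψ50 comes out spuriously less
   negative — reproduced as a test property). The thresholds are not
   from any instrument specification; they were chosen to flag clearly
   rising tails while passing noisy-but-flat ones, and are exposed in
   the configuration.
6. **Fit** — unweighted nonlinear least squares of the raw
   (unclamped) PGD against the sigmoid; clamping to [0, 100] is
   display-only. Starting values come from the closed-form logit
   linearisation ln((100−PGD)/PGD) = a·Ψ − a·Ψ50 computed on strictly
   interior points (falling back to a = 1, Ψ50 = median Ψ if the logit
   slope is degenerate). The sign convention a > 0 (PGD → 100 as
   Ψ → −∞) is asserted after fitting; non-convergence raises an error
   carrying the initial estimates. A warning fires when the points do
   not span both tails (<20% and >80% PGD).
7. **Traits** — fitted: Ψ_x = Ψ50 + ln((100−x)/x)/a for x ∈ {12, 88}.
   Nearest-point: the measured point with PGD closest to x (distance in
   PGD, not Ψ); ties break toward the less negative Ψ — an arbitrary
   but fixed convention.

## Diagnostics

* **Calibration** — water column P = ρgh (ρ = 1000 kg m⁻³,
  g = 9.81 m s⁻²) and isothermal syringe compression
  P_rel = P_atm·(v₀/v − 1). The syringe checkpoints use P_atm =
  100 kPa (their round numbers presume it) while the analysis default
  is 101.3 kPa; both are explicit arguments. The calibration line is
  ordinary least squares of pressure on voltage.
* **Tube sizing** — V_tube (mL) = GDmax (µL)/510.2, an opaque
  empirical precision rule taken as given; complementary restart-based
  check: if the pump restarts within the measuring interval, the tube
  is too small.
* **Leak verdict** — on a blocked run, first cycle dropped, drift =
  (max−min)/max over the rest: ≤2% tight, >5% **and** decreasing in
  ≥80% of consecutive steps leaking, otherwise suspicious. "Decreasing
  regularly" has no canonical definition; the 80% step fraction is this
  package's operationalisation and is configurable.

## What the synthetic experiments show — and what they don't

Passing parameter recovery (Ψ50 within 0.15 MPa and a within 15% in
≥90% of seeded runs at the defaults) demonstrates that the analysis
chain is unbiased and noise-robust *for data generated by this
simulator*: sigmoidal embolism accumulation, first-order extraction,
additive Gaussian sensor noise, exact Ψ schedules, full between-cycle
re-equilibration. Real samples violate these in known ways — non-sigmoid
vulnerability shapes, slow radial gas sources inflating long
extractions, Ψ measurement error, temperature drift, shrinkage-induced
leaks — none of which the generator emulates. The tests certify the
pipeline's correctness and its failure-mode detection, not the field
accuracy of the pneumatic method itself.

Problem sizes follow the study conditions throughout: 40 cycles per
experiment (10 h at 15 min), 20 seeds for the recovery property, 120
samples per trace.

## Known limitations

* Single constant temperature per experiment; no sensor drift model.
* The simulator's leak signatures are phenomenological (see above).
* Gymnosperm (torus–margo) samples are outside the method's validated
  domain and are not modelled.
* No bootstrap confidence intervals on traits; the residual SE of the
  fit is reported instead.
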