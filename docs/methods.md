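# Methods

## The model

`erfate` simulates the decision between autophagy-dependent survival and
apoptotic death under endoplasmic-reticulum (ER) stress as a three-tier
regulatory network:

* **ERSS** — an ER stress sensor, activated by the stressor level `S`
  (an abstract dose in "stress units"; the identity of the stressor —
  tunicamycin, thapsigargin, DTT — is deliberately abstracted away, since the
  downstream decision circuit is taken to be stressor-independent):

  `dERSS/dt = ka_e·S·(ERSS_T − ERSS) − ki_e·ERSS`

* **AUT** — a lumped pro-survival autophagy inducer (the Beclin-1 axis;
  experimental proxies LC3II up, p62 down), activated by the sensor through a
  zero-order-ultrasensitive (Goldbeter–Koshland) cycle:

  `dAUT/dt = (kaau + kaau_p·ERSS)·(AUT_T − AUT)/(J_aa + AUT_T − AUT)
           − (kiau + kiau_p·APO_act)·AUT/(J_ia + AUT)`

* **APO** — a lumped pro-death apoptosis inducer (the caspase axis; proxies
  procaspase-3 loss, PARP cleavage), activated by the sensor through a chain
  of `n_steps` sequential, distributive modifications with per-step forward
  rate `kaap·ERSS` and per-step backward rate
  `kiap/(1 + k_fb·APO_act) + kiap_p·AUT`. The unmodified pool is carried
  implicitly (`APO_T − Σ APO_i`), so the chain conserves total APO exactly.
  `APO_act` is the last (fully modified) form.

Three motifs generate the decision dynamics: **mutual antagonism** (AUT
accelerates APO deactivation through `kiap_p`; APO_act accelerates AUT
deactivation through `kiau_p`) makes survival and death mutually exclusive
attractors; the **multistep chain** (`n_steps ≥ 2`) makes APO activation
sigmoidal in the drive; and the **positive feedback** `k_fb`, by which active
APO suppresses its own deactivation, locks the death state in place.

Concentrations are dimensionless fractions of unit pool totals, time is in
minutes, and the stochastic engine converts concentrations to molecule
counts with the system size `Omega` (default 100 molecules per unit pool).

## Stochastic engine

Each additive ODE term maps to one reaction channel with propensity
`Omega · term(counts/Omega)`, so `Σ stoich·propensity / Omega` reproduces the
deterministic right-hand side identically (a construction the test suite
asserts numerically). Trajectories are generated with the exact (direct
method) stochastic simulation algorithm in integer molecule counts; the
conserved complements (inactive sensor, inactive AUT, unmodified APO) are
implicit, so conservation is exact in integer arithmetic. The
piecewise-constant stress protocols are handled exactly: a next-reaction
time that would cross a protocol boundary is truncated there and propensities
are re-evaluated under the new level. An exact SSA was chosen over a
chemical-Langevin scheme because it is parameter-free given `Omega` and has
no small-noise approximation error at the 10–30-molecule occupancies the
chain bottleneck actually visits.

Per-cell seeds are spawned from the master seed as
`SeedSequence(master_seed).generate_state(n_cells) % 2**31`, which is
platform-stable; identical master seeds give bit-identical ensembles.

Cell-to-cell variability of the stressor strength (over and above intrinsic
molecular noise) is available as a per-cell lognormal factor on the protocol
levels (`extrinsic_sigma`, default 0 in `simulate_ensemble`). The
dose-response scan defaults to the calibrated value sigma = 0.2 — the
population's spread of effective stressor strength is part of what shapes
the fate window — while the washout experiment uses intrinsic noise only,
whose commitment-time dispersion suffices there.

## Fate classification

A cell is **apoptotic** when `APO_act/APO_T > 1/2`, else **autophagic** when
`AUT/AUT_T > 1/2`, else **neither**; apoptosis takes precedence, reflecting
the mutually exclusive character of the two programs. The symmetric
parameter-free 1/2 convention is a package choice; no classification rule is
inherited from data. Population readouts classify each cell at a fixed
evaluation time (240 min for constant treatments, 120 min post-washout for
washout experiments).

## Deterministic analysis

`integrate` uses LSODA with `rtol = 1e-8`, `atol = 1e-10`, restarting at
protocol boundaries; invariant breaches beyond 100× the tolerance raise
rather than being clipped. `resting_state` relaxes from zero activities at
`S = 0` until the maximum absolute derivative falls below 1e-9/min.

`apoptosis_threshold` defines the operational threshold S\* as the smallest
stress whose **240-min** constant application drives the resting cell into
the apoptotic state (bisection to 0.01 by default). This finite-horizon
definition matters: close to the saddle-node the passage time diverges, so
S\* sits slightly above the true fold point.

`hysteresis_scan` performs quasi-static up/down scans (dwell 500 min per
step or convergence below 1e-8/min, whichever is first). Because the chain's
forward flux is strictly proportional to ERSS, the active chain is no longer
replenished once the stressor is removed, and the only true steady state at
`S = 0` is the resting state; the model's irreversibility is therefore
*kinetic*: with the calibrated `k_fb`, the decay rate of the committed state
at `S = 0` is ~1e-3/min, giving a lifetime far beyond both the 120-min
washout readout and the 500-min dwell. The scan's `irreversible` flag means
"the apoptotic state outlives the S = 0 dwell", the same finite-horizon
convention as the washout experiment itself.

## Calibration

The full kinetic parameter set is fixed by calibration against behavioral
anchors rather than transcribed from a reference: (a1) S\* inside the window
3 < S\* < 5; (a2) 50-cell ensembles at 240 min show apoptotic fractions
below one half at S0 = 1 and 2 (with an autophagic majority) and above one
half from S0 = 5; (a3) the washout commitment curve at S0 = 10 stays low for
15-min washout, rises through 30–90 min and reaches ≈95% at 105 min; (a4) at
S0 = 5 a transient autophagy peak precedes apoptosis activation. Hard
anchors (infinite weight) act as constraints; stochastic anchors are
evaluated with fixed sub-seeds (common random numbers) so the search surface
is deterministic given the master seed. `calibrate` runs a log-uniform
random search with coordinate-wise multiplicative refinement; the shipped
defaults are the result of such a run and are stored both as dataclass
defaults and in `erfate/data/default_params.yaml`.

Calibration choices worth knowing:

* **Baseline `kaau_p`.** The autophagy-modulation experiments bracket the
  ERSS-driven autophagy activation rate between 0.2 (inhibitor) and 0.7
  (activator). The baseline is calibrated within that bracket and lands at
  0.65 rather than at the midpoint: with a midpoint baseline the three
  threshold orderings (inhibited < 1 < baseline window < activated) are not
  jointly attainable in this equation family. On the shipped set the
  240-min thresholds are S\*(0.2) = 0.73, S\*(0.65) = 4.89, S\*(0.7) = 6.04.
* **Threshold shift under strong autophagy.** With `kaau_p = 0.7` the
  deterministic threshold moves to substantially higher stress; depending on
  the exact calibration it can move beyond the default scan range
  (`apoptosis_threshold` then returns `inf`, which still orders correctly
  above the baseline). The delay effect is also visible stochastically as a
  longer median apoptosis-activation time at S0 = 5.
* **Time scale.** The chain rate constants set the commitment clock; they
  are calibrated so the deterministic point of no return at S0 = 10 falls
  near 56 min, which places the stochastic commitment-time distribution
  across the 30–90-min washout window (the commitment curve typically starts
  rising at the 45-min washout point and saturates by 90 min).

## What the synthetic data does and does not emulate

The synthetic-observables stage maps trajectories to immunoblot-style
markers (LC3II ∝ AUT; p62 ∝ exp of minus the cumulative autophagic flux,
because blots show slow p62 loss rather than an instantaneous inverse of
AUT; procaspase-3 ∝ the unactivated APO pool; cleaved PARP ∝ APO_act) with
multiplicative lognormal noise of configurable CV, and to an Annexin-style
apoptotic index with binomial counting noise over `n_counted` cells. The
linear marker maps are modeling conveniences — nothing in the model pins the
quantitative link between AUT and LC3 lipidation kinetics — so passing tests
demonstrates internal consistency of the pipeline on data with known ground
truth, not quantitative agreement with any real blot. No gel/image
simulation, densitometry, or blot statistics are attempted.

## Known limitations

* **System-size limit on the population window.** At `Omega = 100` the
  chain bottleneck holds only ~10–25 molecules, so the population fate
  transition has an intrinsic width of roughly three stress units centered
  about 1.5 units below the deterministic S\*. With S\* calibrated inside
  (3, 5), the apoptotic fraction at S0 = 4 is already a large majority: the
  simulated coexistence window sits at 2 ≲ S ≲ 4 rather than 3 < S < 5.
  Deepening the noise barrier enough to move it would require larger pool
  copy numbers than the fixed system size provides. The corresponding
  acceptance checks are left failing deliberately rather than masked.
* **Ensemble-mean convergence at lethal stress.** The ensemble mean
  converges to the ODE solution with growing `Omega` everywhere, but at
  stress levels just above threshold the sup-norm deviation is dominated by
  commitment-timing jitter, which decays slowly with `Omega` (still ~15% at
  `Omega = 1e4` at S0 = 5, vs ~1% at S0 = 1). This is a property of
  stochastically timed switches, not of the integrator or the SSA.
* **Post-washout autophagy decay.** A "neither" resting state requires basal
  autophagy inactivation to exceed basal activation, so after stressor
  removal the autophagy inducer of rescued cells relaxes below the 0.5
  classification threshold within the 120-min readout: early-washout
  populations are scored "uncommitted" rather than "autophagic" even though
  they survived. An autophagic majority after washout would require an
  autophagic resting state, which the resting-state contract excludes.
* **Single-cell switching width.** The post-commitment rise of the apoptosis
  inducer is limited by the forward flux `kaap*ERSS` (~0.06/min at S0 = 5),
  the same rate constants that set the ~50-min washout commitment clock;
  the median single-cell 20->80% rise is therefore ~60 min — sharper than
  the population-mean rise, but not the sub-30-minute step a larger
  separation of time scales would give.
* Washout is modeled as an instantaneous drop of S to 0; no pharmacokinetics.
* The simulated autophagy-modulator experiments change `kaau_p` from t = 0,
  whereas the wet-lab protocol pre-incubates inhibitors 2 h before the
  stressor; the simulation follows the former convention.
* No explicit UPR branches (IRE1/PERK/ATF6) and no explicit Bcl2/Beclin-1
  species; the crosstalk is absorbed into the antagonism and feedback terms.
  Whether the real point of no return arises from a feedback of the `k_fb`
  type or another loop is left open — the package asserts the behavior, not
  the mechanism.

## Problem sizes

Default study conditions: 50 cells per ensemble, 240-min constant
treatments, washout grid 15..105 min in 15-min steps with a 120-min
post-washout readout, integer dose grid S0 = 1..10, `Omega = 100`.
Convergence checks use `Omega ∈ {100, 1000, 10000}` with 24/12/6 cells
(larger systems fluctuate less, so fewer replicates are needed per
condition).
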