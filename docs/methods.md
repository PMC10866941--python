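# Methods

`spheroidsim` is a hybrid discrete–continuous (HDC) simulator of avascular
glioblastoma spheroid growth under chemotherapy. Discrete cell agents live
on a square lattice and are coupled to continuous drug concentration
fields; a probabilistic pharmacodynamic layer converts conventional
dose–response curves into per-cell, per-cycle fate probabilities. The
package targets in-silico drug screening: monotherapy calibration, and
prediction of combination-therapy response under a probabilistic
independence null model, with an "alternative fit" transport hypothesis
available for when the null is rejected.

## Cell agents

Each lattice site (spacing h = 15 µm) holds at most one cell. States:

- **proliferative** — cycling; attempts mitosis when its age reaches its
  doubling time;
- **quiescent** — space-limited and reversible; the cell re-checks its
  neighborhood every step (1 h) and resumes cycling as soon as space frees;
- **G0-arrested** — drug-induced, irreversible (senescence-like); viable
  but permanently non-proliferating; an optional per-cycle necrosis hazard
  (`g0_death_prob`, default 0) can drain this pool;
- **dying** — in lysis for `lysis_period_h` (default 48 h), its site
  blocked;
- **debris** — post-lysis remains; treated as reoccupiable space.

Doubling times are drawn once per cell from Normal(22 h, 1 h), truncated at
±4 SD, and re-drawn at each division for both mother and daughter (no
inheritance — the data motivating the model give no heritability signal, so
the simpler choice is used). Initial ages are Uniform[0, doubling time) per
cell, which desynchronizes divisions from the start. At mitosis a cell
searches Moore rings 1–3 (Chebyshev distance, nearest ring first, uniform
tie-break within a ring) for an empty or debris site; failure parks it in
reversible quiescence with its age held at the threshold.

Spontaneous (intrinsic) death is evaluated once per completed cell cycle at
the mitosis attempt, with per-cycle probability 0.05 by default
(configurable 0–1; the 0.05–0.11 band is the realistic range for gliomas).
Both this default and the 48 h lysis period are exposed configuration
stand-ins rather than measured constants.

Order of checks at mitosis: intrinsic death → drug fate → space search.
Only cells that come through unaffected search for space; a space-blocked
(quiescent) cell is not exposed to the drug-fate draw again until it
actually re-attempts mitosis, and within one cycle the draw is idempotent
(see *Random streams*).

## Drug transport

Each drug concentration field C(x, t) (molar) obeys

∂C/∂t = D ∇²C − γ·ρ(x),

with ρ = 1 on live-cell sites (zeroth-order uptake sink) and Dirichlet
boundary conditions clamping the lattice edge to the current bath dose —
the dish medium acts as an infinite well-mixed reservoir. Reference
parameters: D = 8.68e−7 cm²/s and γ = 1.4e−10 M/(cell·s) for temozolomide
(TMZ); D = 8.68e−8 cm²/s and γ = 1.4e−13 M/(cell·s) for doxorubicin (DOX).

The default solver is Peaceman–Rachford ADI (unconditionally stable,
second-order in space) at a 60 s step, with the uptake sink split
explicitly across the two half-steps. Explicit FTCS would need sub-second
steps for the fast-diffusing drug on a 15 µm grid (stability bound
h²/4D ≈ 0.65 s), which is infeasible for multi-week runs; it is retained
for solver cross-validation on short horizons (the two agree to <1e-8 of
the dose on a 2 h horizon with uptake). The continuous problem satisfies a
maximum principle (0 ≤ C ≤ bath dose); the ADI splitting's sub-1e-6
overshoot is clipped so the discrete field satisfies it exactly. Negative
values produced by the explicit sink near C = 0 are clipped at zero
(physically: no uptake from an empty site), with clips above 1e−12 M
logged.

Transport modes per drug:

- `reaction_diffusion` — the PDE above (spheroid-slice runs);
- `homogeneous` — all sites equal the bath at all times (monolayer wells);
- `no_diffusion_alternative_fit` — spatially uniform concentration with a
  step-dilution schedule (see *Dosing*), used as the reduced-transport
  hypothesis for the cytotoxic drug when the combination null model is
  rejected.

**Dosing.** Time zero is the moment of treatment (day 4 post-seeding in
the emulated protocol). From day 3 post-treatment, half of the medium is
replaced with drug-free medium every 2 days: each exchange rescales the
*bath* dose by (1 − fraction) and leaves the interior to relax through the
PDE, since replenishment changes the surrounding medium, not the
intra-spheroid drug. In the alternative-fit mode, dilution instead happens
as uniform steps every 48 h after the first 72 h; "diluted by 2/3" is read
as retaining 1/3 per event (the default), with the other reading (retaining
2/3, i.e. minimal dilution) exposed as
`alternative_fit_retained_fraction` — the qualitative comparisons in the
acceptance checks use the minimal-dilution reading, since that is the
configuration in which the alternative fit's drug exposure strictly
dominates the null model's.

Chemical degradation/hydrolysis of TMZ and cellular uptake/efflux
pharmacokinetics are not modeled; dilution and the uptake sink are the only
loss terms.

## Pharmacodynamics: from dose–response to single-cell fate

At mitosis, for each drug, a cell is unaffected with probability p and
divides; affected cells arrest (G0) with probability λ or die with
probability 1 − λ. λ is the drug's mechanism dial: λ = 1 for a purely
cytostatic drug (TMZ default), λ = 0 for a purely cytotoxic one (DOX
default), sweepable across [0, 1].

Tracking expectations of this branching process for k cycles:

- cycling cells per founder: P_k = (2p)^k
- arrested (viable, non-cycling): G_k = λ(1−p)·((2p)^k − 1)/(2p − 1)
  (limit k·λ(1−p) at 2p = 1)
- treated/untreated viable ratio: (P_k + G_k)/2^k.

This closed form was verified against an independent Monte Carlo branching
simulator before use in calibration (the tests keep that cross-check).
Equating the ratio to measured % growth inhibition (ratio = 1 − inhibition
/100) and inverting by bisection yields p per measured dose. The assay
spans 72 h ≈ 3.27 cycles of 22 h; the fractional k is used directly via
real powers rather than rounding. A lattice monolayer simulation with
asynchronous ages reproduces the real-power form to within ±2% (the
approximation contract asserted in the tests, on top of sampling error).

Calibration details: target ratios are clamped into (1e−6, 1] (negative
inhibition, i.e. apparent growth stimulation, clamps to p = 1 with a
logged warning); targets below the λ-dependent attainable floor
(ratio(p=0) = λ/2^k — a fully cytostatic drug cannot empty the viable
pool) calibrate to p = 0 with a warning; noisy non-monotone p sequences
are projected onto non-increasing form by pool-adjacent-violators; lookups
between measured doses interpolate linearly in log10 concentration with
constant extrapolation outside the measured range, and zero concentration
is always unaffected.

**Exposure memory.** Fate lookups key on the maximum extracellular
concentration the cell has ever experienced, never the instantaneous one.
This single rule produces the long-term death hazard of a tissue-retained
cytotoxic drug (the hazard re-applies at every later mitosis even after
the field decays) and, for a cytostatic drug, persistent arrest pressure.
The `sustained_death` flag on a fate model records this persistence
semantics for audit; the behavior itself follows from the peak-exposure
rule. Newborn daughters start their exposure record from their own site's
current concentration — exposure history is not inherited.

## Combination therapy

Under probabilistic independence (the null model), per-drug
affected-indicators are drawn independently: P(affected by either) =
P_A + P_B − P_A·P_B. A cell hit by one drug takes that drug's fate split;
a cell hit by both where the realized fates disagree (one arrests, one
kills) has no prescribed outcome, so an intersection policy resolves it:
`toxic_dominates` (default — death is absorbing and observed combination
responses show enhanced cytotoxicity), `static_dominates`, or `coin_flip`.
All three are first-class configuration options. Across policies,
per-timepoint outcomes can differ by at most the both-affected probability
mass.

Population-level supra-additivity is scored against Bliss independence:
expected combined fractional effect E_A + E_B − E_A·E_B, with
excess = observed − expected.

Relapse of a treated/untreated area-ratio trajectory is flagged when the
ratio exceeds 110% of its nadir and stays above that level for at least
2 consecutive observation days. This is an operational definition chosen
for the artifact; the underlying biology is usually described
qualitatively.

## Random streams and reproducibility

Fate draws at mitosis come from counter-based (Philox) streams keyed by
(simulation seed, cell id, cycle index, channel), one channel per drug
plus channels for intrinsic death and the policy coin. Consequences:

- re-evaluating a decision within one cycle (a space-blocked cell
  re-attempting mitosis) reuses the same uniforms — decisions are
  idempotent per cycle;
- adding a drug to a run cannot perturb another drug's realized draws, so
  a combination run at dose (c, 0) is *bitwise identical* to the
  monotherapy run at c (asserted in the tests);
- replicate r of any experiment derives its seed as
  SeedSequence(base_seed, spawn_key=(r,)), independent of the number of
  replicates requested or the drugs in play.

Agents are stepped in a freshly shuffled order each step (main stream) to
avoid directional growth artifacts.

## Metrics

- % growth inhibition = (control − test)·100/control (negative values pass
  through; clamping happens only inside calibration).
- IC50: linear interpolation on (log10 concentration, inhibition) at the
  first upward crossing of 50%; errors if never bracketed.
- RMSE between two treated/untreated area-ratio series on their common
  timepoints: sqrt(Σ_t (r_v(t) − r_s(t))²/N_t). Ratios are built from
  replicate means (mean treated / mean control), with spread propagated
  first-order from replicate SDs; per-replicate pairing is not assumed.
- Simulated "area" = viable-site count × h² (proliferative + quiescent +
  G0), debris excluded — matching segmented central-slice areas. The
  dose-response-from-spheroids convention reads day 10 post-treatment.

## Synthetic data

No raw measurements ship with the package; generators stand in:

- dose–response curves are Hill-shaped, inhibition(c) = 100·c^s/(IC50^s +
  c^s) + Gaussian noise. Defaults emulate the motivating system: TMZ
  IC50 = 550 µM (half-inhibition only above 500 µM), slope 1.5, doses
  5–2000 µM; DOX IC50 = 0.05 µM (four orders of magnitude more potent),
  slope 1.0, doses 0.0015–5 µM.
- reference growth trajectories are parametric (exponential with 4-day
  area doubling, plateau, exponential decay at 0.15/day, or decay-then-
  regrow at 0.35/day after a day-8 nadir) sampled every 2 days to day 21
  with multiplicative lognormal replicate noise.

What these fixtures do **not** emulate: measurement dropout, plate/batch
effects, segmentation error structure, drug-specific deviations from Hill
shape, and any real inter-replicate correlation. Tests passing on these
fixtures therefore demonstrate the internal consistency and contracts of
the simulator, not agreement with any particular laboratory dataset.

## Default experiment template

Treatment at day 4 post-seeding; observation every 2 days to day 21
(simulations record daily); TMZ doses {100, 200, 300, 500, 1000} µM, DOX
doses {0.1, 0.3, 0.5, 0.9} µM, combinations of 500 µM TMZ with each DOX
dose; 10 replicates. The default lattice is 300×300 (4.5 mm span) so a
three-week spheroid run never reaches the boundary ring (boundary contact
raises a warning); the initial spheroid slice is a disc of radius 14 sites
(~630 cells, the central slice of a day-4 spheroid grown from ~625 seeded
cells). Validation and acceptance runs use reduced problem sizes — a
150×150 lattice over 14 days with 2–3 replicates, and 10⁴-cell monolayers
— chosen as the smallest sizes at which the asserted effects are well
resolved above Monte Carlo noise.

## Numerical choices and degenerate inputs

- Agent step 1 h (1/22 of the mean cycle; age-threshold discretization
  error under 5%); PDE step 60 s.
- Bisection for p via Brent to |Δratio| < 1e−9; uniqueness follows from
  strict monotonicity of the ratio in p (property-tested).
- Ratio floor 1e−6 keeps calibration well-posed at 100% inhibition.
- Empty dose lists, non-increasing concentration grids, unknown
  configuration keys, out-of-range probabilities and fractions, and
  stepping a debris site all raise immediately with the offending value
  named.
- A dying cell converts to debris within one agent step of its lysis
  period elapsing.

## Known limitations

- 2D central-slice geometry only; no 3D lattice, no off-lattice mechanics,
  no motility.
- No nutrient/oxygen limitation: untreated growth is limited by space
  competition alone.
- Fate probabilities are time-invariant given peak exposure; dynamic
  pharmacokinetics (uptake, efflux, intracellular accumulation) and
  drug–drug interaction ("memory") effects are out of scope.
- A purely cytostatic calibration at moderate inhibition slows but does
  not halt front growth: with per-cycle arrest probability 1 − p ≈ 0.26
  at 500 µM TMZ, the cycling rim remains supercritical (2p > 1), so the
  treated disc keeps expanding at a reduced rate rather than freezing.
- The independence null model deliberately excludes mechanistic synergy;
  it is the baseline against which supra-additive observations are scored.
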