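# Methods

`biocathode` implements the quantitative chain used to interrogate
polarized-cathode enrichment reactors: which electrons went where, and is
the community on the electrode living off the cathode or off something
else? This note records the models, conventions and design choices behind
each stage, and what the synthetic benchmark does and does not show.

## Coulomb extraction from chronoamperometry

A reactor's cathode is poised at a fixed potential (default −0.6 V vs
SHE) and its current is logged over a 6-day run. Reduction currents are
recorded negative by potentiostats; every statistic here is defined on
magnitudes, so the sign convention of the export does not matter.

Charge is integrated with the left-rectangle rule, Σ |Iₙ|·(tₙ₊₁ − tₙ),
the discretization conventionally applied to irregularly sampled
potentiostat exports. The trapezoid rule is used only as an independent
cross-check in the tests (the two agree to <0.1% at 1 s sampling on
smooth traces). Window boundaries take the zero-order-hold value of the
preceding sample, which makes integration exactly additive over adjacent
windows and exact on piecewise-constant traces.

Derived statistics:

* **j_1h** — the current-density magnitude exactly one hour after
  polarization, linearly interpolated between the bracketing samples.
  It serves as the abiotic baseline: inoculated reactors start at the
  abiotic level and any later excess is attributed to biology.
* **fold increase, j_max/j_1h** — the maximum density beyond the first
  hour over the baseline, with the earliest attaining time. Reported as
  missing (not infinity) when j_1h = 0.
* **biocoulombs** — Σ max(0, |j(tₙ)| − j_1h)·A·(tₙ₊₁ − tₙ) over samples
  tₙ ≥ 3600 s. The first hour is treated as abiotic settling, so any
  flat (abiotic) trace accrues exactly zero. Biocoulombs feed only the
  activity score; coulombic efficiencies and budgets use the *total*
  integrated charge, which is the denominator the CE definition calls
  for.

## Electron equivalents and COD

For an organic CxHyOz, full oxidation to CO₂/H₂O releases
nₑ = 4x + y − 2z electrons per mole; the COD equivalent follows as
8·nₑ g O₂/mol (one mole of O₂ accepts four electrons). The registry
ships eight organic acids (formic through 4-methylvaleric) plus
inorganic half-reactions: H₂ (2 e⁻), thiosulfate→sulfate (8 e⁻),
Fe(III)→Fe(II) (1 e⁻). Species with heteroatoms require an explicit
electron count; the combustion formula is refused for them.

## Donor budgets and classification

For each reactor the coulombs embodied in the products,
Q_P = F·nₑ·Δ[P]·V (Δ[P] the final-minus-initial concentration, V the
catholyte volume), are compared with four potential donors:

* **cathode** — total integrated charge over the run;
* **formate** — consumed formate × 2 F (production is routed to the
  product side instead);
* **thiosulfate** — accepted as a donor only when consumption is
  concomitant with near-stoichiometric sulfate production (2 SO₄²⁻ per
  S₂O₃²⁻ within a ±50% default tolerance — "near-stoichiometric" is a
  qualitative judgement, so the tolerance is deliberately loose and
  configurable); otherwise its consumption is flagged as possible
  membrane crossover or respiration;
* **yeast extract** — from the COD drop, after subtracting the COD of
  the measured products from the final value: Q = (ΔCOD·V/8)·F, floored
  at zero. A COD *increase* after correction is flagged as possible
  carbon fixation (electroautotrophy) and contributes no donor charge.

Coulombic efficiency per product is CE = Q_P/Q_cathode × 100; the total
CE is the sum over products, and a total above 100% is flagged — the
cathode alone cannot explain the products. Classification follows the
budget: `cathode_sufficient` when Q_products ≤ Q_cathode;
`multi_donor_electrofermentation` when the products need the soluble
donors too; `donor_deficit_flag` when even all accounted donors fall
short. Electron-acceptor consumption (nitrate, sulfate, Fe(III)) is
reported descriptively but never budgeted as a donor; iron reduction is
additionally checked against magnetite stoichiometry (Fe(II) ≤ 1/3 of
total Fe, default tolerance 0.05).

Δ[P] uses the first and last timepoints only; intermediate samples are
carried in the report but not fitted — the budget is an endpoint
accounting, not a kinetic model.

## HER feasibility

The equilibrium potential of 2H⁺ + 2e⁻ → H₂ at the hydrogen threshold
pressure p_H₂ is

    E = −(RT ln10/F)·pH − (RT/2F)·ln p_H₂,   E°(SHE) = 0 at all T,

with R = 8.314 J/(mol·K), F = 96 485 C/mol, T in kelvin. Threshold
pressures for downstream hydrogenotrophic metabolism are rarely known
directly, so the module calibrates p_H₂ from anchor potentials (an exact
algebraic inversion; calibrate-then-evaluate round-trips to machine
precision). The bundled anchor table holds the two pH 4.5 anchors
(−0.038 V at 30 °C, −0.104 V at 75 °C); intermediate temperatures are
interpolated log-linearly in p_H₂. A cathode at E_cat can sustain H₂
production when E_cat ≤ E_HER − η, with a default overpotential
allowance η = 0.2 V for the sluggish HER kinetics on graphite. No
activity-coefficient or ionic-strength corrections are applied.

## Activity score and community normalizations

The cumulative activity score sums five components, each in [0, 1]:
biofilm score/5 (ordinal microscopy scale, 5 = full coverage), and four
continuous indicators — bacterial 16S copies/cm², archaeal copies/cm²,
total organic acids produced (mM, sum of positive deltas), biocoulombs —
each divided by its across-reactor maximum (zero if the indicator is
zero everywhere). The score is a relative ranking within an experiment,
not an absolute activity measure.

Amplicon samples are brought to a fixed depth (default 100 000 reads);
shallower samples are excluded with a recorded reason. The default is
proportional rescaling (with largest-count residual correction so column
sums are exact); seeded subsampling without replacement (multivariate
hypergeometric) is available for parity with rarefaction practice.
Counts are aggregated at a chosen rank, keeping taxa that reach a
minimum abundance (default 1%) in at least one sample — or the top N —
and pooling the rest into `other`.

Because universal prokaryotic primers can miss archaea entirely while
qPCR shows them dominant, displayed abundances are projected onto the
qPCR domain split: with f = bacterial/(bacterial+archaeal) copies, each
bacterial taxon shows as relative% × f and a single `Archaea` block
takes 100·(1−f). Projection is applied after aggregation and the 1%
filter. Ordination (MFA/NMDS) is out of scope; the exported indicator
matrix and abundance tables are ready for external tools.

## Synthetic reactor generator

The generator is budget-consistent, not kinetic: it emulates the
*observables* of the five archetypes (abiotic, electrotroph,
electro-fermenter, fermenter, methylotroph) with exact electron
bookkeeping, so the pipeline can be validated against known truth.

* **Trace**: |i(t)| = baseline + plateau·logistic(t; midpoint, rate) +
  Gaussian noise, clipped at zero, recorded negative. When a scenario
  draws from the cathode, the plateau is rescaled so the noiseless
  left-rectangle integral of the whole trace equals the configured draw
  exactly; the cathode draw is therefore defined as the *total* charge
  passed, the same quantity the CE denominator uses.
* **Chemistry**: product coulombs = efficiency × Σ donor draws, split by
  the product profile and converted to concentration deltas by inverting
  Q = F·nₑ·Δ·V; formate/thiosulfate consumption realizes their draws
  (2 SO₄ per S₂O₃); the COD pair encodes the yeast-extract draw plus the
  product COD. Trajectories follow the shared logistic ramp.
* **Biology**: lognormal qPCR copies around configured log₁₀ means,
  a fixed ordinal biofilm score, multinomial amplicon counts over the
  scenario's genus profile.

Default magnitudes are chosen to sit inside the ranges observed on real
enrichment reactors of this kind: baselines of 0.1 mA giving fold
increases of ~1–6 (electrotroph preset ≈ 6-fold), total products below
~2.9 mM, qPCR up to ~10¹⁰ copies/cm², amplicon depths of 150 000 with
one deliberately shallow (20 000-read) abiotic sample that the depth
filter must exclude. Noise defaults reflect plausible instrument
performance: trace SNR 10 (σ = baseline/10), 10% CV on concentrations,
3% CV on COD (photometric kit precision).

Each reactor's pseudo-random stream derives from (master_seed,
CRC32(reactor_id)), so datasets are bit-reproducible and independent of
generation order.

**What passing recovery shows — and does not.** With zero noise the
budget inverts the generator exactly (classification 100%, electrotroph
CE equal to the configured efficiency to <0.1%). At the default noise,
classification recovery is ~96–97% over 500 reactors; the residual
errors sit at the decision boundaries, where measured product coulombs
cross a donor total within measurement noise — exactly the reactors that
would be ambiguous in a real experiment. The generator does not emulate
membrane crossover, pH drift, sampling-volume loss, kinetic limitation
or taxonomic misassignment, so recovery here bounds only the arithmetic
chain, not every failure mode of a wet experiment. The three
fermentative labels map to the same budget class by construction: a
coulomb balance cannot distinguish *which* soluble donor fed the
products, only that soluble donors were needed.

## Problem sizes and numerical choices

Traces are generated at 60 s resolution (8 641 samples over 6 days);
chemistry at 7 daily timepoints. The recovery study uses 100 experiments
× 5 scenarios; the whole suite and the acceptance script each run in a
few seconds on one CPU. Ties in j_max are broken by the earliest time;
fold increase with a zero baseline is reported missing; degenerate
inputs (empty amplicon table, zero qPCR signal, windows outside the
trace span) raise explicit errors rather than propagating NaNs.

## Known limitations

* The budget attributes every COD drop (after product correction) to
  yeast extract; any unmeasured oxidizable species would be mislabeled.
* The COD-based donor term is the noisiest component: a 3% kit CV on a
  ~0.3 g O₂/L background corresponds to ~±30 C, comparable to the
  margins of borderline reactors.
* H₂ thresholds are calibrated from anchor potentials rather than taken
  from direct threshold measurements; users with literature values can
  substitute their own anchor table.
* Geometric single-face electrode area is a configuration value, never
  inferred; absolute current densities (not fold ratios) depend on it.
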