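# Methods

## The tandem two-site scheme

The mechanistic model realizes the minimal mass-action scheme consistent
with vestibule-mediated binding. Five receptor states are tracked, with
free tracer L and competitor A held constant (pseudo-first-order —
membranes are dilute and competitor is in vast excess over sub-nanomolar
tracer):

```
R  <-> R·L(vest)            k_on_vest·[L] / k_off_vest
R·L(vest) <-> R·L(orth)     k_in / k_out
R  <-> R·A(vest)            k_on_block·[A] / k_off_block
R·L(orth) <-> R·L(orth)+A   k_on_block·[A] / k_off_block
R·L(orth)+A -> R·A(vest)    leak · k_out      (tracer lost to bulk)
```

Assumptions: a single vestibule site holding one molecule; the
competitor cannot reach the orthosteric pocket of a tracer-occupied
receptor (steric exclusion) and is never tracked in the orthosteric
state (in dissociation experiments its orthosteric occupancy is
irrelevant to the tracer observable); `leak` interpolates between
complete blockade of egress by the vestibule-bound competitor (leak = 0,
NMS-like full retardation) and partial blockade (leak > 0, QNB-like
incomplete retardation, plateauing at leak·k_out).

The observable defaults to the orthosteric-bound species only: vestibule
complexes are low-affinity and are assumed lost during filtration.
Integration uses BDF with rtol 1e-8 / atol 1e-12 on receptor-fraction
variables (rates may span six orders of magnitude); total receptor is
checked to 1e-8 relative tolerance at every sample and a violation
raises rather than warns.

Macroscopic constants: the apparent tracer K_D is
K_A,vest·K_iso/(1+K_iso) with K_iso = k_out/k_in — K_A,vest times the
equilibrium fraction of bound tracer residing in the vestibule. The
exact half-maximal concentration of the scheme is
K_A,vest·K_iso/(1−K_iso); for the physiological regime K_iso ≤ 0.01 the
two differ by under 2% and the reported form is used. `predicted_kobs`
extracts the observed rate the way the assay analysis does — by fitting
the simulated decay — rather than from the Jacobian eigenvalues, so the
same code path is exercised as for real data.

## Retardation equations

Dissociation time courses normalized to 100% at the start of
dissociation are fitted with

- mono: Y = 100·e^(−k_off·t)
- bi: Y = (100−f)·e^(−k_off1·t) + f·e^(−k_off2·t), f = percent of sites
  dissociating at k_off2.

The bi-exponential model is accepted only when the extra-sum-of-squares
F-test rejects mono at α = 0.05 (AIC is available as a config
alternative); when RSS of the mono fit is already at numerical zero the
simpler model is kept outright. The slower phase is always the rate
carried into the retardation analysis.

Observed rates across competitor concentrations X follow the
full-blockade retardation form

    k_obs = k_0 / (1 + (X/K_A)^nH)

with nH fixed at 1 (simple form) or floated (steep M2/M5-like curves).
K_A is the apparent affinity of the competitor for the vestibule of the
tracer-occupied receptor. No ternary off-rate offset term is included:
the model is chosen to reach k_obs → 0 at saturating competitor, which
matches full NMS-type retardation; QNB-type incomplete retardation is a
property of the mechanistic simulator (`leak`), not of this fitting
equation. The pipeline's default slope-model policy is `auto`: fit the
nH = 1 form, float nH only when the nested F-test (α = 0.05) demands it.
`k_0` floats by default; `fix_k_0` pins it to a measured competitor-free
rate instead.

All equilibrium constants are parameterized as log10 values internally
(bounds: pK ∈ [0, 12], rates ∈ [1e-6, 10] min⁻¹, f ∈ [0, 100],
nH ∈ [0.1, 5]); least squares is unweighted with a weights hook;
convergence failures trigger up to five jittered restarts.

Fits are performed per independent experiment and then averaged as mean
± SEM across experiments (never across wells); many-to-one comparisons
against the reference condition use Dunnett's test (`scipy.stats.dunnett`,
exact critical values). A pooled-fit mode is intentionally absent from
the default path.

## Synthetic experiment generator

The generator emulates the filtration-assay design: saturation with 8
log-spaced tracer concentrations (32 pM–1 nM, triplicate wells, 3
experiments) and dissociation started from pre-equilibrated tracer with
7 log-spaced competitor concentrations (10 µM–10 mM, duplicate wells, 4
experiments) plus a competitor-free control. Noise is multiplicative
Gaussian on the bound signal, truncated at zero (counting error grows
with signal); the default CV of 3% was chosen so that SEMs of recovered
pK values across 4 experiments land in the ±0.01–0.06 range typical of
published tables, and is configurable. Nonspecific binding is linear in
tracer concentration, scaled to 10% of total binding at X = K_D, and is
subtracted in the fitting stage, not in the generator.

Dissociation time grids are adaptive per concentration: 9 points
spanning 3 half-lives of that curve's expected rate. A single global
grid sized for the slowest curve (half-life ≈ 700 min for wild-type M2
at 10 mM competitor) would leave the control curve (half-life 2.6 min)
without informative samples, so per-curve grids are the only design
under which every k_obs in a series is identifiable; this is a
deliberate idealization of real protocols, which stagger sampling by
hand.

One global seed expands into per-experiment substreams
(`numpy.random.SeedSequence.spawn`), so adding experiments does not
perturb earlier ones. `write_fixture_suite` materializes CSV fixtures
for all 18 ground-truth presets with name-derived seeds;
re-running with the same base seed is byte-identical.

What the generator does *not* model: filtration losses, radioactive
decay, instrument dead time, plate-position effects, or any systematic
(non-multiplicative) error. Parameter-recovery results on this
synthetic data therefore demonstrate correctness and statistical
efficiency of the pipeline under the stated noise model, not robustness
to the systematic artefacts of real assays.

The mechanistic generation mode drives the ODE scheme instead of the
closed form; `fast_exchange_rateset` constructs rates in the regime
(vestibule exchange and competitor binding ≫ translocation) where the
two modes agree in fitted k_obs within 3%.

## Trajectory metrics

RMSF: each frame is superposed onto the reference frame (frame 0) by
least-squares rigid alignment (Kabsch, with an explicit collinearity
check) over the chosen subset — backbone (N/CA/C/O) or heavy atoms,
ligand excluded. The residue value is the RMS over frames *and* the
residue's subset atoms of the displacement from the reference positions,
not the mean of per-atom RMSFs. Because the superposition itself absorbs
an O(1/N_atoms) share of any single atom's motion, closed-form checks
use many static anchor atoms.

Contacts: hydrogen bonds require donor–acceptor distance ≤ 3.5 Å and
donor–H–acceptor angle ≥ 120° (donors are N/O with a hydrogen within
1.25 Å in frame 0; both ligand→receptor and receptor→ligand directions
are counted). Ring stacking requires ring-centroid distance ≤ 5.5 Å,
with an optional interplanar-angle cutoff (off by default). Ligand rings
are perceived from a 1.8 Å heavy-atom bond graph (5–7-membered cycles);
receptor rings are the standard aromatic residue ring atom sets
(Phe/Tyr/His/Trp). Frequencies are 100·count/n_frames per residue and
may exceed 100 when the ligand makes several simultaneous contacts. All
thresholds are conventional defaults and exposed in `ContactCriteria`.

## Steered-escape toy model

A deliberately qualitative 1-D analogue of steered unbinding, not a
reimplementation of all-atom steered dynamics. The reaction coordinate
is distance from the pocket bottom; the landscape is two inverted
Gaussians (orthosteric well at 0 Å, depth 12 kT, width 2 Å; vestibule
well at 16 Å, depth 4 kT, width 2.5 Å) with flat bulk beyond 30 Å.
Euler–Maruyama overdamped dynamics with D = 0.1 Å²/τ and dt = 0.01 τ;
the steering acceleration (outward `min(a0/d, cap)` with the cap applied
after the distance division, inward `a0/(scale−d)`) is recomputed every
`apply_interval` = 100 steps and converted to drift through a single
mobility constant (1.5e-4 Å·τ⁻¹ per nm·ns⁻²). The mobility and well
depths are calibrated so the escape threshold lies between the
"never leaves the orthosteric well" and "fully dissociates" regimes of
the schedule's working range, with a clear vestibule pause in between;
absolute a0 values are therefore schedule-relative and not comparable
to accelerations in a molecular simulation. Escaping replicas are
absorbed at the bulk boundary by default; a reflecting mode provides a
closed two-well system for equilibrium checks. Numerical blow-up
(non-finite or absurd coordinates) raises with a suggestion to reduce
dt. Residence is reported both per basin (orthosteric/vestibule/bulk)
and in narrow windows (±half width) around the well bottoms; the
equilibrium occupancy ratio of the narrow windows approaches
exp(Δdepth), which is the detailed-balance check used in the tests.

## Problem sizes and numerical choices in the test suite

Stochastic property tests run at sizes chosen to keep the suite fast
while leaving comfortable statistical margins: model-selection type-I
error uses 500 seeded decays; escape monotonicity uses 50 replicas per
acceleration under common random numbers; pK_A recovery statistics use
40 replications of the 4-experiment design; free-diffusion and
detailed-balance checks use 500 and 32 replicas respectively. Benchmarks
in `tandemsite.benchmarks` regenerate data at the published design
(4 experiments × duplicate wells, or 3 × triplicate) and complete in a
few seconds.

## Known limitations

- The mechanistic scheme omits tracer binding to the vestibule of a
  tracer-occupied receptor and competitor translocation to the
  orthosteric site; both are irrelevant for tracer-dissociation
  observables but would matter for competitor-association kinetics,
  which the package does not fit.
- Equilibrium allosteric ternary-complex (Ehlert-type) competition
  fitting and kinetics-of-competition association fitting are out of
  scope.
- The contact-frequency module uses purely geometric criteria; it knows
  nothing about partial charges or aromaticity beyond ring perception.
- The escape toy has no 3-D directionality, membrane, or energetics; it
  reproduces threshold and two-station phenomenology only.
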