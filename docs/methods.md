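# Methods

## The scientific question

Microbial carbon use efficiency (CUE) — the fraction of assimilated carbon
allocated to biosynthesis rather than respired — is widely assumed to
decline with warming, which in coupled microbe–soil-carbon models damps
soil carbon losses because microbial biomass declines. If communities can
*adapt* (raise their intrinsic CUE under warming), that damping could be
undone. This package implements two models that ask how much adaptation a
rate-yield tradeoff permits: cells that invest more in resource
acquisition (extracellular enzymes, uptake transporters) acquire carbon
faster but respire a larger share of it.

## The analytical model

A homogeneous community grows at G = U·ε with

* U = U_ref · exp[(−E_a/R)(1/(T+273) − 1/(T_ref+273))] — Arrhenius uptake,
* ε = ε_int + m_T (T − T_ref) — linear temperature penalty on CUE,
* ε_int = ε₀ + m_U U_ref — the rate-yield tradeoff (m_U < 0).

Maximizing G over U_ref gives

* U_ref\* = −(ε₀ + m_T (T − T_ref)) / (2 m_U),
* ε_int\* = (ε₀ − m_T (T − T_ref)) / 2.

Two consequences, both tested: the optimal intrinsic CUE rises by
−m_T/2 per degree — adaptation offsets exactly half of the forced CUE
decline (0.04 mg mg⁻¹ for 5 °C with m_T = −0.016) — and is independent
of m_U, while maximal growth falls as |m_U| grows. With m_U = 0 growth is
maximized at unbounded uptake investment, so the optimum is undefined and
raises an error. E_a is stated in kJ mol⁻¹ and converted to J mol⁻¹
internally against R = 8.314 J mol⁻¹ K⁻¹. The closed forms are verified
in tests against a brute-force grid argmax (U_ref ∈ [0, 5], step 10⁻⁴)
and symbolically with sympy.

The analytical tradeoff scenarios are m_U = −0.4 (high) and −0.2 (low).

## The simulation model

A spatially explicit, trait-based, stoichiometrically constrained
decomposition model: 100 virtual taxa (50 % bacterial, 50 % fungal) on a
100 × 100 toroidal lattice degrade 12 organic substrates via a shared
pool of up to 50 extracellular enzymes and take up the resulting
monomers (12 substrate-derived + inorganic N + inorganic P) via up to 14
transporter types. All pools are volumetric (mg cm⁻³); each lattice
point represents 1 cm³, pools do not diffuse, and the only spatial
fluxes are offspring dispersal and fungal nutrient translocation.

**Community generation.** Enzyme target sets are uniform random subsets
of the substrates (coverage repaired so every substrate is degradable by
at least E_S enzymes). Generalists pay a specificity–efficiency
tradeoff: per-substrate Vmax = V_E · n_targets^(−θ); with θ = 1 (the
default) an enzyme's total capacity is fixed and split over its targets,
with θ = 0 the tradeoff is off. Km is tied linearly to Vmax (slope 10),
so a specialist has Vmax = 100, Km = 1000 mg cm⁻³; transporters all have
Vmax = 5 per mg biomass C per day and Km = 1 mg cm⁻³. Taxa draw uniform
gene-set sizes (0–40 enzymes, 1–14 transporters), then sets are repaired
so each taxon can take up every monomer its enzymes release plus at
least one organic monomer; the repaired sets define the investment
fractions f_E, f_U and the intrinsic CUE

    ε_int = ε₀ + f_E m_E + f_U m_U,

with scenario slopes m_E = m_U = −0.2 (high tradeoff) or −0.1 (low).

**Kinetics.** Decay and uptake are Michaelis–Menten; Vmax and Km each
follow their own Arrhenius factor (per-substrate decay activation
energies 34–39 kJ mol⁻¹; E_a = 35 for uptake; E_aK = 20 for every Km, a
single value shared by enzymes and transporters). Cellulose decay is
multiplied by max(0, 1 + λ_Slope·LCI) with the lignocellulose index
LCI = lignin C / (lignin C + cellulose C) and λ_Slope = −0.8; an option
extends the penalty to hemicellulose (off by default).

**Daily update order.** Fungal translocation → enzymatic degradation →
uptake → CUE-partitioned growth → enzyme production → stoichiometric
homeostasis → mortality → enzyme turnover → division/dispersal →
leaching → external inputs. Translocation is pinned to the start of the
iteration; the rest follows source-to-sink causality, with enzyme costs
paid before the stoichiometric balance is settled.

**Physiology.** Per-point decay sums MM fluxes over local enzyme pools
(capacity ∝ enzyme concentration), capped at the standing pool, moving
C/N/P in the pool's current proportions. A cell's uptake capacity
V_U·cellC is split equally across its reachable monomers; when local
demand exceeds a pool, allocations scale down proportionally, and
elements are assimilated in pool proportion. Of assimilated C, ε is
retained and 1 − ε respired, where ε = ε_int + m_T (T − T_ref) clamped
to [0, 1]. Enzyme production has a constitutive part (β_EC = 5×10⁻⁵ per
enzyme per mg cell C per day) and an inducible part (Z_EC = 5×10⁻⁵ per
enzyme per mg gross uptake C), with N cost 0.3 × C cost, pro-rated so
quotas never cross their starvation minima. Homeostasis holds element
mass fractions inside guild-specific bands (e.g., bacterial C fraction
0.825 ± 0.090); because the upper bounds sum to more than one, at most
one element is out of band at a time and the excess is removed exactly
to the boundary — C as overflow respiration (ledgered separately from
growth respiration and excluded from CUE accounting), N and P as
mineralization to the local inorganic pools; removal iterates to a joint
fixed point.

**Demography.** Cells die deterministically if any quota falls below its
minimum (0.086/0.012/0.002 mg for C/N/P) and stochastically at τ_B =
0.02 d⁻¹ (bacteria) or τ_F = 0.01 d⁻¹ (fungi); dead mass enters the
dead-microbe pool, whose stoichiometry is unconstrained. Enzymes decay
at τ_E = 0.04 d⁻¹ into the dead-enzyme pool (C with bound N at 0.3).
Division at the C threshold (2 mg bacterial, 50 mg fungal) splits all
quotas 50/50; bacterial offspring land uniformly on one of the 8
neighbors, fungal offspring move ±1 in y with total probability
ρ_y = 0.05 and otherwise stack on the parent point, producing hypha-like
columns (a config flag switches the non-y case to lateral ±1 x moves).
Fungal taxa translocate: every cell of a taxon is reset to the taxon
mean quota each day.

**Environment.** Substrate pools start uniform at the litter-chemistry
table values; each monomer starts at F_MS = 0.045 of its substrate;
inorganic N/P start empty (fed only by mineralization — their initial
pools are not specified by the chemistry table). Daily inputs are
spatially uniform and preserve each compound's stoichiometry. Dissolved
pools (monomers and inorganic N/P) leach at L = 0.1 d⁻¹; polymers,
enzymes and cells do not leach.

**Initialization of cells.** Expected densities are 0.1 bacterial and
0.004 fungal cells per point (independent Poisson draws per point); a
new cell starts at half its division threshold (1 mg C bacterial, 25 mg
C fungal — the 25× size ratio makes the two guilds start at equal
biomass) with N and P at the guild's balanced fractions. The starting
quota is not dictated by the parameter table; half-threshold is the
natural fixed point of symmetric division.

## Paired warming experiments

A replicate pair shares one seed: community generation, cell placement
and the daily dynamics stream are identical between the 15 °C and 20 °C
runs, so any divergence flows only through temperature-dependent code
paths (a 15-vs-15 pair reproduces exactly, which is tested). Communities
are regenerated for every pair, so between-pair variation reflects
random trait assignment as well as population stochasticity. Per run the
community intrinsic CUE is the biomass-weighted mean of taxon ε_int
across all recorded days (day 0 through the last day); biomass and
substrate C are likewise time means. Pair deltas (20 °C − 15 °C) of
these three quantities are analyzed with a one-sample t-test against
zero and with OLS regressions of Δbiomass and Δsubstrate on Δε_int.
The t-test and OLS are implemented from their closed forms (scipy
supplies only the t-distribution tail) and are cross-checked against
scipy's reference implementations in the test suite.

## Problem sizes

The reference experiment is 20 pairs × 5000 days on a 100 × 100 lattice
per scenario. The shipped test suite exercises the same machinery at a
reduced size — 10 pairs × 500 days on a 20 × 20 lattice per scenario
(about six minutes on one core) — and checks the sign and ordering
structure of the response rather than the full-scale magnitudes:
warming raises community intrinsic CUE under the high tradeoff, the
steeper tradeoff adapts more, Δbiomass and Δsubstrate increase with
Δε_int across pairs, and high-tradeoff communities have lower CUE, more
substrate and less biomass than low-tradeoff ones. Element conservation
is audited daily (C, N and P close to ≤ 10⁻⁹ relative error over 100
days of full biology on a 10 × 10 lattice).

## Numerical choices and degenerate inputs

* Michaelis–Menten fluxes return 0 at Km + S = 0; decay and uptake are
  capped at the standing pool, so pools cannot go negative.
* The homeostasis fixed-point iteration stops when the largest excess is
  below 10⁻¹⁵ of cell mass (at most 50 passes; typically < 5 touch a
  shrinking subset of cells).
* Temperature is constant within a run, so Arrhenius-adjusted constants
  are precomputed once per run.
* Random-number discipline: one root `SeedSequence` spawns named
  streams (community, placement, dynamics); results are bit-reproducible
  for a given (config, seed) and the community CSV round-trips doubles
  exactly (`%.17g` + round-trip float parsing).
* A zero-tradeoff analytical model, an empty enzyme pool, a guild with
  positive density but no taxa, and zero-variance t-test samples all
  raise or are flagged rather than silently degrading.

## What the generator does and does not emulate

The synthetic communities emulate random trait assembly under the stated
constraints; they do not emulate phylogenetic trait correlation, trait
evolution within a run (adaptation is purely selection on a fixed pool),
pH/moisture kinetics, mineral sorption, diffusion, or grazing. Passing
desk-scale tests demonstrates the mechanism — selection against
high-investment taxa under warming, limited by stoichiometric and
spatial constraints — not calibrated magnitudes for any real soil;
magnitudes at reduced lattice size and duration are larger than the
reference-scale values because the bloom transient occupies a larger
share of the averaging window.

## Known limitations

* The full-scale experiment (t = 5000 days, 100 × 100, 20 pairs) is
  feasible but slow (~hours); the package reproduces it via the same
  `run_paired_experiment` call with default parameters.
* Fungal translocation averages quotas in one step per day regardless of
  colony topology; there is no hyphal network cost.
* Inducible enzyme production scales with total gross uptake rather than
  with the monomers matching each enzyme's products (the simplest
  reading of proportionality).
* The dead-microbe monomer inherits the dead pool's instantaneous
  stoichiometry at decay time; no further constraint is imposed.
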