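# Model and methods

`ironcycle` simulates the coupled redox activity of Fe³⁺-reducing bacteria
(FeRB, *Shewanella*-like) and microaerophilic Fe²⁺-oxidizing bacteria (FeOB,
*Sideroxydans*-like) as a stochastic agent-based model on a 21×21×21 toroidal
lattice.  Oxygen is not resolved as a field: an externally supplied schedule
switches the whole world between an anoxic state (only reduction active) and
an oxic state (only biotic and abiotic oxidation active), emulating the
fluctuating redox conditions of wetland soils and sediments.

## Units, time and space

* One tick is one minute.  The per-cell literature rates the model is built
  on (Fe³⁺ reduced or Fe²⁺ oxidized per cell per minute) then apply directly
  per tick, and the adsorption-equilibration calibration ("<5 % of the initial
  deviation left after 2.5 h") comes out at the documented rate of 0.02 per
  tick over 150 ticks.
* One patch edge is 2 µm; the electron-shuttle range of 10 patch lengths is
  20 µm.
* Iron amounts are carried in *iron units* of `unit_scale` = 1e5 atoms.  The
  contact reduction rate of 1×10⁷ atoms/(cell·min) becomes 100 units/tick and
  the maximum biological oxidation rate of 3.6×10⁷ atoms/(cell·min) becomes
  360 units/tick.  Atom-denominated quantities are recovered exactly by
  multiplying with `unit_scale`.

## Lattice and pools

Patches are either traversable *medium* or immobile *bulk mineral* holding a
Fe³⁺ reservoir (default 2×10⁶ units ≈ the iron content of a patch-sized
oxyhydroxide block) and an adsorbed-Fe²⁺ surface pool (`fe2_ads`).  Bulk
patches are placed by clustered growth: `max(1, round(n_bulk·(1−fe_clustering)))`
seeds are drawn uniformly, then medium neighbours of the growing set are
converted uniformly at random until the target count (rounded
`fe_patch_percentage` of all patches) is reached.  `fe_clustering = 1` yields
one compact macroaggregate, `0` a scattered field.  Core patches (all 26
Moore neighbours bulk) are not traversable; an agent whose jump lands in a
core patch is redirected to the nearest edge patch of the same cluster.

Dissolved Fe²⁺ is a single well-mixed pool: at the minute scale of a tick,
diffusive mixing of solutes across a 42-µm box is effectively complete, which
is also why FeOB chemotaxis toward Fe²⁺ is not modelled.  Iron removed by
nanoparticle loss accrues to a ledger so that the global balance
(dissolved + adsorbed + bulk Fe³⁺ + particle iron + ledger) is exactly
conserved; the suite checks conservation to 1e-6 relative tolerance.

## Nanoparticles

Nanoparticles are spheres whose diameter derives from their iron content via
an effective density `iron_per_cubicnm` (model atoms per nm³ of particle
volume).  The default is 5000: it is deliberately an *effective model* value,
not the physical ferrihydrite atom density.  It is calibrated for internal
consistency — an FeOB oxidizing at the literature rate and splitting the
yield over its 40 surface particles then grows each of them through the
observed ~10 nm release size over a few minutes, rather than overshooting it
within a single tick.  The mean diameter at release measured in the suite
(~9.5–9.6 nm) sits at the calibrated 10 nm shedding scale.

Free particles diffuse with speed `max(50 − 0.5·d, 1)` patches/tick and a
tumble probability of 0.3 per tick.  Co-located free particles aggregate with
probability `mineral_aggregation_probability`/100 per contact, summing iron
(the merged particle carries the iron-weighted mean of the two aging clocks).
A particle whose Fe³⁺ share exceeds `np_attachment_threshold` (50 %) binds a
co-located FeRB if the cell's MtrC occupancy (Σ d²/cell surface area) stays
≤ 1.

## FeRB behaviour

Unattached reducers perform run-and-tumble motion (speed 5 patches/tick,
tumble 0.3/tick).  Contact with bulk mineral in the Moore neighbourhood
switches on a chemotactic mode for 30 ticks: tumbling tripled, speed doubled
— the empirically observed electrokinetic response near insoluble electron
acceptors.  A reducer standing on a bulk patch attaches if the patch's
adsorbed Fe²⁺ is strictly below `fe2_ads_tolerance` (300 units); surface
passivation beyond the tolerance triggers release — immediately in the
`electrostatic` adhesion mode, or in the `biofilm` mode with probability
`p₀·2^(−t/τ)/(1+n_near)` (p₀ = 0.2, τ = 60 ticks, doubled when oxic), which
decays with residence time and is damped by neighbouring attached cells; the
exponential form was chosen for its memoryless tail, the constants to give
detachment half-lives of order an hour.

Under anoxia each reducer reduces, per tick:

1. *Contact*: an attached cell moves `contact_reduction_rate` (100 units)
   from the patch's Fe³⁺ to its adsorbed Fe²⁺.
2. *Bound nanoparticles*: a shared capacity of 4×`contact_reduction_rate`
   represents the MtrC/electron-shuttle budget.  A bound particle of diameter
   d receives `(d²/A_cell)·np_mineral_reduction_ratio·contact_reduction_rate·s`
   iron units (s = aging susceptibility), capped by its Fe³⁺ and by the
   remaining capacity; the capacity is charged the transfer divided by
   `np_mineral_reduction_ratio` (100), expressing the ~100-fold faster
   reduction of nanoparticulate oxides.
3. *Electron shuttles*: the remaining capacity is split equally over bulk
   patches within 10 patch lengths, each transfer capped by the patch Fe³⁺.

With no bound particles and mineral in range this reproduces the literature
partition exactly: 80 % of a cell's reduction is shuttle-mediated (4:1
capacity), and the underlying rate bookkeeping recovers
1×10⁷ = (1−0.8)·5×10⁷ atoms/(cell·min) for the contact pathway.

## FeOB behaviour and oxidation

Oxidizers diffuse (2 patches/tick) and never adhere.  Under oxic conditions
each takes `min(dissolved/n_oxidizers, contact_oxidation_rate)` from the
dissolved pool and precipitates it as particulate Fe³⁺ according to its
encrustation-prevention mode:

* `shedding`: the surface is topped up to 40 nanoparticles, each new one
  seeded with 1/40 of the withdrawal; the remainder grows existing surface
  particles in proportion to d².  Surface particles are released
  stochastically when a draw from Normal(d, 2 nm) exceeds the
  `shedding_diameter` (10 nm).
* `low_ph`: the withdrawal precipitates onto nanoparticles within the
  27-patch neighbourhood (equal split), or nucleates one new free particle if
  none are present.

Abiotic oxidation is first order: each Fe²⁺ pool loses
`abiotic_oxidation_ratio` per oxic tick.  Adsorbed and particle Fe²⁺ oxidize
in place; the dissolved share precipitates as Fe³⁺ spread equally over bulk
cluster edge patches (biogenic, not abiotic, oxidation is the dominant source
of *nanoparticulate* oxides, so the abiotic route deposits on existing
surfaces; with no bulk mineral present it nucleates a single free particle
per tick instead).

Bound particles dissociate from FeRB when their Fe²⁺ share exceeds
`np_dissociation_threshold` (0.7) — the surface-passivation analogue for
particles.

## Equilibration

Fe²⁺ partitions between solid surfaces and solution with solids holding the
share `fe2_solid_ineq` (0.9) at equilibrium.  Each solid entity (bulk patch
or nanoparticle) has local target `A* = fe2_solid_ineq·(A + D/N)` with D the
dissolved pool and N the number of solid entities, and moves
`fe2_equilibrium_rate` (0.02) of the deviation per tick, in either direction.
Bulk patches equilibrate first, then nanoparticles, both as synchronous
vectorised stages; draws are scaled down proportionally if they would
overdraw the pool.  How one well-mixed pool should be apportioned among many
solids is a genuinely open design point; the equal D/N share was chosen
because it reduces to the single-solid calibration case — whose residual
decays exactly as (1−rate)ⁿ, asserted in the suite — and is conservative for
any N.

## Aging (secondary-mineral formation)

When enabled, a nanoparticle not reduced for `aging_lag` (200) minutes loses
reduction susceptibility linearly at `aging_rate` (0.003) per minute, clamped
to [0, 1]; any reduction event resets clock and susceptibility.  Aging
applies to nanoparticle reduction only — the mechanism of interest is
crystallization of the young, reactive particle pool — not to bulk mineral.

## Scenario presets

pH enters through three effective channels (values are plain config
overrides):

| pH | abiotic ratio /tick | fe2_ads_tolerance | aggregation % |
|----|---------------------|-------------------|----------------|
| 5  | 0.001               | 3000              | 1              |
| 6  | 0.003               | 300               | 10             |
| 7  | 0.01                | 300               | 100            |

The abiotic endpoints are the values that calibrate the biotic share of total
oxidation to ~20 % (0.01) and ~70 % (0.001); pH 6 is their geometric
midpoint.  The tenfold adhesion tolerance at pH 5 encodes the strong
electrostatic attraction between negatively charged cells and
positively charged mineral surfaces at low pH; aggregation collapses away
from the point of zero charge (pH 7.8).

Mode combinations 1–4 pair `electrostatic`/`biofilm` adhesion with
`shedding`/`low_ph` encrustation prevention.  Oxic/anoxic cycling keeps a
3:1 anoxic:oxic duty cycle in both arms — short: six cycles of 360+120 min,
long: two cycles of 1080+360 min over the same 2880-min horizon — so only
the switching frequency differs.  The interval lengths themselves are a
design choice (the experimental study being emulated does not fix them); the
3:1 ratio matches the observation that anoxic intervals are the longer ones.

## Sensitivity analysis

Saltelli's second-order scheme over scrambled Sobol' sequences gives
N·(2k+2) model evaluations; estimators are Saltelli (2010) for S1, Jansen
for ST and the closed second-order estimator for S2, with bootstrap
confidence half-widths over base samples.  Outputs are centred on the A/B
mean so indices are exactly invariant under affine output rescaling.  The
13-parameter default space is the process-parameter catalogue minus
world-setup and simulation-control entries and minus the two motility speeds
(treated as fixed organism traits); at the full analysis scale, k = 13 and
N = 500 give exactly 14 000 runs.  The estimators are validated in the suite
against analytic variance shares of an additive function and the Ishigami
closed form at N = 1024.

## Default community and problem sizes

The default world carries 50 FeRB and 50 FeOB (an equal community), 10 %
bulk patches at clustering 0.8, no initial nanoparticles or dissolved Fe²⁺,
and runs 2880 min (two days).  The calibration experiments in the test suite
and acceptance script use: one 360-min anoxic + oxic phase pair for the
oxidation-partition measurements (20 replicates in the acceptance script, 10
in the suite); full 2880-min runs for attachment; 1440-min runs (three short
cycles) at 3 replicates for the pH contrast; 4 paired seeds for the cycling
contrast.  The contrasts probed are stable well below these sizes — replicate
standard deviations of the partition measurements are below 0.1 percentage
points.

## Motility defaults

Bacterial speeds are not printed in the source literature at tick scale;
defaults are 5 patches/tick (10 µm/min) for FeRB and 2 patches/tick for the
slower microaerophilic FeOB, with a baseline tumble probability of 0.3/tick
(so the tripled chemotactic tumbling remains a probability) and a 30-tick
chemotactic persistence.  These choices matter mainly for encounter rates
(particle capture, mineral contact); the redox calibrations above are
insensitive to them.

## Known limitations

* Oxygen is binary and global; there are no intra-world redox gradients, and
  dissolved Fe²⁺ has no spatial structure.
* The bacterial populations are fixed — growth is out of scope, justified by
  doubling times (days) long relative to the simulated horizon.
* The reconstructed iron bookkeeping (units, per-patch reservoirs) follows
  the literature rates, not a fitted whole-system inventory.  One visible
  consequence: with the default 2×10⁶-unit bulk reservoirs, sustained
  reduction loads patch surfaces with adsorbed Fe²⁺ far above the 300-unit
  adhesion tolerance for most of a cycling run, so the time-averaged
  attached-FeRB fraction stays in the low percent range rather than the ~20 %
  reported for the original calibration; attachment instead occurs in bursts
  at oxic→anoxic transitions.  The detachment *mechanism* (passivation-driven
  release, oscillating with the oxygen schedule) is reproduced; its time
  average is not.
* The twofold short-vs-long cycling contrast in last-phase reduction rates is
  reproduced in direction (consistently ~1.3× across seeds) but not in full
  magnitude: with bulk reduction bookkept at the literature rates, the
  shuttle pathway onto bulk mineral dominates the total rate, which bounds
  the leverage of the aging-sensitive nanoparticle pool.
* Synthetic worlds emulate clustered mineral geometry and community dynamics,
  not any specific sediment; passing tests demonstrate internal consistency
  and the documented calibrations, not quantitative prediction for real
  habitats.
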