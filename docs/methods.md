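# Methods

`minfibril` simulates a single mineralized collagen fibril at the mesoscale:
tropocollagen molecules are chains of beads 14 Å apart, hydroxyapatite (HAP)
mineral is a set of unbonded beads, and the whole system evolves under
Langevin dynamics in a box that is periodic along the fibril axis.  This
note records the model, the construction choices, the numerical settings,
and what the desk-scale test protocol does and does not demonstrate.

## Model and energy terms

The total energy decomposes as

    E_total   = E_collagen + E_HAP + E_inter
    E_collagen = E_bond + E_angle + E_nonbonded

* **Bonds** (collagen backbone, and crosslinks) are bilinear breakable
  springs.  The force derivative of the stretching energy is
  `kT0 (r − r0)` for `r < r1`, `kT1 (r − r0)` for `r1 ≤ r < r_break`, and 0
  beyond `r_break`, with r0 = 14.00 Å, r1 = 18.20 Å, r_break = 21.00 Å,
  kT0 = 17.13 and kT1 = 97.66 kcal mol⁻¹ Å⁻².  As written, the force jumps
  at `r1` (the bilinear law is applied to `r − r0` on both branches); the
  energy is the continuous piecewise integral with Φ(r0) = 0.  A bond
  evaluated at or beyond `r_break` is flagged broken permanently; its
  energy stays at the rupture plateau Φ(r_break) so the total energy is
  continuous at the breaking step, and its force is zero forever after.
* **Angles** are harmonic in the angle deviation in radians,
  Φ = ½ k_B (φ − φ_i)², k_B = 14.98 kcal mol⁻¹ rad⁻².  Equilibrium angles
  φ_i are assigned per interior bead by measuring the constructed geometry
  and rounding to the nearest integer degree, clamped to [164°, 180°]; the
  construction guarantees exactly 13 distinct values.
* **Pairs** are 12-6 Lennard-Jones terms per species class:
  collagen–collagen (σ 14.72 Å, ε 6.87 kcal/mol), HAP–HAP (σ 10.28, ε
  106.7, cutoff 13.85 Å) and collagen–HAP (σ 9.88, ε 137.1, cutoff 20 Å).
  The collagen–collagen cutoff is not part of the published set; the
  default is 2.5 σ = 36.8 Å (configurable), wide enough to keep the
  adhesive well that sets intermolecular cohesion.  Truncation is plain
  (unshifted) by default; an energy-shifted variant is a `PairTable`
  toggle.  Pairs separated by one or two backbone bonds (1-2, 1-3) are
  excluded, as are crosslinked pairs.

Units are Å, kcal/mol, amu, fs.  All reported forces and stresses flow
through two constants: 1 kcal mol⁻¹ Å⁻¹ = 69.479 pN, and its per-Å² form
1 kcal mol⁻¹ Å⁻³ = 6.9479 GPa.

Bead masses: collagen 1324 amu, mineral 1548 amu.  The source parameter
table lists both masses under the mineral heading; we read 1548 as the HAP
bead and 1324 as the collagen bead, because 1324 amu matches the mass of a
14-Å segment of a triple helix (~15 residues at ~91 Da).  Both are
configurable, and the choice is flagged as an open reading.

## Fibril construction

The cross-section is a quasi-hexagonal lattice of molecule columns.  The
lattice spacing (15.2 Å) and offset are calibrated so a 20-nm-diameter
cylinder holds exactly 158 columns; with one molecule per column per
five-D-period box this reproduces the reference molecule count.  Columns
take stagger class `s = (i + 2j) mod periods` and the class-s molecule
starts at `x = s·D` (D = 670 Å), giving one gap and one overlap region per
D-period — five of each in the default box.

The reference bead total (28,305) divided by 158 molecules is not an
integer; the builder uses 179 beads per molecule and places one extra bead
on the 23 molecules nearest the fibril axis.  This is an explicit
calibration rule standing in for whatever boundary-inclusion rule produced
the reference totals.  A consequence worth stating plainly: a 179-bead
molecule spans ~3.71 D, so the gap:overlap ratio per column is ~0.29:0.71
rather than the canonical 0.54:0.46 of the quarter-staggered scheme.  We
kept the reference totals and the five-period structure and let the ratio
follow; it is recorded on the model (`gap_count`, `overlap_count`,
`gap_slabs`) and used by the gap/overlap profiler as its classification
threshold.

**Crimp.**  Each chain carries a planar zigzag crimp: the turn angle at
interior bead k alternates sign and takes its magnitude from a frozen
integer pattern sweeping 0–16°, so measured interior angles give exactly 13
distinct values spanning 164–180°.  Each molecule uses its own cyclic
phase of the pattern and its own azimuth of the crimp plane (both
deterministic functions of the column index).  This built-in incoherence
is a cheap stand-in for the conformational variability of real molecules:
it breaks the crystallographic registry of a perfectly coherent crimp,
which would otherwise hand the lattice an artificially soft collective
accordion mode.  The chains are rigidly
rotated so the end-to-end vector lies on the column axis; bond lengths are
exactly 14 Å by construction.

**Mineralization.**  The mineral bead count for a target weight fraction w
(percent of total mass) follows the closed form
`N_min = w/(1−w) · N_coll · m_coll / m_min`, rounded; the achieved fraction
must land within ±0.5 points or the builder raises.  Beads are placed on an
FCC lattice at the HAP Lennard-Jones equilibrium spacing 2^(1/6) σ_HAP =
11.54 Å, restricted to the fibril cylinder, excluding sites within 8 Å of
any collagen bead, and filled in order of axial distance to the nearest
gap-slab terminal plane.  Low densities therefore give two disjoint
crystals per gap (one per terminal plane) which grow toward each other and
merge at high density.  The 8-Å clearance admits moderate initial
collagen–mineral overlap energy; a capped-displacement steepest-descent
relaxation before dynamics removes it.  If a target exceeds the available
sites the builder raises with the achievable maximum.

**Crosslinks.**  Optionally each molecule bonds its two end beads to the
nearest bead of a neighboring molecule within 18 Å (up to two per
molecule, emulating two trivalent crosslinks).  Crosslink bonds reuse the
backbone bilinear parameters with a configurable rupture-distance scale
(default 1.0) — the source does not publish a crosslink parameter set, so
this is documented as a free parameter.

## Dynamics

Velocity Verlet with Δt = 10 fs; Langevin thermostat at 300 K with damping
time 1000 fs (friction plus fluctuation added to the conservative forces;
at T = 0 the noise vanishes and the same machinery yields overdamped
quasi-static relaxation, used for the single-molecule closed-form checks).
Neighbor lists are cell lists with per-class candidate cutoffs and a 2-Å
skin, rebuilt when any bead moves half a skin.  The integrator runs in a
compiled kernel in chunks bounded by list validity; bond breaking is
applied in place every step and is irreversible.

Equilibration ("axial NPT") couples the box length to the axial virial
stress by a Berendsen-style rescale toward zero stress (relaxation time
10⁴ fs against a 5-GPa modulus scale, rescale capped at 0.5% per update);
lateral boundaries are open vacuum with a margin larger than the largest
cutoff.  Convergence is reported from the leveling of the windowed
positional RMSD.  Tensile tests extend the box at a constant displacement
rate (1 m/s = 10⁻⁵ Å/fs at full scale) with an affine remap of all
coordinates each step, the barostat off, and block-averaged virial stress
sampled on a fixed cadence.

**Stress.**  The axial virial stress is
σ = −(Σ_b w_b,xx + Σ_b m_b v_b,x²) / V, tension positive, with per-bead
virial contributions w accumulated per interaction (half to each pair
partner; angle terms split equally over the triple) and V = π (d/2)² L
with the diameter held constant at its nominal value.  The kinetic term is
included by default and toggleable.  Mineral "internal stress" is the same
sum over mineral beads only, normalized by the total fibril volume — a
declared convention, since subset stresses have no unique normalization.

**Single-molecule stress convention.**  Molecular stress uses the area per
molecule of a hexagonally packed lattice at the collagen LJ equilibrium
spacing: A = (√3/2)(2^(1/6) σ_coll)² = 236.4 Å².  With this convention the
small-strain modulus of the bilinear chain is kT0 r0 / A = 7.05 GPa,
matching the reported single-molecule stiffness; the bilinear law then
fixes the large-strain stiffness at 5.701 × that value (40.2 GPa), which
brackets the reported backbone stiffness from above.  No single area can
reproduce both reported values because their ratio (4.79) differs from
kT1/kT0 (5.701); we match the small-strain value and state the ratio.

## Desk-scale study conditions

Full-scale runs (158 molecules, 2×10⁶ equilibration steps, ~3×10⁷ pulling
steps) are cluster work.  The shipped test protocol uses:

* the full default builder (geometry checks are exact and cheap);
* a 215-bead single molecule for closed-form mechanics, pulled
  quasi-statically (T = 0, overdamped) for the bilinear checks and at
  300 K / 40 m/s for the thermal modulus;
* a mini fibril — 6-nm diameter, two D-periods (≈14 molecules, ~1000–1700
  beads) — equilibrated 0.2 ns and pulled at 100 m/s, five mineral
  densities.  Contraction is measured relative to the equilibrated
  unmineralized mini fibril, which is also how the reference quantities
  are defined.

What the mini fibril shows is directional: ultimate stress rising with
mineral content (0.45 → 2.7 GPa over 0–25% in the shipped protocol),
contraction peaking at intermediate densities (~16% at 25%, against ~1.5%
residual relaxation at 0%), saw-tooth stress drops at mid densities,
monotone damage accumulation, and crosslink-induced strengthening with
brittle collapse.  Two scale artifacts are worth naming.  First, the
45% density point re-contracts instead of continuing the post-peak
decline: the reduced geometry's gap slabs cannot hold 45% mineral, so the
crystals spill deep into the overlap region and compact it — the
contraction trend check therefore covers 10–35%.  Second, molecules span
only ~1.5 D-periods, so the unconstrained mini fibril fails by gradual
molecular pull-out without backbone rupture; rupture statistics at this
scale come from the crosslinked variant (which does break bonds) and from
the single-molecule tests.  "Failure strain" for the brittleness ordering
is the post-peak collapse strain (stress below half the ultimate), which
separates the ductile pull-out curve from the brittle crosslinked one.
What the mini fibril cannot show: quantitative moduli or plateau values of
the full-scale fibril, mineral platelet shape effects, or hydration.  The
pull rate and durations are part of the frozen study conditions, not
tuning knobs.

## Numerical choices and degenerate inputs

* Bond evaluated exactly at r_break: treated as broken (≥ comparison).
* Collinear angle triples: undefined gradient direction — zero force,
  counted and reported, energy still accumulated.
* Beads closer than 10⁻³ Å in the full evaluation path raise an error
  naming the pair; the integrator's lean kernel skips such pairs (they are
  produced only by pathological inputs, which validation catches first).
* Ultimate point: first global stress maximum wins on ties; a perfectly
  flat curve is integrated end to end.
* Toughness integrates the raw (unsmoothed) curve by trapezoid to the
  ultimate point.  A curve whose maximum sits at the final sample is
  integrated in full rather than rejected — truncated-but-rising curves
  are common at desk scale and refusing them would make the analysis
  unusable there.
* Regime segmentation: centered moving average over a 1%-strain window,
  then exact dynamic-programming piecewise-linear fitting with ≥5 points
  per segment, segment count chosen by BIC; saw-tooth = a post-elastic
  segment with ≥3 single-sample drops exceeding 2% of the stress range.
* The axial barostat cap (0.5% per update) bounds the affine work per
  update; mineralized mini fibrils still run a few percent above the
  thermostat setpoint while they compact — an artifact of the compressed
  timescale, reported in the equilibration record.

## Known limitations

* Dry fibril only; no water, no viscosity beyond the thermostat friction.
* Mineral is an ideal close-packed bead phase: no platelet geometry, no
  lattice substitutions.
* The reported mineral bead counts of the reference model (2037–28,962) are
  not reproduced exactly: with the documented masses the 45% build uses
  ~19.8k mineral beads.  The reported counts are mutually inconsistent
  under any single mass-ratio weight-fraction identity, so the closed-form
  identity (which the tests verify) takes precedence.
* Contraction is always reported relative to the equilibrated
  unmineralized fibril (the fixed-L0 convention of the full-scale
  analysis); the unmineralized mini fibril itself relaxes by only ~1–2%.
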