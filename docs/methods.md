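# Methods

## Physical model and assumptions

Hemolymph flow in wing veins is treated as steady, incompressible, fully
developed laminar flow of a Newtonian fluid through rigid circular conduits.
At the relevant scales (lumen diameters of order 10 µm, velocities of order
100 µm/s, viscosity 1.3×10⁻³ Pa·s, density 1.02×10³ kg/m³) the Reynolds
number is below 10⁻³, so each vein is a linear hydraulic resistor
r = 128 μ l / (π d⁴) and junction ("minor") losses are negligible by
construction — the package never models them. Pulsatile pumping, vessel
compliance and non-Newtonian rheology are out of scope; the solution is the
steady state under a fixed volumetric inflow Q_in = Q_out imposed between the
inlet and outlet nodes.

Two formulations of the Kirchhoff problem are implemented. The primary
solver (`solve_nodal`) assembles the conductance-weighted graph Laplacian,
grounds the outlet at zero pressure and solves the reduced dense system; it
is the simplest formulation to automate for arbitrary graphs. The mesh
solver (`solve_mesh`) instead assigns one unknown loop flow to each chord of
a spanning tree, fixes a known loop flow Q_in around the source path, and
enforces zero signed loss around every fundamental cycle. The two routes
share no linear algebra and serve as mutual oracles; the test suite requires
agreement to 10⁻⁸ relative on randomly generated networks. Networks here
never exceed a few dozen nodes, so dense direct solves are used throughout;
singularity is detected by a conditioning check (threshold 10¹³) and
reported as a singular-network error. Zero-resistance channels are handled
in the nodal route by coalescing their end nodes and recovering their flows
by mass balance on the resulting forest; a cycle of zero-resistance channels
(or a zero-resistance inlet–outlet short) leaves flows indeterminate and is
rejected as degenerate.

Sign conventions: channel flow is positive from `node_a` to `node_b`;
`channel_loss = r·q` carries the same sign and equals the end-pressure
difference; pressures are relative to the outlet, so the inlet pressure is
the total loss. All quantities are SI internally (tables are ingested in the
mm units in which wing geometry is conventionally printed and converted once
at ingestion); presentation rounding to two significant figures happens only
in the human-readable log, never internally.

## The measured wing network

The *D. cyrtoloma* forewing is a ladder: edge-vein rail V_E_1..7 and
base-vein rail V_B_1..7 share the inlet (anterior base) and outlet
(posterior base) terminals and are joined by connecting veins V_C_1..6. The
fourth–sixth connecting veins are split into edge- and base-side segments by
the crossvein junctions: the ECV links the fourth and fifth connecting veins
(nodes A and X), the PCV links the fifth and sixth (nodes X and Y). Node X —
shared by V_C_5_E, V_C_5_B, the ECV and the PCV — is the cruciform junction.
This shared-terminal reading of the topology is validated by the idealized
circuit, where it reproduces the analytically exact benchmark shares (1/4,
2/7) and reduction (6/70).

The packaged geometry table carries the printed per-vein lengths and inner
diameters (the lumen is 20 % of the measured outer diameter; the table's
printed inner-diameter column is used directly rather than recomputed from
the rounded outer diameters, which would lose precision). Because the table
is printed to two significant figures while the original computation used
unrounded measurements, the headline quantities are expected to reproduce
only within input-rounding propagation: the package computes 0.630 kPa for
the ECV-ablated loss (printed: 0.62, +1.6 %), 3.09 % reduction (printed
3.1), ECV share 0.145 Q_in (printed 0.14), PCV gain 29.7 % (printed 30 %).
Measurement resolution also bounds every absolute resistance within
multiplicative factors (1/(1+e_d))⁴(1−e_l) to (1/(1−e_d))⁴(1+e_l) — about
0.48–2.5 for the 20 % diameter and 1.4 % length errors — exposed by
`resistance_uncertainty_bounds`; normalized quantities (shares, reductions)
are far less sensitive because they cancel common factors.

Flow-change classification follows the magnitude convention: change rate
(|q| − |q₀|)/|q₀|, a no-flow label when |q| falls below a threshold fraction
of Q_in (default 0.1 %, configurable), and a separate direction-reversal
flag when the sign flips with both magnitudes above threshold.

## Repositioning geometry

The published planar coordinates of the simplified vein set surrounding the
ECV are not available, so the package defines its own minimal geometry
preserving every printed constraint: the fourth and fifth connecting veins
are parallel straight segments aligned at their base-side endpoints, with
full lengths taken as the sums of the measured split segments (l_C4 = 4.7 mm,
l_C5 = 4.6 mm) and the rail separation calibrated so the straight-line ECV
length at the measured connection fractions (a = 0.486, p = 0.506) equals
the measured 0.62 mm. The PCV junction is fixed at x_pcv = 0.506 of the
fifth connecting vein (it coincides with the ECV's measured posterior
connection). Moving a connection re-splits its vein at the new fraction —
each sub-segment keeping the diameter of the side of the parent vein it lies
on — recomputes the ECV length as the Euclidean A–P distance at constant
diameter, and rebuilds all resistances from Poiseuille's law. When the
posterior connection leaves the PCV junction, a transfer segment of length
l_P = |p − x_pcv|·l_C5 must carry the bypass flow between the crossveins.

Consequences of the unpublished coordinates: absolute surface values away
from the measured position carry geometry-model uncertainty, and the fixed
veins keep their measured (not simplified) lengths, so the original
simplified model's +0.1 % loss overestimate is not reproducible and not
attempted. The qualitative structure is robust and is what the tests
assert: a valley of minima exactly along p = x_pcv for every anterior
position, a monotone decrease of normalized loss as the anterior connection
approaches the edge rail, ≈0.969 normalized loss at the measured position,
and extra loss growing linearly with l_P at small offsets when the ECV
length is held fixed (the repositioning API exposes `fixed_ecv_length_mm`
precisely to isolate that mechanism).

## Idealized circuits

The idealized ladder represents the wing's fourth-to-seventh sections with
uniform microchannels (2 mm full channels, 1 mm connecting halves, 10 µm
diameter). R denotes the initial ECV-channel resistance; connecting halves
are 0.5R. Variant overrides are applied as resistance values directly —
hydraulically only the resistance matters, however it would be fabricated:
`asymmetric` sets the fifth base channel to 0.2R and the sixth edge channel
to 200R (the extreme resistances of the measured wing's corresponding
sections); `asymmetric_highC` additionally sets the fourth/fifth connecting
halves to 10R at the initial position. During position sweeps the
connecting and ECV resistances scale with length at fixed diameter; rungs
are modeled as parallel and aligned, 2 mm apart, making the initial
(midpoint) ECV length 2 mm — the minimal geometry consistent with the
printed initial lengths. The PCV junction stays at the rung-5 midpoint
while the ECV connections move; the benchmark minimum-location properties
confirm this reading.

The uniform variant has exact rational benchmarks, derived by hand from
mirror symmetry plus one loop equation and frozen in the tests: bypass
(PCV) share 1/4 without the ECV at total loss (15/8)·R·Q_in; with the ECV,
ECV and PCV shares 2/7 at total loss (12/7)·R·Q_in, zero flow in the fifth
connecting halves, and a loss reduction of 6/70 ≈ 8.6 %.

**Valley steepness** is defined in this package as the mean, over the
inlet-side grid, of the one-sided gradient jump of the normalized loss
surface across the PCV-junction line, estimated from the three nearest grid
columns: (S(u, v+h) + S(u, v−h) − 2S(u, v))/h. The kink is exactly the
transfer-segment mechanism switching on (extra loss proportional to the
ECV-to-PCV pathway length), so it measures how expensive breaking crossvein
contiguity is. A raw loss penalty at a fixed offset does not discriminate
the variants — the uniform surface's smooth bowl contributes penalty without
any valley — whereas the gradient jump orders them cleanly
(0.087 < 0.091 < 0.94 at grid step 0.01 for uniform, asymmetric and
high-connecting-resistance variants).

## Allometry and mass

The linear scale factor between the Hawaiian fly's wing and the common
fruit fly's is k = √(area ratio) = √8.3 ≈ 2.88; isometry scales masses and
flow rates as k³. k is kept at full precision internally with the rounded
2.9 available as an explicit override (`AllometryParams(k=2.9)`) because
downstream rounded results — e.g. the 65 µg isometric wing mass from a
2.7 µg reference — are reachable only under the rounded convention; both
conventions give a crossvein mass budget that rounds to 1.2 % of the wing
mass. The ECV's mass is lumen volume × hemolymph density (1.02×10³ kg/m³)
plus annular wall volume × cuticle density (1150 kg/m³). Forward computation
from the two-significant-figure table gives 0.0272 µg lumen and 0.736 µg
wall against printed 0.028 and 0.77 (the unrounded dimensions behind the
printed values are unavailable); mass tests therefore use 5 % relative
tolerance, matching the input precision.

## Synthetic data

`random_ladder` generates ladder networks with the structural assumptions
the analysis relies on — two rails sharing inlet/outlet terminals, rungs,
optional crossveins between split rungs — with log-normal lengths (median
1 mm, σ_log 0.8) and lumen diameters (median 8 µm, σ_log 0.5), chosen to
bracket the measured wing's ranges (lengths 0.16–5.0 mm, lumens 2.9–32 µm);
outer diameters apply the 20 % lumen rule in reverse. The seed fully
determines the output. The generator emulates topology and scale only: real
venation's spatial correlations, taper, and branching-law diameter
relationships are not modeled, so passing property tests demonstrate solver
correctness and pipeline robustness on realistic magnitudes, not biological
fidelity of the generated wings. Closed-form fixture circuits (series,
parallel, bridge — whose five-resistor, three-loop unit-resistance form is
the balanced case with branch flows of exactly one half — and the uniform
idealized ladder) anchor both solvers to hand-derived solutions.

## Numerical choices and problem sizes

Double precision throughout; dense `numpy.linalg.solve`. Conservation and
loop-sum residuals are required below 10⁻⁹ of Q_in and Δp_total
respectively; the energy identity Δp_total·Q_in = Σ r_n q_n² and
nodal/mesh agreement below 10⁻⁸ relative. Position sweeps default to the
0.001-step grids of the full experiment via the CLI, while the test suite
and benchmark properties use 0.01-step (and coarser) grids — 99×99 cells per
variant solve in a couple of seconds and already locate minima exactly on
the grid, since the junction line v = 0.5 and the initial position are grid
points. The property suite runs 100 seeded four-rung ladders. Ties in
argmin location cannot occur off the valley line because the kink makes the
junction column strictly lower than its neighbours at machine precision.

## Known limitations

- Steady rigid-tube flow only; flapping-induced deformation, pulsatility
  and aerodynamic loading are outside the model.
- Absolute pressures inherit the full 0.48–2.5× resistance uncertainty of
  the imaged geometry; normalized comparisons are the robust outputs.
- The repositioning surface's absolute values depend on the package's own
  calibrated planar geometry (coordinates of the original simplified model
  being unpublished); only its printed-constraint-preserving structure is
  claimed.
- The generated ladders are statistical stand-ins, not morphogenetic models
  of venation.
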