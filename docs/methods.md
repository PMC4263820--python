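# Methods

## Constitutive model

Cartilage and meniscus are modelled as fibril-reinforced biphasic continua
in the N–mm–s–MPa unit system. The drained, non-fibrillar matrix is linear
isotropic elastic; collagen fibrils add a rank-one, tension-only stiffness
along a per-element direction; the pore fluid contributes a pressure so that
`sigma_total = sigma_effective - p I` (stress tension-positive, pressure
compression-positive); fluid transport is Darcy flow with constant isotropic
permeability. Small-strain kinematics are used throughout (see
*Limitations*).

Default tissue constants (config-overridable presets):

| tissue | E (MPa) | nu | fibril moduli (MPa) | k (mm^4/(N s)) |
|---|---|---|---|---|
| femoral cartilage | 0.64 | 0.08 | tangent 5.6 | 0.00116 |
| tibial cartilage | 0.84 | 0.03 | tangent 5.6 | 0.00326 |
| meniscus | 1.0 | 0.03 | circumferential 40, radial 10 | 0.00100 |

The meniscus matrix modulus is the physiological-strain-rate value rather
than the lowest reported equilibrium value; the stiffer choice keeps the
thin wedge from collapsing onto itself. Cartilage fibrils run tangent to
the articular surfaces (a single in-plane family; a through-thickness
gradient is out of scope). Meniscal *radial* fibrils act in plane; the
*circumferential* family is out of plane in a coronal section and is
represented by the horn anchorage instead (below).

Design note: the matrix is deliberately linear. In the simulated regime the
volumetric response is dominated by fluid incompressibility and the load is
scaled so strains stay mostly moderate, which keeps the linear matrix a
reasonable surrogate for a hyperelastic one; it also makes every
constitutive operator exactly verifiable against closed forms.

## Discretization and solver

* Mixed Q9/Q4 quadrilaterals (biquadratic displacement, bilinear pressure;
  Taylor–Hood family) for inf-sup stability at the instantaneous,
  incompressible limit; 3x3 Gauss quadrature; isoparametric mapping so
  condyle arcs are honoured by the midside nodes.
* Backward Euler in time (first order, unconditionally stable, monotone
  creep without pressure oscillation). Adaptive step control: `dt` grows by
  1.7x per accepted step up to 50 s, halves on Newton failure; every output
  time is hit exactly. Defaults: `dt0 = 0.05 s`, relative Newton tolerance
  1e-6, 25 iterations.
* Direct sparse LU (SuperLU) for the saddle-point systems; mesh sizes are
  desk scale (~3500 DOFs for the default joint), where iterative solvers
  buy nothing and robustness matters.
* The rigid femur is eliminated by a master–slave transformation coupling
  all femoral bone-interface nodes to two generalized DOFs (vertical
  translation, varus–valgus rotation about the joint centre). Small
  grounding springs (0.01 N/mm and 1 N mm/rad per unit depth, i.e. <=0.2 %
  of the applied load at the observed displacements) keep the body
  well-posed before contact engages.
* Newton globalization, needed because penalty contact with switching sets
  and moving projections is only piecewise smooth:
  - C1-regularized penalty law (quadratic blend over a 2e-4 mm gap band) so
    conforming, flat-on-flat interfaces do not chatter at the contact
    boundary;
  - vertex-averaged, slide-continuous contact normals;
  - a backtracking line search on a scaled residual norm, plus a hard cap
    (0.5 mm) on the displacement increment to prevent fall-through of open
    contacts;
  - sealing hysteresis: a point seals only after penetrating past the
    regularization band and unseals only on true separation;
  - after 12 iterations the contact geometry (projections, normals, active/
    sealed sets, fibril tension sets, drainage partition) is frozen, making
    the remaining problem smooth; the frozen-geometry error is quadratic in
    the within-step sliding distance.

## Biphasic contact

Node-to-segment, single pass, frictionless, with the cartilage surface of
each pair as secondary. The auto-penalty rule
`k_p = 100 * min(adjacent H_A) / surface element length` keeps nodal
penetrations well under 1 % of the thinner layer (~2e-3 mm at working
tractions). Six pairs for the intact joint (femoral–meniscus,
meniscus–tibial, femoral–tibial, per compartment), two for the
meniscectomy. Each tibial surface node belongs to exactly one pair
(partitioned at the wedge-tip abscissa), so a patch is never counted twice.

Drainage follows the patch: sealed points tie the secondary pressure to the
interpolated primary pressure by a penalty on the jump (conductance
`1e3 * mean k`, giving relative jump errors ~1e-3); all other contact-face
and peripheral nodes carry `p = 0` exactly (Dirichlet). The partition is
recomputed every Newton iterate. Disabling the switch (forcing free
drainage everywhere) zeroes the surface pressure and is kept as a
regression mechanism test.

## Synthetic joint geometry

All geometry parameters are modelling choices of this package sized to
adult-knee proportions, not measurements: condyle radius 25 mm, centres
44 mm apart, cartilage 2 mm, tibial plateau 70 mm wide, meniscal wedges
0.5 mm tall at the free inner edge and 3.6 mm at the rim. The wedge top
conforms to the condyle arc at a clearance that is smallest (0.005 mm) at
the wedge body and widens parabolically (by 0.08 mm) toward both the free
edge and the rim, so contact engages at the wedge body and spreads — the
thin free edge and the anchored rim corner are protected from displacement-
controlled crushing. The wedge seat is lifted 0.005 mm off the tibial
surface so the reference state is strictly contact-free. The condyle apex
starts 0.13 mm above the tibial cartilage: the menisci take the load first
and the direct cartilage–cartilage path engages part-way up the ramp, which
is what produces the meniscal-dominant initial load share.

Horn attachment: the lower half of each meniscal rim is fixed horizontally
(vertical motion free) — the 2-D analogue of horns anchored in the
transverse plane. This is the module's largest idealization. An alternative
`horn_attachment: spring` mode tethers the rim with the hoop stiffness of
the circumferential fibre bundle, `E_circ * A_wedge / (L_eff * depth)`; at
its physical value (~1 N/mm per unit depth) the wedge extrudes by
millimetres under the contact thrust and the quasi-static solve fails,
which is why rigid anchorage is the default. A real meniscus is also
contained by the dished tibial plateau, which the flat 2-D plateau lacks;
the rigid anchors absorb that missing containment.

Load scaling: the 800 N / 1 s / 1200 s / 5 mm-offset protocol acts on the
plane model as force per unit out-of-plane depth. The default depth is
240 mm, chosen so that peak local strain stays within reach of the
small-strain kinematics (~0.28 at the contact-edge stress concentration;
a 25 mm depth drives local strains past 50 % and the solver regime breaks
down). Depth scales all forces and areas linearly and leaves every
load-share, ratio and timing mechanism intact; absolute displacements and
stresses are therefore *scaled-model* numbers, not predictions of the 3-D
joint.

Meshes are generated deterministically (no randomness) as independent
structured blocks — all inter-tissue coupling is contact, so no nodes are
shared. The default surface mesh size is 1.0 mm.

## Output metrics

* Femoral vertical displacement (meniscectomy displacement is counted from
  first cartilage–cartilage contact, i.e. the free travel across the gap
  left by the removed menisci is excluded).
* Contact areas = active tributary length x depth, reported per pair; the
  compartment and total areas count tibial-surface coverage
  (femoral–tibial + meniscus–tibial) so femoral- and tibial-side measures
  of the same patch are not double counted.
* Interface load partition: the meniscal path is the femoral–meniscus
  vertical force (the load entering the menisci), the direct path the
  femoral–tibial force; compartment forces are femur-side sums, so their
  total equals the applied load at every converged step (observed <=0.15 %).
* Peak compressive stress: magnitude of the most negative principal total
  stress (including the out-of-plane component) over the tibial cartilage.
* Probes: "condyle centre" and "meniscus interface" points are the
  traction-weighted centroids of the femoral–tibial and meniscus–tibial
  patches at the end of the ramp, snapped to the nearest surface pressure
  node and then tracked as fixed material points. The fluid support ratio
  is the pore pressure over the contact pressure, both averaged over a
  1.6 mm window of surface nodes around the probe, because pointwise nodal
  penalty tractions are not mesh-stable.

## What the defaults do and do not show

At the default configuration the model reproduces the qualitative creep
mechanics of a loaded knee: monotone growth of displacement (+81 % over the
hold) and contact area; an initially meniscal-dominant load path (~70 %)
that migrates to the direct cartilage–cartilage path; a stable medial bias
(~59 %) set by the 5 mm load offset, vanishing when the load is centred and
growing monotonically with offset; roughly halved contact area and more
than doubled peak compressive stress after double meniscectomy; and high,
slowly decaying fluid load support at the patch centres versus rapid decay
near the draining meniscus interface. These are mechanisms of the 2-D
scaled model — absolute magnitudes are not comparable to a 3-D joint.

The condyle-centre fluid support ratio at the end of the ramp measures 0.89
at the default 1.0 mm mesh. The quantity is discretization-sensitive
(refinement moves it toward ~0.95, but nodal penalty tractions become noisy
on non-matched finer meshes), and the 2-D plane-strain linear matrix puts a
larger deviatoric share on the solid than a 3-D fibril-stiffened tissue
would; both effects depress the ratio slightly below the ~0.95 expected of
healthy cartilage at load onset.

## Numerical choices and degenerate inputs

* Tie-breaks: closest-point projection takes the first minimal-distance
  segment; projections beyond polyline ends carry no traction.
* A Poisson ratio >= 0.5 raises an incompressibility error — biphasic theory
  needs a compressible drained skeleton.
* Inverted elements (non-positive Jacobians) and zero-length contact
  segments are rejected at construction.
* Singular systems (missing constraints) surface as a solver error naming
  the cause rather than silently returning garbage.
* The confined-creep oracle folds its truncated series tail into the first
  dropped mode, so `u(0) = 0` holds to machine precision at any truncation
  order; 20 vs 200 terms agree to <1e-10 for `t >= 0.01 t_g` (at
  `t = 0.001 t_g` a 20-term series is mathematically ~1e-5 short).

## Known limitations

Small-strain kinematics with contact search on the deformed configuration
(a warning is logged past 15 % strain; the default joint peaks near 28 %
locally at contact edges). No osmotic swelling, intrinsic solid
viscoelasticity, strain-dependent permeability, or depth-dependent property
gradients. Frictionless contact. 2-D plane strain cannot represent
anterior–posterior load sharing, meniscal hoop tension acts only through
the rim anchorage, and meniscectomy-induced realignment is not modelled
(alignment is identical between variants by construction).
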