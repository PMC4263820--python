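# poroknee

Fibril-reinforced biphasic finite-element simulation of time-dependent
tibiofemoral contact in a synthetic 2-D coronal knee joint.

Articular cartilage and meniscus are hydrated, biphasic tissues: an
incompressible interstitial fluid percolating a porous collagen/proteoglycan
skeleton. Under body weight the joint *creeps* — fluid slowly exudes from the
loaded regions, the effective tissue stiffness falls, and contact areas,
displacement and load paths all evolve over hundreds of seconds. Capturing
this requires biphasic contact with the correct fluid boundary conditions:
the pore pressure must be continuous across surfaces in contact, while every
surface outside the contact patch drains freely, and the partition between
the two moves with the patch. `poroknee` implements this whole pipeline for
researchers in cartilage and joint biomechanics who want a desk-scale,
fully scriptable model of the mechanism, rather than a subject-specific 3-D
reconstruction.

## Model

Each tissue obeys a fibril-reinforced biphasic law. The total (mixture)
stress splits as

    sigma = sigma_m(eps) + sigma_f(eps) - p I

with a linear isotropic non-fibrillar matrix
`sigma_m = lambda tr(eps) I + 2 mu eps`, tension-only collagen fibrils
`sigma_f = E_f <eps_f> d (x) d` (`eps_f = d . eps d`, active only in
tension), pore pressure `p` (compression-positive), and Darcy flow
`w = -k grad p` with constant permeability `k`. Mass balance closes the
system: `d(tr eps)/dt = div(k grad p)`.

Discretization is a mixed Q9/Q4 (Taylor–Hood) displacement–pressure
formulation with backward-Euler time stepping, adaptive step control, and a
damped semi-smooth Newton solver. Contact is node-to-segment penalty
(`t_n = k_p * gap`) with automatic penalty estimation from the aggregate
modulus, pressure continuity across sealed (contacting) faces enforced by
penalizing the interfacial pressure jump, and `p = 0` on all exposed faces —
recomputed as the patch evolves.

The synthetic joint is a coronal cross-section: two circular-arc femoral
condyle cartilage layers bonded to a rigid femur (free vertical translation
and varus–valgus rotation), a flat tibial cartilage layer fixed at its base,
and two wedge-shaped menisci whose rims are anchored transversely, mimicking
horn attachment. The standing protocol ramps 800 N over 1 s and holds it for
1200 s, applied 5 mm medial of the joint centre (equivalent to a 4 N m
adduction moment). A double-meniscectomy variant removes the wedges with
unchanged alignment. Plane-strain forces are scaled by an out-of-plane depth.

## Worked example

```python
from poroknee import run_creep

ts = run_creep("intact")
print(f"displacement {ts.displacement[0]:.3f} -> {ts.displacement[-1]:.3f} mm")
print(f"meniscal share {ts.force_meniscus_path[0]/ts.applied_force[0]:.2f} -> "
      f"{ts.force_meniscus_path[-1]/ts.applied_force[-1]:.2f}")
print(f"medial share {ts.force_medial[0]/(ts.force_medial[0]+ts.force_lateral[0]):.2f}")
print(f"centre fluid support {ts.probes['condyle_centre_medial']['fsr'][0]:.2f} -> "
      f"{ts.probes['condyle_centre_medial']['fsr'][-1]:.2f}")
```

prints, with the default configuration:

```
displacement 0.218 -> 0.394 mm
meniscal share 0.70 -> 0.33
medial share 0.59
centre fluid support 0.89 -> 0.72
```

Femoral settlement grows 81 % during the hold as fluid exudes; the menisci
carry ~70 % of the load at the end of the ramp and progressively hand it to
the direct cartilage–cartilage path; the medial compartment bears ~59 % of
the load throughout; and the fluid phase supports ~90 % of the contact
stress at the condyle centre, decaying slowly because the patch centre is
far from the moving drainage boundary. Removing both menisci roughly halves
the contact area and more than doubles the peak compressive stress
(magnitude of the third principal total stress).

The same pipeline is available from the shell:

```
poroknee run --case both --out results/
poroknee dump-config config.yaml
```

which writes per-case CSV time series, JSON summaries, legacy-VTK field
snapshots, and an intact-vs-meniscectomy comparison report.

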