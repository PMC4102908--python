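# pholiage

Instantaneous light capture and net photosynthesis of an individual
three-dimensional tree crown inside a vegetation canopy, with virtual
"liberation" gaps of variable radius.

## The problem

On degraded tropical lands, dense regrowth of shrubs and grasses shades out
young trees and stalls secondary forest succession. A common restoration
measure, *liberation*, clears the vegetation in a radius around a target
tree. Whether liberation pays off depends on how the tree's stature, crown
architecture and leaf physiology interact with the height and density of
the surrounding vegetation — which is exactly what this package computes.
It is aimed at plant ecophysiologists and restoration ecologists who want
to compare species and gap radii before cutting anything.

## The model

A target tree has an axisymmetric ellipsoidal crown (width *w*, length
*l*, leaf area density *lad*) on a stem at the origin; the surrounding
vegetation is a horizontally homogeneous turbid slab of height *H* and
leaf area index *LAI*; a liberation gap is a vertical cylinder of radius
*r* around the stem, cleared from the soil to the canopy top. Diffuse
light from a discretised overcast sky (uniform or standard overcast,
normalised so the horizontal PPFD above the canopy is *I₀*) is traced from
every crown point to every sky sector. Along each ray, Beer's law gives
the transmittance

    T = exp(−[G_veg(β)·lad_veg·s_veg + G_tree(β)·lad_tree·s_crown])

where *s* are the analytic path lengths through each medium and *G(β)* is
the leaf-angle projection function of a discrete inclination distribution
(the "spherical" preset gives *G* = ½ exactly). The absorbed flux per unit
leaf area at a point is φ_p = Σ_s B_s·G_tree(β_s)·T_s.

Leaf nitrogen follows the light gradient of the canopy the leaves grew in
(the intact stand): N_area = N₀·(I/I₀)^0.4, photosynthetic capacity is
proportional to nitrogen (P_max = slope·N_area), and the leaf light
response is a non-rectangular hyperbola with curvature θ (default 0.7)
minus dark respiration R_d. Whole-crown light capture Φ and net
photosynthesis P integrate the point rates over a product-Gauss quadrature
of the crown ellipsoid; Φ_area = Φ/LA and P_area = P/LA correct for plant
size. Opening a gap changes the light instantly but not the (slowly
acclimating) nitrogen profile.

The package ships the measured parameters of three South-East Asian
pioneer species (*Mallotus microcarpus*, *Mallotus paniculatus*,
*Macaranga denticulata*) and of three successional vegetation stands from
a field liberation experiment in central Vietnam, plus a seeded synthetic
scene generator for testing.

## Worked example

Liberate the mean *Mallotus microcarpus* tree (height 1.26 m, leaf area
0.29 m²) in the 1.5-year-old stand (LAI 3.73, height 1.40 m) with the
field treatment's 0.5 m gap:

```python
import pholiage as ph

fix = ph.species_table2()[0]                      # Mallotus microcarpus
stand3 = {s.label: s for s in ph.stands_table1()}["III"]
stand = ph.VegetationStand(height=stand3.height, lai=stand3.lai)
res = ph.simulate_liberation(ph.make_tree(fix), ph.make_physiology(fix),
                             stand, gap_radius=0.5)
print(res.to_frame().round(3))
```

```
 treatment  gap_radius      phi      p  phi_area  p_area
   control         0.0   70.476  1.164   243.021   4.013
 liberated         0.5  108.570  1.500   374.378   5.171
```

Under an overcast sky delivering 1000 μmol m⁻² s⁻¹ on a horizontal plane,
the intact canopy lets this crown capture 70.5 μmol photons s⁻¹ and fix
1.16 μmol CO₂ s⁻¹; clearing a 0.5 m gap raises light capture per unit leaf
area from 243 to 374 μmol m⁻² s⁻¹ and net photosynthesis per unit leaf
area from 4.0 to 5.2 μmol m⁻² s⁻¹ — the instantaneous benefit of the
treatment.

The same experiments are available from the shell: `pholiage
gap-sweep|lai-sweep|height-sweep|stands|liberate --config run.yaml --out
results/` write tidy CSVs plus a run-metadata JSON, and `pholiage fixtures
--list` prints the packaged tables. A config file names the tree, stand,
gap, species physiology, sky and numerics:

```yaml
tree:
  height: 1.26          # m
  crown_volume: 0.04    # m^3
  lw_ratio: 1.18        # crown length : width
  leaf_area: 0.29       # m^2
  lad: 6.72             # m^2 m^-3 (defaults to leaf_area/volume)
  leaf_angle_fractions: [[15, 0.23], [45, 0.48], [75, 0.29]]
stand:
  height: 1.40          # m
  lai: 3.73             # m^2 m^-2
  leaf_angle_fractions: spherical
gap:
  radius: 0.5           # m
species:
  name: Mallotus microcarpus
  n_o: 94.28            # mmol N m^-2, crown-top leaves
  pmax_slope: 0.17      # μmol CO2 m^-2 s^-1 per mmol N m^-2
  r_d: 1.04             # μmol CO2 m^-2 s^-1
  quantum_yield: 0.03   # mol CO2 / mol photons
sky:
  type: uoc             # or soc
  n_elevation: 9
  n_azimuth: 12
  io: 1000.0            # μmol m^-2 s^-1 horizontal PPFD
numerics:
  crown_grid: 16        # quadrature nodes per axis
sweep:
  radii: null           # default: 0 plus 16 log-spaced values 0.05-2.5 m
  normalization_radius: 2.5
```

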