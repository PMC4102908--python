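# Methods

## Scene and radiative transfer

The scene is a single target tree inside a horizontally homogeneous
vegetation layer. Coordinates are metres with z up and the ground at
z = 0; the stem sits at the horizontal origin unless placed elsewhere.

The crown is an axisymmetric ellipsoid with a circular cross-section.
Field allometry reports crown size as a volume V and a length:width ratio
ρ (crowns are measured in four directions but only these two summaries are
reported), so the ellipsoid is reconstructed as w = (6V/(πρ))^(1/3),
l = ρ·w, and attached below the tree top (crown base = height − l; the
insertion height is not measured, so the crown hangs from the top of the
stem). The surrounding vegetation is a turbid slab 0 ≤ z ≤ H with leaf
area density LAI/H; it may overtop the tree. A liberation gap is a
vertical cylinder of cleared vegetation around the stem spanning the full
slab. The vegetation medium is the slab minus the gap cylinder minus the
crown ellipsoid — the tree's own foliage replaces, not augments, the
vegetation where the crown sits, so no volume is double-counted. All
ray–solid intersections are solved analytically as parameter intervals and
combined by inclusion–exclusion; a fixed-step (1 mm) marching integrator
serves as the independent oracle in the test suite (agreement within 2 mm
per solid, 5 mm for the composed medium).

Diffuse sky light is discretised into elevation bands uniform in sin β
(equal solid angle, evaluated at band midpoints, so the horizon itself is
never sampled) times uniform azimuth sectors; the default is 9 × 12
sectors. Radiance is constant for the uniform overcast sky (the default,
matching the overcast conditions under which the field light profiles were
taken) or proportional to (1 + 2 sin β)/3 for the standard overcast sky.
Sector beam irradiances are scaled so that Σ B_s sin β_s equals the
horizontal PPFD above the canopy, I₀ = 1000 μmol m⁻² s⁻¹ by default.
There is no direct solar beam and no diurnal integration: all quantities
are instantaneous.

Extinction follows Beer's law for black (fully absorbing) leaves,
T = exp(−[G_veg·lad_veg·s_veg + G_tree·lad_tree·s_crown]), with the
projection function G(β) of a discrete leaf-inclination distribution
computed from the exact uniform-azimuth closed form; the "spherical"
preset short-circuits to G = ½. Leaf-angle class fractions are used as
tabulated (printed tables round to two decimals and may sum to 1.01; they
are deliberately not renormalised, so tabulated worked examples reproduce
exactly). An absorptance multiplier (default 1.0) is exposed for
sensitivity analyses; scattering is not modelled.

Crown integration uses a spherical-product Gauss rule in normalised
ellipsoid coordinates: Gauss–Legendre nodes in the radial measure u = r³
and the polar cosine, midpoint nodes in azimuth (default 16 × 16 × 16).
Weights sum to the crown volume to machine precision and every node lies
strictly inside the ellipsoid; whole-crown totals change by well under 1%
when the grid is doubled.

## Physiology

Relative light intensity at a crown point is φ_p/φ_top, where φ_top is
the absorbed flux of an unshaded leaf with the same angle distribution
under the same sky, so a fully exposed crown top has relative light 1.
Leaf nitrogen per area scales with relative light to the power 0.4 from
the crown-top value N₀; photosynthetic capacity is proportional to
nitrogen, P_max = slope·N_area (the measured relation has no reported
intercept; an optional intercept, default 0, is exposed). The leaf light
response is a non-rectangular hyperbola — the smaller root of
θP² − (qφ_p + P_max)P + qφ_p·P_max = 0 — with the apparent quantum yield
q applied to absorbed PPFD and curvature θ defaulting to 0.7, the standard
canopy-model choice; θ = 0 recovers the rectangular hyperbola and θ = 1
the Blackman limit. Net rate is gross minus dark respiration R_d. Dark
respiration values (0.24–1.04) are stored in μmol CO₂ m⁻² s⁻¹; the source
table's "mmol" column header is treated as a unit typo, since mmol-scale
respiration is three orders of magnitude beyond leaf physiology.

**Nitrogen acclimation.** Nitrogen redistributes over weeks, not seconds,
while liberation is modelled as instantaneous. The nitrogen gradient
therefore follows the light climate of the *intact* canopy (gap radius 0)
of the current stand, and is held fixed when a gap is opened. This
matters: with nitrogen recomputed from the post-removal light field, deep
leaves would be credited with capacity they cannot yet have, and the
photosynthetic benefit of small gaps is overstated relative to large
ones. All sweeps cache one acclimation profile per tree × stand. The
profile can be overridden per call for scenario studies.

Temperature, CO₂ and stomatal responses are not modelled (gas exchange
was measured at a fixed 370 ppm), and no whole-plant carbon budget is
attempted: respiration of stems and roots, biomass allocation and growth
dynamics are outside the model.

## Simulations

Four experiments wrap the crown model, each returning a tidy DataFrame
and each fully deterministic given its inputs:

- **Gap-radius sweep** — default grid 0 plus 16 log-spaced radii from
  0.05 to 2.5 m, with percent-of-maximum columns normalised to the rate
  at 2.5 m (light capture saturates there for all packaged species).
- **LAI sweep** — vegetation density varies at fixed height, canopy
  intact or with a fixed 0.5 m gap (the field treatment).
- **Height sweep** — vegetation height varies at constant leaf area
  density (LAI grows with height); the first grid height at which net
  photosynthesis turns negative is reported without root refinement.
- **Stand scenarios** — every species × stand × radius combination, with
  photosynthesis as a percentage of both the control (radius 0) and the
  maximum (radius 2.5 m). Packaged mean trees stand in for individual
  field trees, so these outputs are a mean-tree approximation.

With the packaged parameters these reproduce the expected physics: rates
rise monotonically with gap radius and fall with vegetation LAI and
height; the tallest, leafiest species (*M. microcarpus*) captures the
most light in the intact stand but, being the most respiring, is also the
first to go carbon-negative when overtopped; liberation damps the LAI
effect strongly. One consequence of the mean-tree approximation is worth
flagging: because the mean 1.5-year-old trees overtop the younger stands,
the relative benefit of removal *increases* with stand development
(stand I < II < III), whereas individual trees measured in younger stands
were relatively shorter and showed the opposite ranking.

## Synthetic scenes

`random_scene(seed)` draws a tree, stand, gap and physiology uniformly
from ranges bracketing the field system (tree height 0.3–3 m, crown
volume 0.005–0.2 m³, stand LAI 0–8, stand height 0.5–3 m, gap 0–2.5 m,
N₀ 60–120 mmol m⁻², etc.), resampling infeasible crowns. It emulates the
*scale* and *composition* of real scenes, not their correlations: real
allometry couples height, volume and leaf area, and real stands are
heterogeneous. Property tests passing on synthetic scenes therefore
demonstrate geometric and numerical correctness, not field realism.

## Numerical choices and problem sizes

Default resolutions (sky 9 × 12, crown 16³) were chosen so that doubling
either changes whole-crown totals by < 1% and azimuthal refinement by
< 0.5% on the axisymmetric scene. Qualitative direction tests in the
suite run at coarser resolution (sky 6 × 8, crown 8³), which preserves
every ordering tested while keeping the whole suite under ten seconds.
The reproduction script runs the nine species × stand comparisons and the
three 17-point gap sweeps at full default resolution in a few seconds.
Degenerate cases are handled explicitly: a zero-radius gap is bit-exact
the intact canopy, vertical rays hit the cylinder in the axis-parallel
limit, a dark sky (I₀ = 0) yields pure dark respiration, and θ at its
endpoints evaluates the limiting response forms rather than the quadratic.

## Known limitations

- Light capture saturates with gap radius considerably more slowly than
  net photosynthesis: low-elevation sky sectors keep crossing vegetation
  outside any realistic gap, so Φ at a 1 m gap is only 75–88% of its
  2.5 m value for the packaged species (fully converged under grid and
  sky refinement), while P reaches 95% by ~1.1 m. Statements that both
  rates are "near maximum" at 1 m hold for photosynthesis, and for light
  capture only on a logarithmic axis.
- Single tree, axisymmetric crown, homogeneous slab: no neighbour crowns,
  clumping, terrain, penumbra or spectral detail.
- Instantaneous rates only; no coupling to growth, allocation or
  below-ground competition.
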