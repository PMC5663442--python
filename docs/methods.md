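# Methods

## The model in brief

A panoramic *snapshot* taken at a goal location defines two scalar
comparison functions against views elsewhere. Rotating the snapshot about
the vertical (yaw) axis against a view at the same place gives the
rotational image difference function (rotIDF); comparing same-orientation
views at displaced locations gives the translational image difference
function (transIDF), a smooth 3D field with its global minimum at the
snapshot location. All differences are root-mean-square pixel differences
of 8-bit greyscale equirectangular panoramas, in grey levels on the 0–255
scale (the maximum possible difference is 255), computed in double
precision without any contrast normalisation.

The *catchment volume* of a snapshot is the set of grid locations from
which discrete steepest-gradient hill climbing on the transIDF reaches the
snapshot location. A step from the current grid point (value V₁) to a
26-neighbour (value Vₙ, Euclidean separation *distance* = spacing·√d for a
d-axis diagonal) is accepted only when the descending gradient
(V₁ − Vₙ)/*distance* strictly exceeds a threshold. The threshold is
`fraction` (default 0.10) × the maximum of the snapshot's self-rotIDF, per
metre — a relative sensitivity measure tied to local image structure.
Climbs that end at the reference are successes; failures are labelled
`false_minimum` (no descending neighbour), `subthreshold` (descending
neighbours exist but none exceeds the threshold) or `left_volume` (the only
supra-threshold descent points out of the sampled grid; see *Numerical
choices*).

## Rendering pipeline

Views are rendered as six 95°×95° pinhole images (north, east, south, west,
up, down) of `face_res`² pixels, then spherically projected onto an
equirectangular raster of `pano_width` × `pano_width/2` pixels and
flattened to greyscale with ITU-R BT.601 luma weights
(0.299 R + 0.587 G + 0.114 B, rounded). The reference configuration is
128-pixel faces and a 384×192 panorama (360/384 = 0.9375° per pixel);
experiments in this repository run at 32-pixel faces and 192×96 panoramas,
which preserves every convention at a quarter of the angular resolution.
Azimuth 0° is north, increasing clockwise through east; the horizon falls
exactly on the boundary between the upper and lower half of the raster, so
above-horizon masking keeps exactly the top half rows. Projection selects
the cube face with the dominant direction component and samples it
bilinearly; the 5° of FOV beyond 90° is pure overlap margin. No solid-angle
weighting is applied anywhere: polar rows count as much as equatorial rows
in every r.m.s. (a weighting option exists but is off by default).

## The synthetic world

Real nesting habitats are emulated by a procedural generator whose scenes
are pure functions of a declarative spec plus a seed:

* **Ground**: an infinite plane whose albedo inside `ground_extent` is
  multi-octave value noise between `albedo_lo` and `albedo_hi`. The
  coarsest octave has wavelength `noise_scale` (presets: 6–8 m) and six
  octaves halve it down to ~0.2 m. The multi-scale spectrum matters: with
  contrast only at decimetre scale the transIDF plateaus within half a
  metre of the reference, whereas natural ground (grass patches, soil,
  litter) carries albedo structure at all scales and produces transIDFs
  that keep rising over many metres.
* **Trees**: vertical cylinders (trunks) topped by spheres (canopies);
  **clutter**: small spheres resting on the ground. Simplest primitives
  that reproduce the cluttered-site vs open-site scene classes.
* **Lighting**: ambient only — every surface returns its albedo — plus
  hard cast shadows: a surface point whose line to the sun intersects any
  trunk, canopy or clutter sphere has its shade multiplied by
  `shadow_darkening` (presets 0.4; 1.0 disables shadows). There is no
  specular term and no sky gradient.
* **Sky/background**: rays that miss everything return the uniform
  `sky_color`; optionally a flat backdrop colour, or a distant-panorama
  sphere (default radius 500 m) carrying a procedural skyline texture
  (dark tree-line silhouette below a noisy skyline elevation).

Three presets ship with the package: `site1_like` (near trees, clutter,
strong shadows), `site3_like` (open ground, four large distant trees) and
`four_landmarks` (four identical trees at 90° compass spacing with the sun
at the zenith and untextured ground — an exactly four-fold symmetric,
rotationally aliased scene).

What the generator does **not** emulate: photogrammetric reconstruction
artefacts, anisotropic surface reflectance, wind motion, illumination
change, repetitive man-made texture, and the true multi-scale geometry of
vegetation. Passing tests therefore demonstrate the *method's* behaviour
(projection geometry, IDF structure, catchment algorithmics and the
direction of the ablation effects) on controlled scenes, not quantitative
IDF values of any real site.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `face_res` / `pano_width` | 128 / 384 | px | rendering resolution (32 / 192 in shipped experiments) |
| grid `side`, `spacing` | e.g. 10, 0.5 | m | sampling cube; counts = round(side/spacing)+1 per axis |
| `threshold_fraction` | 0.10 | — | gradient threshold as a fraction of max self-rotIDF per metre |
| `shadow_darkening` | 0.4 (presets) | — | albedo multiplier inside cast shadows |
| `noise_scale`, `octaves` | 6–8, 6 | m, — | coarsest ground-noise wavelength and octave count |
| `sphere_radius_m` | 500 | m | distant-panorama sphere radius |
| GD `step_m`, `stop_radius_m` | spacing/2, spacing | m | continuous-descent step and success radius |

## Numerical choices

* Ray–primitive intersection tolerance 1e-9 m; nearest-hit ties break by
  declaration order (ground, trunks, canopies, clutter). A ray starting
  inside a solid primitive returns that primitive's colour (exit surface).
* rotIDF granularity is one pixel column (360/`pano_width` degrees); masks
  used with the rotIDF must keep or drop whole rows so rolling commutes
  with masking.
* Hill-climb tie-breaks among equal steepest gradients use a fixed
  (dz, dy, dx ascending) neighbour order; ties are measure-zero on textured
  scenes but occur in integer-valued test volumes.
* Threshold comparison is strict (> threshold). A constant reference image
  yields threshold 0 (with a warning) and unthresholded climbing.
* `left_volume`: the sampled climbs cannot literally exit the grid, so a
  terminal voxel is labelled `left_volume` when a one-sided check — linear
  extrapolation through the mirror neighbour, V_out = 2·V₁ − V_mirror —
  finds a supra-threshold descent pointing outward. This is an
  interpretation of "left the volume" on a bounded grid.
* Catchment extraction memoizes merged paths (a climb reaching an already
  classified voxel inherits its terminal status); a test asserts equality
  with the unmemoized computation.
* Continuous gradient descent runs on the trilinearly interpolated volume
  with central finite differences (h = spacing/2, one-sided at the hull),
  fixed step length, no threshold, and succeeds within one grid spacing of
  the reference; the "within one spacing" radius is configurable because
  the discrete success criterion does not transfer uniquely to continuous
  space.

## Design choices where the design was open

* **Azimuth origin**: column 0 = north, clockwise. Any consistent choice
  only rotates rotIDF curves.
* **Panorama resolution nominal value**: the panorama covers 360° in 384
  columns; the exact 0.9375°/px is used throughout (0.9° is its rounding).
* **Background sphere radius** defaults to 500 m (1 km diameter),
  configurable.
* **Reference placement**: references sit on the vertical axis through the
  grid centre at the grid plane nearest the requested height.
* **Experiment scale**: shipped experiments use 11³–21³ grids at 32-pixel
  faces; the 51³ × 128-face configuration remains supported but renders
  for hours on one core. The hill-climb/gradient-descent comparison uses
  the 11³ cube with the grid-centre reference; the height/masking
  comparisons use the 10 m cube at 0.5 m spacing, matching the physical
  extent over which the masking ablation's gradient-flattening effect
  operates.

## Known limitations

* IDF values of the synthetic scenes are not comparable to any real site's
  absolute numbers; only structural and directional claims are tested.
* Binary hard shadows ignore penumbrae; shadow edges are one pixel sharp
  at any resolution.
* At a reference very close to textured ground the transIDF is rugged at
  the grid scale and the continuous-descent cross-check legitimately
  diverges from the discrete climb; the agreement property is stated for
  the grid-centre reference.
* No image preprocessing (difference-of-Gaussians filtering, contrast
  normalisation, skyline extraction) is implemented; r.m.s. runs on raw
  grey levels.
* The sign of the distant-background effect on catchment size depends on
  how bright the backdrop is relative to the silhouette texture and on how
  much of the view sphere the silhouette occupies; the shipped procedural
  skyline covers only a few degrees above the horizon and should not be
  read as reproducing any particular real site's direction of effect.
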