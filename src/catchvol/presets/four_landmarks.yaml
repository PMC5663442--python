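# Four identical equidistant landmarks at 90 degree compass spacing: the
# rotationally aliased scene (four indistinguishable rotIDF minima).  The
# ground is untextured and the sun is at the zenith so the scene is exactly
# four-fold symmetric about the vertical axis through the origin.
seed: 4
ground_extent: 40.0
ground_texture: {noise_scale: 0.3, albedo_lo: 0.5, albedo_hi: 0.5}
trees:
  - {position: [0.0, 8.0], trunk_radius: 0.3, trunk_height: 3.0, canopy_radius: 2.0, albedo: 0.2}
  - {position: [8.0, 0.0], trunk_radius: 0.3, trunk_height: 3.0, canopy_radius: 2.0, albedo: 0.2}
  - {position: [0.0, -8.0], trunk_radius: 0.3, trunk_height: 3.0, canopy_radius: 2.0, albedo: 0.2}
  - {position: [-8.0, 0.0], trunk_radius: 0.3, trunk_height: 3.0, canopy_radius: 2.0, albedo: 0.2}
clutter: []
sun: {azimuth_deg: 0.0, elevation_deg: 90.0, shadow_darkening: 0.4}
sky_color: [135, 190, 240]
background: {mode: none}
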