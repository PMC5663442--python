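# Open woodland-park preset: a few large scattered trees, open textured ground.
seed: 33
ground_extent: 60.0
ground_texture: {noise_scale: 8.0, albedo_lo: 0.25, albedo_hi: 0.75, octaves: 6, persistence: 0.55}
trees:
  - {position: [12.0, 6.0], trunk_radius: 0.5, trunk_height: 6.0, canopy_radius: 4.0, albedo: 0.2}
  - {position: [-10.0, 14.0], trunk_radius: 0.6, trunk_height: 7.0, canopy_radius: 5.0, albedo: 0.22}
  - {position: [-14.0, -8.0], trunk_radius: 0.45, trunk_height: 5.5, canopy_radius: 3.5, albedo: 0.21}
  - {position: [8.0, -16.0], trunk_radius: 0.55, trunk_height: 6.5, canopy_radius: 4.5, albedo: 0.23}
clutter: []
sun: {azimuth_deg: 135.0, elevation_deg: 40.0, shadow_darkening: 0.4}
sky_color: [135, 190, 240]
background: {mode: none}
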