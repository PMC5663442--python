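# Cluttered nesting-site preset: near trees, ground clutter, strong shadows.
seed: 11
ground_extent: 40.0
ground_texture: {noise_scale: 6.0, albedo_lo: 0.2, albedo_hi: 0.8, octaves: 6, persistence: 0.55}
trees:
  - {position: [2.5, 3.0], trunk_radius: 0.2, trunk_height: 3.0, canopy_radius: 1.8, albedo: 0.22}
  - {position: [-3.0, 2.0], trunk_radius: 0.25, trunk_height: 3.5, canopy_radius: 2.2, albedo: 0.2}
  - {position: [-2.0, -3.5], trunk_radius: 0.18, trunk_height: 2.5, canopy_radius: 1.5, albedo: 0.24}
  - {position: [4.0, -2.0], trunk_radius: 0.3, trunk_height: 4.0, canopy_radius: 2.5, albedo: 0.21}
  - {position: [0.5, 5.5], trunk_radius: 0.15, trunk_height: 2.2, canopy_radius: 1.2, albedo: 0.25}
  - {position: [-5.0, -1.0], trunk_radius: 0.22, trunk_height: 3.2, canopy_radius: 2.0, albedo: 0.23}
clutter:
  - {position: [0.8, -0.9], radius: 0.15, albedo: 0.45}
  - {position: [-1.2, 0.6], radius: 0.2, albedo: 0.35}
  - {position: [1.5, 1.2], radius: 0.12, albedo: 0.5}
  - {position: [-0.6, -1.8], radius: 0.18, albedo: 0.4}
  - {position: [2.2, -1.5], radius: 0.25, albedo: 0.3}
  - {position: [-2.4, 1.8], radius: 0.14, albedo: 0.55}
  - {position: [0.3, 2.4], radius: 0.16, albedo: 0.42}
  - {position: [-1.8, -0.4], radius: 0.22, albedo: 0.38}
sun: {azimuth_deg: 135.0, elevation_deg: 40.0, shadow_darkening: 0.4}
sky_color: [135, 190, 240]
background: {mode: none}
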