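# Example instrument configuration (pass with --config or LidarConfig.from_toml).
# Missing keys keep the package defaults.

wavelength = 532.0
fovs = [0.040, 0.080, 0.200]   # receiver full angles, rad (in water)
lidar_height = 5.0             # platform height above the surface, m
receiver_radius = 0.1          # effective aperture radius, m
bin_size = 1.0                 # range resolution, m
max_depth = 30.0               # deepest simulated bin, m
system_constant = 1.0          # overall signal scale C0
molecular_f = 0.835            # molecular phase anisotropy, p ~ 1 + f cos^2

[water]                        # pure-seawater coefficients at 532 nm, m^-1
a_w = 0.042
b_w = 0.0022
b_bw = 0.0011
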