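# Fish keratocyte: fast gliding cell, 20 s between frames.
domain_length_um: 81.5
total_time_s: 360.0
frame_interval_s: 20.0
characteristic_force_pN: 10.0
surface_tension_pN: 10.0
friction_pNs_per_um2: 2.62
eps_bar: 0.01
RTS: 10
# tau_bar computed from the physics above (tau L^2 / (F T) = 4.83)
grid_n: 256
theta: 1.0e-3
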