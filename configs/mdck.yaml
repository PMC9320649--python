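# MDCK epithelial kidney cells, 5 min between frames; multiple cells with
# divisions, so the Euler-number trace is the interesting output here.
domain_length_um: 220.0
total_time_s: 1800.0
frame_interval_s: 300.0
characteristic_force_pN: 10.0
surface_tension_pN: 10.0
friction_pNs_per_um2: 2.62
eps_bar: 0.05
RTS: 5
# tau_bar computed from the physics above (tau L^2 / (F T) = 7.04)
grid_n: 256
theta: 1.0e-3
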