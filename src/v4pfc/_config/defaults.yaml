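# Reference configuration of the two-layer V4-vlPFC rate network.
# Times in ms, rates in spikes/s; weights dimensionless.
tau_v4: 50.0
tau_pfc: 20.0
r_thr_v4: 20.0
r_thr_pfc: 0.0
sigma_nr: 90.0
n_nr: 2.0
f_max: 100.0
r_thr1: 30.0
r_thr2: 10.0
tau_a: 30.0
tau_d_ff: 40.0
tau_d_fb: 40.0
w_inf_sff: 0.5
w_inf_wff: 0.2
w_inf_sfb: 1.3
# w_inf_wfb omitted: derived as w_inf_sfb * w_inf_wff / w_inf_sff = 0.52
gain_coeffs: [-0.0017, 0.39, -29.6, 806.0]
noise_std_coeff: 300.0
noise_on: false
dt: 0.01
t_total: 700.0
gain_delay: 0.0
kernel_support: 120.0
kernel_norm: area
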