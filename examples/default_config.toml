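seed = 0
log_level = "INFO"

[risk]
G = 0.001
k1 = 1.0
k2 = 0.05
R2 = 1.0
M2 = 1705.0
threshold = 0.05
duration_mapping = "table1"

[risk.durations]
saeb = 20.0
lci = 15.0
rci = 10.0
rpcr = 6.0

[pre]
detrend_order = 2
movavg_window_s = 0.0

[pre.tddr]
enabled = true
split_hz = 0.5
biweight_c = 4.685
tol = 1e-06
max_iter = 50

[pre.band]
lo = 0.015
hi = 0.08
order = 4
family = "butter"

[feat]
ksvd_k = 4
ksvd_t0 = 1
ksvd_iters = 15
segment_points = 64
canonicalize = true

[stats]
t_mode = "paired"
p_adjust = "none"
glm_direction = "coe_on_risk"

[synth]
n_participants = 1
n_segments = 1
scenarios_per_segment = 12
lead_in_m = 200.0
ego_speed_kmh = 70.0
fs = 10.0
n_channels = 8
activation = [0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.04, 0.12]
coupling_sign = 1

[synth.scenario_mix]
saeb = 3
lci = 3
rci = 3
rpcr = 3
other = 0
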