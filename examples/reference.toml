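# Reference run: the zero-IP6 (water) case.
# Every key is optional; an empty file gives exactly these values.

[model]
D0 = 0.01
T = 0.8
epsilon = 0.1
c = 0.0
L = 1.0

[numerics]
N = 200
t_end = 1.0
snapshot_times = [0.2, 0.4, 0.6, 0.8, 1.0]
dt_policy = "fixed"   # dt defaults to 0.1 / N^2

[initial]
base_value = 0.5
amplitude_fraction = 0.05
seed = 1

[metrics]
theta_void = 0.1
theta_solid = 0.9
min_cells = 4

[output]
directory = "runs/water"
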