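# Calibrated ion-channel-specific parameters of the gating cube
# (18 values: limiting rate A [1/s], midpoint Vhalf [mV], slope r [mV]
# for the opening and closing rate law of each of the three gates).
# Produced by navgate.calibration against the behavioral constraint set;
# see docs/methods.md for the targets and tolerances.
A_act_open: 6000.0
Vhalf_act_open: -30.0
r_act_open: 9.0
A_act_close: 3000.0
Vhalf_act_close: -55.0
r_act_close: 9.0
A_fast_open: 483.0
Vhalf_fast_open: -70.0
r_fast_open: 12.0
A_fast_close: 1200.0
Vhalf_fast_close: -65.0
r_fast_close: 8.0
A_slow_open: 296.0
Vhalf_slow_open: -230.0
r_slow_open: 28.8
A_slow_close: 0.38
Vhalf_slow_close: -55.0
r_slow_close: 8.0
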