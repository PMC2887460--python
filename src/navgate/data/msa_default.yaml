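# Default parameters of the multi-step-activation model, tuned to the
# same behavioral targets as the gating cube at qualitative level
# (fast recovery within the 10 ms hyperpolarizing gap, roughly half the
# population slow-inactivated after 10 s of depolarization, availability
# midpoints with fast inactivation left of slow).  See docs/methods.md.
A_sensor_fwd: 9000.0
Vhalf_sensor_fwd: -35.0
r_sensor_fwd: 30.0
A_sensor_bwd: 12000.0
Vhalf_sensor_bwd: -95.0
r_sensor_bwd: 30.0
open_rate: 8000.0
close_rate: 1200.0
kon_fast: 1.4
koff_fast: 900.0
a_fast: 3.4
kon_slow: 0.4
koff_slow: 11.0
a_slow: 1.5
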