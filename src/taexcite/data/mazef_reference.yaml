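# Reference dimensional parameter set of the mazEF-type TA module
# (seconds, molecules; a_T is per molecule after the volume-factor
# conversion from 1.32e5 /M/s at 0.6 um^3).  d_c here is the value
# consistent with the normalized delta_c = 1.96 (ln2 / 40 min); the
# rounded 0.00028 /s variant is available via mazef_parameters("printed").
parameter_type: ParameterSet
r_F: 0.121
d_m: 0.002
d_large: 0.198
K_t: 15.0
n: 2
b_1: 0.122
b_2: 0.009
a_T: 3.6544850498338867e-04
d_c: 2.8881132523331053e-04
d_a: 2.3104906018664843e-03
F: 0.1
D: 1.0
v_cell: 6.0e-19
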