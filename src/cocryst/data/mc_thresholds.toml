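# Default PASS windows for the molecular-complementarity screen.
#
# A descriptor PASSes when |descriptor(target) - descriptor(coformer)| is at
# most the window below.  These defaults are the package's own calibration of
# the published molecular-complementarity idea (similar shape and polarity
# favour cocrystallization); they are NOT a published threshold set and are
# meant to be overridden when a validated set is available.
#
# units: s_axis Å, dipole Debye, ratios and no_fraction dimensionless

[windows]
s_axis = 1.9
s_over_l = 0.17
m_over_l = 0.23
no_fraction = 0.17
dipole = 5.0
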