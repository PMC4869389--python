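# SYNTHETIC stroke-endpoint coefficients (same Weibull-AFT functional form
# as the coronary file).  These are NOT a published coefficient set: the
# endpoint-specific Framingham stroke table was unavailable, so this file is
# a calibrated stand-in producing epidemiologically plausible 10-year stroke
# risks (e.g. ~2% for a 50-year-old normotensive man, ~16% for a 60-year-old
# hypertensive male smoker), with stroke's stronger dependence on blood
# pressure, LVH and diabetes and weaker dependence on cholesterol.
# Results driven by this file do not reproduce any published risk score.
# version: 1
parameter,value
const_a,12.9800
ln_sbp,-1.1400
smoker,-0.2500
ln_tc_hdl,-0.3500
lvh,-0.8000
male_ln_age,-1.6500
male_diabetes,-0.3000
female_const,-6.8000
female_ln_age74_sq,1.7000
female_diabetes,-0.4500
mu_offset,4.4181
sigma_const,-0.3155
sigma_m,-0.2784
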