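# Weibull accelerated-failure-time coefficients for 10-year coronary
# (CHD/MI endpoint) risk, parametric Framingham model of Anderson,
# Cupples, Wilson & Kannel (1991).
# Model: p(t) = 1 - exp(-exp((ln t - mu) / sigma))
#   a      = const_a + ln_sbp*ln(SBP) + smoker*cig + ln_tc_hdl*ln(TC/HDL) + lvh*LVH
#   m_male = a + male_ln_age*ln(age) + male_diabetes*dia
#   m_fem  = a + female_const + female_ln_age74_sq*ln(age/74)^2 + female_diabetes*dia
#   mu     = mu_offset + m
#   sigma  = exp(sigma_const + sigma_m*m)
# version: 1
parameter,value
const_a,11.1122
ln_sbp,-0.9119
smoker,-0.2767
ln_tc_hdl,-0.7181
lvh,-0.5865
male_ln_age,-1.4792
male_diabetes,-0.1759
female_const,-5.8549
female_ln_age74_sq,1.8515
female_diabetes,-0.3758
mu_offset,4.4181
sigma_const,-0.3155
sigma_m,-0.2784
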