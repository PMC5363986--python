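# Canonical default parameter set for the Notch-Wnt crosstalk model.
# Units: nM and minutes; the Wnt stimulus W is dimensionless with
# W = 1 equivalent to 100 ng/ml.
# Produced by the package's calibration pipeline (see docs/methods.md):
# the decoupled Wnt steady state is pinned to B*(1) = 25 nM with
# hyperstimulation fold changes B*(2)/B*(1) = 2.2 and B*(2)/B*(0) = 8.3,
# and the decoupled Notch pair is fitted to a ~2 h Hes1 oscillation.
# Any subset of keys may be overridden in a user config.
alpha_N: 0.026054
alpha_D: 0.097703
alpha_P: 0.065135
alpha_H1: 1.424842
alpha_H2: 0.05
alpha_A: 0.4
alpha3: 0.231995
alpha4: 8.36493
mu_N: 0.065135
mu_D: 0.065135
mu_F: 0.065135
mu_I1: 0.065135
mu_H1: 0.065135
mu_H2: 0.03
mu_P: 0.065135
mu_B: 6.36e-06
mu_A: 0.2
k3: 0.15
k_CB: 0.0108797
k_cl: 0.065135
k_rev: 0.0495997
k_I2: 3.93185
kappa1: 0.35
kappa2: 5.0
kappa3: 0.5
kappa4: 0.1
kappa5: 6.5
kappa6: 5.0
kappa7: 25.0
kappa_psi: 1.3
kappa_GA: 3.01847
kappa_GW: 2.77168
kappa_A: 8.97449
c_GC: 0.5
m: 3.0
n: 3.0
theta2: 0.75
rho_apc: 1.0
b_ref: 25.0
gsk_total: 50.0
gsk_open: false
mu_G: 0.0
mu_C: 0.0
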