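# Default synthetic-cohort profile for `astigvec simulate --config`.
# Every key is a SimulationParams field; omitted keys keep the library
# defaults (which are identical to the values below).

n: 207            # eyes
seed: 0

# Age (years): truncated normal
age_mean: 68.25
age_sd: 11.33
age_range: [40.0, 95.0]

# Corneal irregularity index (mm): ln(IR) = a + b*age + N(0, sd)
# calibrated so the marginal is ~0.042 +/- 0.019 mm at the default ages
ir_log_intercept: -4.335
ir_log_age_slope: 0.0157
ir_log_noise_sd: 0.393
ir_min: 0.005

# Against-the-rule probability: logistic in age (ATR eyes older on average)
atr_logistic_intercept: -4.70
atr_logistic_age_slope: 0.0623
axis_jitter_sd: 10.0        # degrees around the class-typical flat meridian

# Automated-keratometry cylinder (D): truncated lognormal
ak_magnitude_log_mu: -0.20
ak_magnitude_log_sigma: 0.63
ak_magnitude_range: [0.1, 6.0]

# TCRP3-vs-AK discrepancy magnitude (D):
# ln(delta) = intercept + age_coef*age + ir_coef*IR + ak_coef*AK + N(0, sd)
delta_intercept: -1.867
delta_age_coef: 0.007
delta_ir_coef: 1.613
delta_ak_coef: 0.201
delta_noise_sd: 0.726
tcrp4_damping: 0.9          # TCRP4 discrepancy = 0.9 * TCRP3 discrepancy

# Refraction residual noise per (J0, J45) component:
# SD = ora_noise_sd * (1 + ir_scale * IR)
ora_noise_sd: 0.15
ir_scale: 5.0
sia_true: {magnitude: 0.40, incision_axis: 0.0}
vertex_distance: 0.012      # metres

# Postoperative corneal-plane spherical equivalent (D)
se_mean: -0.25
se_sd: 0.40

# Total corneal irregular astigmatism (um) = a + b*IR + N(0, sd)
irregular_astig_intercept: 0.0
irregular_astig_ir_slope: 10.0
irregular_astig_noise_sd: 0.15

# Corneal spherical aberration (um)
sa_wtr_mean: 0.326
sa_atr_mean: 0.407
sa_sd: 0.20

# Corneal radii (mm); anterior/posterior ratio decreases with IR
ant_radius_mean: 7.80
ant_radius_sd: 0.25
ap_ratio_intercept: 1.22
ap_ratio_ir_slope: -1.0
ap_ratio_noise_sd: 0.02
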