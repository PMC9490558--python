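"""Embedded pediatric PAH cohort: demographics, MRI and catheterization
metrics for the eight subjects, the clinical severity ranking, and the
reported severity-correlation table.

Values are stored exactly as printed in the clinical summary (flows in
L/min, volumes ml, masses g, pressures mmHg, PVRi in WU*m^2, EF and
saturations in %, cycle lengths s).  ``None`` marks cells reported as N/A.
"""

SUBJECT_IDS = [1, 2, 3, 4, 5, 6, 7, 8]

DEMOGRAPHICS = {
    "age_years": [11, 15, 10, 5, 16, 11, 19, 6],
    "sex": ["F", "F", "M", "F", "F", "M", "F", "F"],
    "bsa_m2": [1.23, 1.66, 0.95, 0.74, 1.44, 1.25, 1.61, 0.88],
    "height_cm": [154, 175, 123, 106.7, 152, 152, 165, 121.9],
    "weight_kg": [33.2, 56.3, 26.9, 18.7, 49.8, 35.2, 56.2, 23],
    "who_fc": ["II", "I", "II", "I", "I", "II", "I", "I"],
    "n_pah_medications": [3, 2, 3, 2, 2, 3, 2, 3],
    "years_since_diagnosis": [5, 5, 4, 1, 10, 10, 6, 2],
}

MRI_METRICS = {
    "aorta_flow_lmin": [4.24, 4.38, 3.74, 2.41, 5.37, 4.79, 4.90, 3.16],
    "mpa_flow_lmin": [4.80, 4.89, 3.23, 2.39, 5.34, 3.50, 4.40, 2.95],
    "averaged_co_lmin": [4.52, 4.63, 3.49, 2.40, 5.36, 4.15, 4.65, 3.06],
    "cardiac_index_lmin_m2": [3.7, 2.8, 3.7, 3.2, 3.7, 3.3, 2.9, 3.5],
    "pct_flow_lpa": [45, 37, 51, 40, 47, 51, 41, 49],
    "pulm_regurgitant_factor_pct": [1, 1, None, 1, 1, 2, 8, 0],
    "heart_rate_bpm": [91, 77, 79, 66, 83, 74, 70, 73],
    "cycle_length_s": [0.662, 0.780, 0.756, 0.905, 0.725, 0.815, 0.856, 0.825],
    "rv_edv_ml": [120, 141, 84, 78, 114, 123, 241, 90],
    "rv_esv_ml": [60, 67, 33, 39, 44, 60, 145, 39],
    "rv_sv_ml": [60, 74, 51, 39, 71, 63, 96, 51],
    "rv_edvi_ml_m2": [98, 85, 88, 105, 79, 98, 150, 102],
    "rv_esvi_ml_m2": [49, 40, 35, 53, 31, 48, 90, 44],
    "rv_svi_ml_m2": [49, 45, 54, 53, 49, 50, 60, 58],
    "rv_ef_pct": [50, 52, 61, 49, 62, 51, 40, 57],
    "rv_mass_g": [30, 36, 23, 16, 35, 21, 72, 13],
    "rv_mass_index_g_m2": [24, 22, 24, 22, 24, 17, 45, 14],
    "mpa_sv_ml": [56, 63, 41, 37, 69, 48, 65, 41],
    "lv_edv_ml": [103, 124, 82, 68, 112, 139, 163, 72],
    "lv_esv_ml": [41, 55, 30, 30, 41, 60, 72, 30],
    "lv_sv_ml": [62, 69, 51, 37, 71, 79, 91, 42],
    "lv_edvi_ml_m2": [84, 75, 86, 92, 78, 111, 101, 82],
    "lv_esvi_ml_m2": [33, 33, 32, 41, 28, 48, 45, 34],
    "lv_svi_ml_m2": [50, 42, 54, 50, 49, 63, 57, 48],
    "lv_ef_pct": [60, 55, 63, 55, 63, 57, 56, 58],
    "lv_mass_g": [55, 72, 43, 31, 59, 53, 92, 31],
    "lv_mass_index_g_m2": [45, 43, 45, 42, 41, 42, 57, 35],
    "aao_sv_ml": [53, 60, 51, 39, 73, 67, 78, 44],
    "sedation": ["N", "N", "N", "Y", "N", "Y", "N", "N"],
}

CATH_METRICS = {
    "mpap_mmhg": [59.4, 29.2, 35.1, 82.9, 47.1, 31.2, 58.3, 20.4],
    "pa_pulse_mmhg": [30.6, 18.0, 35.4, 66.2, 36.9, 26.6, 48.0, 24.1],
    "pa_systolic_mmhg": [74.7, 38.2, 52.9, 116.0, 65.5, 44.5, 82.3, 32.5],
    "pvri_wu_m2": [16.2, 7.3, 5.9, 23.2, 9.9, 4.9, 16.0, 3.3],
    "rp_rs": [0.8, 0.4, 0.32, 0.77, 0.55, 0.33, 0.8, 0.2],
    "pcwp_mmhg": [10, 8, 15, 14, 12, 14, 12, 8],
    "cath_heart_rate_bpm": [69, 65, 78, 66, 72, 65, 66, 86],
    "cath_cycle_length_s": [0.870, 0.918, 0.770, 0.909, 0.830, 0.920, 0.905, 0.695],
    "pa_o2_sat_pct": [80, 72, 64, 60, 73, 64, 70, 73],
}

# Clinical disease-severity ranking: 1 = lowest severity, 8 = highest.
SEVERITY_RANK = {8: 1, 2: 2, 3: 3, 6: 4, 5: 5, 4: 6, 1: 7, 7: 8}

# Reported severity-correlation table: metric -> (rho, p-value, BH critical
# value iQ/m).  p-values printed as "<0.001" are stored as 0.001.
REPORTED_CORRELATIONS = {
    "RPA Stiffness": (0.929, 0.001, 0.002),
    "R_pulmonary/R_systemic": (0.929, 0.001, 0.003),
    "RV Stroke Work/LV Stroke Work": (0.905, 0.002, 0.005),
    "RV Contractility (Tref,RV)": (0.905, 0.002, 0.007),
    "MPA Systolic Pressure": (0.905, 0.002, 0.009),
    "RV Stroke Work": (0.881, 0.004, 0.010),
    "MPA Mean Pressure": (0.881, 0.004, 0.012),
    "RV Systolic Pressure/LV Systolic Pressure": (0.857, 0.007, 0.014),
    "MPA Diastolic Pressure": (0.833, 0.010, 0.015),
    "MPA-RPA Pulse Wave Velocity": (0.833, 0.010, 0.018),
    "LV Contractility (Tref,LV)": (-0.810, 0.015, 0.019),
    "Total Pulmonary Arterial Resistance": (0.810, 0.015, 0.021),
    "PVR Index": (0.810, 0.015, 0.023),
    "MPA Stiffness": (0.762, 0.028, 0.025),
    "MPA Pulse Pressure": (0.738, 0.037, 0.026),
    "Pulmonary Arterial Compliance Index": (0.738, 0.037, 0.028),
    "RV Mass Index": (0.738, 0.037, 0.030),
    "RV Ejection Fraction": (-0.667, 0.071, 0.032),
    "MPA-LPA Pulse Wave Velocity": (0.643, 0.086, 0.033),
    "MPA Area Index": (0.643, 0.086, 0.035),
    "RV End-Systolic Volume Index": (0.643, 0.086, 0.037),
    "Systemic Arterial Diastolic Pressure": (0.619, 0.102, 0.039),
    "Total Pulmonary Arterial Compliance": (-0.595, 0.120, 0.040),
    "LPA Stiffness": (0.595, 0.120, 0.042),
    "RV ESPVR": (0.571, 0.139, 0.044),
    "LV Stroke Volume Index": (0.524, 0.183, 0.046),
    "LV Mass Index": (0.476, 0.233, 0.047),
    "LV End-Diastolic Volume Index": (0.476, 0.233, 0.049),
    "MPA Relative Area Change": (-0.476, 0.233, 0.051),
    "Central Pulmonary Arterial Resistance": (-0.429, 0.289, 0.053),
    "RV Ea": (0.429, 0.289, 0.054),
    "LV Emax": (-0.405, 0.320, 0.056),
    "Systemic Arterial Mean Pressure": (0.381, 0.352, 0.058),
    "RV End-Diastolic Volume Index": (0.381, 0.352, 0.060),
    "Systemic Arterial Systolic Pressure": (0.333, 0.420, 0.061),
    "Age": (0.333, 0.420, 0.063),
    "Pulmonary Capillary Wedge Pressure": (0.286, 0.493, 0.065),
    "LV End-Systolic Volume Index": (0.286, 0.493, 0.067),
    "Percentage Flow to LPA": (-0.286, 0.493, 0.068),
    "Catheterization Heart Rate": (0.238, 0.570, 0.070),
    "LV Passive Stiffness (C_LV)": (-0.214, 0.610, 0.072),
    "Height": (0.214, 0.610, 0.074),
    "RV Emax": (-0.143, 0.736, 0.075),
    "RV Passive Stiffness (C_RV)": (-0.143, 0.736, 0.077),
    "RV ESPVR/Ea": (-0.119, 0.779, 0.079),
    "DTA Stiffness": (0.119, 0.779, 0.081),
    "Weight": (0.119, 0.779, 0.082),
    "BSA": (0.119, 0.779, 0.084),
    "AAo-DTA Pulse Wave Velocity": (0.095, 0.823, 0.086),
    "RV SV Index": (0.095, 0.823, 0.088),
    "Central Pulmonary Arterial Compliance": (0.071, 0.867, 0.089),
    "MPA Oxygen Saturation": (-0.071, 0.867, 0.091),
    "AAo Stiffness": (-0.048, 0.911, 0.093),
    "MRI Heart Rate": (-0.048, 0.911, 0.095),
    "Cardiac Index": (0.048, 0.911, 0.096),
    "Systemic Arterial Pulse Pressure": (0.024, 0.955, 0.098),
    "LV Ejection Fraction": (0.000, 1.000, 0.010),
}

N_METRICS_TOTAL = 57  # 36 data-derived + 21 model-derived metrics
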