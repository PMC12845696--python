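"""Published worked-example tables from the lumbar-IMU fatigued-running study.

These are the printed summary tables of the 19-runner study whose analysis
pipeline this package reimplements (the underlying raw recordings are
available on request only and are not shipped here).  They serve as inputs
for desk-scale worked examples: effect-size formulas applied to the printed
mixed-model statistics, aggregation conventions applied to the printed
per-participant metric columns, and variability deltas applied to the
printed trajectory summaries.
"""

from __future__ import annotations

#: total number of strides in the study's feature matrix (2926 NF + 3080 F)
TOTAL_STRIDES = 6006
N_NF_STRIDES = 2926
N_F_STRIDES = 3080

#: mixed-effects fatigue fixed effects for the four headline features:
#: feature -> (coefficient, standard error, Wald z)
MIXED_MODEL_EFFECTS: dict[str, tuple[float, float, float]] = {
    "acc_mag_kurt": (1.430, 0.036, 39.618),
    "acc_z_mean": (-0.842, 0.016, -52.000),
    "acc_y_max": (6.869, 0.204, 33.637),
    "gyro_y_rms": (8.358, 0.292, 28.636),
}

#: published standardized effect sizes: feature -> (Cohen's d, partial R^2)
PUBLISHED_EFFECT_SIZES: dict[str, tuple[float, float]] = {
    "acc_mag_kurt": (1.03, 0.207),
    "acc_z_mean": (1.35, 0.310),
    "acc_y_max": (0.87, 0.158),
    "gyro_y_rms": (0.74, 0.120),
}

#: published residual SD backing the acc_z_mean Cohen's d (|-0.842| / 0.6237 ~ 1.35)
ACC_Z_MEAN_RESIDUAL_SD = 0.6237

#: global LOPO accuracies, one per held-out runner
LOPO_ACCURACIES = [
    0.4781, 0.5051, 0.7296, 0.5597, 0.3772, 0.5012, 0.4801, 0.4375, 0.5064, 0.3462,
    0.4846, 0.5479, 0.5967, 0.8881, 0.4219, 0.4238, 0.6188, 0.6335, 0.8900,
]

#: per-participant supervised personalized RF results:
#: id -> (n_strides, n_f, n_nf, cv_accuracy, cv_f1, cv_auc)
PERSONAL_SUPERVISED_RF: dict[int, tuple[int, int, int, float, float, float]] = {
    4: (251, 130, 121, 0.964000, 0.966864, 0.997115),
    5: (198, 98, 100, 0.994872, 0.994872, 1.000000),
    6: (318, 164, 154, 0.981101, 0.981814, 0.998506),
    7: (159, 75, 84, 0.968347, 0.966422, 0.997598),
    8: (403, 201, 202, 0.997531, 0.997468, 1.000000),
    9: (407, 221, 186, 0.995092, 0.995506, 0.999754),
    10: (327, 177, 150, 0.996970, 0.997260, 1.000000),
    11: (368, 207, 161, 0.970233, 0.973141, 0.995534),
    12: (235, 118, 117, 0.987234, 0.987219, 0.998551),
    13: (156, 100, 56, 0.929234, 0.944859, 0.984773),
    14: (421, 222, 199, 0.964342, 0.965771, 0.995683),
    15: (261, 124, 137, 0.950218, 0.946664, 0.994324),
    17: (419, 211, 208, 0.988038, 0.988233, 0.998910),
    18: (268, 104, 164, 0.973725, 0.965086, 0.996228),
    19: (320, 189, 131, 0.993750, 0.994805, 0.999595),
    20: (420, 209, 211, 0.988095, 0.987834, 0.999320),
    21: (362, 176, 186, 0.953044, 0.951615, 0.993748),
    22: (322, 169, 153, 0.959712, 0.960859, 0.997457),
    23: (391, 185, 206, 1.000000, 1.000000, 1.000000),
}

#: per-participant NF-only One-Class SVM results:
#: id -> (n_strides, n_f, n_nf, accuracy, f1, auc)
PERSONAL_OCSVM: dict[int, tuple[int, int, int, float, float, float]] = {
    4: (251, 130, 121, 0.756972, 0.738197, 0.839987),
    5: (198, 98, 100, 0.949495, 0.951456, 1.000000),
    6: (318, 164, 154, 0.937107, 0.941520, 0.991448),
    7: (159, 75, 84, 0.905660, 0.909091, 1.000000),
    8: (403, 201, 202, 0.967742, 0.968675, 1.000000),
    9: (407, 221, 186, 0.953317, 0.958242, 0.996935),
    10: (327, 177, 150, 0.905199, 0.911681, 0.971337),
    11: (368, 207, 161, 0.907609, 0.915423, 0.965553),
    12: (235, 118, 117, 0.936170, 0.939271, 0.995219),
    13: (156, 100, 56, 0.878205, 0.905473, 0.949286),
    14: (421, 222, 199, 0.786223, 0.764398, 0.875617),
    15: (261, 124, 137, 0.773946, 0.746781, 0.869790),
    17: (419, 211, 208, 0.957041, 0.958140, 0.993894),
    18: (268, 104, 164, 0.951493, 0.941176, 1.000000),
    19: (320, 189, 131, 0.953125, 0.961832, 1.000000),
    20: (420, 209, 211, 0.959524, 0.960920, 1.000000),
    21: (362, 176, 186, 0.906077, 0.903409, 0.972996),
    22: (322, 169, 153, 0.869565, 0.873494, 0.950536),
    23: (391, 185, 206, 0.961637, 0.961039, 1.000000),
}

#: participant-4 stride-to-stride variability worked example:
#: (feature, state) -> (n_strides, cv, trajectory sampen), 4-decimal precision
VARIABILITY_P4: dict[tuple[str, str], tuple[int, float, float]] = {
    ("acc_mag_rms", "F"): (130, 0.0383, 2.5923),
    ("acc_mag_rms", "NF"): (121, 0.0340, 1.9291),
    ("gyro_mag_rms", "F"): (130, 0.0917, 1.4974),
    ("gyro_mag_rms", "NF"): (121, 0.0820, 1.5839),
}

#: participant-4 published F-minus-NF deltas: feature -> (delta_cv, delta_sampen)
VARIABILITY_P4_DELTAS: dict[str, tuple[float, float]] = {
    "acc_mag_rms": (0.0043, 0.6632),
    "gyro_mag_rms": (0.0097, -0.0865),
}
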