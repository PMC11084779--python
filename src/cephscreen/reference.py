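"""Reference cohort statistics for the screening workflow.

These constants describe the 100-patient orthognathic-surgery reference cohort
(non-obese, non-OSAS adults imaged supine) whose summary statistics drive the
synthetic-cohort generator defaults and the worked examples: per-parameter
means and standard deviations, the correlation of every parameter with the
three-dimensional targets A_min and V_PAS, the selected stepwise regression
models, and the ROC screening table (AUC, Youden cut-off, and the two
referral thresholds for three-dimensional imaging).

Units: distances mm, areas mm^2, volumes cm^3, angles degrees, body height cm,
body weight kg, age years. Ratios are dimensionless.

Three entries in the published cohort column are internally inconsistent with
the group-level summaries and are corrected here (each noted inline): the
pooled A_SPAS mean, a DI4/DI6 swap, and a x100 scale slip on S-Go/N-Me.
"""

from __future__ import annotations

COHORT_N = 100

#: Operational thresholds defining the screening outcomes.
SASN_AMIN_CUT = 80.0   # mm^2; superior airway space narrowing: A_min < 80
RSAV_VPAS_CUT = 12.0   # cm^3; reduced airway volume: V_PAS < 12

#: Observed outcome prevalences in the reference cohort (30/100 and 32/100).
SASN_PREVALENCE = 0.30
RSAV_PREVALENCE = 0.32

#: Fraction of female patients (53/100).
FEMALE_FRACTION = 0.53

#: Cohort mean and SD per parameter ("all patients" column).
PARAMETER_STATS: dict[str, tuple[float, float]] = {
    # three-dimensional airway parameters
    "A_min": (143.0, 90.2),
    "V_PAS": (17.2, 8.0),
    "A_Sag": (795.7, 244.9),
    "A_IAS": (242.7, 153.6),
    "A_MAS": (201.4, 137.3),
    # pooled from the group columns (0.3*163.0 + 0.7*283.2); the printed
    # cohort value 337.9 exceeds both group means and cannot be a pooled mean
    "A_SPAS": (247.1, 106.5),
    # two-dimensional airway parameters
    "SPAS": (12.9, 3.7),
    "MPAS": (10.9, 3.6),
    "IPAS": (13.3, 5.3),
    # cranial base
    "S-N": (75.3, 5.1),
    "NSAr": (123.5, 5.5),
    # sagittal dimensions
    "SNA": (80.5, 4.6),
    "SNB": (77.9, 5.8),
    "ANB": (2.6, 5.0),
    "Ans-Pns": (56.4, 5.0),
    "GoGn": (85.0, 7.8),
    # vertical dimensions
    "SP-SN": (8.1, 3.6),
    "MP-SN": (35.8, 7.6),
    "SP-MP": (27.7, 7.4),
    "SArGo": (145.4, 8.3),
    "ArGoMe": (127.0, 8.9),
    "Sum": (395.8, 7.6),
    "NSGn": (69.5, 5.4),
    # face heights
    "S-Go": (86.0, 8.9),
    "N-Me": (132.1, 11.9),
    "N-Ans": (56.4, 4.4),
    "Ans-Me": (74.1, 9.0),
    "S-Go/N-Me": (0.653, 0.055),   # printed 65.3 +/- 5.5 is a x100 scale slip
    "Ans-Me/N-Ans": (1.32, 0.15),
    # hyoid position
    "MP-Hy": (12.9, 6.8),
    # dental relations
    "OJ": (1.9, 5.8),
    "OB": (0.2, 3.1),
    # transversal dimensions (DI4/DI6 cohort values are swapped in the source
    # table relative to both group columns; corrected here)
    "DI4": (36.3, 2.4),
    "DI6": (47.6, 3.6),
    "DMA": (104.8, 8.7),
    "DCH": (115.7, 7.3),
    # soft palate
    "SPL": (36.9, 4.9),
    "SPT": (7.6, 2.2),
    # demographics; BH/BW SDs are not published, values chosen as typical
    # adult dispersion
    "age": (27.2, 8.9),
    "BH": (174.0, 9.0),
    "BW": (76.4, 13.0),
}

#: Pearson correlation of each parameter with A_min in the reference cohort.
AMIN_CORRELATIONS: dict[str, float] = {
    "age": -0.169, "BH": 0.015, "BW": 0.018, "BMI": -0.088,
    "V_PAS": 0.857, "A_Sag": 0.708, "A_SPAS": 0.812, "A_MAS": 0.888,
    "A_IAS": 0.835,
    "SPAS": 0.706, "MPAS": 0.713, "IPAS": 0.684,
    "S-N": 0.208, "NSAr": -0.094,
    "SNA": 0.148, "SNB": 0.211, "ANB": -0.109, "Ans-Pns": 0.110,
    "GoGn": 0.384,
    "SP-SN": -0.018, "MP-SN": -0.109, "SP-MP": -0.104, "SArGo": 0.019,
    "ArGoMe": -0.043, "Sum": -0.110, "NSGn": -0.218,
    "S-Go": 0.121, "N-Me": 0.121, "N-Ans": 0.141, "Ans-Me": 0.129,
    "S-Go/N-Me": 0.014, "Ans-Me/N-Ans": 0.036,
    "MP-Hy": -0.052, "OJ": -0.154, "OB": 0.151,
    "DI4": -0.030, "DI6": 0.048, "DMA": 0.074, "DCH": 0.014,
    "SPL": -0.123, "SPT": -0.093,
}

#: Pearson correlation of each parameter with V_PAS in the reference cohort.
VPAS_CORRELATIONS: dict[str, float] = {
    "age": -0.005, "BH": 0.282, "BW": 0.187, "BMI": 0.063,
    "A_min": 0.857, "A_Sag": 0.873, "A_SPAS": 0.736, "A_MAS": 0.835,
    "A_IAS": 0.890,
    "SPAS": 0.611, "MPAS": 0.662, "IPAS": 0.752,
    "S-N": 0.303, "NSAr": -0.118,
    "SNA": 0.083, "SNB": 0.183, "ANB": -0.136, "Ans-Pns": 0.229,
    "GoGn": 0.426,
    "SP-SN": -0.020, "MP-SN": -0.018, "SP-MP": -0.008, "SArGo": 0.019,
    "ArGoMe": 0.053, "Sum": -0.018, "NSGn": -0.113,
    "S-Go": 0.296, "N-Me": 0.332, "N-Ans": 0.309, "Ans-Me": 0.310,
    "S-Go/N-Me": 0.007, "Ans-Me/N-Ans": 0.115,
    "MP-Hy": 0.178, "OJ": -0.184, "OB": 0.210,
    "DI4": 0.080, "DI6": 0.179, "DMA": 0.223, "DCH": 0.287,
    "SPL": 0.015, "SPT": 0.035,
}

#: Stepwise regression models selected in the reference cohort:
#: response -> {predictor: raw coefficient B}, with "const" the intercept.
REGRESSION_MODELS: dict[str, dict[str, float]] = {
    "A_min": {"const": -91.215, "SPAS": 8.126, "MPAS": 6.636, "IPAS": 4.290},
    "V_PAS": {"const": -29.904, "IPAS": 1.117, "BH": 0.185},
}

#: Reference ROC screening table. sens/spec are fractions; balanced accuracies
#: are percent; lower/upper are the referral-zone thresholds for 3D imaging.
#: Fields: outcome, predictor, auc, ci, cutoff, sens, spec, balanced_accuracy,
#: lower, upper, triage_balanced_accuracy.
ROC_REFERENCE: list[dict] = [
    {"outcome": "SASN", "predictor": "MLRM", "auc": 0.903,
     "ci": (0.841, 0.966), "cutoff": 100.0, "sens": 0.733, "spec": 0.914,
     "balanced_accuracy": 82.3, "lower": 100.0, "upper": 133.0,
     "triage_balanced_accuracy": 90.7},
    {"outcome": "SASN", "predictor": "SPAS", "auc": 0.875,
     "ci": (0.795, 0.955), "cutoff": 11.8, "sens": 0.833, "spec": 0.829,
     "balanced_accuracy": 83.1, "lower": 10.4, "upper": 12.5,
     "triage_balanced_accuracy": 90.7},
    {"outcome": "SASN", "predictor": "MPAS", "auc": 0.867,
     "ci": (0.791, 0.943), "cutoff": 8.8, "sens": 0.733, "spec": 0.871,
     "balanced_accuracy": 80.2, "lower": 8.1, "upper": 10.2,
     "triage_balanced_accuracy": 90.0},
    {"outcome": "SASN", "predictor": "IPAS", "auc": 0.858,
     "ci": (0.779, 0.937), "cutoff": 10.9, "sens": 0.733, "spec": 0.843,
     "balanced_accuracy": 78.8, "lower": 9.4, "upper": 13.5,
     "triage_balanced_accuracy": 90.0},
    {"outcome": "SASN", "predictor": "GoGn", "auc": 0.627,
     "ci": (0.510, 0.744), "cutoff": 90.2, "sens": 0.900, "spec": 0.357,
     "balanced_accuracy": 62.9, "lower": 77.0, "upper": 90.2,
     "triage_balanced_accuracy": 90.0},
    {"outcome": "RSAV", "predictor": "MLRM", "auc": 0.881,
     "ci": (0.817, 0.947), "cutoff": 16.40, "sens": 0.938, "spec": 0.691,
     "balanced_accuracy": 81.5, "lower": 13.00, "upper": 16.4,
     "triage_balanced_accuracy": 91.9},
    {"outcome": "RSAV", "predictor": "IPAS", "auc": 0.843,
     "ci": (0.767, 0.920), "cutoff": 14.0, "sens": 0.969, "spec": 0.544,
     "balanced_accuracy": 75.7, "lower": 9.6, "upper": 14.0,
     "triage_balanced_accuracy": 93.5},
    {"outcome": "RSAV", "predictor": "BH", "auc": 0.683,
     "ci": (0.578, 0.788), "cutoff": 179.0, "sens": 0.938, "spec": 0.441,
     "balanced_accuracy": 68.9, "lower": 160.0, "upper": 179.5,
     "triage_balanced_accuracy": 92.5},
    {"outcome": "RSAV", "predictor": "SPAS", "auc": 0.814,
     "ci": (0.726, 0.902), "cutoff": 12.4, "sens": 0.844, "spec": 0.720,
     "balanced_accuracy": 78.2, "lower": 10.0, "upper": 14.2,
     "triage_balanced_accuracy": 90.9},
    {"outcome": "RSAV", "predictor": "MPAS", "auc": 0.804,
     "ci": (0.708, 0.900), "cutoff": 9.2, "sens": 0.750, "spec": 0.794,
     "balanced_accuracy": 77.2, "lower": 8.1, "upper": 13.2,
     "triage_balanced_accuracy": 90.9},
    {"outcome": "RSAV", "predictor": "GoGn", "auc": 0.683,
     "ci": (0.578, 0.787), "cutoff": 88.8, "sens": 0.969, "spec": 0.485,
     "balanced_accuracy": 72.7, "lower": 74.4, "upper": 88.8,
     "triage_balanced_accuracy": 93.5},
]

#: Parameters that are exact functions of other parameters; the synthetic
#: generator derives them instead of drawing them.
DERIVED_PARAMETERS = ("ANB", "Sum", "S-Go/N-Me", "Ans-Me/N-Ans", "BMI")

#: The 38 cephalometric/airway parameters measured per patient.
ALL_PARAMETERS = tuple(
    k for k in PARAMETER_STATS if k not in ("age", "BH", "BW")
)

#: Three-dimensional airway parameters (not visible on a lateral X-ray).
THREE_D_PARAMETERS = ("A_min", "V_PAS", "A_Sag", "A_IAS", "A_MAS", "A_SPAS")

#: Transversal distances need frontal/axial views, not a lateral X-ray.
TRANSVERSAL_PARAMETERS = ("DI4", "DI6", "DMA", "DCH")

#: Default stepwise candidate set: everything a clinician can read off a
#: lateral cephalometric X-ray, plus demographics.
LATERAL_2D_CANDIDATES = tuple(
    p for p in ALL_PARAMETERS
    if p not in THREE_D_PARAMETERS and p not in TRANSVERSAL_PARAMETERS
) + ("age", "BH", "BW", "BMI", "gender_female")
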