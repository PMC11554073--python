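"""Clinical-table schema: the 28 predictor parameters and the KPS endpoint.

The cohort table has one row per patient. Twenty-eight logical predictors are
recorded alongside the endpoint (6-month postoperative KPS, 10-point grid);
the binary classification target is ``postop_kps_6mo < 70`` (1 = the patient
cannot live independently at 6 months).
"""

from __future__ import annotations

# Binary yes/no (or two-level) parameters, stored as 0/1 integers.
BINARY_PARAMS: tuple[str, ...] = (
    "sex_female",
    "dominant_hand_right",
    "epilepsy",
    "aphasia",
    "paralysis",
    "other_neuro",
    "surgery_biopsy",
    "awake_surgery",
    "five_ala",
    "pdt",
    "carmustine",
    "mep_sep",
    "mgmt_methylation",
    "tertp",
    "mgmt_ihc",
    "tmz",
    "bevacizumab",
    "ependymal_invasion",
    "midline_shift",
    "corpus_callosum_invasion",
    "necrosis_cyst",
)

# Continuous / count-valued parameters.
CONTINUOUS_PARAMS: tuple[str, ...] = (
    "age",
    "preop_kps",
    "mib1_index",
    "radiation_dose",
    "radiation_fractions",
)

LATERALITY_LEVELS: tuple[str, ...] = ("right", "left", "bilateral")

EXTENT_LEVELS: tuple[str, ...] = ("1-49%", "50-89%", "90-99%", "100%")

# The 28 logical clinical parameters, in table column order.
CLINICAL_PARAMS: tuple[str, ...] = (
    BINARY_PARAMS[:6]
    + ("preop_kps",)
    + BINARY_PARAMS[6:12]
    + BINARY_PARAMS[12:15]
    + ("age", "mib1_index", "radiation_dose", "radiation_fractions")
    + BINARY_PARAMS[15:17]
    + ("laterality",)
    + BINARY_PARAMS[17:21]
    + ("extent_of_resection",)
)

ENDPOINT = "postop_kps_6mo"
LABEL = "kps_lt_70"  # derived: postop_kps_6mo < 70

# Non-predictor bookkeeping columns.
META_COLUMNS: tuple[str, ...] = ("patient_id", "operation_date")

KPS_GRID: tuple[int, ...] = tuple(range(0, 101, 10))

assert len(CLINICAL_PARAMS) == 28, "schema must enumerate exactly 28 predictors"


def all_columns() -> list[str]:
    """Full clinical CSV column inventory, in canonical order."""
    return list(META_COLUMNS) + list(CLINICAL_PARAMS) + [ENDPOINT]
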