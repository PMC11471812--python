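"""Default data dictionary: 20 categorical + 24 metric columns.

The agreed spreadsheet format of the bicentric adrenal-metastasis cohort is
not published column by column; this dictionary is a *reconstruction* from
the printed patient-characteristic, therapy-detail and outcome tables, padded
with generic clinical covariates to reach the reported 20 categorical
classifiers and 24 metrical floating-point variables.  Column names and
category codes are therefore illustrative, versioned, and replaceable by any
study-specific dictionary with the same JSON/YAML schema.
"""

from __future__ import annotations

from .table import CATEGORICAL, METRIC, ColumnSpec, DataDictionary

DICTIONARY_VERSION = "reconstruction-1"

_YN = ("0", "1")

_CATEGORICAL: list[ColumnSpec] = [
    ColumnSpec("gender", CATEGORICAL, ("male", "female")),
    ColumnSpec("ecog_status", CATEGORICAL, ("0", "1", "2")),
    ColumnSpec("laterality", CATEGORICAL, ("left", "right", "bilateral")),
    ColumnSpec("timing_metastases", CATEGORICAL,
               ("metachronous", "oligoprogressive", "synchronous", "other")),
    ColumnSpec("metastatic_pattern", CATEGORICAL,
               ("solitary", "oligo", "multiple", "na")),
    ColumnSpec("chemotherapy_timing", CATEGORICAL,
               ("none", "before", "concurrent", "after", "before_and_after")),
    ColumnSpec("immunotherapy_timing", CATEGORICAL,
               ("none", "before", "concurrent", "after", "before_and_after")),
    ColumnSpec("primary_site", CATEGORICAL,
               ("lung", "skin", "liver", "colorectal", "kidney", "other")),
    ColumnSpec("fractionation_group", CATEGORICAL, ("3fx", "5fx")),
    ColumnSpec("motion_management", CATEGORICAL, ("dibh", "debh", "free")),
    ColumnSpec("toxicity_type", CATEGORICAL,
               ("none", "fatigue", "gastrointestinal", "anorexia", "not_reported")),
    ColumnSpec("toxicity_grade", CATEGORICAL, ("0", "1", "2")),
    ColumnSpec("local_control", CATEGORICAL, ("cr", "pr", "sd", "pd", "na")),
    ColumnSpec("event_death", CATEGORICAL, _YN),
    ColumnSpec("complete_remission", CATEGORICAL, _YN),
    ColumnSpec("bed_group", CATEGORICAL, ("lt80", "ge80")),
    ColumnSpec("chemotherapy_any", CATEGORICAL, _YN),
    ColumnSpec("immunotherapy_any", CATEGORICAL, _YN),
    ColumnSpec("adapted_any", CATEGORICAL, _YN),
    ColumnSpec("primary_controlled", CATEGORICAL, _YN),
]

_METRIC: list[ColumnSpec] = [
    ColumnSpec("age", METRIC, unit="years", min_value=0.0),
    ColumnSpec("follow_up", METRIC, unit="months", min_value=0.0),
    ColumnSpec("gtv_cm3", METRIC, unit="cm^3", min_value=0.0),
    ColumnSpec("ptv_cm3", METRIC, unit="cm^3", min_value=0.0),
    ColumnSpec("ptv_margin_mm", METRIC, unit="mm", min_value=0.0),
    ColumnSpec("n_fractions", METRIC, unit="fractions", min_value=1.0),
    ColumnSpec("prescription_dose_gy", METRIC, unit="Gy", min_value=0.0),
    ColumnSpec("dose_per_fraction_gy", METRIC, unit="Gy", min_value=0.0),
    ColumnSpec("bed10_gy", METRIC, unit="Gy", min_value=0.0),
    ColumnSpec("ptvopt_dmax_gy", METRIC, unit="Gy", min_value=0.0),
    ColumnSpec("conformity_index", METRIC, unit="", min_value=0.0),
    ColumnSpec("homogeneity_index", METRIC, unit="", min_value=0.0),
    ColumnSpec("adapted_fractions_n", METRIC, unit="fractions", min_value=0.0),
    ColumnSpec("adapted_fraction_ratio", METRIC, unit="", min_value=0.0),
    ColumnSpec("height_cm", METRIC, unit="cm", min_value=0.0),
    ColumnSpec("weight_kg", METRIC, unit="kg", min_value=0.0),
    ColumnSpec("bmi", METRIC, unit="kg/m^2", min_value=0.0),
    ColumnSpec("karnofsky_index", METRIC, unit="%", min_value=0.0),
    ColumnSpec("creatinine_mg_dl", METRIC, unit="mg/dl", min_value=0.0),
    ColumnSpec("hemoglobin_g_dl", METRIC, unit="g/dl", min_value=0.0),
    ColumnSpec("treatment_duration_days", METRIC, unit="days", min_value=0.0),
    ColumnSpec("time_diagnosis_to_rt_months", METRIC, unit="months", min_value=0.0),
    ColumnSpec("gtv_to_ptv_ratio", METRIC, unit="", min_value=0.0),
    ColumnSpec("accrual_month", METRIC, unit="months", min_value=0.0),
]


def default_dictionary() -> DataDictionary:
    """The 44-column reconstructed study dictionary."""
    return DataDictionary(columns=tuple(_CATEGORICAL + _METRIC),
                          version=DICTIONARY_VERSION)


def single_column_dictionary(name: str = "age", unit: str = "years") -> DataDictionary:
    """Minimal dictionary for single-vector sessions (demos and conformance)."""
    return DataDictionary(
        columns=(ColumnSpec(name, METRIC, unit=unit),),
        version=f"{DICTIONARY_VERSION}-single",
    )
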