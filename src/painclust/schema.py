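"""Column dictionary and measure orientation for cohort tables.

All PROMIS instruments are scored as T-scores normed to the U.S. general
population (mean 50, SD 10).  For symptom-scored measures a higher T-score
means *more* of the symptom (worse); for function-scored measures a higher
T-score means *better* functioning.  The orientation map below is what turns
raw T-scores into impairment-oriented deviations from the norm.
"""

from __future__ import annotations

#: The nine pain-agnostic clustering symptoms, in canonical order.
SYMPTOMS: tuple[str, ...] = (
    "fatigue",
    "sleep_disturbance",
    "sleep_impairment",
    "depression",
    "anxiety",
    "anger",
    "social_isolation",
    "emotional_support",
    "satisfaction_social_roles",
)

#: Pain-specific measures used for cluster validation, never for discovery.
PAIN_MEASURES: tuple[str, ...] = (
    "pain_intensity",              # 0-10 composite numeric rating scale
    "bodymap_segments",            # integer count, 0-74
    "pain_duration_months",        # months since onset, >= 0
    "pain_interference",           # PROMIS T-score
    "pain_behavior",               # PROMIS T-score
    "physical_function",           # PROMIS T-score (function-scored)
    "physical_function_mobility",
    "physical_function_upper_extremity",
    "pain_catastrophizing",        # Pain Catastrophizing Scale, 0-52
)

#: The five PROMIS-based, T-scored pain-specific measures (used for
#: norm-deviation summaries; intensity/segments/duration/PCS are not T-scored).
PROMIS_PAIN_MEASURES: tuple[str, ...] = (
    "pain_interference",
    "pain_behavior",
    "physical_function",
    "physical_function_mobility",
    "physical_function_upper_extremity",
)

GH_MENTAL = "gh_mental"

DEMOGRAPHICS: tuple[str, ...] = (
    "age_band",
    "sex",
    "ethnicity",
    "race",
    "marital_status",
    "education_band",
)

#: Measures where a higher T-score reflects a *better* condition.
FUNCTION_SCORED: frozenset[str] = frozenset(
    {
        "emotional_support",
        "satisfaction_social_roles",
        "physical_function",
        "physical_function_mobility",
        "physical_function_upper_extremity",
        GH_MENTAL,
    }
)

#: Closed numeric ranges for bounded non-T-score measures.
BOUNDED_RANGES: dict[str, tuple[float, float]] = {
    "pain_intensity": (0.0, 10.0),
    "bodymap_segments": (0.0, 74.0),
    "pain_catastrophizing": (0.0, 52.0),
}

#: Mandatory identifier columns for any cohort table.
ID_COLUMNS: tuple[str, ...] = ("patient_id", "timepoint")


def orientation(measure: str) -> int:
    """Impairment orientation sign: +1 if higher score = worse, -1 if better."""
    return -1 if measure in FUNCTION_SCORED else 1


def default_orientation() -> dict[str, int]:
    """Orientation signs for every known T-scored measure."""
    measures = SYMPTOMS + PROMIS_PAIN_MEASURES + (GH_MENTAL,)
    return {m: orientation(m) for m in measures}
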