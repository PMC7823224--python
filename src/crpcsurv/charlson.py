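"""Charlson Comorbidity Index: 17 categories, classic weights, ICD-9-CM-style prefixes.

The index is a weighted count of comorbidity *categories* (each counted once,
however many qualifying codes a patient carries) observed within a lookback
window before an index date. The prefix table below is deliberately compact —
one or two representative code prefixes per category — because the cohort
tables this package consumes use plain ICD-9-like code strings; a site with a
full grouper can pass its own ``weight_map``.
"""

from __future__ import annotations

#: code-prefix -> (category, weight). Longest matching prefix wins.
DEFAULT_CHARLSON_MAP: dict[str, tuple[str, int]] = {
    # weight 1
    "410": ("myocardial_infarction", 1),
    "412": ("myocardial_infarction", 1),
    "428": ("congestive_heart_failure", 1),
    "443": ("peripheral_vascular_disease", 1),
    "430": ("cerebrovascular_disease", 1),
    "290": ("dementia", 1),
    "490": ("chronic_pulmonary_disease", 1),
    "710": ("connective_tissue_disease", 1),
    "531": ("peptic_ulcer_disease", 1),
    "571.5": ("mild_liver_disease", 1),
    "250.0": ("diabetes", 1),
    # weight 2
    "250.4": ("diabetes_with_complications", 2),
    "342": ("hemiplegia", 2),
    "585": ("renal_disease", 2),
    "140": ("malignancy", 2),
    "204": ("leukemia", 2),
    "200": ("lymphoma", 2),
    # weight 3
    "456.0": ("moderate_severe_liver_disease", 3),
    # weight 6
    "196": ("metastatic_solid_tumor", 6),
    "042": ("aids", 6),
}

#: The ten weight-1 categories with a single unambiguous prefix each; the
#: synthetic cohort generator draws from these to plant a known index value.
WEIGHT_ONE_PREFIXES: tuple[str, ...] = (
    "410", "428", "443", "430", "290", "490", "710", "531", "571.5", "250.0",
)


def classify_code(code: str, weight_map: dict[str, tuple[str, int]]) -> tuple[str, int] | None:
    """Return (category, weight) for a code, or None if it maps to no category."""
    code = str(code)
    best = None
    for prefix, cat_w in weight_map.items():
        if code.startswith(prefix):
            if best is None or len(prefix) > best[0]:
                best = (len(prefix), cat_w)
    return best[1] if best else None
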