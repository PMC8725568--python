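"""Reference distributions used to calibrate the synthetic-cohort generator.

The numbers below are the published descriptive statistics of the Breast
Cancer Association Consortium (BCAC) two-array study population (invasive
cases genotyped on the OncoArray and iCOGS arrays), which the simulator is
calibrated to emulate: marker prevalences among cases with the marker
observed, pairwise marker correlations, per-marker missingness, the
intrinsic-like-subtype mix, and the bookkeeping of the published
173-variant heterogeneity screen.  Individual-level consortium data are
access-controlled and are not consumed anywhere in this package.
"""

from __future__ import annotations

import numpy as np

#: Case counts by marker level; "unknown" = marker not assayed/reported.
CASE_MARKER_COUNTS = {
    "ER": {"neg": 16_900, "pos": 70_030, "unknown": 19_641},
    "PR": {"neg": 24_283, "pos": 51_603, "unknown": 30_685},
    "HER2": {"neg": 47_693, "pos": 9_529, "unknown": 49_349},
    "grade": {"1": 15_583, "2": 37_568, "3": 24_382, "unknown": 29_038},
}

#: Case counts by intrinsic-like subtype (classifiable cases only).
SUBTYPE_COUNTS = {
    "luminalA": 27_510,
    "luminalB_HER2neg": 6_804,
    "luminalB_HER2pos": 6_511,
    "HER2pos_nonluminal": 2_797,
    "triple_negative": 7_178,
    "unknown": 55_771,
}

#: Reported pairwise Pearson correlations between coded tumor markers.
MARKER_CORRELATIONS = {
    ("ER", "PR"): 0.61,
    ("ER", "HER2"): -0.16,
    ("ER", "grade"): -0.39,
}

#: Study sizes per genotyping-array stratum: (n_cases, n_controls).
STRATUM_SIZES = {
    "oncoarray": (71_788, 58_134),
    "icogs": (34_783, 37_628),
}

#: Bookkeeping of the published 173-variant heterogeneity screen.
SCREEN_BOOKKEEPING = {
    "variants_screened": 173,
    "global_fdr_significant": 85,
    "marker_p05_ER": 45,
    "marker_p05_grade": 33,
    "multi_marker": 29,
    "no_marker_p05": 18,
    "only_ER": 21,
    "only_grade": 12,
    "only_PR": 4,
    "only_HER2": 1,
}


def marker_prevalences() -> dict:
    """Observed-level frequencies among cases with the marker assayed."""
    out = {}
    for marker, counts in CASE_MARKER_COUNTS.items():
        known = {k: v for k, v in counts.items() if k != "unknown"}
        tot = sum(known.values())
        out[marker] = {k: v / tot for k, v in known.items()}
    return out


def missingness_rates() -> dict:
    """Fraction of cases with each marker unknown."""
    out = {}
    for marker, counts in CASE_MARKER_COUNTS.items():
        tot = sum(counts.values())
        out[marker] = counts["unknown"] / tot
    return out


def subtype_shares() -> dict:
    """Intrinsic-like subtype mix among classifiable cases."""
    known = {k: v for k, v in SUBTYPE_COUNTS.items() if k != "unknown"}
    tot = sum(known.values())
    return {k: v / tot for k, v in known.items()}


def grade_distribution() -> np.ndarray:
    g = CASE_MARKER_COUNTS["grade"]
    tot = g["1"] + g["2"] + g["3"]
    return np.array([g["1"], g["2"], g["3"]]) / tot
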