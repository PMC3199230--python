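"""Bundled study-population table for the training cohort.

The published cohort comprises 11 idiopathic pulmonary fibrosis (IPF)
patients — 6 sampled at diagnostic surgical biopsy and 5 at lung
transplantation (explant), 6 of them with paired upper/lower-lobe samples —
plus 6 normal organ-donor controls (no clinical covariates recorded for
the donors).  Sample IDs encode the lobe (U = upper, L = lower).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PhenotypeTable

# patient, sample, age, sex, FVC%, DLCO%, type, lobe; covariates repeat on
# the lower-lobe row of a pair but summaries deduplicate by patient.
_CASES = [
    ("P01", "Biopsy_140U", 58, "Male", 55, 54, "biopsy", "upper"),
    ("P02", "Biopsy_142U", 56, "Female", 55, 65, "biopsy", "upper"),
    ("P03", "Biopsy_144U", 70, "Male", 84, 87, "biopsy", "upper"),
    ("P04", "Biopsy_145U", 54, "Male", 68, 52, "biopsy", "upper"),
    ("P05", "Biopsy_149U", 58, "Male", 79, 70, "biopsy", "upper"),
    ("P05", "Biopsy_149L", 58, "Male", 79, 70, "biopsy", "lower"),
    ("P06", "Biopsy_159U", 68, "Male", 50, 43, "biopsy", "upper"),
    ("P06", "Biopsy_159L", 68, "Male", 50, 43, "biopsy", "lower"),
    ("P07", "Explant_146L", 64, "Male", 56, 23, "explant", "lower"),
    ("P08", "Explant_152U", 67, "Male", 53, 29, "explant", "upper"),
    ("P08", "Explant_152L", 67, "Male", 53, 29, "explant", "lower"),
    ("P09", "Explant_157U", 67, "Male", 51, 34, "explant", "upper"),
    ("P09", "Explant_157L", 67, "Male", 51, 34, "explant", "lower"),
    ("P10", "Explant_158U", 68, "Female", 78, 18, "explant", "upper"),
    ("P10", "Explant_158L", 68, "Female", 78, 18, "explant", "lower"),
    ("P11", "Explant_160U", 67, "Female", 46, 42, "explant", "upper"),
    ("P11", "Explant_160L", 67, "Female", 46, 42, "explant", "lower"),
]

_CONTROLS = [("C%02d" % i, "Normal_%s" % c) for i, c in
             enumerate("ABCDEF", start=1)]


def load_study_cohort(include_controls: bool = True) -> PhenotypeTable:
    """The training-cohort phenotype table (17 case samples, 6 controls)."""
    rows = []
    for pat, sid, age, sex, fvc, dlco, stype, lobe in _CASES:
        rows.append(dict(sample_id=sid, phenotype=1, patient_id=pat,
                         lobe=lobe, sample_type=stype, age=float(age),
                         sex=sex, fvc_pct=float(fvc), dlco_pct=float(dlco)))
    if include_controls:
        for pat, sid in _CONTROLS:
            rows.append(dict(sample_id=sid, phenotype=0, patient_id=pat,
                             lobe="unknown", sample_type="control",
                             age=np.nan, sex=np.nan, fvc_pct=np.nan,
                             dlco_pct=np.nan))
    return PhenotypeTable(pd.DataFrame(rows))
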