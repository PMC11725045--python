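"""Disease-class registry for the 10-way respiratory diagnosis task.

Class ids are fixed across the whole package: feature matrices, rankings
and confusion matrices all index diseases by these integers.  Lung cancer
and pulmonary tuberculosis share the radiological presentation of a
pulmonary nodule or mass; the optional two-step diagnostic path first
groups them into a composite "lung space-occupying lesions" class and
then separates them with a dedicated binary classifier.
"""

from __future__ import annotations

N_CLASSES = 10

COPD = 0
ASTHMA = 1
BRONCHIECTASIS = 2
AIRWAY_STENOSIS = 3
PULMONARY_HYPERTENSION = 4
LUNG_CANCER = 5
TUBERCULOSIS = 6
PULMONARY_INFECTION = 7
PLEURAL_DISEASE = 8
INTERSTITIAL_LUNG_DISEASE = 9

CLASS_NAMES = {
    COPD: "chronic obstructive pulmonary disease",
    ASTHMA: "bronchial asthma",
    BRONCHIECTASIS: "bronchiectasis",
    AIRWAY_STENOSIS: "airway stenosis",
    PULMONARY_HYPERTENSION: "pulmonary hypertension",
    LUNG_CANCER: "lung cancer",
    TUBERCULOSIS: "pulmonary tuberculosis",
    PULMONARY_INFECTION: "pulmonary infectious diseases",
    PLEURAL_DISEASE: "pleural disease",
    INTERSTITIAL_LUNG_DISEASE: "interstitial lung disease",
}

#: Composite class used by the two-step path; not a member of the 10-way space.
COMPOSITE_LESION = -5
COMPOSITE_MEMBERS = (LUNG_CANCER, TUBERCULOSIS)
COMPOSITE_NAME = "lung space-occupying lesions"


def merge_composite(label: int) -> int:
    """Map a 10-way label into the 9-way space where cancer/TB collapse."""
    return COMPOSITE_LESION if label in COMPOSITE_MEMBERS else label


#: Label order of the 9-way merged space (used by the two-step stage 1).
MERGED_CLASSES = tuple(
    sorted({merge_composite(c) for c in range(N_CLASSES)})
)
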