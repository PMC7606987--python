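"""Default calibration targets for the synthetic study conditions.

These tables hold the published cohort-level summary statistics of normal
cerebrovascular aging in female C57BL/6 mice that the synthetic generator
is calibrated to emulate: apparent cerebral blood volume (aCBV, %) per ROI
and age group, whole-brain and ventricular volumes (mm^3), CD31
immunofluorescence vessel densities (vessels/mm^2), contrast-agent
relaxivities (mM^-1 s^-1), and the pre/post-contrast vascular SNR.  They
are the generator's ground-truth targets and the reference means used by
the worked-example percent-change summaries; nothing downstream treats
them as measured output.
"""

from __future__ import annotations

import pandas as pd

AGE_GROUPS = ("2-4", "14-16", "24-26")
"""Age groups in months: young adulthood, middle age, old age."""

COHORT_N = {"2-4": 14, "14-16": 12, "24-26": 8}
"""Number of imaged subjects per age group in the full cohort."""

HISTOLOGY_N = 5
"""Sections per age group in the immunofluorescence arm."""

#: aCBV (%) mean and SD by ROI and age group for the full cohort.
ACBV_BY_ROI = pd.DataFrame(
    {
        "whole_brain": [(1.64, 0.18), (1.37, 0.25), (1.24, 0.29)],
        "cerebral_cortex": [(1.99, 0.18), (1.73, 0.33), (1.43, 0.37)],
        "cerebellar_cortex": [(1.81, 0.20), (1.54, 0.27), (1.15, 0.43)],
        "entorhinal_cortex": [(4.02, 0.76), (3.52, 0.62), (3.09, 0.53)],
        "hippocampus": [(2.38, 0.27), (1.89, 0.50), (1.75, 0.61)],
        "striatum": [(0.99, 0.27), (0.44, 0.30), (0.41, 0.33)],
    },
    index=list(AGE_GROUPS),
)


def acbv_mean(roi: str, age_group: str) -> float:
    return ACBV_BY_ROI.loc[age_group, roi][0]


def acbv_sd(roi: str, age_group: str) -> float:
    return ACBV_BY_ROI.loc[age_group, roi][1]


#: Whole-brain and ventricular-system volume means (mm^3) by age group.
VOLUMES_MM3 = pd.DataFrame(
    {
        "whole_brain": [439.78, 452.86, 460.40],
        "ventricular_system": [5.16, 6.43, 6.54],
    },
    index=list(AGE_GROUPS),
)

#: Vessel density (vessels/mm^2) mean and SD by section region and age group.
VESSEL_DENSITY = pd.DataFrame(
    {
        "whole_section": [(458.18, 61.28), (420.15, 57.96), (362.94, 49.34)],
        "cerebral_cortex": [(500.60, 81.91), (476.97, 49.18), (377.02, 33.91)],
        "hippocampus": [(465.93, 83.71), (384.32, 68.26), (341.89, 38.18)],
    },
    index=list(AGE_GROUPS),
)

#: Density (vessels/mm^2) of the dominant sub-50-µm-diameter population by age.
SMALL_VESSEL_DENSITY = {"2-4": 456.92, "14-16": 419.35, "24-26": 361.60}

#: Relaxivities at 60 MHz, 40 deg C: (r1, r2) in mM^-1 s^-1 per agent.
RELAXIVITY = {
    "gd_micelle": (12.90, 17.80),
    "gd_dtpa": (3.29, 3.37),
}

#: Vascular SNR without and with blood-pool contrast (mean over 10 ROIs).
SNR_PRE = 36.14
SNR_POST = 115.13
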