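"""Region-of-interest vocabulary shared across the package.

The analysis works on 11 bilateral regions from amyloid-PET SUVR maps:
the four cortical lobes plus insula, amygdala, cingulate, hippocampus,
thalamus, basal ganglia and cerebellum (the SUVR reference region, which
is nevertheless modelled as the final event).
"""

from __future__ import annotations

ROI_NAMES: tuple[str, ...] = (
    "frontal",
    "temporal",
    "parietal",
    "occipital",
    "insula",
    "amygdala",
    "cingulate",
    "hippocampus",
    "thalamus",
    "basal_ganglia",
    "cerebellum",
)

#: Number of biomarker events; one z-score threshold per ROI, hence 11 stages.
N_EVENTS: int = len(ROI_NAMES)

#: Cortical composite used for the global amyloid-positivity ratio
#: (conventional florbetapir cortical composite).
COMPOSITE_ROIS: tuple[str, ...] = ("frontal", "temporal", "parietal", "cingulate")

SUVR_COLUMNS: tuple[str, ...] = tuple(f"suvr_{r}" for r in ROI_NAMES)

COVARIATE_COLUMNS: tuple[str, ...] = ("age", "gender", "education")


def suvr_column(roi: str) -> str:
    if roi not in ROI_NAMES:
        raise ValueError(f"unknown ROI {roi!r}")
    return f"suvr_{roi}"
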