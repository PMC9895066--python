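"""Synthetic amyloid-PET cohort generator with ground-truth labels.

Emulates the statistical structure the downstream analysis assumes: two
latent subtypes with distinct regional event sequences, a latent stage per
subject, piecewise-linear z-score trajectories with Gaussian noise,
covariate effects on SUVR, stage/subtype-linked CSF and cognitive outcomes,
and stage/subtype-linked conversion hazards censored at a fixed horizon.
Each cohort comes with a truth table (subtype, stage) so recovery can be
asserted directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import EventSequence, expected_z
from .rois import N_EVENTS, ROI_NAMES, SUVR_COLUMNS

__all__ = ["GeneratorConfig", "default_config", "generate_cohort",
           "SUBCORTEX_PRIORITY_SEQUENCE", "CORTEX_PRIORITY_SEQUENCE"]

#: Subcortical structures become abnormal first, cortex last.
SUBCORTEX_PRIORITY_SEQUENCE = (
    "thalamus", "basal_ganglia", "hippocampus", "cingulate", "amygdala",
    "insula", "frontal", "temporal", "parietal", "occipital", "cerebellum",
)

#: Cingulate leads, cortical lobes follow, subcortex last.
CORTEX_PRIORITY_SEQUENCE = (
    "cingulate", "frontal", "parietal", "temporal", "occipital", "insula",
    "amygdala", "hippocampus", "thalamus", "basal_ganglia", "cerebellum",
)

OUTCOME_COLUMNS = ("csf_abeta", "csf_ttau", "csf_ptau", "mmse", "memory",
                   "executive", "language", "visuospatial")


def _default_outcome_params() -> dict:
    # intercept, per-stage slope, per-subtype additive offset, residual SD;
    # directions follow the cohort contrasts the analysis is meant to expose
    # (cortex-priority subtype: lower CSF abeta, higher tau, worse cognition)
    return {
        "csf_abeta": dict(intercept=1400.0, stage_slope=-55.0,
                          subtype_offset=(0.0, -180.0), noise_sd=260.0),
        "csf_ttau": dict(intercept=230.0, stage_slope=7.0,
                         subtype_offset=(0.0, 45.0), noise_sd=95.0),
        "csf_ptau": dict(intercept=21.0, stage_slope=0.7,
                         subtype_offset=(0.0, 5.0), noise_sd=10.0),
        "mmse": dict(intercept=29.0, stage_slope=-0.10,
                     subtype_offset=(0.0, -0.45), noise_sd=1.4),
        "memory": dict(intercept=0.95, stage_slope=-0.05,
                       subtype_offset=(0.0, -0.35), noise_sd=0.62),
        "executive": dict(intercept=0.85, stage_slope=-0.04,
                          subtype_offset=(0.0, -0.30), noise_sd=0.82),
        "language": dict(intercept=0.70, stage_slope=-0.03,
                         subtype_offset=(0.0, -0.20), noise_sd=0.72),
        "visuospatial": dict(intercept=0.15, stage_slope=-0.01,
                             subtype_offset=(0.0, 0.0), noise_sd=0.65),
    }


def _default_stage_distribution() -> tuple:
    # mixed CN/MCI cohort: a sizeable normal-biomarker group, the remaining
    # mass spread evenly over the 11 post-onset stages
    rest = 0.7 / N_EVENTS
    return (0.3,) + (rest,) * N_EVENTS


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    Sequences must be permutations of the 11 ROI labels; fractions and the
    stage distribution are probability vectors.  SUVR for ROI ``i`` is
    ``mu_cn_i + sd_cn_i * z_i`` plus linear covariate terms, with ``z_i``
    the subtype trajectory at the subject's stage plus N(0, noise_sd_i)
    noise.  Conversion times are exponential with rate
    ``baseline_rate * hr_subtype^[c=2] * hr_stage^stage``, censored at
    ``censor_horizon`` years.
    """

    n_subjects: int = 600
    subtype_fractions: tuple = (0.5, 0.5)
    sequences: tuple = (SUBCORTEX_PRIORITY_SEQUENCE, CORTEX_PRIORITY_SEQUENCE)
    stage_distribution: tuple = field(default_factory=_default_stage_distribution)
    mu_cn: tuple = (1.0,) * N_EVENTS
    sd_cn: tuple = (0.1,) * N_EVENTS
    z_cut: tuple = (1.0,) * N_EVENTS
    z_max: tuple = (3.0,) * N_EVENTS
    noise_sd: tuple = (1.0,) * N_EVENTS
    # per-ROI linear effects of (age-72), gender and (education-16) on SUVR
    covariate_effects: tuple = ((0.002, 0.01, -0.001),) * N_EVENTS
    outcome_params: dict = field(default_factory=_default_outcome_params)
    apoe_probs: tuple = ((0.71, 0.26, 0.03), (0.46, 0.42, 0.12))
    baseline_rate: float = 0.02
    hr_subtype: float = 3.0
    hr_stage: float = 1.2
    censor_horizon: float = 6.0
    missing_fractions: dict = field(default_factory=dict)
    dataset_label: str = "synthetic"
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    def validate(self) -> None:
        f = np.asarray(self.subtype_fractions, dtype=float)
        if len(self.sequences) != f.size:
            raise ValueError("number of sequences != number of fractions")
        if abs(f.sum() - 1.0) > 1e-12 or (f < 0).any():
            raise ValueError("subtype_fractions must be a probability vector")
        sd = np.asarray(self.stage_distribution, dtype=float)
        if sd.size != N_EVENTS + 1 or abs(sd.sum() - 1.0) > 1e-12 or (sd < 0).any():
            raise ValueError("stage_distribution must be a probability "
                             f"vector over stages 0..{N_EVENTS}")
        for s in self.sequences:
            if sorted(s) != sorted(ROI_NAMES):
                raise ValueError(f"sequence {s!r} is not a permutation of "
                                 "the 11 ROI labels")
        zc = np.asarray(self.z_cut, float)
        zm = np.asarray(self.z_max, float)
        if not ((zm > zc).all() and (zc > 0).all()):
            raise ValueError("need z_max > z_cut > 0 per ROI")
        for name in ("sd_cn", "noise_sd"):
            if (np.asarray(getattr(self, name), float) < 0).any():
                raise ValueError(f"{name} entries must be >= 0")
        if len(self.apoe_probs) != len(self.sequences):
            raise ValueError("apoe_probs must have one row per subtype")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        # JSON round trip turns tuples into lists -> serialisable everywhere
        return json.loads(json.dumps(asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("subtype_fractions", "stage_distribution", "mu_cn",
                    "sd_cn", "z_cut", "z_max", "noise_sd"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("sequences", "apoe_probs", "covariate_effects"):
            if key in d:
                d[key] = tuple(tuple(row) for row in d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))


def default_config(**overrides) -> GeneratorConfig:
    """The default two-subtype study conditions (overridable per field)."""
    return GeneratorConfig(**overrides)


def generate_cohort(config: GeneratorConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort and its ground-truth labels.

    Returns ``(cohort, truth)``: the cohort table holds SUVR values,
    demographics, diagnosis, CSF/cognitive outcomes, APOE genotype and
    conversion follow-up; the truth table holds the hidden (subtype, stage)
    per subject.  Byte-identical output for identical seeds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    C = config.n_subtypes
    E = N_EVENTS

    subtype = rng.choice(C, size=n, p=np.asarray(config.subtype_fractions))
    stage = rng.choice(E + 1, size=n,
                       p=np.asarray(config.stage_distribution))

    age = np.clip(rng.normal(72.0, 7.0, size=n), 55.0, 92.0)
    gender = rng.integers(0, 2, size=n)
    education = np.clip(rng.normal(16.0, 2.6, size=n), 8.0, 22.0)

    positions = np.empty((C, E), dtype=int)
    for c, seq in enumerate(config.sequences):
        s = EventSequence(seq)
        for i, roi in enumerate(ROI_NAMES):
            positions[c, i] = s.position(roi)

    z_cut = np.asarray(config.z_cut, float)
    z_max = np.asarray(config.z_max, float)
    noise_sd = np.asarray(config.noise_sd, float)
    mu = np.asarray(config.mu_cn, float)
    sd = np.asarray(config.sd_cn, float)
    beta = np.asarray(config.covariate_effects, float)  # (E, 3)

    mean_z = np.empty((n, E))
    for c in range(C):
        rows = subtype == c
        if not rows.any():
            continue
        mean_z[rows] = expected_z(positions[c][None, :],
                                  stage[rows, None].astype(float),
                                  z_cut[None, :], z_max[None, :], E)
    z = mean_z + rng.normal(0.0, 1.0, size=(n, E)) * noise_sd[None, :]

    cov = np.column_stack([age - 72.0, gender.astype(float),
                           education - 16.0])  # (n, 3)
    suvr = mu[None, :] + sd[None, :] * z + cov @ beta.T

    # diagnosis tracks stage in a mixed CN/MCI cohort: amyloid-negative
    # subjects are mostly CN, late-stage subjects mostly MCI
    p_mci = np.clip(0.10 + 0.07 * stage, 0.0, 0.90)
    diagnosis = np.where(rng.random(n) < p_mci, "MCI", "CN")

    data = {"subject_id": [f"S{i:05d}" for i in range(n)]}
    for j, col in enumerate(SUVR_COLUMNS):
        data[col] = suvr[:, j]
    data.update(age=age, gender=gender, education=education,
                diagnosis=diagnosis)

    for name in OUTCOME_COLUMNS:
        p = config.outcome_params[name]
        offs = np.asarray(p["subtype_offset"], float)[subtype]
        vals = (p["intercept"] + p["stage_slope"] * stage + offs
                + rng.normal(0.0, p["noise_sd"], size=n))
        data[name] = vals

    apoe = np.empty(n, dtype=int)
    for c in range(C):
        rows = np.where(subtype == c)[0]
        apoe[rows] = rng.choice(3, size=rows.size,
                                p=np.asarray(config.apoe_probs[c]))
    data["apoe_e4"] = apoe

    rate = (config.baseline_rate
            * config.hr_subtype ** (subtype == 1).astype(float)
            * config.hr_stage ** stage.astype(float))
    t_event = rng.exponential(1.0 / rate)
    converted = t_event <= config.censor_horizon
    followup = np.minimum(t_event, config.censor_horizon)
    data["followup_years"] = followup
    data["converted"] = converted.astype(int)
    data["dataset_label"] = config.dataset_label

    cohort = pd.DataFrame(data)

    for col, frac in config.missing_fractions.items():
        mask = rng.random(n) < frac
        cohort.loc[mask, col] = np.nan

    truth = pd.DataFrame({
        "subject_id": cohort["subject_id"],
        "true_subtype": subtype + 1,  # 1-based labels
        "true_stage": stage,
    })
    return cohort, truth
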