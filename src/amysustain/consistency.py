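"""Probabilistic subject assignment, exclusion rules, and sequence-agreement
metrics (Kendall tau, concordance percentages, fold consistency, positional
variance).

Subjects are assigned to the (subtype, stage) pair with the largest
posterior mass.  Subjects whose most likely stage is 0 have no abnormal
region and carry no subtype information; subjects at the final stage are
fully abnormal under every sequence.  Both groups are flagged excluded and
removed from downstream characterisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import (EventSequence, MCMCTrace, SubtypeModel, _subtype_stage_ll)

__all__ = ["AssignmentResult", "PositionalVariance", "assign_subjects",
           "kendall_tau", "similarity_pct", "match_subtypes",
           "fold_consistency", "positional_variance"]


@dataclass
class AssignmentResult:
    """Per-subject posterior over (subtype, stage) and ML assignment.

    ``posterior`` has shape (n, C, E+1) and each subject's slice sums to 1.
    ``table`` holds subject_id, ml_subtype (1-based; <NA> for stage-0
    subjects), ml_stage, excluded flag and reason.
    """

    posterior: np.ndarray
    table: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    def included(self) -> pd.DataFrame:
        return self.table[~self.table["excluded"]]


@dataclass
class PositionalVariance:
    """Per subtype, an ExE matrix: entry (i, k) is the fraction of MCMC
    samples that place ROI i's event at position k+1.  Rows sum to 1."""

    matrices: np.ndarray  # (C, E, E)
    roi_names: tuple


def assign_subjects(Z, model: SubtypeModel, subject_ids=None
                    ) -> AssignmentResult:
    """Posterior P(c, k | z_n) proportional to f_c x P(z_n | S_c, k), with the
    ML pair as hard assignment.  Ties break toward the lower stage, then the
    lower subtype index.  ``ml_stage`` 0 means no subtype (stage0); stages
    0 and E are flagged excluded.
    """
    Z = np.asarray(getattr(Z, "values", Z), dtype=float)
    n = Z.shape[0]
    E = model.n_events
    C = model.n_subtypes
    ll = _subtype_stage_ll(Z, model)
    with np.errstate(divide="ignore"):
        ll = ll + np.log(model.fractions)[None, :, None]
    flat = ll.reshape(n, -1)
    norm = logsumexp(flat, axis=1)
    if not np.all(np.isfinite(norm)):
        raise ValueError("subject with zero posterior mass everywhere")
    post = np.exp(flat - norm[:, None]).reshape(n, C, E + 1)

    # argmax over (stage-major, subtype-minor) order so the first max wins
    # the tie-break: lowest stage, then lowest subtype
    stage_major = post.transpose(0, 2, 1).reshape(n, -1)
    best = np.argmax(np.isclose(stage_major,
                                stage_major.max(axis=1, keepdims=True),
                                rtol=0, atol=1e-12), axis=1)
    ml_stage = best // C
    ml_subtype = best % C + 1

    excluded = (ml_stage == 0) | (ml_stage == E)
    reason = np.where(ml_stage == 0, "stage0",
                      np.where(ml_stage == E, "last_stage", ""))
    subtype_col = pd.array(ml_subtype, dtype="Int64")
    subtype_col[ml_stage == 0] = pd.NA

    if subject_ids is None:
        subject_ids = [f"S{i:05d}" for i in range(n)]
    table = pd.DataFrame({
        "subject_id": np.asarray(subject_ids),
        "ml_subtype": subtype_col,
        "ml_stage": ml_stage,
        "excluded": excluded,
        "reason": reason,
    })
    return AssignmentResult(posterior=post, table=table)


def _positions(seq: EventSequence) -> dict:
    return {lbl: i for i, lbl in enumerate(seq)}


def kendall_tau(seq_a, seq_b) -> float:
    """Kendall rank correlation between two event orderings: (concordant -
    discordant pairs) / total pairs; 1 for identical, -1 for reversed."""
    seq_a, seq_b = EventSequence(seq_a), EventSequence(seq_b)
    if set(seq_a) != set(seq_b):
        raise ValueError("sequences are over different event sets")
    pa, pb = _positions(seq_a), _positions(seq_b)
    events = list(seq_a)
    conc = disc = 0
    for x, y in combinations(events, 2):
        s = (pa[x] - pa[y]) * (pb[x] - pb[y])
        if s > 0:
            conc += 1
        else:
            disc += 1
    return (conc - disc) / (conc + disc)


def similarity_pct(seq_a, seq_b) -> float:
    """Concordant-pair percentage: 100 (1 + tau) / 2."""
    return 100.0 * (1.0 + kendall_tau(seq_a, seq_b)) / 2.0


def match_subtypes(model_a: SubtypeModel, model_b: SubtypeModel) -> tuple:
    """Bijection b = pairing[a] between subtype labels maximising the total
    sequence similarity (labels are arbitrary, so comparisons need this)."""
    if model_a.n_subtypes != model_b.n_subtypes:
        raise ValueError("models have different numbers of subtypes")
    C = model_a.n_subtypes
    sim = np.array([[similarity_pct(model_a.sequences[i],
                                    model_b.sequences[j])
                     for j in range(C)] for i in range(C)])
    best_perm, best_total = None, -np.inf
    for perm in permutations(range(C)):
        total = sum(sim[i, perm[i]] for i in range(C))
        if total > best_total:
            best_perm, best_total = perm, total
    return tuple(best_perm)


def fold_consistency(fold_models) -> float:
    """Mean matched-sequence similarity over all pairs of fold models,
    averaged over subtypes; 100 means identical sequences in every fold."""
    fold_models = list(fold_models)
    if len(fold_models) < 2:
        raise ValueError("need at least two fold models")
    sims = []
    for ma, mb in combinations(fold_models, 2):
        pairing = match_subtypes(ma, mb)
        per_subtype = [similarity_pct(ma.sequences[i], mb.sequences[j])
                       for i, j in enumerate(pairing)]
        sims.append(float(np.mean(per_subtype)))
    return float(np.mean(sims))


def positional_variance(trace: MCMCTrace) -> PositionalVariance:
    """Empirical frequency with which each ROI's event lands at each
    position across the MCMC samples, one matrix per subtype."""
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    S, C, E = trace.sequences.shape
    mats = np.zeros((C, E, E))
    for c in range(C):
        pos = trace.sequences[:, c, :]  # (S, E), 1-based positions
        for i in range(E):
            counts = np.bincount(pos[:, i] - 1, minlength=E)
            mats[c, i] = counts / S
    return PositionalVariance(matrices=mats, roi_names=tuple(trace.roi_names))
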