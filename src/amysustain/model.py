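"""z-score event-based subtype-and-stage model.

The disease course of each latent subtype ``c`` is an ordered sequence
``S_c`` of biomarker events: ROI ``i``'s event is the crossing of its
abnormality threshold ``z_cut_i``.  A subject at stage ``k`` has seen the
first ``k`` events of its subtype's sequence.  The expected z-score of ROI
``i`` at stage ``k`` is piecewise linear: it rises from 0 at stage 0 to
``z_cut_i`` at the event's position, then continues linearly to ``z_max_i``
at the final stage ``E``.  Observed z-scores are the expected trajectory
plus independent Gaussian noise with SD ``sigma_i`` (default 1, since the
inputs are control-referenced z-scores).

Subtype membership and stage are latent; the data likelihood marginalises
both with mixture fractions ``f_c`` and a uniform stage prior over
``0..E``.  Sequences are fitted by greedy coordinate ascent over event
orderings, subtypes by hierarchical splitting with EM refinement, sequence
uncertainty by Metropolis-Hastings MCMC, and the number of subtypes by
ten-fold cross-validation (CVIC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence as SequenceType

import numpy as np
def logsumexp(a, axis=None):
    """Lean log-sum-exp (dense float arrays, finite max) for the hot paths."""
    import numpy as _np
    a = _np.asarray(a, dtype=float)
    m = _np.max(a, axis=axis, keepdims=True)
    m = _np.where(_np.isfinite(m), m, 0.0)
    out = _np.log(_np.sum(_np.exp(a - m), axis=axis, keepdims=True)) + m
    return out if axis is None else _np.squeeze(out, axis=axis)

try:  # estimator base; degrade gracefully if sklearn is absent
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .rois import N_EVENTS, ROI_NAMES

__all__ = [
    "EventSequence",
    "SubtypeModel",
    "MCMCTrace",
    "CVICResult",
    "SubtypeStageModel",
    "expected_z",
    "stage_likelihoods",
    "log_likelihood",
    "greedy_fit_sequence",
    "fit_subtypes",
    "mcmc_sample",
    "cvic",
]

MAX_SUBTYPES = 4

# ---------------------------------------------------------------------------
# containers


class EventSequence(tuple):
    """An ordering of ROI labels; immutable permutation of the event set."""

    def __new__(cls, labels: SequenceType[str]):
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("event sequence contains duplicate labels")
        return super().__new__(cls, labels)

    def position(self, label: str) -> int:
        """1-based rank of ``label``'s event."""
        return self.index(label) + 1


@dataclass
class SubtypeModel:
    """Fitted mixture of event sequences.

    Attributes
    ----------
    sequences : list of EventSequence, length C
    fractions : array, shape (C,), sums to 1
    z_cut, z_max, sigma : arrays, shape (E,), aligned with ``roi_names``
    """

    sequences: list
    fractions: np.ndarray
    z_cut: np.ndarray
    z_max: np.ndarray
    sigma: np.ndarray
    roi_names: tuple = ROI_NAMES
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.z_cut = np.asarray(self.z_cut, dtype=float)
        self.z_max = np.asarray(self.z_max, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.sequences = [EventSequence(s) for s in self.sequences]
        E = len(self.roi_names)
        if len(self.sequences) != len(self.fractions):
            raise ValueError("number of sequences != number of fractions")
        if len(self.sequences) > MAX_SUBTYPES:
            raise ValueError(f"at most {MAX_SUBTYPES} subtypes are supported")
        if abs(self.fractions.sum() - 1.0) > 1e-12 or (self.fractions < 0).any():
            raise ValueError("fractions must be nonnegative and sum to 1")
        for s in self.sequences:
            if sorted(s) != sorted(self.roi_names):
                raise ValueError("sequence is not a permutation of the ROI set")
        for name, arr in (("z_cut", self.z_cut), ("z_max", self.z_max),
                          ("sigma", self.sigma)):
            if arr.shape != (E,):
                raise ValueError(f"{name} must have one entry per ROI")
        if not (self.z_cut > 0).all() or not (self.z_max > self.z_cut).all():
            raise ValueError("need z_max > z_cut > 0 for every ROI")
        if not (self.sigma > 0).all():
            raise ValueError("sigma must be positive")

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    @property
    def n_events(self) -> int:
        return len(self.roi_names)

    def positions(self, c: int) -> np.ndarray:
        """1-based event positions of each ROI (ROI order) for subtype c."""
        seq = self.sequences[c]
        pos = np.empty(len(self.roi_names), dtype=int)
        for i, roi in enumerate(self.roi_names):
            pos[i] = seq.position(roi)
        return pos

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "roi_names": list(self.roi_names),
            "sequences": [list(s) for s in self.sequences],
            "fractions": self.fractions.tolist(),
            "z_cut": self.z_cut.tolist(),
            "z_max": self.z_max.tolist(),
            "sigma": self.sigma.tolist(),
            "log_likelihood": self.log_likelihood,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeModel":
        return cls(
            sequences=[EventSequence(s) for s in d["sequences"]],
            fractions=np.asarray(d["fractions"]),
            z_cut=np.asarray(d["z_cut"]),
            z_max=np.asarray(d["z_max"]),
            sigma=np.asarray(d["sigma"]),
            roi_names=tuple(d["roi_names"]),
            log_likelihood=d.get("log_likelihood"),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SubtypeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class MCMCTrace:
    """Metropolis-Hastings samples over (sequences, fractions).

    ``sequences`` holds 1-based event positions in ROI order, shape
    (n_samples, C, E); ``fractions`` shape (n_samples, C); ``log_likelihoods``
    shape (n_samples,).
    """

    sequences: np.ndarray
    fractions: np.ndarray
    log_likelihoods: np.ndarray
    n_accepted: int
    roi_names: tuple = ROI_NAMES

    @property
    def n_samples(self) -> int:
        return self.sequences.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_samples

    def sequence_labels(self, sample: int, subtype: int) -> EventSequence:
        pos = self.sequences[sample, subtype]
        order = np.argsort(pos)
        return EventSequence(tuple(self.roi_names[i] for i in order))

    def to_dict(self) -> dict:
        return {
            "roi_names": list(self.roi_names),
            "sequences": self.sequences.tolist(),
            "fractions": self.fractions.tolist(),
            "log_likelihoods": self.log_likelihoods.tolist(),
            "n_accepted": int(self.n_accepted),
        }


@dataclass
class CVICResult:
    """Cross-validation information criterion per candidate subtype count."""

    cvic: dict
    fold_test_loglik: dict
    selected: int
    fold_models: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        best = min(self.cvic, key=lambda c: self.cvic[c])
        if self.cvic[self.selected] != self.cvic[best]:
            raise ValueError("selected C does not minimise CVIC")


# ---------------------------------------------------------------------------
# trajectory and likelihood


def expected_z(position, stage, z_cut, z_max, n_events: int = N_EVENTS):
    """Expected z-score for an event at 1-based ``position`` when the subject
    is at ``stage``.

    Rises linearly from 0 (stage 0) to ``z_cut`` exactly at
    ``stage == position``, then from ``z_cut`` to ``z_max`` at the final
    stage.  Vectorised over ``stage``.
    """
    position = np.asarray(position)
    if np.any(position < 1) or np.any(position > n_events):
        raise ValueError(f"position must lie in 1..{n_events}")
    stage = np.asarray(stage, dtype=float)
    pre = z_cut * stage / position
    # the post-threshold branch is unreachable when position == n_events
    denom = np.where(position == n_events, 1, n_events - position)
    post = z_cut + (z_max - z_cut) * (stage - position) / denom
    return np.where(stage <= position, pre, post)


def _trajectory(positions: np.ndarray, z_cut: np.ndarray,
                z_max: np.ndarray) -> np.ndarray:
    """Expected z per (stage, ROI); shape (E+1, E)."""
    E = positions.size
    stages = np.arange(E + 1)[:, None].astype(float)
    pos = positions[None, :].astype(float)
    pre = z_cut[None, :] * stages / pos
    denom = np.where(pos == E, 1.0, E - pos)
    post = z_cut[None, :] + (z_max - z_cut)[None, :] * (stages - pos) / denom
    return np.where(stages <= pos, pre, post)


def _stage_log_likelihoods(Z: np.ndarray, positions: np.ndarray,
                           z_cut: np.ndarray, z_max: np.ndarray,
                           sigma: np.ndarray) -> np.ndarray:
    """log P(z_row | stage k) for each subject and stage; shape (n, E+1)."""
    traj = _trajectory(positions, z_cut, z_max)  # (E+1, E)
    resid = (Z[:, None, :] - traj[None, :, :]) / sigma
    const = -0.5 * Z.shape[1] * np.log(2.0 * np.pi) - np.log(sigma).sum()
    return const - 0.5 * np.einsum("nke,nke->nk", resid, resid)


def stage_likelihoods(z_row: np.ndarray, sequence, model: SubtypeModel) -> np.ndarray:
    """P(z_row | stage k) for k = 0..E under one sequence: the product of
    independent Gaussian densities around the stage-k trajectory."""
    sequence = EventSequence(sequence)
    pos = np.array([sequence.position(r) for r in model.roi_names])
    Z = np.atleast_2d(np.asarray(z_row, dtype=float))
    ll = _stage_log_likelihoods(Z, pos, model.z_cut, model.z_max, model.sigma)
    return np.exp(ll[0])


def _subtype_stage_ll(Z: np.ndarray, model: SubtypeModel) -> np.ndarray:
    """log P(z_n | subtype c, stage k); shape (n, C, E+1)."""
    out = np.empty((Z.shape[0], model.n_subtypes, model.n_events + 1))
    for c in range(model.n_subtypes):
        out[:, c, :] = _stage_log_likelihoods(
            Z, model.positions(c), model.z_cut, model.z_max, model.sigma)
    return out


def _subject_log_marginals(Z: np.ndarray, model: SubtypeModel) -> np.ndarray:
    """log P(z_n | subtype c) with uniform stage prior; shape (n, C)."""
    ll = _subtype_stage_ll(Z, model)
    return logsumexp(ll, axis=2) - np.log(model.n_events + 1)


def log_likelihood(Z: np.ndarray, model: SubtypeModel) -> float:
    """Total data log-likelihood of the mixture, computed in log space:

    sum_n log sum_c f_c (1/(E+1)) sum_k P(z_n | S_c, k)
    """
    Z = np.asarray(Z, dtype=float)
    lm = _subject_log_marginals(Z, model)  # (n, C)
    with np.errstate(divide="ignore"):
        lw = np.log(model.fractions)
    per_subject = logsumexp(lm + lw[None, :], axis=1)
    if not np.all(np.isfinite(per_subject)):
        raise ValueError("subject with zero likelihood mass at every "
                         "(subtype, stage); corrupt input?")
    return float(per_subject.sum())


# ---------------------------------------------------------------------------
# greedy sequence optimisation


def _weighted_seq_ll(Z, positions, z_cut, z_max, sigma, weights, log_stage_prior):
    ll = _stage_log_likelihoods(Z, positions, z_cut, z_max, sigma)
    return float(weights @ (logsumexp(ll, axis=1) + log_stage_prior))


def _trajectory_batch(positions: np.ndarray, z_cut, z_max) -> np.ndarray:
    """Trajectories for many candidate orderings; shape (m, E+1, E)."""
    m, E = positions.shape
    stages = np.arange(E + 1)[None, :, None].astype(float)
    pos = positions[:, None, :].astype(float)
    pre = z_cut[None, None, :] * stages / pos
    denom = np.where(pos == E, 1.0, E - pos)
    post = z_cut[None, None, :] + (z_max - z_cut)[None, None, :] \
        * (stages - pos) / denom
    return np.where(stages <= pos, pre, post)


def _batch_seq_ll(Z, positions, z_cut, z_max, sigma, weights,
                  log_stage_prior) -> np.ndarray:
    """Weighted sequence log-likelihood for each candidate ordering."""
    traj = _trajectory_batch(positions, z_cut, z_max)      # (m, E+1, E)
    scaled = traj / sigma[None, None, :]
    Zs = Z / sigma[None, :]
    # ||z - t||^2 = ||z||^2 - 2 z.t + ||t||^2, batched via matmul
    cross = np.einsum("ne,mke->mnk", Zs, scaled)
    sq_t = np.einsum("mke,mke->mk", scaled, scaled)
    sq_z = np.einsum("ne,ne->n", Zs, Zs)
    const = -0.5 * Z.shape[1] * np.log(2.0 * np.pi) - np.log(sigma).sum()
    ll = const - 0.5 * (sq_z[None, :, None] - 2.0 * cross
                        + sq_t[:, None, :])                # (m, n, E+1)
    return (logsumexp(ll, axis=2) + log_stage_prior) @ weights


def _greedy_refine(Z, order, z_cut, z_max, sigma, weights, rng, log_stage_prior,
                   max_passes=50):
    """Single-start greedy coordinate ascent: repeatedly remove each event and
    reinsert it at the best position until a full pass makes no improvement.
    All insertion slots for one event are scored in a single batched call."""
    E = len(order)
    order = list(order)
    positions = np.empty(E, dtype=int)
    for rank, roi in enumerate(order):
        positions[roi] = rank + 1
    best = _weighted_seq_ll(Z, positions, z_cut, z_max, sigma, weights,
                            log_stage_prior)
    cand_positions = np.empty((E, E), dtype=int)
    for _ in range(max_passes):
        improved = False
        for roi in rng.permutation(E):
            cur_rank = order.index(roi)
            rest = order[:cur_rank] + order[cur_rank + 1:]
            for ins in range(E):
                trial = rest[:ins] + [roi] + rest[ins:]
                for rank, r in enumerate(trial):
                    cand_positions[ins, r] = rank + 1
            lls = _batch_seq_ll(Z, cand_positions, z_cut, z_max, sigma,
                                weights, log_stage_prior)
            # ties keep the earliest insertion slot (argmax -> first max)
            cand_pos = int(np.argmax(lls))
            cand_best = float(lls[cand_pos])
            if cand_best > best + 1e-12:
                order = rest[:cand_pos] + [roi] + rest[cand_pos:]
                best = cand_best
                improved = True
        if not improved:
            break
    for rank, r in enumerate(order):
        positions[r] = rank + 1
    return order, positions.copy(), best


def greedy_fit_sequence(Z: np.ndarray, weights=None, *, z_cut, z_max,
                        sigma=None, n_restarts: int = 25, seed=None,
                        init=None, roi_names=ROI_NAMES):
    """Maximum-likelihood event sequence by greedy ascent with restarts.

    Each restart begins from a random permutation (or ``init`` for the first
    restart if given) and hill-climbs by single-event reinsertion.  Returns
    ``(EventSequence, weighted log-likelihood)``; deterministic given ``seed``.
    """
    Z = np.asarray(Z, dtype=float)
    n, E = Z.shape
    z_cut = np.asarray(z_cut, dtype=float)
    z_max = np.asarray(z_max, dtype=float)
    sigma = np.ones(E) if sigma is None else np.asarray(sigma, dtype=float)
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    rng = np.random.default_rng(seed)
    log_stage_prior = -np.log(E + 1)
    best_order, best_ll = None, -np.inf
    for r in range(max(1, n_restarts)):
        if r == 0 and init is not None:
            seq0 = EventSequence(init)
            start = [roi_names.index(lbl) for lbl in seq0]
        else:
            start = list(rng.permutation(E))
        order, _, ll = _greedy_refine(Z, start, z_cut, z_max, sigma, weights,
                                      rng, log_stage_prior)
        if ll > best_ll:
            best_order, best_ll = order, ll
    labels = EventSequence(tuple(roi_names[i] for i in best_order))
    return labels, best_ll


# ---------------------------------------------------------------------------
# subtype fitting (hierarchical split + EM)


def _em_refine(Z, sequences_idx, fractions, z_cut, z_max, sigma, rng,
               roi_names, tol=1e-6, max_iter=100, greedy_seed=None):
    """EM over (fractions, sequences): E-step responsibilities, M-step
    fraction update and per-subtype greedy sequence re-optimisation."""
    n, E = Z.shape
    C = len(sequences_idx)
    log_stage_prior = -np.log(E + 1)
    sequences_idx = [list(s) for s in sequences_idx]
    fractions = np.asarray(fractions, dtype=float)

    def marginals(seqs):
        lm = np.empty((n, C))
        positions = np.empty(E, dtype=int)
        for c, order in enumerate(seqs):
            for rank, roi in enumerate(order):
                positions[roi] = rank + 1
            ll = _stage_log_likelihoods(Z, positions, z_cut, z_max, sigma)
            lm[:, c] = logsumexp(ll, axis=1) + log_stage_prior
        return lm

    lm = marginals(sequences_idx)
    prev = -np.inf
    for it in range(max_iter):
        with np.errstate(divide="ignore"):
            joint = lm + np.log(fractions)[None, :]
        total = logsumexp(joint, axis=1)
        resp = np.exp(joint - total[:, None])  # (n, C)
        # guard: a collapsed component is re-seeded from the worst-fit rows
        weight = resp.sum(axis=0)
        for c in np.where(weight < 1e-8)[0]:
            worst = np.argsort(total)[: max(2, n // 10)]
            resp[:, c] = 0.0
            resp[worst, c] = 1.0
            resp /= resp.sum(axis=1, keepdims=True)
            weight = resp.sum(axis=0)
        fractions = weight / n
        for c in range(C):
            seq, _ = greedy_fit_sequence(
                Z, resp[:, c], z_cut=z_cut, z_max=z_max, sigma=sigma,
                n_restarts=1, seed=rng.integers(2**31),
                init=tuple(roi_names[i] for i in sequences_idx[c]),
                roi_names=roi_names)
            sequences_idx[c] = [roi_names.index(lbl) for lbl in seq]
        lm = marginals(sequences_idx)
        with np.errstate(divide="ignore"):
            ll_total = float(logsumexp(lm + np.log(fractions)[None, :],
                                       axis=1).sum())
        if ll_total - prev < tol and it > 0:
            prev = ll_total
            break
        prev = ll_total
    return sequences_idx, fractions, prev


def fit_subtypes(Z: np.ndarray, n_subtypes: int, *, z_cut, z_max, sigma=None,
                 n_restarts: int = 25, seed=None, roi_names=ROI_NAMES,
                 tol: float = 1e-6, max_em_iter: int = 100) -> SubtypeModel:
    """Fit a C-subtype model by hierarchical splitting.

    C = 1 is the plain maximum-likelihood sequence.  For C > 1, start from
    the fitted (C-1)-model; hard-assign subjects, try random bipartitions of
    each cluster (``n_restarts`` per cluster), fit a sequence to each half,
    refine the candidate C-model by EM, and keep the best candidate.
    """
    Z = np.asarray(Z, dtype=float)
    n, E = Z.shape
    if not 1 <= n_subtypes <= MAX_SUBTYPES:
        raise ValueError(f"n_subtypes must be in 1..{MAX_SUBTYPES}")
    z_cut = np.asarray(z_cut, dtype=float)
    z_max = np.asarray(z_max, dtype=float)
    sigma = np.ones(E) if sigma is None else np.asarray(sigma, dtype=float)
    rng = np.random.default_rng(seed)
    log_stage_prior = -np.log(E + 1)

    def model_from(seqs_idx, fractions, ll):
        seqs = [EventSequence(tuple(roi_names[i] for i in s)) for s in seqs_idx]
        f = np.clip(np.asarray(fractions, dtype=float), 0, None)
        f = f / f.sum()
        # canonical labelling: subtypes ordered by descending mixture
        # fraction (sequence order breaks exact ties) so labels reproduce
        order = sorted(range(len(seqs)), key=lambda c: (-f[c], seqs[c]))
        seqs = [seqs[c] for c in order]
        f = f[order]
        return SubtypeModel(sequences=seqs, fractions=f, z_cut=z_cut,
                            z_max=z_max, sigma=sigma, roi_names=tuple(roi_names),
                            log_likelihood=ll)

    # C = 1
    seq, _ = greedy_fit_sequence(Z, None, z_cut=z_cut, z_max=z_max, sigma=sigma,
                                 n_restarts=n_restarts,
                                 seed=rng.integers(2**31), roi_names=roi_names)
    seqs_idx = [[roi_names.index(lbl) for lbl in seq]]
    model = model_from(seqs_idx, [1.0], None)
    model.log_likelihood = log_likelihood(Z, model)
    if n_subtypes == 1:
        return model

    for C in range(2, n_subtypes + 1):
        lm = _subject_log_marginals(Z, model)
        with np.errstate(divide="ignore"):
            hard = np.argmax(lm + np.log(model.fractions)[None, :], axis=1)
        best = None
        for c_split in range(C - 1):
            members = np.where(hard == c_split)[0]
            if members.size < 4:
                continue
            for _ in range(max(1, n_restarts)):
                mask = rng.random(members.size) < 0.5
                if mask.sum() < 2 or (~mask).sum() < 2:
                    continue
                halves = (members[mask], members[~mask])
                new_seqs = []
                for half in halves:
                    w = np.zeros(n)
                    w[half] = 1.0
                    s, _ = greedy_fit_sequence(
                        Z, w, z_cut=z_cut, z_max=z_max, sigma=sigma,
                        n_restarts=1, seed=rng.integers(2**31),
                        roi_names=roi_names)
                    new_seqs.append([roi_names.index(lbl) for lbl in s])
                cand_seqs = []
                cand_frac = []
                for c in range(C - 1):
                    if c == c_split:
                        continue
                    cand_seqs.append([roi_names.index(lbl)
                                      for lbl in model.sequences[c]])
                    cand_frac.append(model.fractions[c])
                split_f = model.fractions[c_split]
                for s_new, half in zip(new_seqs, halves):
                    cand_seqs.append(s_new)
                    cand_frac.append(split_f * half.size / members.size)
                cand_frac = np.clip(np.asarray(cand_frac), 1e-6, None)
                cand_frac /= cand_frac.sum()
                seqs_ref, frac_ref, ll_ref = _em_refine(
                    Z, cand_seqs, cand_frac, z_cut, z_max, sigma, rng,
                    roi_names, tol=tol, max_iter=max_em_iter)
                if best is None or ll_ref > best[2]:
                    best = (seqs_ref, frac_ref, ll_ref)
        if best is None:
            raise RuntimeError("no cluster large enough to split")
        model = model_from(best[0], best[1], None)
        model.log_likelihood = log_likelihood(Z, model)
    return model


# ---------------------------------------------------------------------------
# MCMC over sequences and fractions


def mcmc_sample(Z: np.ndarray, start: SubtypeModel, n_samples: int,
                seed=None, fraction_step: float = 0.02) -> MCMCTrace:
    """Metropolis-Hastings over (sequences, fractions).

    Each iteration proposes, with probability 1/2, moving one uniformly
    chosen event of one uniformly chosen subtype to a uniformly chosen new
    position; otherwise it perturbs the mixture fractions with Gaussian
    noise (clipped at 0, renormalised).  Acceptance is min(1, exp(dlogL)).
    Every post-move state is recorded, so the trace length equals
    ``n_samples``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    Z = np.asarray(Z, dtype=float)
    n, E = Z.shape
    C = start.n_subtypes
    rng = np.random.default_rng(seed)
    log_stage_prior = -np.log(E + 1)
    roi_names = start.roi_names

    positions = np.stack([start.positions(c) for c in range(C)])  # (C, E)
    fractions = start.fractions.copy()

    def marginal(pos):
        ll = _stage_log_likelihoods(Z, pos, start.z_cut, start.z_max,
                                    start.sigma)
        return logsumexp(ll, axis=1) + log_stage_prior

    lm = np.stack([marginal(positions[c]) for c in range(C)], axis=1)  # (n, C)

    def total(lm_, f_):
        with np.errstate(divide="ignore"):
            return float(logsumexp(lm_ + np.log(f_)[None, :], axis=1).sum())

    cur_ll = total(lm, fractions)
    seq_out = np.empty((n_samples, C, E), dtype=np.int16)
    frac_out = np.empty((n_samples, C))
    ll_out = np.empty(n_samples)
    n_accepted = 0

    for t in range(n_samples):
        if rng.random() < 0.5:
            c = rng.integers(C)
            ev = rng.integers(E)
            new_rank = rng.integers(1, E + 1)
            old_rank = positions[c, ev]
            new_pos = positions[c].copy()
            if new_rank != old_rank:
                # shift the events between old and new rank
                if new_rank > old_rank:
                    sel = (new_pos > old_rank) & (new_pos <= new_rank)
                    new_pos[sel] -= 1
                else:
                    sel = (new_pos >= new_rank) & (new_pos < old_rank)
                    new_pos[sel] += 1
                new_pos[ev] = new_rank
            new_col = marginal(new_pos)
            lm_prop = lm.copy()
            lm_prop[:, c] = new_col
            prop_ll = total(lm_prop, fractions)
            if prop_ll - cur_ll >= 0 or rng.random() < np.exp(prop_ll - cur_ll):
                positions[c] = new_pos
                lm = lm_prop
                cur_ll = prop_ll
                n_accepted += 1
        else:
            f_prop = fractions + rng.normal(0.0, fraction_step, size=C)
            f_prop = np.clip(f_prop, 0.0, None)
            s = f_prop.sum()
            if s > 0:
                f_prop = f_prop / s
                prop_ll = total(lm, f_prop)
                if prop_ll - cur_ll >= 0 or rng.random() < np.exp(prop_ll - cur_ll):
                    fractions = f_prop
                    cur_ll = prop_ll
                    n_accepted += 1
        seq_out[t] = positions
        frac_out[t] = fractions
        ll_out[t] = cur_ll

    return MCMCTrace(sequences=seq_out.astype(int), fractions=frac_out,
                     log_likelihoods=ll_out, n_accepted=n_accepted,
                     roi_names=tuple(roi_names))


# ---------------------------------------------------------------------------
# cross-validated model selection


def _heldout_scores(Z_test: np.ndarray, trace: MCMCTrace, model: SubtypeModel,
                    thin: int = 1) -> np.ndarray:
    """Per-subject log of the MCMC-averaged mixture likelihood."""
    n = Z_test.shape[0]
    E = model.n_events
    log_stage_prior = -np.log(E + 1)
    cache: dict = {}
    idx = np.arange(0, trace.n_samples, thin)
    per_sample = np.empty((idx.size, n))
    for j, t in enumerate(idx):
        cols = []
        for c in range(model.n_subtypes):
            key = tuple(trace.sequences[t, c])
            if key not in cache:
                ll = _stage_log_likelihoods(Z_test, np.asarray(key),
                                            model.z_cut, model.z_max,
                                            model.sigma)
                cache[key] = logsumexp(ll, axis=1) + log_stage_prior
            cols.append(cache[key])
        lm = np.stack(cols, axis=1)
        with np.errstate(divide="ignore"):
            per_sample[j] = logsumexp(
                lm + np.log(trace.fractions[t])[None, :], axis=1)
    return logsumexp(per_sample, axis=0) - np.log(idx.size)


def cvic(Z: np.ndarray, C_range=(1, 2, 3, 4), n_folds: int = 10, *,
         z_cut, z_max, sigma=None, n_restarts: int = 10,
         mcmc_samples: int = 1000, seed=None, roi_names=ROI_NAMES,
         use_mcmc_average: bool = True, keep_fold_models: bool = True,
         max_em_iter: int = 30) -> CVICResult:
    """Choose the number of subtypes by ten-fold cross-validation.

    CVIC(C) = -2 x (sum over held-out subjects of the log MCMC-averaged
    mixture likelihood under the model fitted to the training folds); the
    selected C minimises CVIC.  With ``use_mcmc_average=False`` the held-out
    score uses only the maximum-likelihood fold model.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValueError("need 2 <= n_folds <= n_subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    sigma_arr = np.ones(Z.shape[1]) if sigma is None else np.asarray(sigma)

    cvic_vals: dict = {}
    fold_ll: dict = {}
    fold_models: dict = {}
    for C in C_range:
        scores = []
        models_c = []
        for f, test_idx in enumerate(folds):
            if test_idx.size == 0:
                raise ValueError("degenerate fold with no subjects")
            train_idx = np.setdiff1d(perm, test_idx)
            sub_seed = int(rng.integers(2**31))
            model = fit_subtypes(Z[train_idx], C, z_cut=z_cut, z_max=z_max,
                                 sigma=sigma_arr, n_restarts=n_restarts,
                                 seed=sub_seed, roi_names=roi_names,
                                 max_em_iter=max_em_iter)
            if use_mcmc_average and mcmc_samples > 0:
                trace = mcmc_sample(Z[train_idx], model, mcmc_samples,
                                    seed=sub_seed + 1)
                sc = _heldout_scores(Z[test_idx], trace, model)
            else:
                lm = _subject_log_marginals(Z[test_idx], model)
                with np.errstate(divide="ignore"):
                    sc = logsumexp(lm + np.log(model.fractions)[None, :],
                                   axis=1)
            scores.append(float(sc.sum()))
            models_c.append(model)
        fold_ll[C] = scores
        cvic_vals[C] = -2.0 * sum(scores)
        if keep_fold_models:
            fold_models[C] = models_c
    selected = min(cvic_vals, key=lambda c: cvic_vals[c])
    return CVICResult(cvic=cvic_vals, fold_test_loglik=fold_ll,
                      selected=selected, fold_models=fold_models)


# ---------------------------------------------------------------------------
# estimator facade


class SubtypeStageModel(BaseEstimator):
    """Subtype-and-stage mixture estimator with a scikit-learn interface.

    Parameters
    ----------
    n_subtypes : int, default 2
        Number of latent subtypes (event sequences), at most 4.
    z_cut, z_max : array-like of shape (n_events,) or None
        Abnormality threshold and late-stage ceiling per ROI, in z units.
        When ``z_max`` is None it is derived from the data at fit time as
        max(95th percentile of the ROI's z-scores, z_cut + 0.5).
    sigma : array-like or None
        Residual SD per ROI in z units; None means 1 for every ROI.
    n_restarts : int, default 25
        Greedy-fit restarts (also bipartition trials per split).
    random_state : int or None
        Seed for all fitting randomness.

    Attributes
    ----------
    model_ : SubtypeModel
    sequences_ : list of EventSequence
    fractions_ : ndarray of shape (n_subtypes,)
    log_likelihood_ : float
    """

    def __init__(self, n_subtypes: int = 2, z_cut=None, z_max=None,
                 sigma=None, n_restarts: int = 25, random_state=None,
                 roi_names=ROI_NAMES):
        self.n_subtypes = n_subtypes
        self.z_cut = z_cut
        self.z_max = z_max
        self.sigma = sigma
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.roi_names = roi_names

    # -- helpers -----------------------------------------------------------
    def _resolve_thresholds(self, Z: np.ndarray):
        if self.z_cut is None:
            raise ValueError("z_cut must be provided (calibrate with "
                             "preprocess.regional_cutoffs)")
        z_cut = np.asarray(self.z_cut, dtype=float)
        if self.z_max is None:
            z_max = np.maximum(np.percentile(Z, 95, axis=0), z_cut + 0.5)
        else:
            z_max = np.asarray(self.z_max, dtype=float)
        sigma = (np.ones(Z.shape[1]) if self.sigma is None
                 else np.asarray(self.sigma, dtype=float))
        return z_cut, z_max, sigma

    @staticmethod
    def _as_array(X) -> np.ndarray:
        X = np.asarray(getattr(X, "values", X), dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D z-score matrix")
        return X

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None):
        Z = self._as_array(X)
        z_cut, z_max, sigma = self._resolve_thresholds(Z)
        self.model_ = fit_subtypes(
            Z, self.n_subtypes, z_cut=z_cut, z_max=z_max, sigma=sigma,
            n_restarts=self.n_restarts, seed=self.random_state,
            roi_names=tuple(self.roi_names))
        self.sequences_ = self.model_.sequences
        self.fractions_ = self.model_.fractions
        self.log_likelihood_ = self.model_.log_likelihood
        self.n_features_in_ = Z.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")

    def joint_posterior(self, X) -> np.ndarray:
        """P(subtype c, stage k | z_n); shape (n, C, E+1), rows sum to 1."""
        self._check_fitted()
        Z = self._as_array(X)
        ll = _subtype_stage_ll(Z, self.model_)
        with np.errstate(divide="ignore"):
            ll = ll + np.log(self.model_.fractions)[None, :, None]
        flat = ll.reshape(Z.shape[0], -1)
        post = np.exp(flat - logsumexp(flat, axis=1)[:, None])
        return post.reshape(ll.shape)

    def predict_proba(self, X) -> np.ndarray:
        """Posterior subtype membership, marginalised over stages."""
        return self.joint_posterior(X).sum(axis=2)

    def predict(self, X) -> np.ndarray:
        """Most-probable subtype index (0-based) per subject."""
        return np.argmax(self.predict_proba(X), axis=1)

    def predict_stage(self, X) -> np.ndarray:
        """Most-probable stage of the joint (subtype, stage) posterior."""
        post = self.joint_posterior(X)
        n, C, K = post.shape
        # argmax with ties resolved toward the lower stage then lower subtype
        flat = post.transpose(0, 2, 1).reshape(n, -1)
        best = np.argmax(flat, axis=1)
        return best // C

    def score(self, X, y=None) -> float:
        """Mean per-subject log-likelihood."""
        self._check_fitted()
        Z = self._as_array(X)
        return log_likelihood(Z, self.model_) / Z.shape[0]

    def sample_posterior(self, X, n_samples: int = 100_000,
                         seed=None) -> MCMCTrace:
        """MCMC over sequences/fractions around the fitted model."""
        self._check_fitted()
        return mcmc_sample(self._as_array(X), self.model_, n_samples,
                           seed=self.random_state if seed is None else seed)
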