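"""Chromatin-state segmentation over binned ChIP signals.

The segmentation follows the classic binarize-then-segment recipe: each
mark's bin counts are thresholded against a Poisson background whose
rate is the genome-wide mean count per bin (a bin is "on" when its
count is improbably high at tail probability <= ``p_threshold``), and a
hidden Markov model with independent Bernoulli emissions per mark is
fitted to the resulting binary matrix by Baum-Welch. Chromosomes are
independent observation sequences; decoding is Viterbi (posterior
optional). States that occupy almost none of the genome and emit almost
nothing can be merged into a single quiescent class, the usual way
near-empty classes are collapsed before a segmentation is displayed.

All recursions run on scaled probabilities (log-likelihood accumulated
from the scaling factors), which is algebraically equivalent to the
log-space formulation and considerably faster in numpy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .core_io import BinnedTrackSet

logger = logging.getLogger(__name__)

_B_EPS = 1e-6  # Bernoulli parameters clipped to [eps, 1-eps]


@dataclass
class BinaryTrackSet:
    """Per-chromosome (n_bins x M) 0/1 matrices, one column per mark."""

    bin_size: int
    marks: list[str]
    bits: dict[str, np.ndarray]
    thresholds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.bits.items():
            arr = np.asarray(arr)
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{chrom}: non-binary entries")
            self.bits[chrom] = arr.astype(np.uint8)

    @property
    def chroms(self) -> list[str]:
        return list(self.bits)

    @property
    def n_bins_total(self) -> int:
        return int(sum(a.shape[0] for a in self.bits.values()))


@dataclass
class StateModel:
    """HMM parameters: K states over M independent Bernoulli emission tracks."""

    pi: np.ndarray          # (K,) initial distribution
    A: np.ndarray           # (K, K) transition matrix, row-stochastic
    B: np.ndarray           # (K, M) Bernoulli emission probabilities
    marks: list[str]
    trained_loglik: float = np.nan

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        K = self.pi.shape[0]
        if self.A.shape != (K, K) or self.B.shape[0] != K:
            raise ValueError("inconsistent pi/A/B shapes")
        if abs(self.pi.sum() - 1) > 1e-10 or np.abs(self.A.sum(axis=1) - 1).max() > 1e-10:
            raise ValueError("pi and rows of A must sum to 1 (tol 1e-10)")
        if (self.B < 0).any() or (self.B > 1).any():
            raise ValueError("B entries must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.pi.shape[0]


@dataclass
class StatePath:
    """Per-chromosome 0-based state labels (and optional posteriors)."""

    states: dict[str, np.ndarray]
    n_states: int
    posterior: dict[str, np.ndarray] | None = None

    def occupancy(self) -> np.ndarray:
        """Genome-wide fraction of bins per state."""
        counts = np.zeros(self.n_states)
        for arr in self.states.values():
            counts += np.bincount(arr, minlength=self.n_states)
        return counts / max(1, sum(len(a) for a in self.states.values()))


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def poisson_threshold(lam: float, p_threshold: float) -> int:
    """Smallest count c with P(X >= c | Poisson(lam)) <= p_threshold."""
    if lam <= 0:
        return 1  # unreachable by all-zero data; every positive count flags
    c = int(poisson.isf(p_threshold, lam)) + 1
    while c > 1 and poisson.sf(c - 2, lam) <= p_threshold:
        c -= 1
    while poisson.sf(c - 1, lam) > p_threshold:
        c += 1
    return c


def binarize(tracks: BinnedTrackSet, p_threshold: float = 1e-4) -> BinaryTrackSet:
    """Poisson-background binarization of every mark.

    The background rate per mark is its genome-wide mean count per bin;
    bin bit = 1 iff the upper-tail probability of its count under that
    Poisson background is <= ``p_threshold``.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")
    n_total = sum(a.shape[0] for a in tracks.counts.values())
    thresholds: dict[str, int] = {}
    for j, mark in enumerate(tracks.marks):
        lam = sum(a[:, j].sum() for a in tracks.counts.values()) / n_total
        if lam == 0:
            logger.warning("mark %s has zero genome-wide signal; all bits 0", mark)
        thresholds[mark] = poisson_threshold(lam, p_threshold)
    cut = np.array([thresholds[m] for m in tracks.marks])
    bits = {chrom: (arr >= cut).astype(np.uint8) for chrom, arr in tracks.counts.items()}
    return BinaryTrackSet(tracks.bin_size, list(tracks.marks), bits, thresholds)


# ---------------------------------------------------------------------------
# Forward-backward / Baum-Welch
# ---------------------------------------------------------------------------

def _emission_probs(bits: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(T, K) per-bin emission likelihoods under independent Bernoullis."""
    Bc = np.clip(B, _B_EPS, 1 - _B_EPS)
    logem = bits @ np.log(Bc).T + (1 - bits) @ np.log1p(-Bc).T
    return np.exp(logem)


def _forward(em: np.ndarray, pi: np.ndarray, A: np.ndarray):
    """Scaled forward pass; returns (alpha, scales, loglik)."""
    T, K = em.shape
    alpha = np.empty((T, K))
    scales = np.empty(T)
    a = pi * em[0]
    scales[0] = a.sum()
    alpha[0] = a / scales[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * em[t]
        scales[t] = a.sum()
        alpha[t] = a / scales[t]
    return alpha, scales, float(np.log(scales).sum())


def _backward(em: np.ndarray, A: np.ndarray, scales: np.ndarray):
    T, K = em.shape
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (em[t + 1] * beta[t + 1])) / scales[t + 1]
    return beta


def forward_loglik(model: StateModel, bits: BinaryTrackSet) -> float:
    """Total log-likelihood of the binary data (sum over chromosomes)."""
    total = 0.0
    for arr in bits.bits.values():
        em = _emission_probs(arr.astype(float), model.B)
        total += _forward(em, model.pi, model.A)[2]
    return total


def backward_loglik(model: StateModel, bits: BinaryTrackSet) -> float:
    """Log-likelihood recomputed from the backward recursion (cross-check)."""
    total = 0.0
    for arr in bits.bits.values():
        em = _emission_probs(arr.astype(float), model.B)
        # unscaled backward in log space via rescaling trick
        T, K = em.shape
        beta = np.ones(K)
        log_c = 0.0
        for t in range(T - 1, 0, -1):
            beta = model.A @ (em[t] * beta)
            s = beta.sum()
            beta /= s
            log_c += np.log(s)
        total += log_c + np.log((model.pi * em[0] * beta).sum())
    return total


def _init_model(bits: BinaryTrackSet, K: int, rng: np.random.Generator,
                prototype: bool = False) -> StateModel:
    """Random emission initialization, sticky-uniform transitions.

    Two alternating styles: perturbed genome-wide mark frequencies, and
    "prototype" rows copied from randomly drawn observed bin profiles
    (blended toward the mean) — the latter gives EM a basin around rare
    but distinct signatures that frequency perturbations rarely reach.
    """
    M = len(bits.marks)
    n = bits.n_bins_total
    freq = sum(a.sum(axis=0) for a in bits.bits.values()) / n
    if prototype:
        stacked = np.vstack(list(bits.bits.values()))
        idx = rng.integers(0, n, size=K)
        B = 0.7 * stacked[idx] + 0.3 * freq[None, :] \
            + rng.uniform(-0.05, 0.05, size=(K, M))
    else:
        B = (freq[None, :]
             + rng.uniform(-0.4, 0.4, size=(K, M)) * (freq + 0.05)[None, :]
             + rng.uniform(0, 0.3, size=(K, M)))
    B = np.clip(B, _B_EPS, 1 - _B_EPS)
    A = np.full((K, K), 0.1 / max(1, K - 1))
    np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
    A /= A.sum(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)
    return StateModel(pi, A, B, list(bits.marks))


def train_hmm(bits: BinaryTrackSet, K: int = 16, n_restarts: int = 5, seed: int = 0,
              tol: float = 1e-4, max_iter: int = 300) -> StateModel:
    """Fit a K-state Bernoulli-emission HMM by Baum-Welch.

    Each chromosome is an independent sequence. The best of
    ``n_restarts`` random initializations (by final log-likelihood) is
    returned; results are deterministic given ``seed``. The EM
    log-likelihood is asserted non-decreasing at every step.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > bits.n_bins_total:
        raise ValueError(f"K={K} exceeds the {bits.n_bins_total} available bins")
    seqs = [arr.astype(float) for arr in bits.bits.values()]
    rng = np.random.default_rng(seed)
    best: StateModel | None = None
    for restart in range(max(1, n_restarts)):
        model = _init_model(bits, K, rng, prototype=restart % 2 == 1)
        prev_ll = -np.inf
        for _ in range(max_iter):
            ll = 0.0
            pi_acc = np.zeros(K)
            trans_num = np.zeros((K, K))
            emit_num = np.zeros((K, len(bits.marks)))
            gamma_sum = np.zeros(K)
            for x in seqs:
                em = _emission_probs(x, model.B)
                alpha, scales, seq_ll = _forward(em, model.pi, model.A)
                beta = _backward(em, model.A, scales)
                gamma = alpha * beta
                gamma /= gamma.sum(axis=1, keepdims=True)
                ll += seq_ll
                pi_acc += gamma[0]
                if len(x) > 1:
                    # xi summed over t, unnormalized then scaled per step
                    xi = (alpha[:-1, :, None] * model.A[None, :, :]
                          * (em[1:] * beta[1:])[:, None, :] / scales[1:, None, None])
                    trans_num += xi.sum(axis=0)
                emit_num += gamma.T @ x
                gamma_sum += gamma.sum(axis=0)
            assert ll >= prev_ll - 1e-8, "EM log-likelihood decreased"
            converged = ll - prev_ll < tol and np.isfinite(prev_ll)
            prev_ll = ll
            # M-step
            model = StateModel(
                pi=pi_acc / pi_acc.sum(),
                A=(trans_num / np.maximum(trans_num.sum(axis=1, keepdims=True), 1e-300)
                   if K > 1 else np.ones((1, 1))),
                B=np.clip(emit_num / gamma_sum[:, None], _B_EPS, 1 - _B_EPS),
                marks=list(bits.marks),
                trained_loglik=ll,
            )
            if converged:
                break
        if best is None or model.trained_loglik > best.trained_loglik:
            best = model
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def decode(model: StateModel, bits: BinaryTrackSet, method: str = "viterbi") -> StatePath:
    """Per-bin state assignment: Viterbi (default) or posterior decoding."""
    if method not in ("viterbi", "posterior"):
        raise ValueError(f"unknown decoding method {method!r}")
    states: dict[str, np.ndarray] = {}
    posteriors: dict[str, np.ndarray] = {}
    logA = np.log(np.maximum(model.A, 1e-300))
    logpi = np.log(np.maximum(model.pi, 1e-300))
    for chrom, arr in bits.bits.items():
        x = arr.astype(float)
        em = _emission_probs(x, model.B)
        logem = np.log(np.maximum(em, 1e-300))
        T, K = logem.shape
        if method == "viterbi":
            delta = logpi + logem[0]
            back = np.zeros((T, K), dtype=np.int64)
            for t in range(1, T):
                cand = delta[:, None] + logA
                back[t] = cand.argmax(axis=0)
                delta = cand.max(axis=0) + logem[t]
            path = np.empty(T, dtype=np.int64)
            path[-1] = int(delta.argmax())
            for t in range(T - 1, 0, -1):
                path[t - 1] = back[t, path[t]]
            states[chrom] = path
        else:
            alpha, scales, _ = _forward(em, model.pi, model.A)
            beta = _backward(em, model.A, scales)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            states[chrom] = gamma.argmax(axis=1)
            posteriors[chrom] = gamma
    return StatePath(states, model.K, posteriors or None)


# ---------------------------------------------------------------------------
# Sparse-state merging
# ---------------------------------------------------------------------------

def merge_sparse_states(model: StateModel, path: StatePath,
                        occupancy_floor: float = 0.005,
                        emission_ceiling: float = 0.05) -> tuple[StateModel, StatePath]:
    """Collapse near-empty, near-silent states into one quiescent class.

    A state is merged when its genome occupancy is below
    ``occupancy_floor`` AND its strongest emission probability is below
    ``emission_ceiling``. Surviving classes (plus the merged quiescent
    class, if any) are renumbered by descending occupancy.
    """
    occ = path.occupancy()
    sparse = (occ < occupancy_floor) & (model.B.max(axis=1) < emission_ceiling)
    if sparse.all():
        raise ValueError("merging would remove every state")
    keep = np.flatnonzero(~sparse)
    merged = np.flatnonzero(sparse)
    if merged.size == 0:
        order = np.argsort(-occ, kind="stable")
        relabel = np.empty(model.K, dtype=np.int64)
        relabel[order] = np.arange(model.K)
        new_model = StateModel(model.pi[order] / model.pi[order].sum(),
                               model.A[np.ix_(order, order)]
                               / model.A[np.ix_(order, order)].sum(axis=1, keepdims=True),
                               model.B[order], list(model.marks), model.trained_loglik)
        return new_model, StatePath({c: relabel[a] for c, a in path.states.items()},
                                    model.K)
    # group map: old state -> new group index (pre-ordering)
    groups = [np.array([s]) for s in keep] + [merged]
    n_new = len(groups)
    w = np.maximum(occ, 1e-12)
    pi_new = np.array([model.pi[g].sum() for g in groups])
    B_new = np.array([(model.B[g] * w[g, None]).sum(axis=0) / w[g].sum() for g in groups])
    A_new = np.empty((n_new, n_new))
    for i, gi in enumerate(groups):
        row = (model.A[gi] * w[gi, None]).sum(axis=0) / w[gi].sum()
        A_new[i] = [row[gj].sum() for gj in groups]
    A_new /= A_new.sum(axis=1, keepdims=True)
    occ_new = np.array([occ[g].sum() for g in groups])
    order = np.argsort(-occ_new, kind="stable")
    rank = np.empty(n_new, dtype=np.int64)
    rank[order] = np.arange(n_new)
    old_to_new = np.empty(model.K, dtype=np.int64)
    for i, g in enumerate(groups):
        old_to_new[g] = rank[i]
    new_model = StateModel(pi_new[order] / pi_new[order].sum(),
                           A_new[np.ix_(order, order)], B_new[order],
                           list(model.marks), model.trained_loglik)
    new_path = StatePath({c: old_to_new[a] for c, a in path.states.items()}, n_new)
    logger.info("merged %d near-empty states into one quiescent class", merged.size)
    return new_model, new_path


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: StateModel) -> dict:
    return {"pi": model.pi.tolist(), "A": model.A.tolist(), "B": model.B.tolist(),
            "marks": list(model.marks), "trained_loglik": model.trained_loglik}


def model_from_dict(d: dict) -> StateModel:
    return StateModel(np.array(d["pi"]), np.array(d["A"]), np.array(d["B"]),
                      list(d["marks"]), float(d.get("trained_loglik", np.nan)))


def path_to_bed(path: StatePath, bin_size: int, out_path) -> None:
    """Write the decoded path as BED with one line per run of equal class."""
    with open(out_path, "w") as fh:
        for chrom, arr in path.states.items():
            if len(arr) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(arr)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * bin_size}\t{e * bin_size}\tclass_{arr[s] + 1}\n")
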