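"""Joint multivariate Bernoulli-emission hidden Markov model.

A single K-state model is learned from the pooled binary observation
sequences of both sexes (each chromosome of each sex is an independent
sequence sharing one parameter set).  Emissions are per-state per-mark
Bernoulli probabilities; fitting is Baum-Welch EM with scaled
forward-backward recursions; decoding assigns each bin the state with
maximal posterior probability (Viterbi offered as an option).  The number
of states is chosen by fitting a reference model with many states and
tracking, for smaller models, how well each reference state's emission
profile is recovered (best Pearson correlation across states).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment

EMISSION_EPS = 1e-6


@dataclass
class BernoulliHMM:
    emission: np.ndarray      # (K, M) in [eps, 1-eps]
    transition: np.ndarray    # (K, K) row-stochastic
    initial: np.ndarray       # (K,)
    marks: list[str]
    seed: int | None = None
    n_iter: int = 0
    log_likelihood: float = float("nan")
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        K, M = self.emission.shape
        if self.transition.shape != (K, K) or self.initial.shape != (K,):
            raise ValueError("inconsistent parameter shapes")
        if len(self.marks) != M:
            raise ValueError("mark names do not match emission columns")
        if np.any(self.emission < EMISSION_EPS - 1e-12) or np.any(
                self.emission > 1 - EMISSION_EPS + 1e-12):
            raise ValueError("emission probabilities outside [eps, 1-eps]")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.emission.shape[0]

    @property
    def state_names(self) -> list[str]:
        return [f"E{k + 1}" for k in range(self.n_states)]

    # -- serialization as a TSV bundle -------------------------------------
    def save(self, prefix) -> None:
        prefix = str(prefix)
        pd.DataFrame(self.emission, index=self.state_names, columns=self.marks) \
            .to_csv(prefix + ".emission.tsv", sep="\t")
        pd.DataFrame(self.transition, index=self.state_names, columns=self.state_names) \
            .to_csv(prefix + ".transition.tsv", sep="\t")
        pd.DataFrame({"state": self.state_names, "initial": self.initial}) \
            .to_csv(prefix + ".initial.tsv", sep="\t", index=False)
        meta = pd.DataFrame(
            {"key": ["seed", "n_iter", "log_likelihood", "n_states"],
             "value": [self.seed, self.n_iter, self.log_likelihood, self.n_states]})
        meta.to_csv(prefix + ".meta.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, prefix) -> "BernoulliHMM":
        prefix = str(prefix)
        em = pd.read_csv(prefix + ".emission.tsv", sep="\t", index_col=0)
        tr = pd.read_csv(prefix + ".transition.tsv", sep="\t", index_col=0)
        init = pd.read_csv(prefix + ".initial.tsv", sep="\t")
        meta = pd.read_csv(prefix + ".meta.tsv", sep="\t").set_index("key")["value"]
        return cls(emission=em.to_numpy(), transition=tr.to_numpy(),
                   initial=init["initial"].to_numpy(), marks=list(em.columns),
                   seed=None if pd.isna(meta.get("seed")) else int(float(meta["seed"])),
                   n_iter=int(float(meta["n_iter"])),
                   log_likelihood=float(meta["log_likelihood"]))


@dataclass
class Segmentation:
    """Bin-aligned, sorted, non-overlapping tiles covering each chromosome."""

    tiles: pd.DataFrame  # columns: chromosome, start, end, state
    bin_size: int = 200
    sample: str = ""

    def states_for(self, chromosome: str) -> pd.DataFrame:
        return self.tiles[self.tiles["chromosome"] == chromosome]


# ---------------------------------------------------------------------------
# Scaled forward-backward (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward(b, a, pi):
    T, K = b.shape
    alpha = np.empty((T, K))
    scale = np.empty(T)
    av = pi * b[0]
    s = av.sum()
    scale[0] = s
    alpha[0] = av / s
    for t in range(1, T):
        av = (alpha[t - 1] @ a) * b[t]
        s = av.sum()
        scale[t] = s
        alpha[t] = av / s
    return alpha, scale


@njit(cache=True)
def _backward(b, a, scale):
    T, K = b.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (a @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    return beta


@njit(cache=True)
def _xi_sums(b, a, alpha, beta, scale):
    T, K = b.shape
    xi = np.zeros((K, K))
    for t in range(T - 1):
        w = b[t + 1] * beta[t + 1] / scale[t + 1]
        for i in range(K):
            xi[i] += alpha[t, i] * a[i] * w
    return xi


def _emission_probs(X: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """P(x_t | state k) for every t, k; X is (T, M) in {0,1}."""
    logE = np.log(emission)
    log1E = np.log1p(-emission)
    logb = X @ logE.T + (1 - X) @ log1E.T
    # subtract per-row max for numerical headroom before exponentiation
    logb -= logb.max(axis=1, keepdims=True)
    return np.exp(logb), logb


def forward_backward(model: BernoulliHMM, X: np.ndarray):
    """Posterior state probabilities and total log-likelihood for one sequence."""
    X = np.asarray(X, dtype=float)
    b, logb_shift = _emission_probs(X, model.emission)
    alpha, scale = _forward(b, model.transition, model.initial)
    beta = _backward(b, model.transition, scale)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # undo the per-row shift: true loglik = sum(log scale) + sum(row maxima)
    X2 = np.asarray(X)
    logE = np.log(model.emission)
    log1E = np.log1p(-model.emission)
    row_max = (X2 @ logE.T + (1 - X2) @ log1E.T).max(axis=1)
    loglik = float(np.log(scale).sum() + row_max.sum())
    return gamma, loglik


def _as_sequences(observations) -> tuple[list[np.ndarray], list[str]]:
    """Pool BinaryMatrix objects (one per sex) into independent sequences."""
    from chromsig.io_tracks import BinaryMatrix

    if isinstance(observations, BinaryMatrix):
        observations = [observations]
    marks = None
    seqs: list[np.ndarray] = []
    for bm in observations:
        if marks is None:
            marks = list(bm.marks)
        elif list(bm.marks) != marks:
            raise ValueError("mark order mismatch between observation sets")
        seqs.extend(np.asarray(s, dtype=float) for s in bm.sequences())
    if not seqs:
        raise ValueError("no observation sequences")
    return seqs, marks


def fit_hmm(
    observations,
    K: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> BernoulliHMM:
    """Baum-Welch fit of a K-state Bernoulli-emission HMM.

    ``observations`` is one BinaryMatrix or a list of them (e.g. one per sex);
    every chromosome of every matrix is an independent sequence sharing the one
    parameter set.  Emissions are initialized uniformly in [0.1, 0.9] from the
    seeded generator; transition rows and the initial distribution start
    uniform.  Stops when the total log-likelihood improves by less than ``tol``
    or after ``max_iter`` iterations.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    seqs, marks = _as_sequences(observations)
    M = len(marks)
    rng = np.random.default_rng(seed)
    emission = rng.uniform(0.1, 0.9, size=(K, M))
    transition = np.full((K, K), 1.0 / K)
    initial = np.full(K, 1.0 / K)

    ll_history: list[float] = []
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        total_ll = 0.0
        init_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        em_num = np.zeros((K, M))
        em_den = np.zeros(K)
        for X in seqs:
            b, _ = _emission_probs(X, emission)
            alpha, scale = _forward(b, transition, initial)
            beta = _backward(b, transition, scale)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            logE = np.log(emission)
            log1E = np.log1p(-emission)
            row_max = (X @ logE.T + (1 - X) @ log1E.T).max(axis=1)
            total_ll += float(np.log(scale).sum() + row_max.sum())
            init_acc += gamma[0]
            if len(X) > 1 and K > 1:
                xi_acc += _xi_sums(b, transition, alpha, beta, scale)
            em_num += gamma.T @ X
            em_den += gamma.sum(axis=0)
        ll_history.append(total_ll)
        # M step
        initial = init_acc / init_acc.sum()
        if K == 1:
            transition = np.ones((1, 1))
        elif xi_acc.sum() > 0:
            rows = xi_acc.sum(axis=1, keepdims=True)
            transition = np.where(rows > 0, xi_acc / np.where(rows > 0, rows, 1.0),
                                  1.0 / K)
        emission = np.clip(em_num / em_den[:, None], EMISSION_EPS, 1 - EMISSION_EPS)
        if len(ll_history) >= 2 and ll_history[-1] - ll_history[-2] < tol:
            break

    return BernoulliHMM(
        emission=emission, transition=transition, initial=initial, marks=marks,
        seed=seed, n_iter=n_iter, log_likelihood=ll_history[-1],
        ll_history=ll_history)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def posterior_decode_states(model: BernoulliHMM, X: np.ndarray) -> np.ndarray:
    gamma, _ = forward_backward(model, X)
    # ties broken by lowest state index (argmax returns the first maximum)
    return np.argmax(np.round(gamma, 12), axis=1)


def viterbi_states(model: BernoulliHMM, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    logE = np.log(model.emission)
    log1E = np.log1p(-model.emission)
    logb = X @ logE.T + (1 - X) @ log1E.T
    logA = np.log(model.transition + 1e-300)
    T, K = logb.shape
    delta = np.log(model.initial + 1e-300) + logb[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logb[t]
    states = np.empty(T, dtype=np.int64)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    return states


def decode(model: BernoulliHMM, observations, method: str = "posterior") -> Segmentation:
    """Segment a per-sex BinaryMatrix into state tiles.

    Per-bin state is the posterior argmax (default) or the Viterbi path;
    consecutive equal-state bins merge into tiles; the trailing partial bin
    is clipped to nothing here because bin boundaries define tile ends.
    """
    from chromsig.io_tracks import BinaryMatrix

    if not isinstance(observations, BinaryMatrix):
        raise TypeError("decode expects a BinaryMatrix")
    if list(observations.marks) != list(model.marks):
        raise ValueError("mark order mismatch between model and observations")
    decoder = viterbi_states if method == "viterbi" else posterior_decode_states
    rows = []
    bs = observations.bin_size
    for chrom, X in observations.data.items():
        states = decoder(model, X.astype(float))
        # run-length encode
        change = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(states)]])
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s) * bs, int(e) * bs, f"E{states[s] + 1}"))
    tiles = pd.DataFrame(rows, columns=["chromosome", "start", "end", "state"])
    return Segmentation(tiles=tiles, bin_size=bs, sample=observations.sample)


# ---------------------------------------------------------------------------
# Model comparison and state-count selection
# ---------------------------------------------------------------------------

def _emission_correlation(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
    """Pearson correlation between every emission row of a and of b.
    Constant rows get correlation 0 by convention."""
    a = ea - ea.mean(axis=1, keepdims=True)
    b = eb - eb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    corr = np.zeros((ea.shape[0], eb.shape[0]))
    ok = np.outer(na > 1e-12, nb > 1e-12)
    denom = np.outer(np.where(na > 1e-12, na, 1.0), np.where(nb > 1e-12, nb, 1.0))
    corr = np.where(ok, (a @ b.T) / denom, 0.0)
    return corr


def state_similarity(model_a: BernoulliHMM, model_b: BernoulliHMM) -> pd.DataFrame:
    """Best-matching state of model_b for every state of model_a, by Pearson
    correlation of emission profiles."""
    if list(model_a.marks) != list(model_b.marks):
        raise ValueError("mark sets differ between models")
    corr = _emission_correlation(model_a.emission, model_b.emission)
    best = corr.argmax(axis=1)
    return pd.DataFrame({
        "state_a": model_a.state_names,
        "best_state_b": [f"E{j + 1}" for j in best],
        "correlation": corr[np.arange(corr.shape[0]), best],
    })


def match_states(emission_true: np.ndarray, emission_fit: np.ndarray) -> np.ndarray:
    """One-to-one assignment of fitted states to true states maximizing total
    emission correlation (Hungarian algorithm); returns, per true state, the
    index of its matched fitted state."""
    corr = _emission_correlation(emission_true, emission_fit)
    rows, cols = linear_sum_assignment(-corr)
    out = np.empty(emission_true.shape[0], dtype=int)
    out[rows] = cols
    return out


def select_state_count(
    observations,
    k_max: int = 17,
    k_min: int = 8,
    seed: int = 0,
    similarity_floor: float = 0.9,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of states by emission-recovery correlation.

    Fits the ``k_max``-state reference model, then each smaller model down to
    ``k_min``; for every reference state records the best emission correlation
    in the smaller model, and reports the per-k minimum over reference states.
    The chosen K is the smallest k whose minimum correlation still reaches
    ``similarity_floor`` (i.e. the smallest model that retains every reference
    state); if no k qualifies the reference ``k_max`` is kept.
    """
    if k_min < 1 or k_min > k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    reference = fit_hmm(observations, K=k_max, seed=seed, max_iter=max_iter, tol=tol)
    rows = []
    models = {k_max: reference}
    for k in range(k_max - 1, k_min - 1, -1):
        m = fit_hmm(observations, K=k, seed=seed, max_iter=max_iter, tol=tol)
        models[k] = m
        sim = state_similarity(reference, m)
        rows.append((k, float(sim["correlation"].min()), float(sim["correlation"].mean())))
    curve = pd.DataFrame(rows, columns=["k", "min_correlation", "mean_correlation"])
    qualifying = curve[curve["min_correlation"] >= similarity_floor]["k"]
    chosen = int(qualifying.min()) if len(qualifying) else k_max
    return chosen, curve
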