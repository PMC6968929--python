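"""Bayesian nonparametric inference of progenitor types from layer occupancy.

Model
-----
Each lineage *i* is assigned a progenitor type ``t_i`` drawn from a
categorical distribution with frequencies ``f``; its occupancy count in
layer *j* is ``S_ij ~ Binomial(N_max, p_{t_i, j})`` with ``N_max = 20`` the
cap on neurons per layer per lineage.  A binary selection mask ``sigma_ij``
censors, for each lineage, the most superficial run of empty layers: such
zeros may be spurious, reflecting an external interruption of the lineage
rather than its generative program.  The joint likelihood of assignments and
counts is::

    P(t, S | p, f) = (prod_t f_t^{n_t})
                     * prod_{i,j} [ p_{t_i j}^{S_ij} (1-p_{t_i j})^{N_max-S_ij} ]^{sigma_ij}

(the binomial coefficient, constant in all parameters, is omitted).  Beta
priors on the occupancy probabilities and a Dirichlet-process prior over
types let a Gibbs sampler remove existing types or introduce new ones, so
the number of types K is itself inferred.  The type-assignment step is an
auxiliary-component (Chinese-restaurant-process) sampler with ``n_aux``
fresh candidate types per update; occupancy probabilities are conjugately
resampled from ``Beta(a + sum sigma*S, b + sum sigma*(N_max - S))``.

Arrays are in canonical generation order (VI, V, IV, II/III).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from .lineage import GENERATION_ORDER, LayerCounts, Lineage

__all__ = [
    "DirichletProcessBinomialMixture",
    "PosteriorSamples",
    "selection_mask",
    "log_likelihood",
    "gibbs_sweep",
    "run_inference",
    "progenitor_count_distribution",
    "posterior_predictive",
    "crp_expected_k",
    "lineages_to_occupancy",
]


def lineages_to_occupancy(dataset: Sequence[Lineage]) -> np.ndarray:
    """Stack lineages into an N x 4 occupancy matrix in generation order."""
    return np.array(
        [lin.counts.as_array(GENERATION_ORDER) for lin in dataset], dtype=np.int64
    )


def _validate_counts(S: np.ndarray, n_max: int) -> np.ndarray:
    S = np.asarray(S)
    if S.ndim != 2 or S.shape[1] != 4:
        raise ValueError(f"occupancy matrix must be N x 4, got shape {S.shape}")
    if not np.issubdtype(S.dtype, np.integer):
        if np.any(S != np.floor(S)):
            raise ValueError("occupancy counts must be integers")
        S = S.astype(np.int64)
    if np.any(S < 0):
        raise ValueError("occupancy counts must be non-negative")
    if np.any(S > n_max):
        raise ValueError(
            f"occupancy count {S.max()} exceeds the per-layer cap N_max={n_max}"
        )
    return S.astype(np.int64)


def selection_mask(S: np.ndarray) -> np.ndarray:
    """Censoring mask: drop each lineage's terminal superficial zeros.

    Scanning from the most superficial layer (II/III) toward deep, empty
    layers are masked (sigma = 0) until the first occupied layer; zeros
    sandwiched between occupied layers are kept, since they are informative
    about the generative program rather than about interruption.  In
    generation order this masks the trailing zero run of each row.  A fully
    empty row is fully masked.
    """
    S = np.asarray(S)
    if S.ndim != 2 or S.shape[1] != 4:
        raise ValueError(f"occupancy matrix must be N x 4, got shape {S.shape}")
    occupied = S > 0
    # index of the deepest-to-most-superficial last occupied layer per row
    rev_any = np.maximum.accumulate(occupied[:, ::-1], axis=1)[:, ::-1]
    sigma = rev_any.astype(np.int8)
    if np.any(~occupied.any(axis=1)):
        warnings.warn(
            "occupancy matrix contains fully empty lineage rows; they are "
            "fully masked and contribute only prior terms",
            stacklevel=2,
        )
    return sigma


def log_likelihood(
    S: np.ndarray,
    sigma: np.ndarray,
    t: np.ndarray,
    p: np.ndarray,
    f: np.ndarray,
    n_max: int = 20,
) -> float:
    """Joint log probability of assignments and counts (coefficient omitted).

    ``sum_t n_t log f_t + sum_{ij} sigma_ij [S_ij log p + (N_max-S_ij) log(1-p)]``.
    A probability of exactly 0 or 1 contradicted by a count yields ``-inf``.
    """
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    t = np.asarray(t, dtype=np.int64)
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    n_t = np.bincount(t, minlength=len(f))
    if np.any((n_t > 0) & (f <= 0)):
        return -np.inf
    with np.errstate(divide="ignore"):
        prior_term = float(np.sum(n_t[n_t > 0] * np.log(f[n_t > 0])))
        logp = np.log(p[t])          # (N, 4)
        log1mp = np.log1p(-p[t])
    succ = sigma * S
    fail = sigma * (n_max - S)
    # 0 * log(0) is a vanishing factor, not a -inf one
    terms = succ * np.where(succ > 0, logp, 0.0) + fail * np.where(fail > 0, log1mp, 0.0)
    return prior_term + float(terms.sum())


@dataclass
class _GibbsState:
    """Mutable sampler state: assignments and per-type parameters."""

    t: np.ndarray                 # (N,) type index per lineage
    p: list[np.ndarray]           # per occupied type, (4,) occupancy probs
    n_t: list[int]                # per occupied type, member count

    @property
    def k(self) -> int:
        return len(self.p)

    def frequencies(self) -> np.ndarray:
        return np.array(self.n_t, dtype=float) / len(self.t)


@dataclass
class PosteriorSamples:
    """Retained Gibbs draws of the progenitor-type model."""

    k: np.ndarray                        # (n_samples,) occupied types per draw
    t: np.ndarray                        # (n_samples, N) assignments
    p: list[np.ndarray]                  # per draw, (K_s, 4)
    f: list[np.ndarray]                  # per draw, (K_s,) occupied-type fractions
    log_likelihood: np.ndarray           # (n_samples,)
    n_max: int = 20

    def __len__(self) -> int:
        return len(self.k)


def _assignment_sweep(
    state: _GibbsState,
    A: np.ndarray,
    B: np.ndarray,
    alpha: float,
    beta_a: float,
    beta_b: float,
    n_aux: int,
    rng: np.random.Generator,
) -> None:
    """Resample every assignment under the CRP with auxiliary components.

    ``A = sigma * S`` and ``B = sigma * (N_max - S)`` are the per-row
    sufficient statistics, so a candidate type with probabilities ``q`` has
    conditional log-likelihood ``A_i . log q + B_i . log(1 - q)``.
    """
    n = len(state.t)
    for i in range(n):
        ti = state.t[i]
        state.n_t[ti] -= 1
        freed: Optional[np.ndarray] = None
        if state.n_t[ti] == 0:
            # vacated singleton: recycle its parameter as an auxiliary candidate
            freed = state.p.pop(ti)
            state.n_t.pop(ti)
            state.t[state.t > ti] -= 1
        aux = rng.beta(beta_a, beta_b, size=(n_aux, 4))
        if freed is not None:
            aux[0] = freed
        cand = np.vstack(state.p + [aux]) if state.p else aux
        log_w = np.concatenate(
            [np.log(state.n_t), np.full(n_aux, np.log(alpha / n_aux))]
        )
        log_w = log_w + A[i] @ np.log(cand).T + B[i] @ np.log1p(-cand).T
        log_w -= log_w.max()
        w = np.exp(log_w)
        choice = rng.choice(len(w), p=w / w.sum())
        if choice < len(state.p):
            state.t[i] = choice
            state.n_t[choice] += 1
        else:
            state.p.append(cand[choice].copy())
            state.n_t.append(1)
            state.t[i] = len(state.p) - 1


def _parameter_sweep(
    state: _GibbsState,
    A: np.ndarray,
    B: np.ndarray,
    beta_a: float,
    beta_b: float,
    rng: np.random.Generator,
) -> None:
    """Conjugate Beta update of every occupied type's occupancy probabilities."""
    for t_idx in range(state.k):
        members = state.t == t_idx
        state.p[t_idx] = rng.beta(
            beta_a + A[members].sum(axis=0), beta_b + B[members].sum(axis=0)
        )


def gibbs_sweep(
    state: _GibbsState,
    S: np.ndarray,
    sigma: np.ndarray,
    *,
    n_max: int = 20,
    alpha: float = 1.0,
    beta_a: float = 1.0,
    beta_b: float = 1.0,
    n_aux: int = 3,
    rng: np.random.Generator,
) -> _GibbsState:
    """One full Gibbs sweep: all assignments, then all type parameters."""
    A = (sigma * S).astype(float)
    B = (sigma * (n_max - S)).astype(float)
    _assignment_sweep(state, A, B, alpha, beta_a, beta_b, n_aux, rng)
    _parameter_sweep(state, A, B, beta_a, beta_b, rng)
    return state


class DirichletProcessBinomialMixture(BaseEstimator):
    """Dirichlet-process mixture of binomial layer-occupancy profiles.

    A clustering-style estimator: :meth:`fit` runs the Gibbs sampler on an
    N x 4 occupancy matrix (or a list of lineages) and retains posterior
    draws of the type assignments, per-type occupancy probabilities and the
    number of occupied types K.

    Parameters
    ----------
    n_draws : int
        Retained posterior draws after burn-in (before thinning).
    burn_in : int
        Discarded initial sweeps.
    thinning : int
        Keep every ``thinning``-th post-burn-in draw.
    n_max : int
        Binomial cap on neurons per layer per lineage.
    beta_a, beta_b : float
        Beta prior on each occupancy probability (uniform by default).
    alpha : float
        Dirichlet-process concentration.
    n_aux : int
        Auxiliary candidate types per assignment update.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    samples_ : PosteriorSamples
    mask_ : ndarray of shape (N, 4)
        The censoring mask applied to the training matrix.
    k_distribution_ : dict mapping K to posterior fraction
    n_types_ : int
        Posterior modal number of progenitor types.
    labels_ : ndarray of shape (N,)
        Type assignments from the highest-likelihood retained draw.
    """

    def __init__(
        self,
        n_draws: int = 4000,
        burn_in: int = 1000,
        thinning: int = 1,
        n_max: int = 20,
        beta_a: float = 1.0,
        beta_b: float = 1.0,
        alpha: float = 1.0,
        n_aux: int = 3,
        random_state: Union[None, int, np.random.Generator] = None,
    ) -> None:
        self.n_draws = n_draws
        self.burn_in = burn_in
        self.thinning = thinning
        self.n_max = n_max
        self.beta_a = beta_a
        self.beta_b = beta_b
        self.alpha = alpha
        self.n_aux = n_aux
        self.random_state = random_state

    def _check_params(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.burn_in < 0 or self.thinning < 1:
            raise ValueError("burn_in must be >= 0 and thinning >= 1")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta prior parameters must be positive")
        if self.alpha <= 0:
            raise ValueError("DP concentration alpha must be positive")
        if self.n_aux < 1:
            raise ValueError("n_aux must be >= 1")

    def fit(
        self, X: Union[np.ndarray, Sequence[Lineage]], y: None = None
    ) -> "DirichletProcessBinomialMixture":
        """Run the Gibbs sampler on an occupancy matrix or lineage list."""
        self._check_params()
        if len(X) and isinstance(X[0], Lineage):
            X = lineages_to_occupancy(X)
        S = _validate_counts(X, self.n_max)
        if len(S) == 0:
            raise ValueError("need at least one lineage")
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        sigma = selection_mask(S)
        n = len(S)
        state = _GibbsState(
            t=np.zeros(n, dtype=np.int64),
            p=[rng.beta(self.beta_a, self.beta_b, size=4)],
            n_t=[n],
        )
        ks, ts, ps, fs, lls = [], [], [], [], []
        total = self.burn_in + self.n_draws
        for sweep in range(total):
            gibbs_sweep(
                state,
                S,
                sigma,
                n_max=self.n_max,
                alpha=self.alpha,
                beta_a=self.beta_a,
                beta_b=self.beta_b,
                n_aux=self.n_aux,
                rng=rng,
            )
            if sweep < self.burn_in or (sweep - self.burn_in) % self.thinning:
                continue
            f = state.frequencies()
            ks.append(state.k)
            ts.append(state.t.copy())
            p_draw = np.array(state.p)
            ps.append(p_draw)
            fs.append(f)
            lls.append(log_likelihood(S, sigma, state.t, p_draw, f, self.n_max))
        self.samples_ = PosteriorSamples(
            k=np.array(ks),
            t=np.array(ts),
            p=ps,
            f=fs,
            log_likelihood=np.array(lls),
            n_max=self.n_max,
        )
        self.mask_ = sigma
        self.k_distribution_ = progenitor_count_distribution(self.samples_)
        self.n_types_ = max(self.k_distribution_, key=self.k_distribution_.get)
        best = int(np.argmax(self.samples_.log_likelihood))
        self.labels_ = self.samples_.t[best].copy()
        self.n_features_in_ = 4
        return self

    def fit_predict(
        self, X: Union[np.ndarray, Sequence[Lineage]], y: None = None
    ) -> np.ndarray:
        return self.fit(X).labels_

    def sample(
        self,
        n_lineages: int,
        size_filter: Optional[tuple[int, int]] = (3, 12),
        random_state: Union[None, int, np.random.Generator] = None,
    ) -> list[Lineage]:
        """Posterior-predictive lineages (see :func:`posterior_predictive`)."""
        if not hasattr(self, "samples_"):
            raise RuntimeError("fit the model before sampling")
        rng = (
            random_state
            if isinstance(random_state, np.random.Generator)
            else np.random.default_rng(random_state)
        )
        return posterior_predictive(self.samples_, n_lineages, size_filter, rng)


def run_inference(S: np.ndarray, config: Optional[dict] = None, **kwargs) -> PosteriorSamples:
    """Functional wrapper: fit the DP mixture and return the posterior draws."""
    params = dict(config or {})
    params.update(kwargs)
    model = DirichletProcessBinomialMixture(**params)
    return model.fit(S).samples_


def progenitor_count_distribution(samples: PosteriorSamples) -> dict[int, float]:
    """Normalized posterior histogram of the number of occupied types K."""
    if len(samples) == 0:
        raise ValueError("no posterior samples")
    values, counts = np.unique(samples.k, return_counts=True)
    return {int(v): float(c) / len(samples) for v, c in zip(values, counts)}


def posterior_predictive(
    samples: PosteriorSamples,
    n_lineages: int,
    size_filter: Optional[tuple[int, int]] = (3, 12),
    rng: Optional[np.random.Generator] = None,
) -> list[Lineage]:
    """Simulate lineages from the posterior.

    Per lineage: draw a retained posterior sample uniformly, a type by the
    sample's occupied-type fractions, then per-layer counts
    ``Binomial(N_max, p_tj)``; finally apply the clone-size filter used for
    the experimental data (pass ``None`` to skip it).
    """
    if len(samples) == 0:
        raise ValueError("no posterior samples")
    if rng is None:
        rng = np.random.default_rng()
    out: list[Lineage] = []
    draw_idx = rng.integers(0, len(samples), size=n_lineages)
    for m, d in enumerate(draw_idx):
        f = samples.f[d]
        t_idx = rng.choice(len(f), p=f / f.sum())
        counts = rng.binomial(samples.n_max, samples.p[d][t_idx])
        lin = Lineage(
            id=f"pp{m}",
            method="simulated",
            area="model",
            age="model",
            counts=LayerCounts.from_array(counts, GENERATION_ORDER),
        )
        if size_filter is None or size_filter[0] <= lin.total() <= size_filter[1]:
            out.append(lin)
    return out


def crp_expected_k(n: int, alpha: float) -> float:
    """Expected number of occupied types under the CRP prior for n items."""
    return float(np.sum(alpha / (alpha + np.arange(n))))
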