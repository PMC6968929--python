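"""Sequential stochastic simulator of pyramidal-cell lineage generation.

An in-silico progenitor produces neurons layer by layer in the inside-out
order VI, V, IV, II/III.  For each layer it receives a random number of
*opportunities*, drawn uniformly between one and a per-layer cap (the cap
mirrors the maximum count observed for that layer in any experimental
lineage).  At each opportunity the lineage may first be interrupted with
probability ``q`` — modelling premature terminal division or progenitor
death, which terminates the entire remaining lineage — and otherwise a
neuron is generated with the layer-specific probability ``P_j``.

A *model* is a mixture of one (Model 1) or two (Model 2) such progenitor
types with population fractions.  Simulated datasets (by default 100
progenitors per repeat, 100 repeats, clone sizes filtered to 3-12) are
compared to experimental summaries through normalized z-scores, and the
generation probabilities, interruption probability and population fractions
can be fitted to a target summary by seeded coordinate descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .lineage import GENERATION_ORDER, LayerCounts, Lineage
from .stats import DegenerateSpreadError, SummaryStats, summarize, zscore_report

__all__ = [
    "SimProgenitorSpec",
    "SimModelSpec",
    "SequentialLineageModel",
    "simulate_lineage",
    "simulate_model",
    "fit_model",
    "opportunity_caps_from_data",
]

_LAYER_LABELS = ("VI", "V", "IV", "II/III")  # generation order


@dataclass(frozen=True)
class SimProgenitorSpec:
    """One progenitor type: opportunity caps and probabilities.

    All per-layer vectors are in generation order (VI, V, IV, II/III).
    """

    m: tuple[int, int, int, int]          # max opportunities per layer
    p: tuple[float, float, float, float]  # generation probability per layer
    q: float = 0.0                        # interruption probability per opportunity
    fraction: float = 1.0                 # population share

    def __post_init__(self) -> None:
        if len(self.m) != 4 or any(int(v) != v or v < 1 for v in self.m):
            raise ValueError(f"opportunity caps must be four integers >= 1, got {self.m}")
        for name, vals in (("p", self.p), ("q", (self.q,)), ("fraction", (self.fraction,))):
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ValueError(f"{name} entries must lie in [0, 1]")


@dataclass(frozen=True)
class SimModelSpec:
    """A mixture of progenitor types plus replication settings."""

    types: tuple[SimProgenitorSpec, ...]
    n_progenitors: int = 100
    n_repeats: int = 100
    size_filter: Optional[tuple[int, int]] = (3, 12)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.types:
            raise ValueError("at least one progenitor type is required")
        total = sum(t.fraction for t in self.types)
        if not np.isclose(total, 1.0):
            raise ValueError(f"population fractions must sum to 1, got {total}")
        if self.n_progenitors < 1 or self.n_repeats < 1:
            raise ValueError("n_progenitors and n_repeats must be >= 1")


def simulate_lineage(
    spec: SimProgenitorSpec, rng: np.random.Generator
) -> tuple[LayerCounts, bool]:
    """Simulate one lineage opportunity by opportunity.

    This scalar path follows the generative story literally (interruption is
    tested before generation at every opportunity) and serves as the
    reference for the vectorised batch simulator.
    """
    counts = [0, 0, 0, 0]
    for j in range(4):
        n_opp = int(rng.integers(1, spec.m[j] + 1))
        for _ in range(n_opp):
            if spec.q > 0 and rng.random() < spec.q:
                return LayerCounts.from_array(counts, GENERATION_ORDER), True
            if rng.random() < spec.p[j]:
                counts[j] += 1
    return LayerCounts.from_array(counts, GENERATION_ORDER), False


def _batch_simulate(
    types: np.ndarray,
    m: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised simulation of many progenitors.

    Exploits that the number of opportunities survived before interruption is
    geometric: opportunity k completes iff the first k interruption tests all
    fail, so the count of completed opportunities is ``G - 1`` with
    ``G ~ Geometric(q)`` (trial index of the first success).  Completed
    opportunities are then allotted to layers in generation order and each
    yields a neuron with the layer's probability.
    """
    n = len(types)
    n_opp = rng.integers(1, m[types] + 1)              # (n, 4)
    cum = np.cumsum(n_opp, axis=1)
    prev = cum - n_opp
    total = cum[:, -1]
    qv = q[types]
    survived = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    pos = qv > 0
    if np.any(pos):
        survived[pos] = rng.geometric(qv[pos]) - 1
    completed = np.clip(survived[:, None] - prev, 0, n_opp)
    counts = rng.binomial(completed, p[types])
    interrupted = survived < total
    return counts, interrupted


def _spec_arrays(spec: SimModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    m = np.array([t.m for t in spec.types], dtype=np.int64)
    p = np.array([t.p for t in spec.types], dtype=float)
    q = np.array([t.q for t in spec.types], dtype=float)
    fractions = np.array([t.fraction for t in spec.types], dtype=float)
    return m, p, q, fractions / fractions.sum()


def simulate_model(
    spec: SimModelSpec,
    rng: Optional[np.random.Generator] = None,
    return_truth: bool = False,
):
    """Simulate ``spec.n_repeats`` datasets of ``spec.n_progenitors`` each.

    Each progenitor is assigned a type by the population fractions, simulated
    sequentially, and the resulting lineages are clone-size filtered.  With
    ``return_truth`` the unfiltered per-progenitor type labels, counts and
    interruption flags are returned alongside.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    m, p, q, fractions = _spec_arrays(spec)
    repeats: list[list[Lineage]] = []
    truth: list[dict] = []
    lo, hi = spec.size_filter if spec.size_filter else (0, np.inf)
    for r in range(spec.n_repeats):
        types = rng.choice(len(fractions), size=spec.n_progenitors, p=fractions)
        counts, interrupted = _batch_simulate(types, m, p, q, rng)
        sizes = counts.sum(axis=1)
        dataset = [
            Lineage(
                id=f"sim{r}.{i}",
                method="simulated",
                area="model",
                age="model",
                counts=LayerCounts.from_array(counts[i], GENERATION_ORDER),
            )
            for i in range(spec.n_progenitors)
            if lo <= sizes[i] <= hi
        ]
        repeats.append(dataset)
        if return_truth:
            truth.append(
                {"types": types, "counts": counts, "interrupted": interrupted}
            )
    if return_truth:
        return repeats, truth
    return repeats


def opportunity_caps_from_data(datasets: Sequence[Sequence[Lineage]]) -> tuple[int, ...]:
    """Per-layer opportunity caps: the maximum count of that layer in any
    single lineage across the pooled experimental datasets."""
    caps = np.zeros(4, dtype=np.int64)
    for dataset in datasets:
        for lin in dataset:
            caps = np.maximum(caps, lin.counts.as_array(GENERATION_ORDER))
    if np.any(caps < 1):
        raise ValueError("every layer needs at least one observed neuron to set caps")
    return tuple(int(c) for c in caps)


# ---------------------------------------------------------------------------
# fast per-repeat summaries used by the fitting objective


def _counts_to_stats(
    counts: np.ndarray, size_filter: tuple[int, int], size_range: tuple[int, int]
) -> Optional[SummaryStats]:
    """SummaryStats straight from a (n, 4) generation-order count array."""
    sizes = counts.sum(axis=1)
    keep = (sizes >= size_filter[0]) & (sizes <= size_filter[1])
    kept = counts[keep]
    if len(kept) == 0:
        return None
    sizes = sizes[keep]
    grand = kept.sum()
    # generation order (VI,V,IV,II/III) -> superficial order (II/III,IV,V,VI)
    lam = kept.sum(axis=0)[::-1].astype(float) / grand
    lo, hi = size_range
    hist = {s: int(np.sum(sizes == s)) for s in range(lo, hi + 1)}
    sup = kept[:, 2:].sum(axis=1)
    deep = kept[:, :2].sum(axis=1)
    translam = np.mean((sup >= 1) & (deep >= 1))
    deep_only = np.mean((deep >= 1) & (sup == 0))
    cls = np.array([translam, deep_only, 1.0 - translam - deep_only])
    bits = (kept[:, ::-1] > 0).astype(int)  # superficial order presence
    codes = bits @ np.array([8, 4, 2, 1])
    code_counts = np.bincount(codes, minlength=16)[1:]
    freqs = {
        tuple((c >> (3 - k)) & 1 for k in range(4)): code_counts[c - 1] / len(kept)
        for c in range(1, 16)
    }
    rho: Optional[float] = None
    if len(kept) >= 3 and np.ptp(sup) > 0 and np.ptp(deep) > 0:
        rho = float(sps.spearmanr(sup, deep).statistic)
    return SummaryStats(
        laminar_fractions=lam,
        size_histogram=hist,
        size_range=size_range,
        n_out_of_range=int(np.sum(~keep)),
        class_fractions=cls,
        config_frequencies=freqs,
        spearman_r=rho,
        n_lineages=int(len(kept)),
    )


class SequentialLineageModel(BaseEstimator):
    """Mixture of sequential stochastic progenitor types, fittable to data.

    Parameters
    ----------
    opportunities : sequence of 4-tuples
        Per-type opportunity caps in generation order (VI, V, IV, II/III).
        The length of this sequence sets the number of progenitor types
        (one -> Model 1, two -> Model 2); caps are fixed, not fitted.
    probabilities : sequence of 4-tuples, optional
        Initial generation probabilities per type (default 0.5 everywhere).
    interruption : float or sequence of float
        Initial per-type interruption probability.
    fractions : sequence of float, optional
        Initial population fractions (default uniform).
    n_progenitors, n_repeats : int
        Replication settings of every simulated comparison.
    size_filter : (int, int)
        Clone-size window applied to simulated lineages.
    fit_classes : bool
        Include the three laminar-class fractions in the fitting objective
        alongside the laminar fractions and size-histogram bins.
    n_passes : int
        Coordinate-descent passes over the free parameters.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    types_ : tuple of SimProgenitorSpec — the fitted types
    spec_ : SimModelSpec — fitted spec, ready for :func:`simulate_model`
    objective_trace_ : list of float — objective after each accepted move
    zscores_ : dict — final per-statistic z-scores against the target
    """

    def __init__(
        self,
        opportunities: Sequence[tuple[int, int, int, int]] = ((6, 4, 4, 8),),
        probabilities: Optional[Sequence[tuple[float, float, float, float]]] = None,
        interruption: Union[float, Sequence[float]] = 0.05,
        fractions: Optional[Sequence[float]] = None,
        n_progenitors: int = 100,
        n_repeats: int = 100,
        size_filter: tuple[int, int] = (3, 12),
        fit_classes: bool = False,
        n_passes: int = 3,
        random_state: Union[None, int, np.random.Generator] = None,
    ) -> None:
        self.opportunities = opportunities
        self.probabilities = probabilities
        self.interruption = interruption
        self.fractions = fractions
        self.n_progenitors = n_progenitors
        self.n_repeats = n_repeats
        self.size_filter = size_filter
        self.fit_classes = fit_classes
        self.n_passes = n_passes
        self.random_state = random_state

    # -- construction helpers -------------------------------------------------

    def _initial_spec(self) -> SimModelSpec:
        k = len(self.opportunities)
        probs = self.probabilities
        if probs is None:
            probs = [(0.5, 0.5, 0.5, 0.5)] * k
        qs = self.interruption
        if np.isscalar(qs):
            qs = [float(qs)] * k
        fracs = self.fractions
        if fracs is None:
            fracs = [1.0 / k] * k
        types = tuple(
            SimProgenitorSpec(
                m=tuple(int(v) for v in self.opportunities[t]),
                p=tuple(float(v) for v in probs[t]),
                q=float(qs[t]),
                fraction=float(fracs[t]),
            )
            for t in range(k)
        )
        return SimModelSpec(
            types=types,
            n_progenitors=self.n_progenitors,
            n_repeats=self.n_repeats,
            size_filter=self.size_filter,
        )

    def _simulated_stats(
        self, spec: SimModelSpec, seed: int, size_range: tuple[int, int]
    ) -> list[SummaryStats]:
        rng = np.random.default_rng(seed)
        m, p, q, fractions = _spec_arrays(spec)
        out = []
        for _ in range(spec.n_repeats):
            types = rng.choice(len(fractions), size=spec.n_progenitors, p=fractions)
            counts, _ = _batch_simulate(types, m, p, q, rng)
            stats = _counts_to_stats(counts, spec.size_filter, size_range)
            if stats is not None:
                out.append(stats)
        return out

    def _objective(
        self, spec: SimModelSpec, target: SummaryStats, seed: int
    ) -> tuple[float, dict[str, float]]:
        sims = self._simulated_stats(spec, seed, target.size_range)
        if len(sims) < 2:
            return np.inf, {}
        try:
            report = zscore_report(target, sims, include_classes=self.fit_classes)
        except DegenerateSpreadError:
            return np.inf, {}
        tracked = {
            k: v
            for k, v in report.items()
            if k.startswith(("laminar_fraction", "size_fraction", "class_fraction"))
        }
        return float(sum(z * z for z in tracked.values())), report

    # -- estimator API ---------------------------------------------------------

    def fit(self, X: SummaryStats, y: None = None) -> "SequentialLineageModel":
        """Fit generation probabilities, interruption and fractions to a
        target :class:`~pyrclone.stats.SummaryStats` by coordinate descent.

        Candidate moves per parameter shrink geometrically across passes;
        every objective evaluation reuses one seeded random stream (common
        random numbers), so the search is deterministic given
        ``random_state``.
        """
        if not isinstance(X, SummaryStats):
            raise TypeError("fit expects a SummaryStats target")
        if not np.isclose(X.laminar_fractions.sum(), 1.0):
            raise ValueError("target laminar fractions must sum to 1")
        seed_rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        eval_seed = int(seed_rng.integers(0, 2**31 - 1))
        spec = self._initial_spec()
        k = len(spec.types)

        def get_params_vec(s: SimModelSpec) -> list[float]:
            vec: list[float] = []
            for t in s.types:
                vec.extend(t.p)
                vec.append(t.q)
            if k > 1:
                vec.extend(t.fraction for t in s.types[:-1])
            return vec

        def set_params_vec(s: SimModelSpec, vec: Sequence[float]) -> SimModelSpec:
            vec = list(vec)
            types = []
            pos = 0
            for t in s.types:
                p = tuple(float(np.clip(v, 0.0, 1.0)) for v in vec[pos : pos + 4])
                q = float(np.clip(vec[pos + 4], 0.0, 1.0))
                types.append(replace(t, p=p, q=q))
                pos += 5
            if k > 1:
                heads = [float(np.clip(v, 0.0, 0.999)) for v in vec[pos : pos + k - 1]]
                total_head = sum(heads)
                if total_head >= 1.0:
                    heads = [h / (total_head + 1e-9) for h in heads]
                fracs = heads + [1.0 - sum(heads)]
                types = [replace(t, fraction=f) for t, f in zip(types, fracs)]
            return replace(s, types=tuple(types))

        vec = get_params_vec(spec)
        best_obj, best_report = self._objective(spec, X, eval_seed)
        trace = [best_obj]
        steps = [0.2 * (0.5**i) for i in range(self.n_passes)]
        for step in steps:
            for idx in range(len(vec)):
                candidates = [vec[idx] + d for d in (-2 * step, -step, step, 2 * step)]
                for cand in candidates:
                    trial = list(vec)
                    trial[idx] = cand
                    trial_spec = set_params_vec(spec, trial)
                    obj, report = self._objective(trial_spec, X, eval_seed)
                    if obj < best_obj:
                        best_obj, best_report = obj, report
                        vec = trial
                        trace.append(best_obj)
        fitted = set_params_vec(spec, vec)
        self.types_ = fitted.types
        self.spec_ = fitted
        self.objective_trace_ = trace
        self.objective_ = best_obj
        self.zscores_ = best_report
        self.eval_seed_ = eval_seed
        return self

    def sample(
        self,
        random_state: Union[None, int, np.random.Generator] = None,
    ) -> list[list[Lineage]]:
        """Simulate repeat datasets from the fitted (or initial) spec."""
        spec = getattr(self, "spec_", None) or self._initial_spec()
        rng = (
            random_state
            if isinstance(random_state, np.random.Generator)
            else np.random.default_rng(random_state)
        )
        return simulate_model(spec, rng=rng)


def fit_model(
    target: SummaryStats,
    template: SimModelSpec,
    search: Optional[dict] = None,
) -> tuple[SimModelSpec, dict]:
    """Functional wrapper over :class:`SequentialLineageModel`.

    ``template`` fixes the number of types, the opportunity caps and the
    starting values; ``search`` may set ``n_passes``, ``fit_classes`` and
    ``seed``.
    """
    search = dict(search or {})
    model = SequentialLineageModel(
        opportunities=[t.m for t in template.types],
        probabilities=[t.p for t in template.types],
        interruption=[t.q for t in template.types],
        fractions=[t.fraction for t in template.types],
        n_progenitors=template.n_progenitors,
        n_repeats=template.n_repeats,
        size_filter=template.size_filter or (3, 12),
        fit_classes=search.pop("fit_classes", False),
        n_passes=search.pop("n_passes", 3),
        random_state=search.pop("seed", template.seed),
    )
    if search:
        raise ValueError(f"unknown search options: {sorted(search)}")
    model.fit(target)
    report = {
        "objective": model.objective_,
        "objective_trace": model.objective_trace_,
        "zscores": model.zscores_,
    }
    return model.spec_, report
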