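"""Summary statistics and model-data comparison measures for clonal datasets.

All statistics operate on lists of :class:`~pyrclone.lineage.Lineage` and are
invariant to the order of lineages in the input.  Fraction-valued outputs are
reported in superficial-to-deep layer order (II/III, IV, V, VI) and sum to
one up to machine precision.

Model-data agreement is quantified by a normalized z-score: the absolute
difference between the experimental value and the mean across simulation
repeats, divided by the (sample) standard deviation across repeats.  Values
above one flag a discrepancy larger than the repeat-to-repeat variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .lineage import (
    SUPERFICIAL_ORDER,
    ConfigCode,
    EmptyLineageError,
    LaminarClass,
    Lineage,
    classify_laminar,
    configuration_code,
)

__all__ = [
    "SummaryStats",
    "DegenerateSpreadError",
    "laminar_fractions",
    "size_histogram",
    "class_fractions",
    "config_frequencies",
    "superficial_deep_correlation",
    "subtype_diversity",
    "zscore",
    "zscore_report",
    "compare_datasets",
    "summarize",
]

CLASS_ORDER = (
    LaminarClass.TRANSLAMINAR,
    LaminarClass.DEEP_RESTRICTED,
    LaminarClass.SUPERFICIAL_RESTRICTED,
)


class DegenerateSpreadError(ValueError):
    """Raised when a z-score is requested against zero simulation spread."""


def laminar_fractions(dataset: Sequence[Lineage]) -> np.ndarray:
    """Fraction of all neurons per layer, order (II/III, IV, V, VI)."""
    totals = np.zeros(4, dtype=float)
    for lin in dataset:
        totals += lin.counts.as_array(SUPERFICIAL_ORDER)
    grand = totals.sum()
    if grand == 0:
        raise EmptyLineageError("dataset holds no neurons")
    return totals / grand


def size_histogram(
    dataset: Sequence[Lineage], size_range: tuple[int, int] = (3, 12)
) -> tuple[dict[int, int], int]:
    """Counts of lineages per clonal size within ``size_range``.

    Returns the in-range histogram (every size in the range keyed, missing
    sizes as zero) and the number of out-of-range lineages.
    """
    lo, hi = size_range
    hist = {size: 0 for size in range(lo, hi + 1)}
    out = 0
    for lin in dataset:
        n = lin.total()
        if lo <= n <= hi:
            hist[n] += 1
        else:
            out += 1
    return hist, out


def class_fractions(dataset: Sequence[Lineage]) -> np.ndarray:
    """Fractions of (translaminar, deep-restricted, superficial-restricted)."""
    if not dataset:
        raise EmptyLineageError("cannot compute class fractions of an empty dataset")
    counts = {cls: 0 for cls in CLASS_ORDER}
    for lin in dataset:
        counts[classify_laminar(lin.counts)] += 1
    return np.array([counts[cls] for cls in CLASS_ORDER], dtype=float) / len(dataset)


def config_frequencies(dataset: Sequence[Lineage]) -> dict[tuple[int, ...], float]:
    """Relative frequency of each of the 15 laminar configurations."""
    if not dataset:
        raise EmptyLineageError("cannot compute configurations of an empty dataset")
    freqs = {tuple(code): 0.0 for code in ConfigCode.all_codes()}
    for lin in dataset:
        freqs[tuple(configuration_code(lin.counts))] += 1.0
    n = len(dataset)
    return {code: c / n for code, c in freqs.items()}


def superficial_deep_correlation(
    dataset: Sequence[Lineage], use_fractions: bool = False
) -> float:
    """Spearman rank correlation of superficial vs deep neuron numbers.

    With ``use_fractions`` the per-lineage counts are divided by clone size
    first (the two variants are reported interchangeably in the field; counts
    are the default here).  Ties receive average ranks.
    """
    if len(dataset) < 3:
        raise ValueError("need at least three lineages for a rank correlation")
    sup = np.array([lin.counts.superficial() for lin in dataset], dtype=float)
    deep = np.array([lin.counts.deep() for lin in dataset], dtype=float)
    if use_fractions:
        totals = sup + deep
        if np.any(totals == 0):
            raise EmptyLineageError("fractions undefined for an empty lineage")
        sup, deep = sup / totals, deep / totals
    if np.all(sup == sup[0]) or np.all(deep == deep[0]):
        raise DegenerateSpreadError("correlation undefined for a constant vector")
    return float(sps.spearmanr(sup, deep).statistic)


def subtype_diversity(dataset: Sequence[Lineage]) -> np.ndarray:
    """Distribution of subtype richness among fully annotated all-layer clones.

    Considers translaminar lineages occupying every layer whose projection
    subtypes are completely annotated (subtype counts covering every neuron;
    clones containing unclassified cells are excluded).  Returns fractions of
    clones containing 1, 2, 3 or 4 distinct subclasses.
    """
    bins = np.zeros(4, dtype=float)
    included = 0
    for lin in dataset:
        if lin.subtype_counts is None:
            continue
        if not configuration_code(lin.counts).is_full:
            continue
        if sum(lin.subtype_counts.values()) != lin.counts.total():
            continue  # incompletely annotated / unclassified cells present
        distinct = sum(1 for v in lin.subtype_counts.values() if v > 0)
        bins[distinct - 1] += 1
        included += 1
    if included == 0:
        raise EmptyLineageError("no fully annotated all-layer translaminar lineages")
    return bins / included


@dataclass
class SummaryStats:
    """The summary statistics tracked for model-data comparison."""

    laminar_fractions: np.ndarray
    size_histogram: dict[int, int]
    size_range: tuple[int, int]
    n_out_of_range: int
    class_fractions: np.ndarray
    config_frequencies: dict[tuple[int, ...], float]
    spearman_r: Optional[float]
    n_lineages: int

    def size_fractions(self) -> np.ndarray:
        """Size histogram normalised over in-range lineages."""
        counts = np.array(
            [self.size_histogram[s] for s in range(self.size_range[0], self.size_range[1] + 1)],
            dtype=float,
        )
        total = counts.sum()
        return counts / total if total > 0 else counts


def summarize(
    dataset: Sequence[Lineage], size_range: tuple[int, int] = (3, 12)
) -> SummaryStats:
    """Compute the full summary-statistic set for one dataset."""
    if not dataset:
        raise EmptyLineageError("cannot summarise an empty dataset")
    hist, out = size_histogram(dataset, size_range)
    try:
        rho = superficial_deep_correlation(dataset)
    except (ValueError, DegenerateSpreadError):
        rho = None
    return SummaryStats(
        laminar_fractions=laminar_fractions(dataset),
        size_histogram=hist,
        size_range=size_range,
        n_out_of_range=out,
        class_fractions=class_fractions(dataset),
        config_frequencies=config_frequencies(dataset),
        spearman_r=rho,
        n_lineages=len(dataset),
    )


def zscore(experimental: float, sim_values: Sequence[float]) -> float:
    """Normalized distance between an experimental value and simulations.

    ``|mean(sim) - experimental| / std(sim)`` with the sample (n-1) standard
    deviation across simulation repeats.
    """
    sims = np.asarray(sim_values, dtype=float)
    if sims.size < 2:
        raise ValueError("need at least two simulation values")
    std = sims.std(ddof=1)
    mean = sims.mean()
    # spread at float-rounding scale is no spread (e.g. exactly conserved
    # statistics accumulated in different orders)
    tol = 1e-9 * max(1.0, abs(mean), abs(experimental))
    if std <= tol:
        if abs(mean - experimental) <= tol:
            return 0.0
        raise DegenerateSpreadError("zero spread across simulation repeats")
    return float(abs(mean - experimental) / std)


def zscore_report(
    observed: SummaryStats,
    simulated: Sequence[SummaryStats],
    include_classes: bool = True,
) -> dict[str, float]:
    """Per-statistic z-scores of an observed dataset against repeat datasets.

    Tracks the four laminar fractions, the normalised size-histogram bins,
    the three laminar-class fractions (optional) and, when defined in both
    observed and simulated data, the superficial-deep Spearman correlation.
    Statistics with zero spread report z = 0 on exact agreement and
    ``inf`` on disagreement (an observed value the ensemble never produces).
    """

    def _z(experimental: float, sims) -> float:
        try:
            return zscore(experimental, sims)
        except DegenerateSpreadError:
            return float("inf")

    report: dict[str, float] = {}
    layer_labels = ("II/III", "IV", "V", "VI")
    sim_lam = np.array([s.laminar_fractions for s in simulated])
    for j, label in enumerate(layer_labels):
        report[f"laminar_fraction[{label}]"] = _z(
            observed.laminar_fractions[j], sim_lam[:, j]
        )
    sizes = range(observed.size_range[0], observed.size_range[1] + 1)
    obs_sizes = observed.size_fractions()
    sim_sizes = np.array([s.size_fractions() for s in simulated])
    for k, size in enumerate(sizes):
        report[f"size_fraction[{size}]"] = _z(obs_sizes[k], sim_sizes[:, k])
    if include_classes:
        sim_cls = np.array([s.class_fractions for s in simulated])
        for j, label in enumerate(("translaminar", "deep", "superficial")):
            report[f"class_fraction[{label}]"] = _z(
                observed.class_fractions[j], sim_cls[:, j]
            )
    rhos = [s.spearman_r for s in simulated]
    if observed.spearman_r is not None and all(r is not None for r in rhos):
        report["spearman_r"] = _z(observed.spearman_r, rhos)
    return report


def compare_datasets(
    observed_a: Optional[Sequence[int]] = None,
    observed_b: Optional[Sequence[int]] = None,
    expected_fractions: Optional[Sequence[float]] = None,
    sizes_a: Optional[Sequence[int]] = None,
    sizes_b: Optional[Sequence[int]] = None,
) -> dict[str, object]:
    """Categorical or rank tests between datasets, naming the test used.

    Three call patterns:

    * two count vectors (or one 2xC table) -> chi-square test of homogeneity,
      switching to Fisher's exact test for 2x2 tables or when any expected
      cell count falls below five;
    * one count vector + ``expected_fractions`` -> chi-square goodness of fit;
    * ``sizes_a`` and ``sizes_b`` -> Mann-Whitney U rank test of clone sizes.
    """
    if sizes_a is not None or sizes_b is not None:
        if sizes_a is None or sizes_b is None:
            raise ValueError("both size samples are required")
        res = sps.mannwhitneyu(sizes_a, sizes_b, alternative="two-sided")
        return {"test": "mann-whitney", "statistic": float(res.statistic),
                "p_value": float(res.pvalue)}

    if observed_a is None:
        raise ValueError("provide count vectors or size samples")
    a = np.asarray(observed_a, dtype=float)
    if expected_fractions is not None:
        if a.ndim != 1:
            raise ValueError("goodness-of-fit needs a single count vector")
        exp = np.asarray(expected_fractions, dtype=float)
        if not np.isclose(exp.sum(), 1.0):
            raise ValueError("expected fractions must sum to 1")
        if a.sum() == 0:
            raise ValueError("zero-total input")
        res = sps.chisquare(a, f_exp=exp * a.sum())
        return {"test": "chi-square-gof", "statistic": float(res.statistic),
                "p_value": float(res.pvalue)}

    if observed_b is not None:
        table = np.vstack([a, np.asarray(observed_b, dtype=float)])
    else:
        table = np.atleast_2d(a)
    if table.sum() == 0 or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero-total input")
    # drop categories empty in both groups (chi-square undefined there)
    table = table[:, table.sum(axis=0) > 0]
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    use_fisher = table.shape == (2, 2) or np.any(expected < 5)
    if use_fisher and table.shape == (2, 2):
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return {"test": "fisher-exact", "statistic": float(odds), "p_value": float(p)}
    res = sps.chi2_contingency(table, correction=False)
    name = "chi-square (low expected counts; interpret with care)" if use_fisher else "chi-square"
    return {"test": name, "statistic": float(res.statistic), "p_value": float(res.pvalue)}
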