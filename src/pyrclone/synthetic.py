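"""Synthetic clonal datasets with ground-truth labels.

Two generators cover the two generative processes the analyses assume:

* :func:`generate_occupancy_dataset` draws layer-occupancy counts directly
  from the binomial mixture the Bayesian model posits (types drawn by
  mixture fractions, counts ``Binomial(N_max, p_tj)``) — the matched input
  for parameter-recovery tests of the Dirichlet-process sampler;
* :func:`generate_lineage_dataset` runs the sequential inside-out simulator
  and records every progenitor's true type *before* any clone-size
  filtering, so the filter itself is testable downstream.

Each lineage consumes its own random substream spawned deterministically
from the master seed, so enlarging a dataset never perturbs earlier
lineages.  The shipped two-type preset mimics the experimental narrative —
a majority type producing larger translaminar clones and a minority type
producing small superficial-biased clones — with parameter values of our
own choosing, stored in ``presets.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .lineage import GENERATION_ORDER, LayerCounts, Lineage
from .sequential import SimModelSpec, SimProgenitorSpec, simulate_lineage

__all__ = [
    "GroundTruth",
    "generate_occupancy_dataset",
    "generate_lineage_dataset",
    "load_preset",
    "two_type_preset",
]


@dataclass
class GroundTruth:
    """True generating labels and parameters of a synthetic dataset."""

    labels: np.ndarray          # per-lineage true type index
    params: dict                # the generating parameters
    seed: Optional[int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)


def _substreams(seed: Optional[int], n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def generate_occupancy_dataset(
    k: int,
    p: Sequence[Sequence[float]],
    f: Sequence[float],
    n: int,
    n_max: int = 20,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Draw an occupancy matrix from the binomial mixture model.

    Parameters
    ----------
    k : number of types
    p : k x 4 per-type occupancy probabilities, generation order
    f : k mixture fractions, summing to one
    n : number of lineages
    n_max : binomial cap per layer
    seed : master seed

    Returns the N x 4 count matrix and the ground truth.
    """
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    if p.shape != (k, 4):
        raise ValueError(f"p must be {k} x 4, got shape {p.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("occupancy probabilities must lie in [0, 1]")
    if f.shape != (k,) or not np.isclose(f.sum(), 1.0) or np.any(f < 0):
        raise ValueError("mixture fractions must be non-negative and sum to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    S = np.empty((n, 4), dtype=np.int64)
    labels = np.empty(n, dtype=np.int64)
    for i, rng in enumerate(_substreams(seed, n)):
        t = rng.choice(k, p=f)
        labels[i] = t
        S[i] = rng.binomial(n_max, p[t])
    truth = GroundTruth(
        labels=labels,
        params={"k": k, "p": p.tolist(), "f": f.tolist(), "n_max": n_max},
        seed=seed,
    )
    return S, truth


def generate_lineage_dataset(
    spec: SimModelSpec, seed: Optional[int] = None
) -> tuple[list[Lineage], GroundTruth]:
    """Simulate ``n_progenitors * n_repeats`` lineages with true type labels.

    Lineages are returned *unfiltered*; apply
    :func:`~pyrclone.lineage.neurogenic_filter` downstream.  The master seed
    (argument, falling back to ``spec.seed``) drives type assignment and one
    substream per progenitor.
    """
    if seed is None:
        seed = spec.seed
    fractions = np.array([t.fraction for t in spec.types], dtype=float)
    fractions = fractions / fractions.sum()
    total = spec.n_progenitors * spec.n_repeats
    streams = _substreams(seed, total + 1)
    type_rng, streams = streams[0], streams[1:]
    labels = type_rng.choice(len(spec.types), size=total, p=fractions)
    dataset: list[Lineage] = []
    interrupted = np.zeros(total, dtype=bool)
    for i, rng in enumerate(streams):
        counts, flag = simulate_lineage(spec.types[labels[i]], rng)
        interrupted[i] = flag
        dataset.append(
            Lineage(
                id=f"synth{i}",
                method="simulated",
                area="model",
                age="model",
                counts=counts,
            )
        )
    truth = GroundTruth(
        labels=labels,
        params={
            "types": [
                {"m": list(t.m), "p": list(t.p), "q": t.q, "fraction": t.fraction}
                for t in spec.types
            ],
            "interrupted": interrupted.tolist(),
        },
        seed=seed,
    )
    return dataset, truth


def load_preset(name: str) -> SimModelSpec:
    """Load a named simulator preset shipped with the package."""
    text = resources.files("pyrclone").joinpath("presets.yaml").read_text()
    presets = yaml.safe_load(text)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    raw = presets[name]
    types = tuple(
        SimProgenitorSpec(
            m=tuple(t["m"]), p=tuple(t["p"]), q=float(t["q"]),
            fraction=float(t["fraction"]),
        )
        for t in raw["types"]
    )
    return SimModelSpec(
        types=types,
        n_progenitors=int(raw.get("n_progenitors", 100)),
        n_repeats=int(raw.get("n_repeats", 100)),
        size_filter=tuple(raw.get("size_filter", (3, 12))),
    )


def two_type_preset() -> SimModelSpec:
    """The default experiment-like two-type preset (see module docstring)."""
    return load_preset("two_type")
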