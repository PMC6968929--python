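"""Domain types and deterministic rules for pyramidal-cell lineages.

A *lineage* (clone) is the set of labelled neurons descended from one tagged
ventricular-zone progenitor, recorded as neuron counts in cortical layers
II/III, IV, V and VI (layer I houses no pyramidal cells and is never
represented).  The internal canonical layer order is the *generation*
(inside-out) order VI, V, IV, II/III, because both the censoring rule of the
Bayesian occupancy model and the sequential simulator operate in the order in
which layers are produced.  External tables always use explicit column names,
so layer order is never positional at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GENERATION_ORDER",
    "SUPERFICIAL_ORDER",
    "LayerCounts",
    "Lineage",
    "LaminarClass",
    "ConfigCode",
    "MadmDivision",
    "ProjectionSubtype",
    "EmptyLineageError",
    "classify_laminar",
    "configuration_code",
    "neurogenic_filter",
    "split_madm_lineage",
    "classify_projection_subtype",
]

#: Canonical inside-out generation order of the layer fields.
GENERATION_ORDER: tuple[str, ...] = ("l6", "l5", "l4", "l23")
#: Superficial-to-deep order used for presence codes (II/III, IV, V, VI).
SUPERFICIAL_ORDER: tuple[str, ...] = ("l23", "l4", "l5", "l6")


class EmptyLineageError(ValueError):
    """Raised when an operation requires at least one neuron in the lineage."""


@dataclass(frozen=True)
class LayerCounts:
    """Neuron counts of one lineage per cortical layer.

    One row ``S_i.`` of the occupancy count matrix: how many neurons of
    lineage *i* sit in each of layers II/III, IV, V and VI.
    """

    l23: int = 0
    l4: int = 0
    l5: int = 0
    l6: int = 0

    def __post_init__(self) -> None:
        for name in SUPERFICIAL_ORDER:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"layer count {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"layer count {name} must be >= 0, got {v}")

    def total(self) -> int:
        return self.l23 + self.l4 + self.l5 + self.l6

    def superficial(self) -> int:
        """Neurons in the superficial compartment (layers II/III and IV)."""
        return self.l23 + self.l4

    def deep(self) -> int:
        """Neurons in the deep compartment (layers V and VI)."""
        return self.l5 + self.l6

    def as_array(self, order: Sequence[str] = GENERATION_ORDER) -> np.ndarray:
        return np.array([getattr(self, name) for name in order], dtype=np.int64)

    @classmethod
    def from_array(
        cls, values: Iterable[int], order: Sequence[str] = GENERATION_ORDER
    ) -> "LayerCounts":
        return cls(**{name: int(v) for name, v in zip(order, values, strict=True)})

    def __add__(self, other: "LayerCounts") -> "LayerCounts":
        return LayerCounts(
            self.l23 + other.l23,
            self.l4 + other.l4,
            self.l5 + other.l5,
            self.l6 + other.l6,
        )


class LaminarClass(enum.Enum):
    """Laminar class of a clone: spanning both compartments or restricted."""

    TRANSLAMINAR = "translaminar"
    DEEP_RESTRICTED = "deep_restricted"
    SUPERFICIAL_RESTRICTED = "superficial_restricted"


class MadmDivision(enum.Enum):
    """Division mode inferred from the two reporter sub-clones of a MADM event."""

    SYMMETRIC = "symmetric"
    ASYMMETRIC_NEUROGENIC = "asymmetric_neurogenic"
    EXCLUDED_SMALL = "excluded_small"


class ProjectionSubtype(enum.Enum):
    """Projection-neuron subclasses defined by Ctip2/Satb2 levels and layer."""

    CCPN = "CCPN"  # cortico-cortical
    SCPN = "SCPN"  # subcerebral
    CTHPN = "CThPN"  # cortico-thalamic
    HPN = "HPN"  # heterogeneous (layer V, Ctip2 high / Satb2 high)
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ConfigCode:
    """Laminar configuration: which layers a clone occupies.

    The presence bits are ordered superficial-to-deep (II/III, IV, V, VI).
    There are exactly 15 possible non-empty codes.
    """

    presence: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.presence) != 4 or any(b not in (0, 1) for b in self.presence):
            raise ValueError(f"presence must be four 0/1 bits, got {self.presence}")
        if sum(self.presence) == 0:
            raise EmptyLineageError("the all-empty configuration code is not defined")

    @property
    def is_full(self) -> bool:
        return sum(self.presence) == 4

    def __iter__(self):
        return iter(self.presence)

    @staticmethod
    def all_codes() -> list["ConfigCode"]:
        """The 15 non-empty configurations, in lexicographic bit order."""
        codes = []
        for bits in range(1, 16):
            presence = tuple((bits >> (3 - k)) & 1 for k in range(4))
            codes.append(ConfigCode(presence))
        return codes


@dataclass
class Lineage:
    """One clone: its layer counts plus experimental provenance.

    ``subclone_a``/``subclone_b`` carry the per-reporter (MADM green/red)
    sub-clone counts when available; ``subtype_counts`` maps projection
    subtypes to neuron counts when marker calls are available.
    """

    id: str
    method: str
    area: str
    age: str
    counts: LayerCounts
    subclone_a: Optional[LayerCounts] = None
    subclone_b: Optional[LayerCounts] = None
    subtype_counts: Optional[Mapping[str, int]] = None

    VALID_METHODS = frozenset({"retroviral", "madm", "genetic", "simulated"})

    def __post_init__(self) -> None:
        if self.method not in self.VALID_METHODS:
            raise ValueError(
                f"lineage {self.id!r}: unknown method {self.method!r}; "
                f"expected one of {sorted(self.VALID_METHODS)}"
            )
        if (self.subclone_a is None) != (self.subclone_b is None):
            raise ValueError(
                f"lineage {self.id!r}: both MADM subclones must be present or absent"
            )
        if self.subclone_a is not None and self.subclone_b is not None:
            summed = self.subclone_a + self.subclone_b
            if summed != self.counts:
                raise ValueError(
                    f"lineage {self.id!r}: subclone counts do not sum to the "
                    f"lineage counts per layer"
                )
        if self.subtype_counts is not None:
            if any(v < 0 for v in self.subtype_counts.values()):
                raise ValueError(f"lineage {self.id!r}: negative subtype count")
            if sum(self.subtype_counts.values()) > self.counts.total():
                raise ValueError(
                    f"lineage {self.id!r}: subtype counts exceed total neuron count"
                )

    def total(self) -> int:
        return self.counts.total()


def classify_laminar(counts: LayerCounts) -> LaminarClass:
    """Classify a clone as translaminar or laminar-restricted.

    Translaminar clones hold neurons in both the deep (V, VI) and superficial
    (II/III, IV) compartments; restricted clones occupy only one.
    """
    if counts.total() == 0:
        raise EmptyLineageError("cannot classify an empty lineage")
    if counts.superficial() >= 1 and counts.deep() >= 1:
        return LaminarClass.TRANSLAMINAR
    if counts.deep() >= 1:
        return LaminarClass.DEEP_RESTRICTED
    return LaminarClass.SUPERFICIAL_RESTRICTED


def configuration_code(counts: LayerCounts) -> ConfigCode:
    """Presence/absence pattern of a clone across layers II/III, IV, V, VI."""
    if counts.total() == 0:
        raise EmptyLineageError("cannot derive a configuration for an empty lineage")
    return ConfigCode(
        tuple(int(getattr(counts, name) > 0) for name in SUPERFICIAL_ORDER)
    )


def neurogenic_filter(
    dataset: Sequence[Lineage], min_size: int = 3, max_size: float = 12
) -> list[Lineage]:
    """Keep lineages whose total size lies within ``[min_size, max_size]``.

    The defaults implement the neurogenic-lineage window used throughout:
    clones below three cells are ambiguous (neuron- or IPC-derived labelling)
    and clones above twelve cells largely trace symmetrically dividing
    progenitors.  Order is preserved; the filter is idempotent.
    """
    if min_size > max_size:
        raise ValueError(f"min_size {min_size} exceeds max_size {max_size}")
    return [lin for lin in dataset if min_size <= lin.total() <= max_size]


def split_madm_lineage(lineage: Lineage) -> tuple[MadmDivision, Lineage, Lineage]:
    """Classify a MADM clone by division mode and return its two sub-clones.

    A clone with three or more cells in *each* reporter colour traces a
    symmetric progenitor division; clones of one or two cells in total are
    excluded; everything else is an asymmetric neurogenic division.
    """
    if lineage.method != "madm":
        raise ValueError(f"lineage {lineage.id!r}: not a MADM lineage")
    if lineage.subclone_a is None or lineage.subclone_b is None:
        raise ValueError(f"lineage {lineage.id!r}: missing subclone data")
    a, b = lineage.subclone_a, lineage.subclone_b
    if a.total() >= 3 and b.total() >= 3:
        label = MadmDivision.SYMMETRIC
    elif a.total() + b.total() <= 2:
        label = MadmDivision.EXCLUDED_SMALL
    else:
        label = MadmDivision.ASYMMETRIC_NEUROGENIC
    sub_a = Lineage(
        id=f"{lineage.id}.a", method="madm", area=lineage.area, age=lineage.age,
        counts=a,
    )
    sub_b = Lineage(
        id=f"{lineage.id}.b", method="madm", area=lineage.area, age=lineage.age,
        counts=b,
    )
    return label, sub_a, sub_b


# Per-layer lookup: (ctip2, satb2) -> subtype.  Combinations absent from a
# table are UNCLASSIFIED; layer VI high/high cells are explicitly left
# unclassified because the marker pair cannot separate identities there.
_SUBTYPE_RULES: dict[str, dict[tuple[str, str], ProjectionSubtype]] = {
    "V": {
        ("high", "low"): ProjectionSubtype.SCPN,
        ("high", "high"): ProjectionSubtype.HPN,
        ("low", "high"): ProjectionSubtype.CCPN,
    },
    "VI": {
        ("high", "low"): ProjectionSubtype.CTHPN,
        ("low", "high"): ProjectionSubtype.CCPN,
        ("low", "low"): ProjectionSubtype.CCPN,
    },
    "II/III": {("low", "high"): ProjectionSubtype.CCPN},
    "IV": {("low", "high"): ProjectionSubtype.CCPN},
}


def classify_projection_subtype(
    layer: str, ctip2: str, satb2: str
) -> ProjectionSubtype:
    """Map categorical Ctip2/Satb2 calls plus layer to a projection subtype.

    Layer V: Ctip2^high/Satb2^low -> SCPN, high/high -> HPN, low/high -> CCPN.
    Layer VI: high/low -> CThPN, low/anything -> CCPN, high/high unclassified.
    Layers II/III and IV carry the default cortico-cortical identity
    (low/high); other superficial combinations are left unclassified rather
    than guessed.
    """
    if layer not in _SUBTYPE_RULES:
        raise ValueError(f"unknown layer {layer!r}; expected II/III, IV, V or VI")
    for level, name in ((ctip2, "ctip2"), (satb2, "satb2")):
        if level not in ("high", "low"):
            raise ValueError(f"{name} level must be 'high' or 'low', got {level!r}")
    return _SUBTYPE_RULES[layer].get((ctip2, satb2), ProjectionSubtype.UNCLASSIFIED)
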