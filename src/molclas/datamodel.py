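"""Core domain types for entropy-based molecular classification.

A compound is described by an ordered binary fingerprint (the *property
vector*): each position records the presence/absence of one structural
feature, and the position itself encodes the feature's rank — position 1
is the feature believed to matter most for the property being modelled
(here, chromatographic retention). Similarity between compounds weights
a match at rank ``k`` by ``a_k ** k``, so agreement on high-rank features
dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PropertyVector",
    "StructuralDescriptors",
    "WeightScheme",
    "CompoundRecord",
    "SimilarityMatrix",
    "Partition",
    "EntropyProfile",
    "PeriodicCell",
    "RegressionResult",
    "validate_record",
]


@dataclass(frozen=True)
class PropertyVector:
    """Ordered binary fingerprint ``<i1 ... ik>``, most-important first.

    Parameters
    ----------
    bits
        Sequence of 0/1 values; position 1 (index 0) is the highest-rank
        feature.
    labels
        Optional per-position feature labels (e.g. ``cyc123``).
    """

    bits: tuple[int, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if len(bits) < 1:
            raise ValueError("property vector needs at least one position")
        if any(b not in (0, 1) for b in bits):
            raise ValueError(f"bits must be 0/1, got {bits}")
        if self.labels is not None and len(self.labels) != len(bits):
            raise ValueError("labels length must match bits length")
        object.__setattr__(self, "bits", bits)

    @classmethod
    def from_string(cls, s: str, labels: Sequence[str] | None = None) -> "PropertyVector":
        """Parse a vector from a compact string like ``"001010"``."""
        s = s.strip().strip("<>")
        if not s or any(c not in "01" for c in s):
            raise ValueError(f"malformed vector string {s!r}")
        return cls(tuple(int(c) for c in s), tuple(labels) if labels else None)

    def to_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __len__(self) -> int:
        return len(self.bits)

    def __iter__(self):
        return iter(self.bits)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.int8)


#: Feature labels of the six-bit pesticide scheme, in rank order.
PESTICIDE_LABELS: tuple[str, ...] = ("cyc123", "O0345", "NP", "S=", "N13", "Cl3")


@dataclass(frozen=True)
class StructuralDescriptors:
    """Raw structural counts/flags from which the 6-bit vector is encoded.

    ``has_thiono_S`` flags a double-bonded (thiono) sulphur, not any S atom.
    """

    n_cycles: int
    n_O: int
    nonplanar: bool
    has_thiono_S: bool
    n_N: int
    n_Cl: int

    def __post_init__(self) -> None:
        for name in ("n_cycles", "n_O", "n_N", "n_Cl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class WeightScheme:
    """Per-position base weights ``a_k``; position k contributes ``a_k ** k``.

    The geometric decay makes rank matter: with the default ``a_k = 0.5``
    a match on the top-ranked feature is worth 0.5, on the second 0.25,
    and so on. The self-similarity (similarity of a vector with itself)
    is ``sum_k a_k**k``, strictly below 1 for finite k.
    """

    a: tuple[float, ...]

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.a)
        if any(not (0.0 <= x <= 1.0) for x in a):
            raise ValueError("base weights must lie in [0, 1]")
        object.__setattr__(self, "a", a)
        if self.self_similarity > 1.0 + 1e-9:
            raise ValueError(
                f"self-similarity sum(a_k^k) = {self.self_similarity:.4f} exceeds 1; "
                "similarity indices would leave [0, 1]"
            )

    @classmethod
    def equal(cls, k: int, a: float = 0.5) -> "WeightScheme":
        """Equal base weights ``a_k = a`` for all k positions."""
        return cls((a,) * k)

    @property
    def n_positions(self) -> int:
        return len(self.a)

    def effective_weights(self) -> np.ndarray:
        """``a_k ** k`` for k = 1..K (1-based rank)."""
        a = np.asarray(self.a, dtype=float)
        return a ** np.arange(1, len(a) + 1)

    @property
    def self_similarity(self) -> float:
        return float(self.effective_weights().sum())


@dataclass
class CompoundRecord:
    """One compound with its fingerprint and optional measured properties.

    At least one of ``descriptors`` / ``vector`` must be present; when both
    are given they must agree under the encoding rules.
    """

    name: str
    formula: str | None = None
    descriptors: StructuralDescriptors | None = None
    vector: PropertyVector | None = None
    retention_time: float | None = None  # R_t, minutes
    logP: float | None = None
    pKa: float | None = None
    D: float | None = None  # molecular fractal dimension (external input)
    Dprime: float | None = None  # fractal dimension over non-buried atoms
    is_internal_standard: bool = False


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of pairwise similarity indices.

    ``stabilized`` marks the fixed point of max-min composition
    (min-transitive closure); grouping into classes requires it.
    """

    values: np.ndarray
    item_ids: tuple[str, ...]
    weight_scheme: WeightScheme
    stabilized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} items")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        self.values = v

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def off_diagonal_values(self) -> np.ndarray:
        """Upper-triangle entries (each unordered pair once)."""
        iu = np.triu_indices(self.n_items, k=1)
        return self.values[iu]


@dataclass
class Partition:
    """Disjoint, exhaustive classes of items at grouping level ``b``."""

    level_b: float
    classes: tuple[tuple[str, ...], ...]
    class_matrix: np.ndarray | None = None
    entropy_h: float | None = None

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def items(self) -> tuple[str, ...]:
        return tuple(i for c in self.classes for i in c)

    def as_sets(self) -> list[frozenset[str]]:
        return [frozenset(c) for c in self.classes]


@dataclass
class EntropyProfile:
    """Entropy-versus-level staircase from a classification scan.

    ``rows`` holds ``(b, n_classes, h)`` sorted by descending b; ``h_max``
    is the entropy of the finest (all-singletons) classification and sets
    the slope of the equipartition line ``h = h_max * b``.
    """

    rows: tuple[tuple[float, int, float], ...]
    h_max: float
    ssd: float | None = None

    def levels(self) -> np.ndarray:
        return np.array([r[0] for r in self.rows])

    def class_counts(self) -> np.ndarray:
        return np.array([r[1] for r in self.rows])

    def entropies(self) -> np.ndarray:
        return np.array([r[2] for r in self.rows])


@dataclass(frozen=True)
class PeriodicCell:
    """Cell of the compound periodic table: group = leading bits, period = last bit.

    ``P`` is the decimal reading of the bit vector,
    ``P = sum_k 10**(K-k) * i_k`` (100 010 for <100010>).
    """

    group_key: str  # "g" + i1..i_{K-1}
    period_key: str  # "p" + i_K
    P: int

    def decode(self) -> PropertyVector:
        """Reconstruct the bit vector from (group_key, period_key)."""
        return PropertyVector.from_string(self.group_key[1:] + self.period_key[1:])


@dataclass
class RegressionResult:
    """OLS fit summary in the conventions of QSPR reporting.

    ``r`` is the multiple correlation coefficient (sqrt of R^2); ``AEV``
    (approximation error variance) is ``1 - r**2``; MAPE is the mean
    absolute percentage error over observations with nonzero response.
    """

    coefficients: np.ndarray  # intercept first
    n: int
    r: float
    s: float
    F: float
    MAPE: float
    AEV: float
    predictor_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0 + 1e-12):
            raise ValueError("multiple correlation must lie in [0, 1]")
        if abs(self.AEV - (1.0 - self.r**2)) > 1e-9:
            raise ValueError("AEV must equal 1 - r^2")


def validate_record(rec: CompoundRecord) -> list[str]:
    """Check a compound record's invariants; return violations (empty = valid).

    Reports rather than raises so callers can collect problems across a file.
    """
    from .featurize import featurize  # deferred: avoid import cycle

    violations: list[str] = []
    if rec.descriptors is None and rec.vector is None:
        violations.append(f"{rec.name}: neither descriptors nor vector present")
        return violations
    if rec.descriptors is not None and rec.vector is not None:
        derived = featurize(rec.descriptors)
        if derived.bits != rec.vector.bits:
            violations.append(
                f"{rec.name}: descriptors encode to <{derived.to_string()}> "
                f"but vector is <{rec.vector.to_string()}>"
            )
    if rec.retention_time is not None and rec.retention_time < 0:
        violations.append(f"{rec.name}: negative retention time")
    return violations
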