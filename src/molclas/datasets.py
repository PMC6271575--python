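"""Packaged reference data and seeded synthetic generators.

``load_table1`` returns the nine-pesticide LC-MS-MS benchmark set
(names, 6-bit fingerprints, structural descriptors, retention times,
log P, pKa and fractal dimensions; TPP flagged as internal standard).
The loader cross-checks the stored vectors against the descriptor
encoding and the stored retention ratios against recomputation, so a
corrupted data file fails loudly.

The generators produce reproducible random fingerprint sets and hidden
weight schemes for property tests and learning-recovery simulations.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .datamodel import (
    CompoundRecord,
    PropertyVector,
    SimilarityMatrix,
    StructuralDescriptors,
    WeightScheme,
    validate_record,
)
from .similarity import similarity_matrix

__all__ = [
    "load_table1",
    "load_periodic_extended",
    "generate_vectors",
    "generate_reference_scheme",
]


def _data_path(name: str):
    return resources.files("molclas.data").joinpath(name)


def load_table1() -> list[CompoundRecord]:
    """The nine-pesticide benchmark records, validated at load time."""
    with resources.as_file(_data_path("pesticides.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype={"vector": str})
    records: list[CompoundRecord] = []
    for _, row in df.iterrows():
        rec = CompoundRecord(
            name=row["name"],
            formula=row["formula"],
            descriptors=StructuralDescriptors(
                n_cycles=int(row["n_cycles"]),
                n_O=int(row["n_O"]),
                nonplanar=bool(row["nonplanar"]),
                has_thiono_S=bool(row["has_thiono_S"]),
                n_N=int(row["n_N"]),
                n_Cl=int(row["n_Cl"]),
            ),
            vector=PropertyVector.from_string(row["vector"]),
            retention_time=float(row["retention_time"]),
            logP=float(row["logP"]),
            pKa=float(row["pKa"]),
            D=float(row["D"]),
            Dprime=float(row["Dprime"]),
            is_internal_standard=bool(row["is_internal_standard"]),
        )
        bad = validate_record(rec)
        if bad:
            raise RuntimeError(f"packaged fixture corrupt: {bad}")
        records.append(rec)
    # stored relative-retention column must agree with recomputation
    rt0 = min(r.retention_time for r in records)
    stored = df["ratio"].to_numpy(dtype=float)
    recomputed = np.array([(r.retention_time - rt0) / rt0 for r in records])
    if not np.allclose(stored, recomputed, atol=5e-6):
        raise RuntimeError("packaged fixture corrupt: ratio column mismatch")
    return records


def load_periodic_extended() -> pd.DataFrame:
    """Extended periodic-table membership (POPs, phenyl/sulphonylureas).

    These compounds ship with their group/period keys only — their
    vectors are decoded from the keys, no structural descriptors are
    carried. Columns: name, group_key, period_key, category, vector.
    """
    with resources.as_file(_data_path("periodic_extended.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    df["vector"] = df["group_key"].str[1:] + df["period_key"].str[1:]
    return df


def generate_vectors(
    n_items: int, n_bits: int, density: float = 0.5, seed: int = 0
) -> list[PropertyVector]:
    """Seeded Bernoulli(density) fingerprint set; same seed, same set."""
    if n_items < 2 or n_bits < 1:
        raise ValueError("need n_items >= 2 and n_bits >= 1")
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bits = (rng.random((n_items, n_bits)) < density).astype(int)
    return [PropertyVector(tuple(row)) for row in bits]


def generate_reference_scheme(
    n_bits: int, seed: int = 0, n_items: int = 12, density: float = 0.5
) -> tuple[WeightScheme, SimilarityMatrix, list[PropertyVector]]:
    """Hidden random weight scheme + the reference matrix it induces.

    The first weight is pinned at 0.5 — learning holds a_1 constant, so
    a recoverable reference must share it. The remaining a_k are drawn
    uniformly in (0.05, 0.95) and, if needed, their effective weights
    are rescaled uniformly so the self-similarity stays below 1.
    Generates a fingerprint set and builds the similarity matrix — the
    setup for weight-learning recovery experiments.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.05, 0.95, n_bits)
    a[0] = 0.5
    ranks = np.arange(2, n_bits + 1)
    tail = float((a[1:] ** ranks).sum())
    if tail > 0.48:  # leave room under 1 - a_1 = 0.5
        # a_k -> a_k * s^(1/k) scales every effective weight by s
        a[1:] = a[1:] * (0.48 / tail) ** (1.0 / ranks)
    hidden = WeightScheme(tuple(a))
    items = generate_vectors(n_items, n_bits, density, seed=seed + 1)
    return hidden, similarity_matrix(items, hidden), items
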