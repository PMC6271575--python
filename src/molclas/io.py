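"""Readers and writers: compound tables, Newick, NEXUS distances, graphs.

Input tables are delimited text with a header. Each row needs a
``name`` and either a ``vector`` column (compact bit string such as
``001010``) or the six descriptor columns (``n_cycles``, ``n_O``,
``nonplanar``, ``has_thiono_S``, ``n_N``, ``n_Cl``); optional numeric
columns (``retention_time``, ``logP``, ``pKa``, ``D``, ``Dprime``) and
an ``is_internal_standard`` flag are carried through.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import DendrogramNode
from .datamodel import (
    CompoundRecord,
    EntropyProfile,
    Partition,
    PropertyVector,
    SimilarityMatrix,
    StructuralDescriptors,
    validate_record,
)
from .similarity import BinDiagram

__all__ = [
    "read_compounds",
    "to_newick",
    "write_newick",
    "write_nexus_distances",
    "write_edge_list",
    "partition_to_dict",
    "profile_to_dict",
    "write_json",
]

_DESCRIPTOR_COLS = ("n_cycles", "n_O", "nonplanar", "has_thiono_S", "n_N", "n_Cl")
_NUMERIC_COLS = ("retention_time", "logP", "pKa", "D", "Dprime")


def read_compounds(path: str | Path, dialect: str | None = None) -> list[CompoundRecord]:
    """Read and validate compound records from a delimited-text file.

    ``dialect`` is the field separator (inferred when omitted). Rows
    lacking descriptors get their vector from the ``vector`` column;
    rows with descriptors only are encoded on the fly. Errors name the
    offending row.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=dialect,
        engine="python" if dialect is None else "c",
        dtype={"vector": str},  # keep leading zeros
    )
    if "name" not in df.columns:
        raise ValueError(f"{path.name}: missing required column 'name'")
    has_desc = all(c in df.columns for c in _DESCRIPTOR_COLS)
    has_vec = "vector" in df.columns
    if not (has_desc or has_vec):
        raise ValueError(
            f"{path.name}: need a 'vector' column or all of {', '.join(_DESCRIPTOR_COLS)}"
        )
    records: list[CompoundRecord] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        vector = None
        if has_vec and not pd.isna(row["vector"]):
            s = str(row["vector"]).strip()
            try:
                vector = PropertyVector.from_string(s)
            except ValueError as e:
                raise ValueError(f"{path.name} row {rowno}: {e}") from None
            if len(vector) != 6:
                raise ValueError(
                    f"{path.name} row {rowno}: vector {s!r} has length "
                    f"{len(vector)}, expected 6"
                )
        descriptors = None
        if has_desc and not any(pd.isna(row[c]) for c in _DESCRIPTOR_COLS):
            try:
                descriptors = StructuralDescriptors(
                    n_cycles=int(row["n_cycles"]),
                    n_O=int(row["n_O"]),
                    nonplanar=bool(int(row["nonplanar"])),
                    has_thiono_S=bool(int(row["has_thiono_S"])),
                    n_N=int(row["n_N"]),
                    n_Cl=int(row["n_Cl"]),
                )
            except (ValueError, TypeError) as e:
                raise ValueError(f"{path.name} row {rowno}: bad descriptors: {e}") from None
        if vector is None and descriptors is not None:
            from .featurize import featurize

            vector = featurize(descriptors)

        def num(col: str) -> float | None:
            if col not in df.columns or pd.isna(row[col]):
                return None
            try:
                return float(row[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path.name} row {rowno}: non-numeric value in column {col!r}"
                ) from None

        rec = CompoundRecord(
            name=str(row["name"]),
            formula=str(row["formula"]) if "formula" in df.columns and not pd.isna(row.get("formula")) else None,
            descriptors=descriptors,
            vector=vector,
            retention_time=num("retention_time"),
            logP=num("logP"),
            pKa=num("pKa"),
            D=num("D"),
            Dprime=num("Dprime"),
            is_internal_standard=bool(int(row["is_internal_standard"]))
            if "is_internal_standard" in df.columns and not pd.isna(row.get("is_internal_standard"))
            else False,
        )
        bad = validate_record(rec)
        if bad:
            raise ValueError(f"{path.name} row {rowno}: " + "; ".join(bad))
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# tree / matrix / graph writers


def _escape(name: str) -> str:
    return name.replace(" ", "_").replace(",", "").replace("(", "").replace(")", "")


def to_newick(node: DendrogramNode) -> str:
    """Newick string with branch lengths (child height differences)."""

    def walk(n: DendrogramNode, parent_height: float) -> str:
        bl = max(parent_height - n.height, 0.0)
        if n.is_leaf:
            return f"{_escape(n.name or '')}:{bl:.6f}"
        inner = ",".join(walk(c, n.height) for c in n.children)
        return f"({inner}):{bl:.6f}"

    if node.is_leaf:
        return f"{_escape(node.name or '')};"
    inner = ",".join(walk(c, node.height) for c in node.children)
    return f"({inner});"


def write_newick(node: DendrogramNode, path: str | Path) -> None:
    Path(path).write_text(to_newick(node) + "\n")


def write_nexus_distances(m: SimilarityMatrix, path: str | Path) -> None:
    """NEXUS DISTANCES block with d = 1 - r (raw similarities).

    The transform is stated in the file header; split-network viewers
    (e.g. SplitsTree) read this block directly.
    """
    n = m.n_items
    d = 1.0 - m.values
    np.fill_diagonal(d, 0.0)
    lines = [
        "#NEXUS",
        "[distances d_ij = 1 - r_ij from the raw similarity matrix]",
        "BEGIN TAXA;",
        f"  DIMENSIONS NTAX={n};",
        "  TAXLABELS " + " ".join(_escape(i) for i in m.item_ids) + ";",
        "END;",
        "BEGIN DISTANCES;",
        f"  DIMENSIONS NTAX={n};",
        "  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;",
        "  MATRIX",
    ]
    for i in range(n):
        row = " ".join(f"{d[i, j]:.6f}" for j in range(n))
        lines.append(f"    {_escape(m.item_ids[i])} {row}")
    lines += ["  ;", "END;"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_edge_list(diagram: BinDiagram, path: str | Path) -> None:
    """Tab-separated (source, target, bin) edges of the similarity diagram."""
    lines = ["source\ttarget\tbin"]
    lines += [f"{a}\t{b}\t{binname}" for a, b, binname in diagram.edge_list()]
    Path(path).write_text("\n".join(lines) + "\n")


def partition_to_dict(p: Partition) -> dict:
    return {
        "level_b": p.level_b,
        "n_classes": p.n_classes,
        "classes": [list(c) for c in p.classes],
    }


def profile_to_dict(profile: EntropyProfile) -> dict:
    return {
        "h_max": profile.h_max,
        "ssd": profile.ssd,
        "rows": [
            {"b": b, "n_classes": n, "h": h} for b, n, h in profile.rows
        ],
    }


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
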