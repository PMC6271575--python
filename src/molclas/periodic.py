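"""Periodic-table layout of compounds and the P, D, R series.

A 6-bit fingerprint <i1..i6> places a compound in a two-way table:
vertical *groups* are the leading five bits <i1..i5>, horizontal
*periods* the trailing bit <i6>. Reading the whole vector as a decimal
number,

    P = 1e5*i1 + 1e4*i2 + 1e3*i3 + 1e2*i4 + 10*i5 + i6,

gives a scalar property that orders the table. Walking the compounds in
table order (group ascending, then period), successive differences
D(p) = P(p+1) - P(p) and ratios R(p) = P(p+1)/P(p) probe how regularly
the "periodic law" holds along the layout; both are assigned to the
earlier compound of each pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .datamodel import CompoundRecord, PeriodicCell, PropertyVector

__all__ = ["assign_cell", "build_table", "PeriodicTable", "series_PDR", "PDRSeries"]


def assign_cell(v: PropertyVector) -> PeriodicCell:
    """Group/period keys and decimal property P of a 6-bit vector."""
    if len(v) != 6:
        raise ValueError(f"periodic layout is defined for 6-bit vectors, got {len(v)}")
    bits = v.bits
    p = sum(b * 10 ** (5 - k) for k, b in enumerate(bits))
    return PeriodicCell(
        group_key="g" + "".join(str(b) for b in bits[:5]),
        period_key="p" + str(bits[5]),
        P=p,
    )


@dataclass
class PeriodicTable:
    """Groups x periods grid with member compound names per cell."""

    group_keys: tuple[str, ...]  # ascending binary order
    period_keys: tuple[str, ...]  # ("p0", "p1")
    cells: dict[tuple[str, str], list[str]]  # (group, period) -> names

    def members(self, group_key: str, period_key: str) -> list[str]:
        return self.cells.get((group_key, period_key), [])

    def to_frame(self):
        """Groups as columns, periods as rows, names semicolon-joined."""
        import pandas as pd

        data = {
            g: [";".join(self.members(g, p)) for p in self.period_keys]
            for g in self.group_keys
        }
        return pd.DataFrame(data, index=list(self.period_keys))


def _vector_of(rec: CompoundRecord) -> PropertyVector:
    if rec.vector is not None:
        return rec.vector
    if rec.descriptors is not None:
        from .featurize import featurize

        return featurize(rec.descriptors)
    raise ValueError(f"{rec.name}: no vector or descriptors")


def build_table(records: Sequence[CompoundRecord]) -> PeriodicTable:
    """Lay compounds out in the periodic table.

    Groups are ordered by ascending binary value of the 5-bit key;
    members keep input order. Compounds sharing a cell have, by
    construction, identical vectors.
    """
    cells: dict[tuple[str, str], list[str]] = {}
    groups: set[str] = set()
    for rec in records:
        cell = assign_cell(_vector_of(rec))
        groups.add(cell.group_key)
        cells.setdefault((cell.group_key, cell.period_key), []).append(rec.name)
    return PeriodicTable(
        group_keys=tuple(sorted(groups, key=lambda g: int(g[1:], 2) if g[1:] else 0)),
        period_keys=("p0", "p1"),
        cells=cells,
    )


@dataclass
class PDRSeries:
    """Aligned P(p), D(p), R(p) sequences over compounds in table order."""

    names: tuple[str, ...]
    P: tuple[int, ...]
    D: tuple[int, ...]  # length len(P) - 1, assigned to the earlier compound
    R: tuple[float | None, ...]  # None where P(p) == 0 (ratio undefined)


def series_PDR(records: Sequence[CompoundRecord]) -> PDRSeries:
    """Decimal property series along the periodic ordering.

    Compounds are sorted by group (ascending binary key), then period;
    ties keep input order. ``D[p] = P[p+1] - P[p]`` and
    ``R[p] = P[p+1] / P[p]`` (``None`` when dividing by P = 0).
    """
    if len(records) < 2:
        raise ValueError("need at least two compounds")
    cells = [(rec.name, assign_cell(_vector_of(rec))) for rec in records]
    cells.sort(key=lambda nc: (int(nc[1].group_key[1:], 2), nc[1].period_key))
    names = tuple(n for n, _ in cells)
    P = tuple(c.P for _, c in cells)
    D = tuple(P[i + 1] - P[i] for i in range(len(P) - 1))
    R = tuple(P[i + 1] / P[i] if P[i] != 0 else None for i in range(len(P) - 1))
    return PDRSeries(names=names, P=P, D=D, R=R)
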