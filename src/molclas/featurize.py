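"""Encode structural descriptors into the six-bit pesticide fingerprint.

Bit rules, in decaying order of expected importance for LC retention:

==== ========= ==========================================
rank label     set to 1 when
==== ========= ==========================================
1    cyc123    1-3 rings present
2    O0345     0 or 3-5 oxygen atoms
3    NP        molecule is nonplanar
4    S=        a double-bonded (thiono) sulphur is present
5    N13       1 or 3 nitrogen atoms
6    Cl3       exactly 3 chlorine atoms
==== ========= ==========================================

Counts outside the labelled ranges (e.g. 4+ rings, 4+ nitrogens) encode
to 0: only the labelled ranges are defined as positive.
"""

from __future__ import annotations

from .datamodel import PESTICIDE_LABELS, PropertyVector, StructuralDescriptors

__all__ = ["featurize"]


def featurize(d: StructuralDescriptors) -> PropertyVector:
    """Encode descriptors into the ranked 6-bit property vector."""
    bits = (
        1 if d.n_cycles in (1, 2, 3) else 0,
        1 if d.n_O in (0, 3, 4, 5) else 0,
        1 if d.nonplanar else 0,
        1 if d.has_thiono_S else 0,
        1 if d.n_N in (1, 3) else 0,
        1 if d.n_Cl == 3 else 0,
    )
    return PropertyVector(bits, PESTICIDE_LABELS)
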