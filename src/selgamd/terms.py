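"""Energy-term bookkeeping shared by the toy systems and the decomposition.

A :class:`TermIndex` names one entry of the per-group energy-term catalogue:
for ``N`` atom groups the potential splits into ``N`` bonded terms
(``bonded_i``), ``N`` nonbonded self terms (``self_i``, interactions within
group ``i``) and ``N(N-1)/2`` nonbonded pair terms (``pair_ij``, ``i < j``).
When dual boosting is requested the torsional part of each ``bonded_i`` is
carved out into a separate ``dihedral_i`` term so it can receive its own
boost.
"""
from __future__ import annotations

from dataclasses import dataclass

KINDS = ("bonded", "self", "pair", "dihedral")


@dataclass(frozen=True, order=True)
class TermIndex:
    """One entry of the energy-term catalogue.

    Parameters
    ----------
    kind:
        ``"bonded"``, ``"self"``, ``"pair"`` or ``"dihedral"``.
    i:
        Group index (first group for pair terms).
    j:
        Second group index for ``pair`` terms (``i < j``); ``-1`` otherwise.
    """

    kind: str
    i: int
    j: int = -1

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "pair":
            if not 0 <= self.i < self.j:
                raise ValueError("pair term requires 0 <= i < j")
        elif self.j != -1:
            raise ValueError(f"{self.kind} term takes no second group index")

    @property
    def label(self) -> str:
        """Render as the field's ``i-i`` / ``i-j`` notation.

        ``bonded`` terms are ``b<i>``, ``dihedral`` terms ``d<i>``; nonbonded
        self and pair terms use ``i-i`` and ``i-j``.
        """
        if self.kind == "bonded":
            return f"b{self.i}"
        if self.kind == "dihedral":
            return f"d{self.i}"
        if self.kind == "self":
            return f"{self.i}-{self.i}"
        return f"{self.i}-{self.j}"

    @classmethod
    def from_label(cls, label: str) -> "TermIndex":
        """Parse the ``label`` notation back into a TermIndex."""
        if label.startswith("b") and label[1:].isdigit():
            return cls("bonded", int(label[1:]))
        if label.startswith("d") and label[1:].isdigit():
            return cls("dihedral", int(label[1:]))
        left, _, right = label.partition("-")
        if right and left.isdigit() and right.isdigit():
            i, j = int(left), int(right)
            if i == j:
                return cls("self", i)
            return cls("pair", min(i, j), max(i, j))
        raise ValueError(f"cannot parse term label {label!r}")
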