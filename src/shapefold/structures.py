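"""Core domain objects: RNA sequences and pseudoknot-free secondary structures.

All in-memory indices are 0-based; every file representation (CT, ``.shape``,
dot-bracket reports) is 1-based.  A secondary structure is a set of base pairs
``(i, j)`` with ``i < j`` such that no position occurs in two pairs (no base
triples) and no two pairs cross (no pseudoknots).  Each structure induces a
binary indicator vector ``x`` with ``x[i] = 1`` iff position ``i`` is unpaired
— the convention under which probing data ``q[i] = Pr(i unpaired)`` and
structures live on the same scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Base pairs the folding engine may form (Watson-Crick + GU wobble).
ALLOWED_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})

_VALID_RESIDUES = frozenset("ACGU")


@dataclass(frozen=True)
class RnaSequence:
    """A single RNA sequence over the alphabet {A, C, G, U}.

    ``T`` is accepted on input and silently converted to ``U``; lowercase is
    uppercased.  Construction rejects anything else.
    """

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("T", "U")
        for pos, ch in enumerate(norm, start=1):
            if ch not in _VALID_RESIDUES:
                raise ValueError(
                    f"invalid residue {ch!r} at position {pos} "
                    f"in sequence {self.identifier!r}"
                )
        if not norm:
            raise ValueError(f"empty sequence {self.identifier!r}")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def can_pair(a: str, b: str) -> bool:
    """True if residues *a* and *b* form a Watson-Crick or GU wobble pair."""
    return a + b in ALLOWED_PAIRS


class StructureError(ValueError):
    """A secondary-structure invariant was violated."""


@dataclass(frozen=True)
class SecondaryStructure:
    """An immutable pseudoknot-free set of base pairs over ``n`` positions.

    Parameters
    ----------
    n:
        Sequence length.
    pairs:
        Iterable of 0-based ``(i, j)`` tuples, ``i < j``.
    theta:
        If given, enforce the hairpin constraint ``j - i > theta``.
    sequence:
        If given, check every pair against the allowed-pair rule.
    severity:
        ``"reject"`` raises :class:`StructureError` on theta/pairing-rule
        violations, ``"warn"`` logs and keeps the pair (useful for reference
        structures from crystallography that contain non-canonical pairs).
        Involution/triple/pseudoknot violations always raise.
    """

    n: int
    pairs: tuple[tuple[int, int], ...]
    theta: int | None = field(default=None, compare=False)
    sequence: str | None = field(default=None, compare=False)
    severity: str = field(default="reject", compare=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise StructureError("structure length must be >= 1")
        canon = tuple(sorted((min(i, j), max(i, j)) for i, j in self.pairs))
        object.__setattr__(self, "pairs", canon)
        seen: set[int] = set()
        for i, j in canon:
            if i == j:
                raise StructureError(f"position {i + 1} paired with itself")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise StructureError(f"pair ({i + 1},{j + 1}) out of range 1..{self.n}")
            for p in (i, j):
                if p in seen:
                    raise StructureError(f"base triple at position {p + 1}")
                seen.add(p)
        # pseudoknot check: pairs sorted by i; crossing iff i < k < j < l
        for a, (i, j) in enumerate(canon):
            for k, l in canon[a + 1 :]:
                if k >= j:
                    break
                if l > j:
                    raise StructureError(
                        f"pseudoknot: pairs ({i + 1},{j + 1}) and ({k + 1},{l + 1}) cross"
                    )
        for i, j in canon:
            if self.theta is not None and j - i <= self.theta:
                self._violation(
                    f"pair ({i + 1},{j + 1}) violates hairpin constraint "
                    f"(j-i={j - i} <= theta={self.theta})"
                )
            if self.sequence is not None and not can_pair(
                self.sequence[i], self.sequence[j]
            ):
                self._violation(
                    f"pair ({i + 1},{j + 1}) = "
                    f"{self.sequence[i]}{self.sequence[j]} is not Watson-Crick/GU"
                )

    def _violation(self, msg: str) -> None:
        if self.severity == "reject":
            raise StructureError(msg)
        logger.warning("structure: %s (kept)", msg)

    # ------------------------------------------------------------------
    @property
    def pair_table(self) -> np.ndarray:
        """0-based partner index per position, -1 if unpaired."""
        table = np.full(self.n, -1, dtype=np.int64)
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table

    @property
    def x(self) -> np.ndarray:
        """Indicator vector: ``x[i] = 1.0`` iff position i is unpaired."""
        x = np.ones(self.n)
        for i, j in self.pairs:
            x[i] = 0.0
            x[j] = 0.0
        return x

    def __len__(self) -> int:
        return self.n

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = min(pair), max(pair)
        return (i, j) in set(self.pairs)

    def to_dotbracket(self) -> str:
        chars = ["."] * self.n
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)
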