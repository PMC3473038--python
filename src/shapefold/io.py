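"""File codecs: FASTA, ``.shape`` reactivity files, CT, dot-bracket, reports.

File coordinates are 1-based throughout (CT and ``.shape`` conventions);
everything returned to Python is 0-based.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .structures import RnaSequence, SecondaryStructure

logger = logging.getLogger(__name__)

#: Sentinel used by the ``.shape`` dialect for missing reactivities.
MISSING_SENTINEL = -999.0


def read_fasta(path: str | Path) -> RnaSequence:
    """Read the first record of a FASTA file as an RNA sequence.

    DNA-style input (lowercase, T) is normalized; residues outside
    {A, C, G, U, T} raise with the offending 1-based position.  Additional
    records are ignored with a warning: the tool is single-sequence.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        logger.warning(
            "%s: %d records found; using the first (%s)",
            path, len(records), records[0].id,
        )
    rec = records[0]
    return RnaSequence(identifier=rec.id, residues=str(rec.seq))


def read_reactivity(path: str | Path, n: int) -> np.ndarray:
    """Read a two-column (1-based position, reactivity) probing file.

    Returns a length-``n`` float vector with NaN for missing entries.
    Positions absent from the file and values equal to -999 are both missing;
    duplicate or out-of-range positions are errors.
    """
    values = np.full(n, np.nan)
    seen: set[int] = set()
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {ln}: expected 'position value'")
            try:
                pos = int(fields[0])
                val = float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: non-numeric field") from exc
            if not (1 <= pos <= n):
                raise ValueError(
                    f"{path}: line {ln}: position {pos} outside 1..{n}"
                )
            if pos in seen:
                raise ValueError(f"{path}: line {ln}: duplicate position {pos}")
            seen.add(pos)
            if val != MISSING_SENTINEL:
                values[pos - 1] = val
    return values


def write_reactivity(path: str | Path, values: np.ndarray) -> None:
    """Write a probing vector in the two-column dialect (NaN -> -999)."""
    with open(path, "w") as fh:
        for i, v in enumerate(values, start=1):
            out = MISSING_SENTINEL if (v is None or math.isnan(v)) else v
            fh.write(f"{i} {out:.6f}\n")


# ----------------------------------------------------------------------
# dot-bracket


def parse_structure(
    text: str,
    *,
    theta: int | None = None,
    sequence: str | None = None,
    severity: str = "warn",
) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Balanced ``()`` with ``.`` for unpaired.  Validation severity for the
    hairpin/pairing-rule checks defaults to ``"warn"`` because reference
    structures may contain non-canonical pairs; the folding engine constructs
    its own structures with ``"reject"``.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text.strip()):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos + 1}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {pos + 1}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return SecondaryStructure(
        n=len(text.strip()), pairs=tuple(pairs),
        theta=theta, sequence=sequence, severity=severity,
    )


def write_structure(structure: SecondaryStructure) -> str:
    """Dot-bracket rendering (inverse of :func:`parse_structure`)."""
    return structure.to_dotbracket()


# ----------------------------------------------------------------------
# CT


def read_ct(path: str | Path) -> tuple[RnaSequence, SecondaryStructure]:
    """Read a standard 6-column CT file (first structure record)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed CT header") from exc
    body = lines[1 : 1 + n]
    if len(body) != n:
        raise ValueError(f"{path}: header says {n} rows, found {len(body)}")
    residues = []
    partner = [0] * (n + 1)
    for row_no, line in enumerate(body, start=1):
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"{path}: CT row {row_no}: expected 6 columns")
        idx = int(fields[0])
        if idx != row_no:
            raise ValueError(f"{path}: CT row {row_no}: index column says {idx}")
        residues.append(fields[1])
        partner[row_no] = int(fields[4])
    pairs = []
    for i in range(1, n + 1):
        j = partner[i]
        if j == 0:
            continue
        if not (1 <= j <= n) or partner[j] != i:
            raise ValueError(
                f"{path}: inconsistent partner columns at position {i} "
                f"(partner({i})={j}, partner({j})={partner[j] if 1 <= j <= n else '?'})"
            )
        if j > i:
            pairs.append((i - 1, j - 1))
    name = " ".join(header[1:]) or str(path)
    seq = RnaSequence(identifier=name, residues="".join(residues))
    return seq, SecondaryStructure(n=n, pairs=tuple(pairs), severity="warn")


def write_ct(
    seq: RnaSequence,
    structure: SecondaryStructure,
    path: str | Path,
    energy: float | None = None,
) -> None:
    """Write a 6-column CT file; the header carries the energy if given."""
    n = len(seq)
    if structure.n != n:
        raise ValueError("sequence/structure length mismatch")
    table = structure.pair_table
    with open(path, "w") as fh:
        head = f"{n}"
        if energy is not None:
            head += f" ENERGY = {energy:.2f}"
        head += f" {seq.identifier}"
        fh.write(head + "\n")
        for i in range(1, n + 1):
            j = int(table[i - 1]) + 1  # 0 if unpaired
            fh.write(
                f"{i} {seq.residues[i - 1]} {i - 1} {(i + 1) % (n + 1)} {j} {i}\n"
            )


# ----------------------------------------------------------------------
# reports


def write_bpp(
    path: str | Path, p: np.ndarray, threshold: float = 1e-6
) -> None:
    """Write base-pair probabilities as 1-based ``i j p`` triples (p >= threshold)."""
    n = p.shape[0]
    with open(path, "w") as fh:
        for i in range(n):
            for j in range(i + 1, n):
                if p[i, j] >= threshold:
                    fh.write(f"{i + 1} {j + 1} {p[i, j]:.6f}\n")


def write_metrics_json(path: str | Path, metrics: dict) -> None:
    """Serialize a metrics report to JSON (numpy scalars/arrays converted)."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, default=default)
        fh.write("\n")
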