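"""Deterministic synthetic data: sequences, structures, probing profiles.

The generator emulates the shape of real probing experiments on short RNAs:
a ground-truth structure induces an unpaired indicator x, and the synthetic
normalized profile is q = x +- uniform noise (clipped to [0, 1]); synthetic
*raw* SHAPE-like reactivities place paired positions in the low-reactivity
band and unpaired positions in the moderate-to-high band of the conventional
0..2.2 scale.  Everything is driven by a seeded generator so fixture
directories are byte-identical across runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .energy import EnergyParams
from .io import write_reactivity
from .oracle import enumerate_structures
from .structures import RnaSequence, SecondaryStructure

_BASES = np.array(list("ACGU"))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform random RNA sequence (GC-ish bias helps form some structure)."""
    return "".join(rng.choice(_BASES, size=length, p=[0.2, 0.3, 0.3, 0.2]))


def random_structure(
    seq: str, params: EnergyParams, rng: np.random.Generator
) -> SecondaryStructure:
    """A structure drawn uniformly from the full structure space of *seq*."""
    structures = enumerate_structures(seq, params)
    return structures[int(rng.integers(len(structures)))]


def structured_sequence(
    rng: np.random.Generator, n_helices: int = 2, stem: int = 5, loop: int = 4
) -> tuple[str, SecondaryStructure]:
    """A sequence designed around known helices, with its target structure.

    Builds ``n_helices`` consecutive stem-loops joined by short single-strand
    linkers — long enough to have a rich ensemble, short enough to fold fast.
    """
    seq_parts: list[str] = []
    pairs: list[tuple[int, int]] = []
    pos = 0
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    for _ in range(n_helices):
        stem_seq = "".join(rng.choice(_BASES, size=stem, p=[0.15, 0.35, 0.35, 0.15]))
        loop_seq = "".join(rng.choice(_BASES, size=loop))
        rev = "".join(comp[b] for b in reversed(stem_seq))
        start = pos
        seq_parts.append(stem_seq + loop_seq + rev)
        total = 2 * stem + loop
        for k in range(stem):
            pairs.append((start + k, start + total - 1 - k))
        pos += total
        linker = "".join(rng.choice(_BASES, size=3))
        seq_parts.append(linker)
        pos += 3
    seq = "".join(seq_parts)
    structure = SecondaryStructure(
        n=len(seq), pairs=tuple(pairs), theta=3, sequence=seq, severity="reject"
    )
    return seq, structure


def synthetic_profile(
    structure: SecondaryStructure,
    rng: np.random.Generator,
    noise: float = 0.2,
    missing_frac: float = 0.0,
    discordant_frac: float = 0.0,
) -> np.ndarray:
    """Normalized profile q = x +- U(0, noise), clipped to [0, 1].

    ``missing_frac`` of the positions are replaced by NaN to emulate
    unreadable bands/no-data positions; ``discordant_frac`` of the positions
    report the *opposite* pairing state (q centered on 1 - x), emulating the
    discrepancies real probing data shows against crystallographic structures
    (tertiary contacts, differential reagent accessibility).
    """
    x = structure.x
    target = x.copy()
    if discordant_frac > 0.0:
        flip = rng.random(x.size) < discordant_frac
        target[flip] = 1.0 - target[flip]
    q = np.clip(target + rng.uniform(-noise, noise, size=x.size), 0.0, 1.0)
    if missing_frac > 0.0:
        mask = rng.random(x.size) < missing_frac
        q[mask] = np.nan
    return q


def synthetic_raw_shape(
    structure: SecondaryStructure,
    rng: np.random.Generator,
    missing_frac: float = 0.0,
) -> np.ndarray:
    """Raw SHAPE-like reactivities on the conventional 0..2.2 scale."""
    x = structure.x
    raw = np.where(
        x == 1.0,
        rng.uniform(0.7, 2.2, size=x.size),
        rng.uniform(0.0, 0.25, size=x.size),
    )
    if missing_frac > 0.0:
        mask = rng.random(x.size) < missing_frac
        raw[mask] = np.nan
    return raw


def make_fixtures(seed: int, outdir: str | Path, params: EnergyParams) -> Path:
    """Write a deterministic fixture directory (same seed => same bytes).

    Contents: random valid sequences (length 8..16) with a sampled structure
    and a noisy profile each, one designed two-helix instance, and malformed
    negative files for the I/O error paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    for idx in range(5):
        length = int(rng.integers(8, 17))
        seq = random_sequence(rng, length)
        structure = random_structure(seq, params, rng)
        q = synthetic_profile(structure, rng, noise=0.2)
        stem = outdir / f"random_{idx}"
        (stem.with_suffix(".fa")).write_text(f">random_{idx}\n{seq}\n")
        (stem.with_suffix(".db")).write_text(structure.to_dotbracket() + "\n")
        write_reactivity(stem.with_suffix(".shape"), q)
    seq, structure = structured_sequence(rng)
    (outdir / "twohelix.fa").write_text(f">twohelix\n{seq}\n")
    (outdir / "twohelix.db").write_text(structure.to_dotbracket() + "\n")
    write_reactivity(outdir / "twohelix.shape", synthetic_profile(structure, rng, 0.1))
    # malformed negatives for I/O tests
    (outdir / "bad_residue.fa").write_text(">bad\nACGNA\n")
    (outdir / "bad_duplicate.shape").write_text("1 0.2\n1 0.3\n")
    (outdir / "bad_range.shape").write_text("99 0.5\n")
    (outdir / "bad_unbalanced.db").write_text("((..\n")
    (outdir / "bad_partner.ct").write_text(
        "5 bad\n1 G 0 2 5 1\n2 G 1 3 0 2\n3 A 2 4 0 3\n4 C 3 5 0 4\n5 C 4 0 0 5\n"
    )
    return outdir


def sequence_record(name: str, seq: str) -> RnaSequence:
    """Convenience wrapper used by tests and examples."""
    return RnaSequence(identifier=name, residues=seq)
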