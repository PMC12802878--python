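"""Reproducible synthetic proteomes for testing and demonstration.

Generates a FASTA of random protein sequences with a controlled
small/large composition (exact counts, not expectations) and
configurable residue frequencies. Defaults approximate average bacterial
proteome composition, so every catalogued protease finds cleavage sites
at realistic densities. Headers carry the true length class
(``group=small``/``group=large``) so tests can assert grouping
independently of the grouping code.

A synthetic proteome emulates the *combinatorics* of a real database —
length distribution across the small/large boundary, substring-level
peptide sharing, per-protease site densities — but not homology
structure: real proteomes contain paralogous families with long shared
stretches, so real uniqueness rates are lower than synthetic ones.
"""

from __future__ import annotations

import math

import numpy as np

from .prep import ProteinRecord

__all__ = ["DEFAULT_RESIDUE_FREQS", "generate_synthetic_proteome", "write_fasta"]

#: Approximate average residue frequencies of a bacterial proteome.
DEFAULT_RESIDUE_FREQS = {
    "A": 0.089, "R": 0.053, "N": 0.040, "D": 0.054, "C": 0.008,
    "E": 0.062, "Q": 0.038, "G": 0.073, "H": 0.021, "I": 0.066,
    "L": 0.097, "K": 0.063, "M": 0.024, "F": 0.042, "P": 0.043,
    "S": 0.062, "T": 0.055, "W": 0.012, "Y": 0.032, "V": 0.066,
}


def generate_synthetic_proteome(
    n_proteins: int,
    small_fraction: float = 0.3,
    small_length_range: tuple[int, int] = (20, 70),
    large_length_range: tuple[int, int] = (71, 450),
    residue_freqs: dict[str, float] | None = None,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Generate ``n_proteins`` random proteins with an exact small fraction.

    Exactly ``round(small_fraction * n_proteins)`` proteins (half-up) draw
    their length uniformly from ``small_length_range``; the rest from
    ``large_length_range``. Residues are i.i.d. with the given
    frequencies (zero frequencies allowed, e.g. to build site-free
    controls for a protease). Identical seeds give identical proteomes.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not 0.0 <= small_fraction <= 1.0:
        raise ValueError("small_fraction must be in [0, 1]")
    freqs = dict(DEFAULT_RESIDUE_FREQS if residue_freqs is None else residue_freqs)
    letters = sorted(freqs)
    probs = np.array([freqs[aa] for aa in letters], dtype=float)
    if probs.sum() <= 0 or np.any(probs < 0):
        raise ValueError("residue frequencies must be non-negative and sum > 0")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    n_small = int(math.floor(small_fraction * n_proteins + 0.5))
    records = []
    width = max(5, len(str(n_proteins)))
    for i in range(n_proteins):
        is_small = i < n_small
        lo, hi = small_length_range if is_small else large_length_range
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(letters)[rng.choice(len(letters), size=length, p=probs)])
        label = "small" if is_small else "large"
        records.append(
            ProteinRecord(
                protein_id=f"syn{i + 1:0{width}d}",
                sequence=seq,
                description=f"syn{i + 1:0{width}d} group={label}",
            )
        )
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as a plain multi-line FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.description or rec.protein_id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
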