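"""Per-peptide detectability scores that modulate sampling weights.

Not every peptide a protease produces is observable by LC-MS: extreme
lengths and extreme hydrophobicity hurt ionisation, chromatography and
fragmentation. Detectability enters the simulation as a score in [0, 1]
multiplying the abundance-derived sampling weight of each peptide.

Scores come from one of three sources:

``file``
    A two-column TSV (``peptide\\tscore``) produced by any external
    predictor (e.g. a deep-learning detectability model).
``heuristic``
    A deterministic built-in surrogate based on peptide length and the
    Kyte–Doolittle GRAVY index (see :func:`heuristic_score`).
``uniform``
    Every peptide scores 1 — detectability effectively disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "DetectabilityTable",
    "load_detectability",
    "heuristic_score",
    "combine_weight",
    "KYTE_DOOLITTLE",
]

logger = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class DetectabilityTable:
    """Mapping peptide sequence -> detectability score in [0, 1]."""

    source: str  # "file", "heuristic" or "uniform"
    scores: dict[str, float] = field(default_factory=dict)
    missing_fallback: float = 1.0
    _warned_missing: int = 0

    def lookup(self, peptide: str) -> float:
        if self.source == "uniform":
            return 1.0
        if self.source == "heuristic":
            return heuristic_score(peptide)
        try:
            return self.scores[peptide]
        except KeyError:
            if self._warned_missing == 0:
                logger.warning(
                    "peptide %s absent from detectability file; using neutral "
                    "fallback %.2f (further misses logged at debug level)",
                    peptide,
                    self.missing_fallback,
                )
            else:
                logger.debug("peptide %s absent from detectability file", peptide)
            self._warned_missing += 1
            return self.missing_fallback


def load_detectability(path) -> DetectabilityTable:
    """Read a peptide/score TSV into a :class:`DetectabilityTable`.

    Duplicate peptides must agree to 1e-9; scores outside [0, 1] are fatal
    with the offending line number.
    """
    path = Path(path)
    scores: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "peptide" and lineno == 1:
                continue
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            pep, raw = fields
            try:
                score = float(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1]")
            if pep in scores and abs(scores[pep] - score) > 1e-9:
                raise ValueError(
                    f"{path}:{lineno}: conflicting scores for peptide {pep!r}"
                )
            scores[pep] = score
    return DetectabilityTable(source="file", scores=scores)


def heuristic_score(peptide: str) -> float:
    """Deterministic length- and hydrophobicity-penalised score in [0, 1].

    The score is the product of two penalties::

        f_len   = clip(1 - 0.04 * max(0, 8 - L) - 0.02 * max(0, L - 20), 0.05, 1)
        f_gravy = clip(1 - 0.15 * max(0, |GRAVY| - 1.5), 0.05, 1)

    where ``L`` is the residue count and GRAVY the mean Kyte–Doolittle
    hydropathy. Peptides of 8–20 residues with moderate hydropathy score 1;
    very short, very long, very hydrophobic or very hydrophilic peptides
    are progressively penalised, floored at 0.05 so no peptide is ever
    fully excluded.
    """
    n = len(peptide)
    if n == 0:
        raise ValueError("empty peptide")
    f_len = 1.0 - 0.04 * max(0, 8 - n) - 0.02 * max(0, n - 20)
    f_len = min(1.0, max(0.05, f_len))
    gravy = sum(KYTE_DOOLITTLE.get(aa, 0.0) for aa in peptide) / n
    f_gravy = 1.0 - 0.15 * max(0.0, abs(gravy) - 1.5)
    f_gravy = min(1.0, max(0.05, f_gravy))
    return f_len * f_gravy


def combine_weight(abundance: float, detectability: float, enabled: bool) -> float:
    """Sampling weight: abundance, optionally scaled by detectability."""
    if abundance < 0:
        raise ValueError("abundance must be >= 0")
    if enabled:
        if not 0.0 <= detectability <= 1.0:
            raise ValueError("detectability must be in [0, 1]")
        return abundance * detectability
    return abundance
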