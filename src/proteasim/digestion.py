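"""In-silico proteolytic digestion and peptide-to-proteome mapping.

Digestion enumerates, per protease, every peptide with up to ``max_mc``
missed cleavages: with internal cleavage boundaries ``b_1 < ... < b_c``
the 0-MC peptides are the ``c+1`` fragments between consecutive
boundaries (termini included), and an m-MC peptide is the concatenation
of ``m+1`` consecutive fragments. Peptides are then filtered by length
and uncharged monoisotopic mass, and mapped back onto the *whole*
proteome as plain substrings — deliberately ignoring cleavage
specificity, because semi- and non-specific cleavage occur in practice
and a peptide that is unique only under the assumption of specific
cleavage can cause false-positive identifications. A peptide is unique
iff it occurs at exactly one position in the database; identical
sequences generated by different proteases are tracked independently per
protease, mirroring an experimental design where each digest is measured
separately.

Coordinates are 0-based half-open in memory and 1-based inclusive in the
TSV output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .prep import CANONICAL_RESIDUES, ProteinRecord
from .proteases import ProteaseSpec

__all__ = [
    "PeptideRecord",
    "PeptideFilter",
    "WATER_MONO",
    "cleavage_sites",
    "digest",
    "peptide_mass",
    "filter_peptides",
    "map_peptides",
    "SubstringIndex",
    "digest_proteome",
    "build_peptide_table",
    "write_peptide_table",
    "read_peptide_table",
    "PEPTIDE_TABLE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Monoisotopic mass of one water molecule (Da), added once per peptide.
WATER_MONO = 18.0105646863

_RESIDUE_MASS = {aa: _ptmass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES}


@dataclass
class PeptideRecord:
    """An in-silico peptide with its provenance annotations."""

    sequence: str
    protease: str
    mc_count: int
    mass: float = float("nan")
    occurrences: list[tuple[str, int, int]] = field(default_factory=list)
    is_unique: bool = False
    detectability: float | None = None


@dataclass(frozen=True)
class PeptideFilter:
    """Detection window: inclusive residue-length and mass (Da) ranges.

    Defaults cover a typical bottom-up LC-MS window.
    """

    min_length: int = 6
    max_length: int = 45
    min_mass: float = 400.0
    max_mass: float = 6000.0

    def __post_init__(self):
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")
        if self.min_mass > self.max_mass:
            raise ValueError("min_mass > max_mass")


def cleavage_sites(sequence: str, protease: ProteaseSpec) -> list[int]:
    """Internal boundary indices where the protease may cut.

    A boundary ``b`` (0 < b < len) separates residues ``b-1`` and ``b``.
    C-terminal rule: residue ``b-1`` is recognised and residue ``b`` is not
    blocked; N-terminal rule: residue ``b`` is recognised. Protein termini
    are never boundaries.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sites: list[int] = []
    if protease.side == "C":
        for b in range(1, len(sequence)):
            if sequence[b - 1] in protease.residues and sequence[b] not in protease.blocked_next:
                sites.append(b)
    else:
        for b in range(1, len(sequence)):
            if sequence[b] in protease.residues:
                sites.append(b)
    return sites


def digest(sequence: str, protease: ProteaseSpec, max_mc: int) -> list[PeptideRecord]:
    """Enumerate peptides of ``sequence`` with 0..max_mc missed cleavages."""
    if max_mc < 0:
        raise ValueError("max_mc must be >= 0")
    records = []
    for start, end, mc in digest_spans(sequence, protease, max_mc):
        records.append(
            PeptideRecord(sequence=sequence[start:end], protease=protease.name, mc_count=mc)
        )
    return records


def digest_spans(sequence, protease, max_mc):
    """Yield (start, end, mc_count) spans of the digestion of ``sequence``."""
    cuts = [0] + cleavage_sites(sequence, protease) + [len(sequence)]
    n_frag = len(cuts) - 1
    for mc in range(0, max_mc + 1):
        for i in range(n_frag - mc):
            yield cuts[i], cuts[i + mc + 1], mc


def peptide_mass(sequence: str) -> float:
    """Uncharged monoisotopic mass (Da): residue masses plus one water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER_MONO
    for aa in sequence:
        try:
            total += _RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"non-canonical residue {aa!r} in peptide") from None
    return total


def filter_peptides(peptides, flt: PeptideFilter):
    """Keep peptides inside the inclusive length and mass windows."""
    kept = []
    for p in peptides:
        n = len(p.sequence)
        if flt.min_length <= n <= flt.max_length and flt.min_mass <= p.mass <= flt.max_mass:
            kept.append(p)
    return kept


class SubstringIndex:
    """Exact-substring lookup over a proteome.

    A k-mer positional index over the concatenated database; candidate
    positions for a peptide come from its first k residues and are then
    verified, so all occurrences — including overlapping matches within
    one protein — are reported. Peptides shorter than k fall back to a
    sliding scan.
    """

    def __init__(self, proteome: list[ProteinRecord], k: int = 5):
        self.k = k
        self._ids = [rec.protein_id for rec in proteome]
        self._seqs = [rec.sequence for rec in proteome]
        sep = "\x00"
        self._text = sep.join(self._seqs)
        offsets = []
        pos = 0
        for s in self._seqs:
            offsets.append(pos)
            pos += len(s) + 1
        self._offsets = np.array(offsets, dtype=np.int64)
        index: dict[str, list[int]] = {}
        text = self._text
        for i in range(len(text) - k + 1):
            kmer = text[i : i + k]
            if sep in kmer:
                continue
            index.setdefault(kmer, []).append(i)
        self._index = index

    def _locate(self, global_pos: int) -> tuple[int, int]:
        prot_idx = int(np.searchsorted(self._offsets, global_pos, side="right")) - 1
        return prot_idx, global_pos - int(self._offsets[prot_idx])

    def occurrences(self, peptide: str) -> list[tuple[str, int, int]]:
        """All (protein_id, start, end) matches, 0-based half-open."""
        n = len(peptide)
        out = []
        if n >= self.k:
            for gpos in self._index.get(peptide[: self.k], ()):
                if self._text[gpos : gpos + n] == peptide:
                    prot_idx, local = self._locate(gpos)
                    if local + n <= len(self._seqs[prot_idx]):
                        out.append((self._ids[prot_idx], local, local + n))
        else:
            for prot_idx, seq in enumerate(self._seqs):
                start = seq.find(peptide)
                while start != -1:
                    out.append((self._ids[prot_idx], start, start + n))
                    start = seq.find(peptide, start + 1)
        return out


def map_peptides(peptides, proteome, require_unique: bool = True, index=None):
    """Annotate peptides with database occurrences and the uniqueness flag.

    Occurrence lists contain every exact substring match in the database,
    regardless of cleavage sites. ``is_unique`` means exactly one
    occurrence; with ``require_unique`` non-unique peptides are dropped.
    """
    if index is None:
        index = SubstringIndex(proteome)
    kept = []
    for p in peptides:
        occ = index.occurrences(p.sequence)
        p.occurrences = occ
        p.is_unique = len(occ) == 1
        if require_unique and not p.is_unique:
            continue
        kept.append(p)
    return kept


PEPTIDE_TABLE_COLUMNS = [
    "peptide",
    "protease",
    "mc_count",
    "mass_da",
    "protein_id",
    "start_1based",
    "end_1based",
    "n_occurrences",
    "is_unique",
    "detectability",
]


def digest_proteome(
    proteome: list[ProteinRecord],
    proteases: list[ProteaseSpec],
    max_mc: int,
    flt: PeptideFilter | None = None,
    require_unique: bool = True,
) -> pd.DataFrame:
    """Digest the whole proteome with each protease and build the peptide table.

    Returns one row per (peptide sequence, protease, database occurrence).
    A sequence generated at several positions/MC levels by one protease is
    listed once per protease with its minimum MC count. Peptides containing
    non-canonical residues (X and other ambiguity codes) are discarded with
    a logged count.

    Uses per-protein prefix sums of residue masses, so filtering by mass is
    O(1) per peptide.
    """
    if flt is None:
        flt = PeptideFilter()
    index = SubstringIndex(proteome)

    # per-protein mass prefix sums + non-canonical position prefix counts
    prefixes = {}
    for rec in proteome:
        seq = rec.sequence
        masses = np.zeros(len(seq) + 1)
        bad = np.zeros(len(seq) + 1, dtype=np.int32)
        for i, aa in enumerate(seq):
            m = _RESIDUE_MASS.get(aa)
            masses[i + 1] = masses[i] + (m if m is not None else 0.0)
            bad[i + 1] = bad[i] + (m is None)
        prefixes[rec.protein_id] = (masses, bad)

    frames = []
    for protease in proteases:
        # min mc per candidate sequence
        seq_mc: dict[str, int] = {}
        seq_mass: dict[str, float] = {}
        n_ambiguous = 0
        for rec in proteome:
            seq = rec.sequence
            masses, bad = prefixes[rec.protein_id]
            for start, end, mc in digest_spans(seq, protease, max_mc):
                n = end - start
                if n < flt.min_length or n > flt.max_length:
                    continue
                if bad[end] - bad[start]:
                    n_ambiguous += 1
                    continue
                m = masses[end] - masses[start] + WATER_MONO
                if m < flt.min_mass or m > flt.max_mass:
                    continue
                pep = seq[start:end]
                prev = seq_mc.get(pep)
                if prev is None or mc < prev:
                    seq_mc[pep] = mc
                    seq_mass[pep] = m
        if n_ambiguous:
            logger.info(
                "%s: discarded %d peptides containing non-canonical residues",
                protease.name,
                n_ambiguous,
            )
        rows = []
        for pep, mc in seq_mc.items():
            occ = index.occurrences(pep)
            n_occ = len(occ)
            unique = n_occ == 1
            if require_unique and not unique:
                continue
            for pid, start, end in occ:
                rows.append(
                    (pep, protease.name, mc, seq_mass[pep], pid, start + 1, end,
                     n_occ, unique)
                )
        frame = pd.DataFrame(
            rows,
            columns=PEPTIDE_TABLE_COLUMNS[:-1],
        )
        frames.append(frame)
        logger.info("%s: %d peptide rows after filtering", protease.name, len(frame))
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=PEPTIDE_TABLE_COLUMNS[:-1])
    )
    table["detectability"] = np.nan
    table = table.sort_values(
        ["protease", "protein_id", "start_1based", "peptide"], kind="mergesort"
    ).reset_index(drop=True)
    return table


def build_peptide_table(per_protease_peptides: dict[str, list[PeptideRecord]]) -> pd.DataFrame:
    """Combine mapped ``PeptideRecord`` lists into the annotated table.

    One row per (sequence, protease, occurrence); deterministic order
    (protease, protein_id, start).
    """
    rows = []
    for protease, peptides in per_protease_peptides.items():
        for p in peptides:
            for pid, start, end in p.occurrences:
                rows.append(
                    (
                        p.sequence,
                        protease,
                        p.mc_count,
                        p.mass,
                        pid,
                        start + 1,
                        end,
                        len(p.occurrences),
                        p.is_unique,
                        np.nan if p.detectability is None else p.detectability,
                    )
                )
    table = pd.DataFrame(rows, columns=PEPTIDE_TABLE_COLUMNS)
    return table.sort_values(
        ["protease", "protein_id", "start_1based", "peptide"], kind="mergesort"
    ).reset_index(drop=True)


def write_peptide_table(table: pd.DataFrame, path) -> None:
    """Write the peptide table as TSV (1-based inclusive coordinates)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# peptide table; coordinates are 1-based inclusive\n")
        # %.17g guarantees masses survive the text round-trip exactly
        table.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_peptide_table(path) -> pd.DataFrame:
    """Read a peptide table TSV, validating the column schema."""
    table = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in PEPTIDE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table {path} is missing columns {missing}")
    extra = [c for c in table.columns if c not in PEPTIDE_TABLE_COLUMNS]
    if extra:
        raise ValueError(f"peptide table {path} has unknown columns {extra}")
    return table[PEPTIDE_TABLE_COLUMNS]
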