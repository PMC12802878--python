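"""Proteome preparation: database loading, length grouping, virtual samples.

A proteomics experiment never detects the whole proteome. To emulate that,
each Monte-Carlo replicate ("virtual sample") assigns every protein either
a random abundance drawn from a configurable distribution (default
log-normal, spanning several orders of magnitude like protein copy numbers
in bacterial cells) or zero, marking the protein as absent. The fraction
of absent proteins is applied as an exact per-group count,
``round(fraction * group_size)`` with half-up rounding, so that e.g. a 45%
undetectable fraction on 1000 small proteins zeroes exactly 450 of them.

The preparation table is a plain TSV that users may edit — to regroup
proteins (e.g. by localisation instead of length) or to paste in measured
abundances — before it is fed to the downstream modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "GroupDefinition",
    "AbundanceModel",
    "VirtualSample",
    "DEFAULT_GROUPS",
    "load_fasta",
    "assign_groups",
    "sample_abundances",
    "write_prep_table",
    "read_prep_table",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProteinRecord:
    """One database entry: id, sequence and per-run annotations.

    ``length`` defaults to the residue count; records re-imported from a
    preparation table carry a length but no sequence.
    """

    protein_id: str
    sequence: str
    description: str = ""
    group: str | None = None
    length: int = 0

    def __post_init__(self):
        if self.sequence:
            if self.length and self.length != len(self.sequence):
                raise ValueError(
                    f"protein {self.protein_id!r}: stated length {self.length} "
                    f"!= sequence length {len(self.sequence)}"
                )
            self.length = len(self.sequence)
        elif self.length < 0:
            raise ValueError(f"protein {self.protein_id!r}: negative length")


@dataclass(frozen=True)
class GroupDefinition:
    """A length interval [min_length, max_length], both inclusive.

    ``max_length=None`` means unbounded above.
    """

    label: str
    min_length: int
    max_length: int | None = None

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError(f"group {self.label!r}: min_length must be >= 1")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError(f"group {self.label!r}: max_length < min_length")

    def contains(self, length: int) -> bool:
        if length < self.min_length:
            return False
        return self.max_length is None or length <= self.max_length


#: Default partition: small proteins (<= 70 aa, the sORF-encoded protein
#: size class) versus everything larger.
DEFAULT_GROUPS: tuple[GroupDefinition, ...] = (
    GroupDefinition("small", 1, 70),
    GroupDefinition("large", 71, None),
)


@dataclass(frozen=True)
class AbundanceModel:
    """Distribution of simulated protein abundances.

    ``location``/``scale`` parametrise the log of the abundance for the
    default log-normal (scale 2.0 spans roughly four orders of magnitude);
    ``undetectable_fraction`` is the per-group fraction of proteins set
    absent (abundance 0) in every virtual sample.
    """

    distribution_name: str = "lognormal"
    location: float = 0.0
    scale: float = 2.0
    undetectable_fraction: float = 0.45

    def __post_init__(self):
        if self.distribution_name != "lognormal":
            raise ValueError(
                f"unsupported abundance distribution {self.distribution_name!r}"
            )
        if self.scale <= 0:
            raise ValueError("abundance scale must be > 0")
        if not 0.0 <= self.undetectable_fraction <= 1.0:
            raise ValueError("undetectable_fraction must be in [0, 1]")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(mean=self.location, sigma=self.scale, size=n)


@dataclass
class VirtualSample:
    """One Monte-Carlo replicate's protein-abundance assignment."""

    sample_index: int
    seed: int
    abundances: dict[str, float]


def load_fasta(path) -> list[ProteinRecord]:
    """Load a protein FASTA into records, preserving file order.

    The protein id is the first whitespace-delimited token of the header;
    the full header is kept as ``description``. Sequences are upper-cased.
    Duplicate ids, empty files and empty sequences are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        seq = str(entry.seq).upper()
        if not seq:
            raise ValueError(f"FASTA entry {pid!r} has an empty sequence")
        if pid in seen:
            raise ValueError(f"duplicate protein identifier {pid!r} in {path}")
        seen.add(pid)
        records.append(
            ProteinRecord(protein_id=pid, sequence=seq, description=entry.description)
        )
    if not records:
        raise ValueError(f"FASTA file {path} contains no entries")
    return records


def _check_partition(groups) -> None:
    """Groups must partition [1, inf): no overlaps, no gaps, one unbounded."""
    if not groups:
        raise ValueError("no group definitions given")
    ordered = sorted(groups, key=lambda g: g.min_length)
    if ordered[0].min_length != 1:
        raise ValueError("group intervals must start at length 1")
    for lo, hi in zip(ordered, ordered[1:]):
        if lo.max_length is None:
            raise ValueError(
                f"group {lo.label!r} is unbounded but {hi.label!r} follows it"
            )
        if lo.max_length + 1 != hi.min_length:
            kind = "overlap" if lo.max_length >= hi.min_length else "gap"
            raise ValueError(
                f"group intervals {lo.label!r} and {hi.label!r} {kind} "
                f"at length {min(lo.max_length, hi.min_length)}"
            )
    if ordered[-1].max_length is not None:
        raise ValueError("last group interval must be unbounded (max_length=None)")
    if len({g.label for g in groups}) != len(list(groups)):
        raise ValueError("group labels must be distinct")


def assign_groups(records, groups=DEFAULT_GROUPS) -> list[ProteinRecord]:
    """Label each record with the unique group interval containing its length."""
    groups = tuple(groups)
    _check_partition(groups)
    for rec in records:
        for g in groups:
            if g.contains(rec.length):
                rec.group = g.label
                break
    return list(records)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_abundances(
    records,
    model: AbundanceModel,
    sample_index: int,
    seed: int,
) -> VirtualSample:
    """Build one virtual sample.

    Per group, exactly ``round_half_up(fraction * group_size)`` proteins are
    set absent (abundance 0), chosen uniformly at random; the rest draw
    independent abundances. The per-sample RNG seed is ``seed + sample_index``
    so replicates are independently reproducible.
    """
    if any(rec.group is None for rec in records):
        raise ValueError("records must be grouped before sampling abundances")
    sample_seed = seed + sample_index
    rng = np.random.default_rng(sample_seed)
    abundances: dict[str, float] = {}
    by_group: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.group, []).append(rec)
    # iterate groups in first-appearance order for determinism
    for group, members in by_group.items():
        n_zero = _round_half_up(model.undetectable_fraction * len(members))
        zero_idx = set(
            rng.choice(len(members), size=n_zero, replace=False).tolist()
        )
        draws = model.draw(rng, len(members))
        for i, rec in enumerate(members):
            abundances[rec.protein_id] = 0.0 if i in zero_idx else float(draws[i])
    ordered = {rec.protein_id: abundances[rec.protein_id] for rec in records}
    return VirtualSample(sample_index=sample_index, seed=sample_seed, abundances=ordered)


_FIXED_COLUMNS = ("protein_id", "length", "group")


def write_prep_table(records, samples, path) -> None:
    """Serialise records + virtual samples as an editable UTF-8 TSV.

    Header: ``protein_id  length  group  abundance_s0  abundance_s1 ...``.
    Abundances use ``repr`` formatting so the round-trip is lossless.
    """
    samples = sorted(samples, key=lambda s: s.sample_index)
    header = list(_FIXED_COLUMNS) + [f"abundance_s{s.sample_index}" for s in samples]
    lines = ["\t".join(header)]
    for rec in records:
        row = [rec.protein_id, str(rec.length), rec.group or ""]
        for s in samples:
            row.append(repr(s.abundances[rec.protein_id]))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_prep_table(path):
    """Read a (possibly user-edited) preparation table.

    Returns ``(records, samples)``. Records carry no sequences (the table
    does not store them); their lengths and groups come from the file.
    Unknown columns or non-numeric abundances are fatal with a line number.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"prep table {path} is empty")
    header = lines[0].split("\t")
    if tuple(header[:3]) != _FIXED_COLUMNS:
        raise ValueError(
            f"{path}:1: prep table must start with columns {list(_FIXED_COLUMNS)}, "
            f"got {header[:3]}"
        )
    sample_indices: list[int] = []
    for col in header[3:]:
        if not col.startswith("abundance_s"):
            raise ValueError(f"{path}:1: unknown column {col!r}")
        try:
            sample_indices.append(int(col[len("abundance_s"):]))
        except ValueError:
            raise ValueError(f"{path}:1: unknown column {col!r}") from None
    records: list[ProteinRecord] = []
    lengths: dict[str, int] = {}
    per_sample: dict[int, dict[str, float]] = {i: {} for i in sample_indices}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        pid, length_s, group = fields[0], fields[1], fields[2]
        if pid in lengths:
            raise ValueError(f"{path}:{lineno}: duplicate protein_id {pid!r}")
        try:
            length = int(length_s)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-integer length {length_s!r}"
            ) from None
        lengths[pid] = length
        records.append(
            ProteinRecord(protein_id=pid, sequence="", group=group or None, length=length)
        )
        for idx, value in zip(sample_indices, fields[3:]):
            try:
                per_sample[idx][pid] = float(value)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric abundance {value!r} "
                    f"for protein {pid!r}"
                ) from None
    samples = [
        VirtualSample(sample_index=i, seed=-1, abundances=per_sample[i])
        for i in sample_indices
    ]
    return records, samples
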