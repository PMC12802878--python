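"""Run configuration: a single YAML file validated before any computation.

The file has flat sections per pipeline stage; every protease named in
``proteases`` must either exist in the built-in catalogue or specify its
cleavage rule inline. A copy of the parsed configuration is written into
each run's output directory for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .digestion import PeptideFilter
from .prep import AbundanceModel, GroupDefinition, DEFAULT_GROUPS
from .proteases import ProteaseSpec, get_protease
from .scoring import ScoreWeights

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    """Validated configuration for a full prediction run."""

    fasta_path: Path
    output_dir: Path = Path("proteasim_out")
    groups: tuple[GroupDefinition, ...] = DEFAULT_GROUPS
    abundance: AbundanceModel = field(default_factory=AbundanceModel)
    proteases: list[ProteaseSpec] = field(default_factory=list)
    peptides_per_protease: dict[str, int] = field(default_factory=dict)
    peptide_filter: PeptideFilter = field(default_factory=PeptideFilter)
    max_mc: int = 5
    require_unique: bool = True
    detectability_source: str = "uniform"  # uniform | heuristic | file
    detectability_path: Path | None = None
    control: tuple[str, ...] = ("trypsin",)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    max_k: int | None = None
    n_samples: int = 10
    master_seed: int = 0
    with_replacement: bool = False

    def __post_init__(self):
        if not self.proteases:
            raise ValueError("at least one protease must be configured")
        names = [p.name for p in self.proteases]
        if len(set(names)) != len(names):
            raise ValueError("duplicate protease names in configuration")
        for name in self.control:
            if name not in names:
                raise ValueError(
                    f"control protease {name!r} is not among the configured "
                    f"proteases {names}"
                )
        for name in names:
            if name not in self.peptides_per_protease:
                raise ValueError(f"no sampled-peptide count for protease {name!r}")
        if self.max_mc < 0:
            raise ValueError("max_mc must be >= 0")
        if self.max_k is not None and not 1 <= self.max_k <= len(names):
            raise ValueError(f"max_k must be in [1, {len(names)}]")
        if self.detectability_source not in ("uniform", "heuristic", "file"):
            raise ValueError(
                f"unknown detectability source {self.detectability_source!r}"
            )
        if self.detectability_source == "file" and self.detectability_path is None:
            raise ValueError("detectability source 'file' requires a path")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def detectability_enabled(self) -> bool:
        return self.detectability_source != "uniform"


def _parse_protease(entry, max_mc: int) -> tuple[ProteaseSpec, int]:
    if isinstance(entry, str):
        entry = {"name": entry}
    name = entry["name"].lower()
    peptides = int(entry.get("peptides", 10_000))
    if "residues" in entry:  # fully inline specification
        spec = ProteaseSpec(
            name=name,
            residues=frozenset(entry["residues"]),
            side=entry.get("side", "C"),
            blocked_next=frozenset(entry.get("blocked_next", "")),
            mc_fractions=tuple(entry.get("mc_fractions", (1.0,))),
        )
    else:
        spec = get_protease(name)
        if "mc_fractions" in entry:
            spec = spec.with_mc_fractions(entry["mc_fractions"])
    # trim or pad the MC profile to max_mc bins, renormalising
    fr = list(spec.mc_fractions[: max_mc + 1])
    fr += [0.0] * (max_mc + 1 - len(fr))
    total = sum(fr)
    if total <= 0:
        raise ValueError(f"protease {name!r}: mc_fractions all zero after trimming")
    spec = spec.with_mc_fractions([f / total for f in fr])
    return spec, peptides


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if "fasta" not in raw:
        raise ValueError(f"{path}: missing required key 'fasta'")
    max_mc = int(raw.get("max_mc", 5))

    groups = DEFAULT_GROUPS
    if "groups" in raw:
        groups = tuple(
            GroupDefinition(
                label=g["label"],
                min_length=int(g["min_length"]),
                max_length=None if g.get("max_length") is None else int(g["max_length"]),
            )
            for g in raw["groups"]
        )

    ab = raw.get("abundance", {})
    abundance = AbundanceModel(
        distribution_name=ab.get("distribution", "lognormal"),
        location=float(ab.get("location", 0.0)),
        scale=float(ab.get("scale", 2.0)),
        undetectable_fraction=float(ab.get("undetectable_fraction", 0.45)),
    )

    prot_entries = raw.get("proteases", ["trypsin"])
    proteases = []
    peptides_per_protease = {}
    for entry in prot_entries:
        spec, peptides = _parse_protease(entry, max_mc)
        proteases.append(spec)
        peptides_per_protease[spec.name] = peptides

    fl = raw.get("filter", {})
    peptide_filter = PeptideFilter(
        min_length=int(fl.get("min_length", 6)),
        max_length=int(fl.get("max_length", 45)),
        min_mass=float(fl.get("min_mass", 400.0)),
        max_mass=float(fl.get("max_mass", 6000.0)),
    )

    det = raw.get("detectability", {})
    w = raw.get("weights", {})
    control = raw.get("control", ["trypsin"])
    if isinstance(control, str):
        control = [control]

    return RunConfig(
        fasta_path=Path(raw["fasta"]),
        output_dir=Path(raw.get("output_dir", "proteasim_out")),
        groups=groups,
        abundance=abundance,
        proteases=proteases,
        peptides_per_protease=peptides_per_protease,
        peptide_filter=peptide_filter,
        max_mc=max_mc,
        require_unique=bool(raw.get("require_unique", True)),
        detectability_source=det.get("source", "uniform"),
        detectability_path=(
            Path(det["path"]) if det.get("path") is not None else None
        ),
        control=tuple(c.lower() for c in control),
        weights=ScoreWeights(
            w_prot=float(w.get("prot", 1.0)),
            w_pep=float(w.get("pep", 1.0)),
            w_cov=float(w.get("cov", 1.0)),
        ),
        max_k=None if raw.get("max_k") is None else int(raw["max_k"]),
        n_samples=int(raw.get("n_samples", 10)),
        master_seed=int(raw.get("master_seed", 0)),
        with_replacement=bool(raw.get("with_replacement", False)),
    )


def config_hash(path) -> str:
    """Stable hash of the configuration file contents (for run provenance)."""
    data = Path(path).read_bytes()
    return hashlib.sha256(data).hexdigest()[:16]
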