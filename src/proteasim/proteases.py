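"""Protease cleavage rules and missed-cleavage frequency profiles.

A protease is described by the residues it recognises, whether it cuts on
the C- or N-terminal side of the matched residue, an optional set of
residues that block cleavage when they immediately follow the cut site
(classically proline for trypsin and chymotrypsin), and a missed-cleavage
(MC) frequency profile: the expected fraction of identified peptides
carrying 0, 1, ... ``max_mc`` uncut internal sites.

The bundled MC profiles are configurable stand-ins chosen to be
qualitatively realistic for typical digestion protocols (Arg-C digestion
is nearly complete; chymotrypsin leaves most sites uncut; trypsin and
LysArgiNase sit in between with protocol-dependent spread). Users with
protocol-specific MC statistics should override them in the run
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["ProteaseSpec", "CATALOGUE", "get_protease"]

_MC_TOL = 1e-9


@dataclass(frozen=True)
class ProteaseSpec:
    """Cleavage rule plus missed-cleavage frequency distribution.

    Parameters
    ----------
    name
        Catalogue name, lower case by convention.
    residues
        Amino-acid letters recognised by the protease.
    side
        ``"C"`` if the bond C-terminal to the matched residue is cut,
        ``"N"`` for the bond on its N-terminal side.
    blocked_next
        Residues that suppress cleavage when they directly follow the
        cut position (C-terminal rules only; empty set disables).
    mc_fractions
        Expected fraction of identified peptides with 0..max_mc missed
        cleavages; must sum to 1.
    """

    name: str
    residues: frozenset[str]
    side: str  # "C" or "N"
    blocked_next: frozenset[str] = frozenset()
    mc_fractions: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protease {self.name!r}: empty residue set")
        if self.side not in ("C", "N"):
            raise ValueError(f"protease {self.name!r}: side must be 'C' or 'N'")
        if not self.mc_fractions:
            raise ValueError(f"protease {self.name!r}: empty mc_fractions")
        if any(f < 0 for f in self.mc_fractions):
            raise ValueError(f"protease {self.name!r}: negative mc fraction")
        if abs(sum(self.mc_fractions) - 1.0) > _MC_TOL:
            raise ValueError(
                f"protease {self.name!r}: mc_fractions sum to "
                f"{sum(self.mc_fractions)!r}, expected 1"
            )

    @property
    def max_mc(self) -> int:
        return len(self.mc_fractions) - 1

    def with_mc_fractions(self, fractions) -> "ProteaseSpec":
        return replace(self, mc_fractions=tuple(float(f) for f in fractions))


def _spec(name, residues, side, blocked="", mc=(1.0,)):
    return ProteaseSpec(
        name=name,
        residues=frozenset(residues),
        side=side,
        blocked_next=frozenset(blocked),
        mc_fractions=tuple(mc),
    )


def _norm(v):
    s = sum(v)
    return tuple(x / s for x in v)


# Default MC profiles over 0..5 missed cleavages (see module docstring).
_MC_DEFAULTS = {
    "trypsin": _norm((0.70, 0.20, 0.07, 0.02, 0.007, 0.003)),
    "trypsin/p": _norm((0.70, 0.20, 0.07, 0.02, 0.007, 0.003)),
    "lys-c": _norm((0.82, 0.13, 0.04, 0.007, 0.002, 0.001)),
    "arg-c": _norm((0.95, 0.04, 0.01, 0.0, 0.0, 0.0)),
    "chymotrypsin": _norm((0.20, 0.30, 0.25, 0.15, 0.07, 0.03)),
    "chymotrypsin-strict": _norm((0.20, 0.30, 0.25, 0.15, 0.07, 0.03)),
    "glu-c": _norm((0.55, 0.25, 0.12, 0.05, 0.02, 0.01)),
    "glu-c/ed": _norm((0.55, 0.25, 0.12, 0.05, 0.02, 0.01)),
    "lysarginase": _norm((0.60, 0.22, 0.10, 0.05, 0.02, 0.01)),
    "lys-n": _norm((0.75, 0.17, 0.05, 0.02, 0.007, 0.003)),
    "asp-n": _norm((0.65, 0.22, 0.08, 0.03, 0.015, 0.005)),
}

#: Built-in protease catalogue. Trypsin and chymotrypsin apply the proline
#: block by default; the ``/p`` and ``-strict`` variants expose the common
#: alternative conventions. All entries can be overridden from the config.
CATALOGUE: dict[str, ProteaseSpec] = {
    s.name: s
    for s in [
        _spec("trypsin", "KR", "C", blocked="P", mc=_MC_DEFAULTS["trypsin"]),
        _spec("trypsin/p", "KR", "C", mc=_MC_DEFAULTS["trypsin/p"]),
        _spec("lys-c", "K", "C", mc=_MC_DEFAULTS["lys-c"]),
        _spec("arg-c", "R", "C", mc=_MC_DEFAULTS["arg-c"]),
        _spec("chymotrypsin", "FWYL", "C", blocked="P",
              mc=_MC_DEFAULTS["chymotrypsin"]),
        _spec("chymotrypsin-strict", "FWY", "C",
              mc=_MC_DEFAULTS["chymotrypsin-strict"]),
        _spec("glu-c", "E", "C", mc=_MC_DEFAULTS["glu-c"]),
        _spec("glu-c/ed", "ED", "C", mc=_MC_DEFAULTS["glu-c/ed"]),
        _spec("lysarginase", "KR", "N", mc=_MC_DEFAULTS["lysarginase"]),
        _spec("lys-n", "K", "N", mc=_MC_DEFAULTS["lys-n"]),
        _spec("asp-n", "D", "N", mc=_MC_DEFAULTS["asp-n"]),
    ]
}


def get_protease(name: str) -> ProteaseSpec:
    """Look up a catalogued protease by (case-insensitive) name."""
    key = name.lower()
    if key not in CATALOGUE:
        known = ", ".join(sorted(CATALOGUE))
        raise KeyError(f"unknown protease {name!r}; catalogue: {known}")
    return CATALOGUE[key]
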