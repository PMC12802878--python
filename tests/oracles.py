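"""Independent brute-force reference implementations used only by tests.

These deliberately take the slow, obviously-correct route: digestion by
checking every substring of the protein against the cleavage rule, and
mapping by a sliding-window scan over every protein.
"""

from __future__ import annotations


def cut_allowed(sequence: str, b: int, protease) -> bool:
    """May the protease cut between residues b-1 and b? (0 < b < len)."""
    if protease.side == "C":
        return (
            sequence[b - 1] in protease.residues
            and sequence[b] not in protease.blocked_next
        )
    return sequence[b] in protease.residues


def brute_force_digest(sequence: str, protease, max_mc: int):
    """Every (start, end, mc) span by checking all substrings.

    A substring [i, j) is a digest peptide iff both ends are either a
    protein terminus or an allowed cut, with mc = number of allowed cuts
    strictly inside it.
    """
    n = len(sequence)
    internal = [b for b in range(1, n) if cut_allowed(sequence, b, protease)]
    boundaries = [0] + internal + [n]
    # number of allowed internal cuts <= x, for O(1) missed-cleavage counts
    n_cuts_upto = [0] * (n + 1)
    count = 0
    cut_set = set(internal)
    for x in range(n + 1):
        if x in cut_set:
            count += 1
        n_cuts_upto[x] = count
    spans = set()
    for a, i in enumerate(boundaries):
        for j in boundaries[a + 1 :]:
            mc = n_cuts_upto[j - 1] - n_cuts_upto[i]
            if mc <= max_mc:
                spans.add((i, j, mc))
    return spans


def naive_occurrences(peptide: str, proteome):
    """All substring matches by a sliding-window scan (includes overlaps)."""
    out = []
    n = len(peptide)
    for rec in proteome:
        seq = rec.sequence
        for i in range(len(seq) - n + 1):
            if seq[i : i + n] == peptide:
                out.append((rec.protein_id, i, i + n))
    return out
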