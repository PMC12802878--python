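"""Monte-Carlo core: MC-bin allocation, weighted sampling, protein inference.

Each virtual sample is "measured" once per protease: the requested number
of identified peptides is split across missed-cleavage bins according to
the protease's expected MC frequency profile (10 000 peptides with a 5%
one-MC fraction give 500 one-MC and 9500 fully-cleaved peptides), and
each bin is sampled without replacement with probability proportional to
peptide weight (protein abundance, optionally scaled by detectability).
Proteins are then inferred from the sampled peptides: a protein counts as
identified when at least ``min_unique`` distinct unique peptides map to
it (reported for both the 1-unique and the stricter two-unique-peptides
rule), and its sequence coverage is the fraction of residues covered by
the union of its sampled peptides' positions.

Protease combinations emulate separately measured digests of the same
sample: identified-protein sets are unioned, sampled peptide counts
summed, and coverage computed from the union of peptide intervals across
the member proteases. With the uniqueness filter off, indistinguishable
proteins form protein groups whose coverage and peptide count are the
medians over group members (metaproteomics-style reporting).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detectability import DetectabilityTable
from .prep import ProteinRecord, VirtualSample
from .proteases import ProteaseSpec

__all__ = [
    "SamplingConfig",
    "PeptideEntity",
    "ProteinStats",
    "InferenceResult",
    "IdentifiedEntity",
    "allocate_mc_bins",
    "weighted_sample",
    "infer_proteins",
    "run_monte_carlo",
    "MonteCarloRun",
    "build_protein_info",
    "merge_intervals",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingConfig:
    """Knobs of the Monte-Carlo measurement simulation."""

    peptides_per_protease: dict[str, int]
    n_samples: int = 10
    master_seed: int = 0
    detectability_enabled: bool = False
    with_replacement: bool = False
    require_unique: bool = True

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name, n in self.peptides_per_protease.items():
            if n < 1:
                raise ValueError(f"peptides_per_protease[{name!r}] must be >= 1")


@dataclass
class PeptideEntity:
    """One sampleable peptide: a (sequence, protease) pair with annotations."""

    sequence: str
    protease: str
    mc_count: int
    occurrences: list[tuple[str, int, int]]
    is_unique: bool
    detectability: float = 1.0

    @property
    def key(self) -> tuple[str, str]:
        return (self.protease, self.sequence)


@dataclass
class ProteinInfo:
    length: int
    group: str
    order: int


def build_protein_info(records: list[ProteinRecord]) -> dict[str, ProteinInfo]:
    return {
        rec.protein_id: ProteinInfo(length=rec.length, group=rec.group, order=i)
        for i, rec in enumerate(records)
    }


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    quotas = total * fractions
    alloc = np.floor(quotas).astype(np.int64)
    rem = int(total - alloc.sum())
    if rem > 0:
        frac_part = quotas - alloc
        # largest fractional part first; ties broken by lower bin index
        order = np.lexsort((np.arange(len(fractions)), -frac_part))
        alloc[order[:rem]] += 1
    return alloc


def allocate_mc_bins(total, mc_fractions, pool_sizes=None) -> np.ndarray:
    """Split ``total`` across MC bins by largest-remainder rounding.

    When ``pool_sizes`` is given, bins are capped at their pool size and
    the excess is redistributed to the remaining bins proportionally to
    their fractions (again with largest-remainder rounding). An overall
    shortfall — total pool smaller than ``total`` — allocates the whole
    pool and is logged; a completely empty pool is an error.
    """
    fractions = np.asarray(mc_fractions, dtype=float)
    if total < 0:
        raise ValueError("total must be >= 0")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"mc_fractions sum to {fractions.sum()!r}, expected 1")
    alloc = _largest_remainder(total, fractions)
    if pool_sizes is None:
        return alloc
    pools = np.asarray(pool_sizes, dtype=np.int64)
    if len(pools) != len(fractions):
        raise ValueError("pool_sizes length must match mc_fractions")
    if total > 0 and pools.sum() == 0:
        raise ValueError("all missed-cleavage peptide pools are empty")
    if total > pools.sum():
        logger.warning(
            "requested %d peptides but only %d available across all MC bins",
            total,
            int(pools.sum()),
        )
        return pools.copy()
    realloc_round = 0
    while True:
        overflow = np.maximum(alloc - pools, 0)
        excess = int(overflow.sum())
        if excess == 0:
            return alloc
        realloc_round += 1
        alloc = np.minimum(alloc, pools)
        open_bins = alloc < pools
        sub_fractions = fractions[open_bins]
        if sub_fractions.sum() <= 0:
            # remaining capacity sits in zero-fraction bins; spread evenly
            sub_fractions = np.ones(int(open_bins.sum()))
        sub_fractions = sub_fractions / sub_fractions.sum()
        extra = _largest_remainder(excess, sub_fractions)
        alloc[open_bins] += extra
        logger.info(
            "MC-bin reallocation round %d: moved %d peptides out of "
            "exhausted bins",
            realloc_round,
            excess,
        )


def weighted_sample(pool, weights, n, rng, with_replacement=False):
    """Draw ``n`` items from ``pool`` with probability proportional to weight.

    Without replacement this realises successive sampling — each draw
    proportional to weight among the remaining candidates — via the
    Efraimidis–Spirakis exponential-key method (select the ``n`` smallest
    ``Exp(w_i)`` arrival times), which is equivalent in distribution and
    fully vectorised. Zero-weight items are never drawn. If fewer than
    ``n`` positive-weight items exist, all of them are returned and the
    shortfall is logged.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(pool):
        raise ValueError("pool and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    if n == 0:
        return []
    pos = np.flatnonzero(weights > 0)
    if with_replacement:
        if len(pos) == 0:
            logger.warning("weighted_sample: no positive-weight items available")
            return []
        p = weights[pos] / weights[pos].sum()
        idx = rng.choice(pos, size=n, replace=True, p=p)
        return [pool[i] for i in idx]
    # exponential arrival times: smaller = drawn earlier
    keys = rng.exponential(size=len(pos)) / weights[pos]
    if n >= len(pos):
        if n > len(pos):
            logger.warning(
                "weighted_sample: requested %d but only %d positive-weight "
                "items; returning all",
                n,
                len(pos),
            )
        order = np.argsort(keys, kind="stable")
        return [pool[i] for i in pos[order]]
    part = np.argpartition(keys, n)[:n]
    order = part[np.argsort(keys[part], kind="stable")]
    return [pool[i] for i in pos[order]]


def merge_intervals(intervals):
    """Union of half-open intervals as a sorted, disjoint list."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _covered(intervals) -> int:
    return sum(e - s for s, e in intervals)


@dataclass
class ProteinStats:
    """Sampled-peptide evidence accumulated for one protein."""

    n_unique: int = 0
    n_pep: int = 0
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def merged(self) -> "ProteinStats":
        return ProteinStats(
            n_unique=self.n_unique,
            n_pep=self.n_pep,
            intervals=merge_intervals(self.intervals),
        )


@dataclass
class IdentifiedEntity:
    """An identified protein (or protein group in shared-peptide mode)."""

    members: tuple[str, ...]
    group: str
    coverage: float
    n_pep: float
    n_unique: int


@dataclass
class InferenceResult:
    """Identified entities for one (sample, protease-set, rule)."""

    min_unique: int
    entities: list[IdentifiedEntity]

    @property
    def identified_proteins(self) -> set[str]:
        return {pid for ent in self.entities for pid in ent.members}

    def metrics_by_group(self, group_labels) -> dict[str, tuple[int, float, float]]:
        """Per group label: (N_Prot, N_Pep, mean coverage)."""
        out = {}
        for label in group_labels:
            ents = [e for e in self.entities if e.group == label]
            n_prot = len(ents)
            n_pep = float(sum(e.n_pep for e in ents))
            cov = float(np.mean([e.coverage for e in ents])) if ents else 0.0
            out[label] = (n_prot, n_pep, cov)
        return out


def _accumulate_stats(sampled, protein_info) -> dict[str, ProteinStats]:
    """Per-protein unique-peptide counts, peptide counts and intervals."""
    stats: dict[str, ProteinStats] = {}
    for pep in sampled:
        for pid, start, end in pep.occurrences:
            st = stats.setdefault(pid, ProteinStats())
            st.n_pep += 1
            st.intervals.append((start, end))
            if pep.is_unique:
                st.n_unique += 1
    return stats


def _entities_from_stats(stats, min_unique, protein_info):
    entities = []
    for pid, st in stats.items():
        if st.n_unique < min_unique:
            continue
        info = protein_info[pid]
        cov = _covered(merge_intervals(st.intervals)) / info.length
        entities.append(
            IdentifiedEntity(
                members=(pid,),
                group=info.group,
                coverage=cov,
                n_pep=st.n_pep,
                n_unique=st.n_unique,
            )
        )
    entities.sort(key=lambda e: protein_info[e.members[0]].order)
    return entities


def _majority_group(members, protein_info) -> str:
    counts: dict[str, int] = {}
    for pid in sorted(members, key=lambda p: protein_info[p].order):
        counts[protein_info[pid].group] = counts.get(protein_info[pid].group, 0) + 1
    best = max(counts.values())
    for pid in sorted(members, key=lambda p: protein_info[p].order):
        if counts[protein_info[pid].group] == best:
            return protein_info[pid].group
    raise AssertionError("unreachable")


def _infer_shared(sampled, min_unique, protein_info):
    """Protein-group inference for shared-peptide (uniqueness-off) mode.

    Proteins sharing exactly the same set of sampled peptides form one
    group; a peptide counts as group-unique when all its occurrences fall
    inside the group. Coverage and peptide counts are medians over group
    members.
    """
    pep_sets: dict[str, set] = {}
    per_protein: dict[str, ProteinStats] = {}
    for pep in sampled:
        for pid, start, end in pep.occurrences:
            pep_sets.setdefault(pid, set()).add(pep.key)
            st = per_protein.setdefault(pid, ProteinStats())
            st.n_pep += 1
            st.intervals.append((start, end))
    groups: dict[frozenset, list[str]] = {}
    for pid, peps in pep_sets.items():
        groups.setdefault(frozenset(peps), []).append(pid)
    # group-uniqueness: all occurrence proteins of the peptide are members
    occ_proteins = {
        pep.key: {pid for pid, _, _ in pep.occurrences} for pep in sampled
    }
    entities = []
    for peps, members in groups.items():
        member_set = set(members)
        n_unique = sum(1 for key in peps if occ_proteins[key] <= member_set)
        if n_unique < min_unique:
            continue
        covs = []
        npeps = []
        for pid in members:
            info = protein_info[pid]
            st = per_protein[pid]
            covs.append(_covered(merge_intervals(st.intervals)) / info.length)
            npeps.append(st.n_pep)
        members_t = tuple(sorted(members, key=lambda p: protein_info[p].order))
        entities.append(
            IdentifiedEntity(
                members=members_t,
                group=_majority_group(members, protein_info),
                coverage=float(np.median(covs)),
                n_pep=float(np.median(npeps)),
                n_unique=n_unique,
            )
        )
    entities.sort(key=lambda e: protein_info[e.members[0]].order)
    return entities


def infer_proteins(sampled, min_unique, protein_info, shared_mode=False) -> InferenceResult:
    """Infer identified proteins (or protein groups) from sampled peptides.

    ``sampled`` items must carry ``occurrences`` (0-based half-open) and
    ``is_unique``. A protein is identified iff at least ``min_unique``
    distinct sampled unique peptides map to it; ``n_pep`` counts sampled
    peptides assigned to identified proteins only.
    """
    if isinstance(protein_info, list):
        protein_info = build_protein_info(protein_info)
    if shared_mode:
        entities = _infer_shared(sampled, min_unique, protein_info)
    else:
        stats = _accumulate_stats(sampled, protein_info)
        entities = _entities_from_stats(stats, min_unique, protein_info)
    return InferenceResult(min_unique=min_unique, entities=entities)


def _sub_seed(master_seed: int, sample_index: int, protease: str) -> np.random.Generator:
    """Deterministic per-(sample, protease) RNG, independent of run composition."""
    tag = zlib.crc32(protease.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, sample_index, tag])
    )


def entities_from_table(table: pd.DataFrame, detect_table=None) -> dict[str, list[PeptideEntity]]:
    """Collapse peptide-table rows into per-protease sampleable entities.

    Rows sharing (protease, peptide) are one entity whose occurrence list
    collects all mapped positions (coordinates converted back to 0-based
    half-open). Detectability comes from the table column when present,
    else from ``detect_table`` (neutral 1.0 without either).
    """
    out: dict[str, list[PeptideEntity]] = {}
    sorted_t = table.sort_values(["protease", "peptide"], kind="mergesort")
    by_key: dict[tuple[str, str], PeptideEntity] = {}
    cols = ["protease", "peptide", "mc_count", "protein_id", "start_1based",
            "end_1based", "is_unique", "detectability"]
    for protease, pep, mc, pid, s, e, uniq, det_col in zip(
        *(sorted_t[c].to_numpy() for c in cols)
    ):
        key = (protease, pep)
        ent = by_key.get(key)
        if ent is None:
            if pd.notna(det_col):
                det = float(det_col)
            elif detect_table is not None:
                det = detect_table.lookup(pep)
            else:
                det = 1.0
            ent = PeptideEntity(
                sequence=pep,
                protease=protease,
                mc_count=int(mc),
                occurrences=[],
                is_unique=bool(uniq),
                detectability=det,
            )
            by_key[key] = ent
            out.setdefault(protease, []).append(ent)
        ent.occurrences.append((pid, int(s) - 1, int(e)))
    return out


@dataclass
class MonteCarloRun:
    """All per-(sample, protease) outcomes of one Monte-Carlo run."""

    config: SamplingConfig
    protein_info: dict[str, ProteinInfo]
    proteases: list[str]
    sample_indices: list[int]
    #: (sample_index, protease) -> sampled peptide entities
    sampled: dict[tuple[int, str], list[PeptideEntity]]
    #: (sample_index, protease) -> per-protein evidence (unique mode)
    stats: dict[tuple[int, str], dict[str, ProteinStats]]

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for info in self.protein_info.values():
            if info.group not in seen:
                seen.append(info.group)
        return seen

    def combination_inference(self, sample_index, combo, min_unique) -> InferenceResult:
        """Inference for a protease combination within one virtual sample.

        Unique mode: union of the member proteases' identified-protein
        sets; peptide counts summed and coverage from the union of
        intervals across members. Shared-peptide mode: member digests are
        pooled and protein-group inference re-run on the pool.
        """
        combo = tuple(combo)
        if not self.config.require_unique:
            pooled = [p for name in combo for p in self.sampled[(sample_index, name)]]
            return infer_proteins(
                pooled, min_unique, self.protein_info, shared_mode=True
            )
        identified: set[str] = set()
        merged: dict[str, ProteinStats] = {}
        for name in combo:
            for pid, st in self.stats[(sample_index, name)].items():
                agg = merged.setdefault(pid, ProteinStats())
                agg.n_pep += st.n_pep
                agg.intervals.extend(st.intervals)
                if st.n_unique >= min_unique:
                    identified.add(pid)
                agg.n_unique = max(agg.n_unique, st.n_unique)
        entities = []
        for pid in identified:
            info = self.protein_info[pid]
            st = merged[pid]
            cov = _covered(merge_intervals(st.intervals)) / info.length
            entities.append(
                IdentifiedEntity(
                    members=(pid,),
                    group=info.group,
                    coverage=cov,
                    n_pep=st.n_pep,
                    n_unique=st.n_unique,
                )
            )
        entities.sort(key=lambda e: self.protein_info[e.members[0]].order)
        return InferenceResult(min_unique=min_unique, entities=entities)


def run_monte_carlo(
    config: SamplingConfig,
    proteome: list[ProteinRecord],
    samples: list[VirtualSample],
    peptide_table: pd.DataFrame,
    proteases: list[ProteaseSpec],
    detect_table: DetectabilityTable | None = None,
) -> MonteCarloRun:
    """Sample peptides for every (virtual sample x protease) and infer proteins.

    For each protease the requested peptide count is allocated across MC
    bins by the protease's MC frequency profile (empty bins reallocated),
    each bin sampled without replacement with abundance(x detectability)
    weights, and the per-protein evidence accumulated.
    """
    protein_info = build_protein_info(proteome)
    entities = entities_from_table(peptide_table, detect_table=detect_table)
    spec_by_name = {p.name: p for p in proteases}
    for name in spec_by_name:
        if name not in config.peptides_per_protease:
            raise ValueError(f"no peptides_per_protease entry for {name!r}")
        if name not in entities:
            raise ValueError(
                f"protease {name!r} has no peptides in the peptide table"
            )
    # vectorised weight assembly: entity weight = sum of occurrence-protein
    # abundances (x detectability); most entities have one occurrence
    pid_order = {pid: i for i, pid in enumerate(protein_info)}
    prepared = {}
    for name, pool in entities.items():
        det = np.array([pep.detectability for pep in pool])
        single = np.full(len(pool), -1, dtype=np.int64)
        multi = []
        for i, pep in enumerate(pool):
            idxs = [pid_order[pid] for pid, _, _ in pep.occurrences if pid in pid_order]
            if len(idxs) == 1:
                single[i] = idxs[0]
            else:
                multi.append((i, np.array(idxs, dtype=np.int64)))
        mc = np.array([pep.mc_count for pep in pool])
        prepared[name] = (det, single, multi, mc)

    sampled_all: dict[tuple[int, str], list[PeptideEntity]] = {}
    stats_all: dict[tuple[int, str], dict[str, ProteinStats]] = {}
    for sample in samples:
        ab_vec = np.array([sample.abundances.get(pid, 0.0) for pid in protein_info])
        for name, spec in spec_by_name.items():
            pool = entities[name]
            det, single, multi, mc = prepared[name]
            weights = np.zeros(len(pool))
            mask = single >= 0
            weights[mask] = ab_vec[single[mask]]
            for i, idxs in multi:
                weights[i] = ab_vec[idxs].sum() if len(idxs) else 0.0
            if config.detectability_enabled:
                weights = weights * det
            max_mc = spec.max_mc
            pool_sizes = [
                int(np.sum((mc == m) & (weights > 0))) for m in range(max_mc + 1)
            ]
            try:
                alloc = allocate_mc_bins(
                    config.peptides_per_protease[name], spec.mc_fractions, pool_sizes
                )
            except ValueError as exc:
                raise RuntimeError(
                    f"sampling failed for protease {name!r} in sample "
                    f"{sample.sample_index}: {exc}"
                ) from exc
            rng = _sub_seed(config.master_seed, sample.sample_index, name)
            drawn: list[PeptideEntity] = []
            for m in range(max_mc + 1):
                if alloc[m] == 0:
                    continue
                bin_idx = np.flatnonzero(mc == m)
                drawn.extend(
                    weighted_sample(
                        [pool[i] for i in bin_idx],
                        weights[bin_idx],
                        int(alloc[m]),
                        rng,
                        with_replacement=config.with_replacement,
                    )
                )
            key = (sample.sample_index, name)
            sampled_all[key] = drawn
            stats_all[key] = {
                pid: st.merged()
                for pid, st in _accumulate_stats(drawn, protein_info).items()
            }
    return MonteCarloRun(
        config=config,
        protein_info=protein_info,
        proteases=sorted(spec_by_name),
        sample_indices=[s.sample_index for s in samples],
        sampled=sampled_all,
        stats=stats_all,
    )
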