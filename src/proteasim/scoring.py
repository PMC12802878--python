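"""The protease score: a weighted geometric mean of workflow/control ratios.

For a protein group G and workflow A (a protease or protease
combination), with control workflow C (tryptic digestion by default):

    S_{G,A} = [ (N_Prot_A / N_Prot_C)^W_Prot
              * (N_Pep_A  / N_Pep_C )^W_Pep
              * (COV_A    / COV_C   )^W_COV ] ^ (1 / (W_Prot + W_Pep + W_COV))

where N_Prot is the number of identified proteins in G, N_Pep the number
of identified peptides belonging to them, and COV their mean sequence
coverage. Scores above 1 mean workflow A outperforms the control under
the chosen weighting. Normalisation is paired per Monte-Carlo round: each
round's workflow metrics divide the control metrics of the *same* virtual
sample, removing between-sample abundance noise from the ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .simulation import MonteCarloRun

__all__ = [
    "ScoreWeights",
    "ScoreInputs",
    "protease_score",
    "enumerate_combinations",
    "score_run",
    "summarize",
    "RESULTS_FILENAME",
    "SUMMARY_FILENAME",
    "write_results",
    "write_summary",
]

logger = logging.getLogger(__name__)

RESULTS_FILENAME = "protease_scores.tsv"
SUMMARY_FILENAME = "protease_scores_summary.tsv"


@dataclass(frozen=True)
class ScoreWeights:
    """Non-negative emphasis weights for the three score components."""

    w_prot: float = 1.0
    w_pep: float = 1.0
    w_cov: float = 1.0

    def __post_init__(self):
        if min(self.w_prot, self.w_pep, self.w_cov) < 0:
            raise ValueError("score weights must be >= 0")
        if self.w_prot + self.w_pep + self.w_cov <= 0:
            raise ValueError("score weights must not all be zero")


@dataclass(frozen=True)
class ScoreInputs:
    """The three metrics for one (group x workflow): counts and coverage."""

    n_prot: float
    n_pep: float
    cov: float

    def __post_init__(self):
        if self.n_prot < 0 or self.n_pep < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.cov <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


def protease_score(a: ScoreInputs, c: ScoreInputs, w: ScoreWeights = ScoreWeights()) -> float:
    """Weighted geometric mean of the three workflow/control ratios.

    Returns NaN (with a warning) when any control quantity is zero, so a
    degenerate control cell never aborts a run.
    """
    if c.n_prot == 0 or c.n_pep == 0 or c.cov == 0:
        logger.warning(
            "control workflow has a zero metric (n_prot=%s, n_pep=%s, cov=%s); "
            "score undefined",
            c.n_prot,
            c.n_pep,
            c.cov,
        )
        return float("nan")
    total_w = w.w_prot + w.w_pep + w.w_cov
    log_score = (
        w.w_prot * math.log(a.n_prot / c.n_prot)
        + w.w_pep * math.log(a.n_pep / c.n_pep)
        + w.w_cov * math.log(a.cov / c.cov)
        if min(a.n_prot, a.n_pep, a.cov) > 0
        else float("-inf")
    )
    return math.exp(log_score / total_w)


def enumerate_combinations(proteases, max_k: int) -> list[tuple[str, ...]]:
    """All non-empty protease subsets of size <= max_k.

    Deterministic order: by size, then lexicographic.
    """
    names = sorted(proteases)
    if not 1 <= max_k <= len(names):
        raise ValueError(f"max_k must be in [1, {len(names)}], got {max_k}")
    out: list[tuple[str, ...]] = []
    for k in range(1, max_k + 1):
        out.extend(combinations(names, k))
    return out


RESULTS_COLUMNS = [
    "sample_index",
    "combination",
    "group",
    "rule",
    "n_prot",
    "n_pep",
    "mean_cov",
    "score",
]


def score_run(
    run: MonteCarloRun,
    combos=None,
    control=("trypsin",),
    weights: ScoreWeights = ScoreWeights(),
    rules=(1, 2),
    max_k: int | None = None,
) -> pd.DataFrame:
    """Score every (sample x combination x group x rule) against the control.

    Returns the per-round results table; the control combination itself is
    included (its score is exactly 1 whenever its metrics are non-zero).
    """
    control = tuple(sorted(control))
    for name in control:
        if name not in run.proteases:
            raise ValueError(f"control protease {name!r} was not simulated")
    if combos is None:
        combos = enumerate_combinations(run.proteases, max_k or len(run.proteases))
    combos = list(combos)
    if control not in [tuple(sorted(c)) for c in combos]:
        combos.append(control)
    labels = run.group_labels()
    rows = []
    for sample_index in run.sample_indices:
        control_metrics = {}
        for rule in rules:
            res = run.combination_inference(sample_index, control, rule)
            control_metrics[rule] = res.metrics_by_group(labels)
        for combo in combos:
            combo = tuple(sorted(combo))
            for rule in rules:
                res = run.combination_inference(sample_index, combo, rule)
                metrics = res.metrics_by_group(labels)
                for label in labels:
                    n_prot, n_pep, cov = metrics[label]
                    c_prot, c_pep, c_cov = control_metrics[rule][label]
                    score = protease_score(
                        ScoreInputs(n_prot, n_pep, cov),
                        ScoreInputs(c_prot, c_pep, c_cov),
                        weights,
                    )
                    rows.append(
                        (
                            sample_index,
                            "+".join(combo),
                            label,
                            f"{rule}-unique",
                            n_prot,
                            n_pep,
                            cov,
                            score,
                        )
                    )
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


SUMMARY_COLUMNS = [
    "combination",
    "group",
    "rule",
    "score_mean",
    "score_sd",
    "n_rounds",
    "n_nan",
]


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of the score per (combination x group x rule).

    NaN rounds (undefined scores) are excluded from the statistics and
    counted in ``n_nan``; a single valid round reports SD 0.
    """
    rows = []
    grouped = results.groupby(["combination", "group", "rule"], sort=True)
    for (combo, label, rule), sub in grouped:
        scores = sub["score"].to_numpy(dtype=float)
        valid = scores[~np.isnan(scores)]
        n_nan = int(np.isnan(scores).sum())
        if len(valid) == 0:
            mean, sd = float("nan"), float("nan")
        elif len(valid) == 1:
            mean, sd = float(valid[0]), 0.0
        else:
            mean, sd = float(valid.mean()), float(valid.std(ddof=1))
        rows.append((combo, label, rule, mean, sd, len(valid), n_nan))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_results(results: pd.DataFrame, directory) -> Path:
    path = Path(directory) / RESULTS_FILENAME
    results.to_csv(path, sep="\t", index=False)
    return path


def write_summary(summary: pd.DataFrame, directory) -> Path:
    path = Path(directory) / SUMMARY_FILENAME
    summary.to_csv(path, sep="\t", index=False)
    return path
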