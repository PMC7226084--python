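"""Rank-based comparison of windows and algorithms across subjects.

A performance matrix holds one metric (e.g. AUC) for N subjects × k
conditions.  The Friedman test (with the standard tie correction) asks
whether conditions differ consistently across subjects; after a rejection,
either the Nemenyi critical difference on mean ranks or pairwise z-tests with
Holm or Bergmann–Hommel adjustment localizes the differences.  The
"significance graph" connects conditions that are NOT significantly
different, the representation used to summarize classifier comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import FeasibilityError, SizeError

#: q_0.05(k) = studentized-range 95% quantile at infinite df / sqrt(2);
#: fallback if the scipy distribution is unavailable at run time.
_Q05_TABLE = {2: 1.960, 3: 2.344, 4: 2.569, 5: 2.728, 6: 2.850,
              7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164}


def _as_matrix(values) -> np.ndarray:
    M = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) \
        else np.asarray(values, dtype=float)
    if M.ndim != 2:
        raise SizeError("performance matrix must be 2-D (subjects x conditions)")
    n, k = M.shape
    if n < 2 or k < 2:
        raise SizeError(f"need N >= 2 subjects and k >= 2 conditions, got {M.shape}")
    if not np.all(np.isfinite(M)):
        raise SizeError("performance matrix has missing/non-finite cells")
    return M


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p_value: float
    mean_ranks: np.ndarray


def friedman_test(values) -> FriedmanResult:
    """Tie-corrected Friedman test on an N×k matrix (rows = subjects).

    Per-row average ranks R_ij give column rank sums R_j; the statistic is
    ``(12/(Nk(k+1))) Σ R_j² − 3N(k+1)``, divided by the tie correction
    ``1 − Σ(t³−t) / (Nk(k²−1))``.  p comes from χ² with k−1 df.
    """
    M = _as_matrix(values)
    n, k = M.shape
    ranks = sstats.rankdata(M, axis=1)
    rank_sums = ranks.sum(axis=0)
    numer = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums ** 2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in M:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    denom = 1.0 - ties / (n * k * (k * k - 1))
    if denom <= 0:  # every row fully tied
        chi2 = 0.0
    else:
        chi2 = numer / denom
    df = k - 1
    p = float(sstats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return FriedmanResult(chi2=float(chi2), df=df, p_value=p,
                          mean_ranks=rank_sums / n)


def nemenyi_cd(k: int, n_subjects: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference ``q_α(k) sqrt(k(k+1)/(6N))``.

    Two conditions differ significantly iff their mean ranks differ by more
    than the CD.  ``q_α(k)`` is the studentized-range quantile at infinite df
    divided by √2 (cached table fallback for α = 0.05).
    """
    if not 2 <= k <= 10:
        raise SizeError(f"Nemenyi CD supported for 2 <= k <= 10, got k={k}")
    if n_subjects < 2:
        raise SizeError("need N >= 2 subjects")
    try:
        q = float(sstats.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2))
    except Exception:
        if abs(alpha - 0.05) > 1e-12:
            raise
        q = _Q05_TABLE[k]
    return q * np.sqrt(k * (k + 1) / (6.0 * n_subjects))


def _set_partitions(items: list[int]):
    """All partitions of a list into non-empty blocks (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _exhaustive_sets(k: int) -> list[frozenset]:
    """Bergmann–Hommel exhaustive hypothesis sets for all-pairs comparison:
    for each partition of the conditions into equal-groups, the set of
    within-block pair hypotheses that would then be simultaneously true."""
    sets = set()
    for part in _set_partitions(list(range(k))):
        hyp = frozenset(pair for block in part
                        for pair in combinations(sorted(block), 2))
        if hyp:
            sets.add(hyp)
    return sorted(sets, key=lambda s: (len(s), sorted(s)))


@dataclass
class PosthocResult:
    condition_labels: list[str]
    mean_ranks: np.ndarray
    method: str
    alpha: float
    raw_p: dict[tuple[int, int], float]
    adjusted_p: dict[tuple[int, int], float]
    #: pairs NOT significantly different at alpha (the significance-graph edges)
    edges: list[tuple[str, str]] = field(default_factory=list)
    critical_difference: float | None = None


def pairwise_posthoc(values, condition_labels: list[str] | None = None,
                     correction: str = "holm",
                     alpha: float = 0.05) -> PosthocResult:
    """All-pairs post-hoc after Friedman: z = (R̄_i − R̄_j)/sqrt(k(k+1)/(6N)),
    two-sided normal p, adjusted by Holm or by Bergmann–Hommel exhaustive-set
    enumeration (feasible for k <= 6)."""
    M = _as_matrix(values)
    n, k = M.shape
    labels = list(condition_labels) if condition_labels is not None \
        else [f"c{j}" for j in range(k)]
    if correction not in ("holm", "bergmann_hommel"):
        raise FeasibilityError(f"unknown correction {correction!r}")
    if correction == "bergmann_hommel" and k > 6:
        raise FeasibilityError(
            f"Bergmann-Hommel enumeration is infeasible for k={k} > 6; use holm")
    mean_ranks = friedman_test(M).mean_ranks
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(combinations(range(k), 2))
    raw = {pair: float(2 * sstats.norm.sf(
        abs(mean_ranks[pair[0]] - mean_ranks[pair[1]]) / se)) for pair in pairs}

    if correction == "holm":
        adj_vals = multipletests([raw[p] for p in pairs], method="holm")[1]
        adjusted = {pair: float(v) for pair, v in zip(pairs, adj_vals)}
    else:
        idx = {pair: i for i, pair in enumerate(pairs)}
        pvec = np.array([raw[p] for p in pairs])
        adjusted = {pair: 0.0 for pair in pairs}
        for hyp_set in _exhaustive_sets(k):
            bound = len(hyp_set) * min(pvec[idx[h]] for h in hyp_set)
            for h in hyp_set:
                if bound > adjusted[h]:
                    adjusted[h] = bound
        adjusted = {pair: float(min(v, 1.0)) for pair, v in adjusted.items()}

    edges = [(labels[i], labels[j]) for (i, j) in pairs
             if adjusted[(i, j)] >= alpha]
    return PosthocResult(condition_labels=labels, mean_ranks=mean_ranks,
                         method=correction, alpha=alpha, raw_p=raw,
                         adjusted_p=adjusted, edges=edges)


def nemenyi_posthoc(values, condition_labels: list[str] | None = None,
                    alpha: float = 0.05) -> PosthocResult:
    """Nemenyi critical-difference post-hoc; edges connect conditions whose
    mean-rank gap does not exceed the CD."""
    M = _as_matrix(values)
    n, k = M.shape
    labels = list(condition_labels) if condition_labels is not None \
        else [f"c{j}" for j in range(k)]
    mean_ranks = friedman_test(M).mean_ranks
    cd = nemenyi_cd(k, n, alpha)
    pairs = list(combinations(range(k), 2))
    edges = [(labels[i], labels[j]) for (i, j) in pairs
             if abs(mean_ranks[i] - mean_ranks[j]) <= cd]
    return PosthocResult(condition_labels=labels, mean_ranks=mean_ranks,
                         method="nemenyi", alpha=alpha, raw_p={},
                         adjusted_p={}, edges=edges, critical_difference=cd)


@dataclass
class ComparisonResult:
    friedman: FriedmanResult
    posthoc: PosthocResult

    def to_dict(self) -> dict:
        ph = self.posthoc
        return {
            "friedman": {"chi2": self.friedman.chi2, "df": self.friedman.df,
                         "p_value": self.friedman.p_value},
            "conditions": ph.condition_labels,
            "mean_ranks": [float(r) for r in ph.mean_ranks],
            "posthoc_method": ph.method,
            "alpha": ph.alpha,
            "critical_difference": ph.critical_difference,
            "adjusted_p": {f"{ph.condition_labels[i]}|{ph.condition_labels[j]}": p
                           for (i, j), p in sorted(ph.adjusted_p.items())},
            "not_significant_edges": [list(e) for e in ph.edges],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def compare_conditions(values, condition_labels: list[str] | None = None,
                       posthoc: str = "nemenyi",
                       alpha: float = 0.05) -> ComparisonResult:
    """Friedman test plus the requested post-hoc on a subjects × conditions
    metric matrix (DataFrame columns become condition labels)."""
    if isinstance(values, pd.DataFrame) and condition_labels is None:
        condition_labels = [str(c) for c in values.columns]
    fr = friedman_test(values)
    if posthoc == "nemenyi":
        ph = nemenyi_posthoc(values, condition_labels, alpha)
    else:
        ph = pairwise_posthoc(values, condition_labels, posthoc, alpha)
    return ComparisonResult(friedman=fr, posthoc=ph)


def plot_significance_graph(result: ComparisonResult, path: str | Path) -> None:
    """Draw the not-significantly-different graph: nodes on a circle labelled
    with mean ranks, edges between statistically indistinguishable pairs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ph = result.posthoc
    k = len(ph.condition_labels)
    theta = 2 * np.pi * np.arange(k) / k
    xy = np.column_stack([np.cos(theta), np.sin(theta)])
    fig, ax = plt.subplots(figsize=(4, 4))
    pos = {lab: xy[i] for i, lab in enumerate(ph.condition_labels)}
    for a, b in ph.edges:
        ax.plot(*zip(pos[a], pos[b]), color="0.6", zorder=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=300, color="steelblue", zorder=2)
    for i, lab in enumerate(ph.condition_labels):
        ax.annotate(f"{lab}\n(R̄={ph.mean_ranks[i]:.2f})", xy[i],
                    ha="center", va="center", fontsize=7, zorder=3)
    ax.set_axis_off()
    ax.set_title(f"{ph.method}, α={ph.alpha}", fontsize=9)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
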