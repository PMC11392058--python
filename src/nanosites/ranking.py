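"""Statistical grouping of materials by an oxidative-potential descriptor.

Replicate descriptor values (OP_mass, OP_area or OxTOF) are log-transformed
(multiplicative assay noise is closer to normal on the log scale), compared
by one-way ANOVA, then by Tukey's honestly-significant-difference test on
all pairs, and finally summarized as a compact letter display: samples
sharing a letter are not significantly different at the chosen alpha, and
the number of distinct letters is the number of reactivity categories.

The letter display is produced by the insert-and-absorb algorithm and is
verified against the pairwise matrix on every run (an exhaustive internal
consistency check): a pair shares a letter if and only if it is not
significantly different.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExclusionRecord",
    "RankingResult",
    "log_transform",
    "one_way_anova",
    "tukey_hsd",
    "compact_letters",
    "check_letters_consistent",
    "rank_samples",
]


@dataclass(frozen=True)
class ExclusionRecord:
    sample_id: str
    reason: str
    n_dropped: int = 0


@dataclass
class RankingResult:
    descriptor: str
    f_statistic: float
    p_anova: float
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    n_categories: int
    alpha: float
    group_means_log: dict[str, float]
    excluded: list[ExclusionRecord] = field(default_factory=list)


def log_transform(
    groups: Mapping[str, Sequence[float]],
) -> tuple[dict[str, np.ndarray], list[ExclusionRecord]]:
    """Natural log of the replicate values, per sample.

    Non-positive replicates are dropped (recorded); a sample with no
    positive replicate at all is excluded with an error record.  The log
    base is irrelevant to F statistics, Tukey decisions and letters.
    """
    out: dict[str, np.ndarray] = {}
    excluded: list[ExclusionRecord] = []
    for sid, values in groups.items():
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        pos = arr[arr > 0]
        dropped = arr.size - pos.size
        if pos.size == 0:
            excluded.append(ExclusionRecord(sid, "no positive replicates", arr.size))
            continue
        if dropped:
            excluded.append(ExclusionRecord(sid, "non-positive replicates dropped", dropped))
        out[sid] = np.log(pos)
    return out, excluded


def _validate_groups(groups: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    clean = {}
    for sid, values in groups.items():
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        if arr.size < 2:
            raise ValueError(f"group {sid!r} has n = {arr.size} < 2 replicates")
        clean[sid] = arr
    return clean


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical between/within variance decomposition; p from the F
    distribution.  Degenerate cases: zero between-group variation gives
    (0, 1); zero within- with non-zero between-group variation gives
    (inf, 0)."""
    g = _validate_groups(groups)
    all_values = np.concatenate(list(g.values()))
    grand = float(np.mean(all_values))
    k = len(g)
    n_total = all_values.size
    ss_between = sum(v.size * (np.mean(v) - grand) ** 2 for v in g.values())
    ss_within = sum(float(np.sum((v - np.mean(v)) ** 2)) for v in g.values())
    scale = max(float(np.sum((all_values - grand) ** 2)), 1.0)
    if ss_between <= 1e-14 * scale:
        return 0.0, 1.0
    if ss_within <= 1e-14 * scale:
        return float("inf"), 0.0
    df_between = k - 1
    df_within = n_total - k
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Tukey HSD p-values (studentized-range distribution with
    pooled within-group variance; Tukey-Kramer for unbalanced groups).

    Returns a symmetric DataFrame with unit diagonal, indexed by sample id.
    """
    g = _validate_groups(groups)
    ids = list(g)
    samples = [g[s] for s in ids]
    within = sum(float(np.sum((v - np.mean(v)) ** 2)) for v in samples)
    if within <= 0:
        # degenerate: no within-group spread; equal means are identical,
        # unequal means are trivially separated
        n = len(ids)
        p = np.ones((n, n))
        means = [float(np.mean(v)) for v in samples]
        for i, j in itertools.combinations(range(n), 2):
            if means[i] != means[j]:
                p[i, j] = p[j, i] = 0.0
        return pd.DataFrame(p, index=ids, columns=ids)
    res = stats.tukey_hsd(*samples)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.clip((p + p.T) / 2.0, 0.0, 1.0)  # symmetrize numerical asymmetry
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=ids, columns=ids)


def compact_letters(
    pairwise_p: pd.DataFrame,
    means: Mapping[str, float],
    alpha: float = 0.05,
) -> tuple[dict[str, str], int]:
    """Insert-and-absorb compact letter display.

    Starts with one column holding every sample; each significant pair
    splits every column containing both, and columns that became subsets of
    another are absorbed.  Letters are ordered by descending column-best
    mean, so 'a' marks the top category.  Returns per-sample letter strings
    and the number of distinct letters (= categories).
    """
    ids = list(pairwise_p.index)
    columns: list[set[str]] = [set(ids)]
    for i, j in itertools.combinations(ids, 2):
        if pairwise_p.loc[i, j] >= alpha:
            continue
        new_columns: list[set[str]] = []
        for col in columns:
            if i in col and j in col:
                new_columns.append(col - {i})
                new_columns.append(col - {j})
            else:
                new_columns.append(col)
        # absorb: drop empty columns, proper subsets and duplicates
        absorbed: list[set[str]] = []
        for col in new_columns:
            if not col or any(col < other for other in new_columns):
                continue
            if col not in absorbed:
                absorbed.append(col)
        columns = absorbed
    columns.sort(key=lambda col: (-max(means[s] for s in col), sorted(col)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {s: [] for s in ids}
    for letter, col in zip(alphabet, columns):
        for s in col:
            letters[s].append(letter)
    return {s: "".join(sorted(v)) for s, v in letters.items()}, len(columns)


def check_letters_consistent(
    letters: Mapping[str, str],
    pairwise_p: pd.DataFrame,
    alpha: float = 0.05,
) -> bool:
    """Exhaustive check of the display: every pair shares a letter iff the
    pair is not significantly different."""
    for i, j in itertools.combinations(pairwise_p.index, 2):
        share = bool(set(letters[i]) & set(letters[j]))
        significant = bool(pairwise_p.loc[i, j] < alpha)
        if share == significant:
            return False
    return True


def rank_samples(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    descriptor: str = "OxTOF",
    exclude: Sequence[str] = (),
) -> RankingResult:
    """Full grouping pipeline: log-transform, ANOVA, Tukey HSD, letters.

    ``exclude`` removes samples before analysis (e.g. dissolution-suspect
    materials whose DTT signal is carried by dissolved ions, or
    below-detection samples).  The letter display is verified against the
    pairwise matrix on every call.
    """
    excluded = [ExclusionRecord(s, "excluded by caller") for s in exclude if s in groups]
    working = {s: v for s, v in groups.items() if s not in set(exclude)}
    logs, log_excl = log_transform(working)
    excluded.extend(log_excl)
    logs = {s: v for s, v in logs.items() if v.size >= 2}
    for rec in log_excl:
        if rec.reason == "non-positive replicates dropped" and rec.sample_id not in logs:
            excluded.append(ExclusionRecord(rec.sample_id, "fewer than 2 positive replicates"))
    f, p = one_way_anova(logs)
    pairwise = tukey_hsd(logs, alpha=alpha)
    means = {s: float(np.mean(v)) for s, v in logs.items()}
    letters, n_categories = compact_letters(pairwise, means, alpha=alpha)
    if not check_letters_consistent(letters, pairwise, alpha=alpha):
        raise RuntimeError("compact letter display inconsistent with pairwise matrix")
    return RankingResult(
        descriptor=descriptor,
        f_statistic=f,
        p_anova=p,
        pairwise_p=pairwise,
        letters=letters,
        n_categories=n_categories,
        alpha=alpha,
        group_means_log=means,
        excluded=excluded,
    )
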