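"""Amplicon count-table analysis: abundances, merging, responder screen,
and diversity summaries.

Count tables are pandas DataFrames with taxa as rows and samples as
columns.  Sample metadata (arm, time, molecule) travels in a separate
frame indexed by sample id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln


class CommunityError(ValueError):
    pass


def _validate_counts(counts: pd.DataFrame) -> None:
    arr = counts.to_numpy()
    if np.any(arr < 0):
        raise CommunityError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise CommunityError("counts must be integral")
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise CommunityError("taxa and sample ids must be unique")


def drop_singletons(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove taxa whose total count across all samples is exactly 1."""
    _validate_counts(counts)
    return counts.loc[counts.sum(axis=1) != 1]


def relative_abundances(counts: pd.DataFrame, remove_singletons: bool = True) -> pd.DataFrame:
    """Per-sample proportions (columns sum to 1), singletons removed first."""
    table = drop_singletons(counts) if remove_singletons else counts.copy()
    totals = table.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise CommunityError(f"samples with zero total count: {list(zero.index)}")
    return table / totals


def validate_similarity(sim: pd.DataFrame, tol: float = 1e-9) -> None:
    arr = sim.to_numpy(dtype=float)
    if sim.shape[0] != sim.shape[1] or not sim.index.equals(sim.columns):
        raise CommunityError("similarity matrix must be square with matching labels")
    if np.any(arr < -tol) or np.any(arr > 1 + tol):
        raise CommunityError("similarities must lie in [0, 1]")
    if not np.allclose(arr, arr.T, atol=tol):
        raise CommunityError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(arr), 1.0, atol=tol):
        raise CommunityError("similarity matrix diagonal must be exactly 1")


def merge_phylotypes(
    counts: pd.DataFrame, sim: pd.DataFrame, threshold: float = 0.97
) -> pd.DataFrame:
    """Merge highly similar phylotypes by summing their counts.

    Phylotypes whose pairwise similarity meets ``threshold`` are linked;
    connected components of that graph (single linkage) merge into one
    taxon labeled by the most abundant member.  Per-sample totals are
    preserved exactly.
    """
    _validate_counts(counts)
    validate_similarity(sim)
    missing = counts.index.difference(sim.index)
    if len(missing):
        raise CommunityError(f"similarity matrix lacks phylotypes: {list(missing)}")
    sub = sim.loc[counts.index, counts.index].to_numpy(dtype=float)
    adjacency = csr_matrix(sub >= threshold)
    n_comp, labels = connected_components(adjacency, directed=False)

    totals = counts.sum(axis=1).to_numpy()
    merged_rows = {}
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        rep = members[np.argmax(totals[members])]
        rep_id = counts.index[rep]
        merged_rows[rep_id] = counts.iloc[members].sum(axis=0)
    out = pd.DataFrame(merged_rows).T
    out.index.name = counts.index.name
    # keep original row order of the representatives
    order = [t for t in counts.index if t in merged_rows]
    return out.loc[order]


def aggregate_taxonomy(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, rank: str = "family"
) -> pd.DataFrame:
    """Sum counts (or abundances) up to a taxonomy rank.

    ``taxonomy`` is indexed by taxon id with at least the requested rank
    column; unresolvable taxa raise rather than silently dropping.
    """
    missing = counts.index.difference(taxonomy.index)
    if len(missing):
        raise CommunityError(f"taxa missing from taxonomy map: {list(missing)[:5]}")
    groups = taxonomy.loc[counts.index, rank]
    return counts.groupby(groups, sort=False).sum()


def time_averaged_abundance(series: pd.Series, periods: list[float]) -> float:
    """Arithmetic mean abundance over the listed sampling periods.

    ``series`` is indexed by sampling period (h); time zero is excluded
    by convention (callers pass post-supplementation periods only).
    """
    missing = [p for p in periods if p not in series.index]
    if missing:
        raise CommunityError(f"periods absent from series: {missing}")
    return float(series.loc[list(periods)].mean())


def responsive_taxa(
    treatment_pct: pd.DataFrame,
    control_pct: pd.DataFrame,
    threshold_pp: float,
    average_periods: list[float] | None = None,
) -> pd.DataFrame:
    """Screen taxa for increase over the paired control.

    Inputs are percent-abundance tables (taxa x sampling periods, one
    value per period per arm).  A taxon is responsive when treatment
    minus control reaches ``threshold_pp`` percentage points in at least
    one period.  Conventional thresholds: 5 pp at family level, 2 pp at
    phylotype level.

    Returns a frame indexed by taxon with columns ``max_increase_pp``,
    ``at_period``, ``responsive``, ``threshold_pp``, and
    ``time_averaged_pct`` (mean treatment abundance over
    ``average_periods``, default: all non-zero periods).
    """
    if not treatment_pct.columns.equals(control_pct.columns):
        raise CommunityError("treatment and control sampling periods differ")
    taxa = treatment_pct.index.union(control_pct.index)
    t = treatment_pct.reindex(taxa, fill_value=0.0)
    c = control_pct.reindex(taxa, fill_value=0.0)
    diff = t - c
    if average_periods is None:
        average_periods = [p for p in treatment_pct.columns if float(p) != 0.0]
    report = pd.DataFrame(
        {
            "max_increase_pp": diff.max(axis=1),
            "at_period": diff.idxmax(axis=1),
            "responsive": diff.max(axis=1) >= threshold_pp,
            "threshold_pp": threshold_pp,
            "time_averaged_pct": t[average_periods].mean(axis=1),
        }
    )
    return report.sort_values("max_increase_pp", ascending=False)


def shannon_index(counts: pd.Series | np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i, in nats."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise CommunityError("sample total must be positive")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def rarefied_richness(counts: pd.Series | np.ndarray, depth: int) -> float:
    """Analytic expected richness at a rarefaction depth.

    E[S] = sum_i 1 - C(N - n_i, d) / C(N, d), the hypergeometric
    expectation of the number of taxa seen in ``d`` draws without
    replacement.
    """
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    n_total = arr.sum()
    if depth > n_total:
        raise CommunityError(f"depth {depth} exceeds sample total {int(n_total)}")
    if depth < 0:
        raise CommunityError("depth must be >= 0")

    def log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    remaining = n_total - arr
    prob_absent = np.where(
        remaining >= depth,
        np.exp(log_choose(remaining, depth) - log_choose(n_total, depth)),
        0.0,
    )
    return float(np.sum(1.0 - prob_absent))


def chao1_richness(counts: pd.Series | np.ndarray) -> float:
    """Chao1 expected richness: S_obs + F1^2 / (2 F2).

    Bias-corrected form F1 (F1 - 1) / 2 when no doubletons exist.
    """
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise CommunityError("sample total must be positive")
    s_obs = arr.size
    f1 = int(np.sum(arr == 1))
    f2 = int(np.sum(arr == 2))
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1) / 2.0)


def expected_richness(
    counts: pd.Series | np.ndarray, depth: int | None = None, mode: str = "rarefaction"
) -> float:
    """Dispatch between rarefaction and chao1 expected-richness modes."""
    if mode == "rarefaction":
        if depth is None:
            raise CommunityError("rarefaction mode requires a depth")
        return rarefied_richness(counts, depth)
    if mode == "chao1":
        return chao1_richness(counts)
    raise CommunityError(f"unknown mode {mode!r}")
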