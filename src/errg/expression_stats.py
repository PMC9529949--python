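"""Expression characterization of eRRGs and the random-gene resampling null.

Two questions are answered here. First, do eRRGs differ from size-matched
random gene sets in expression level (per-gene mean) and stability
(coefficient of variation, reported in percent)? Second, after a two-group
differential-expression analysis with the standard thresholds
(FDR < 0.05 and |log2 FC| > 1, both strict), how many up/down calls would a
random gene set of the same size contain on average?

The built-in per-gene test (`de_stats`) is a rank test on log2(CPM + pc)
and exists so the pipeline is self-contained and testable; on real data a
differential-expression table from a dedicated count-model tool should be
supplied instead (see `read_external_de`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_FC_CUT = 1.0
DEFAULT_FDR_CUT = 0.05
EXACT_WILCOXON_MAX_N = 12


# ---------------------------------------------------------------------------
# matrix I/O


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Feature x sample matrix from TSV (first column = feature ids)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    if m.index.has_duplicates:
        raise ValueError("duplicate feature ids in matrix")
    if m.columns.has_duplicates:
        raise ValueError("duplicate sample ids in matrix")
    return m


def read_groups(path: str | Path) -> pd.Series:
    """Sample -> group label from a two-column TSV (sample, group)."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million library-size normalization (column-wise)."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample with zero total counts")
    return counts * 1e6 / libsize


def log2_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.log2(cpm(counts) + pseudocount)


# ---------------------------------------------------------------------------
# summaries


def filter_unexpressed(matrix: pd.DataFrame, gene_set: Iterable[str]) -> list[str]:
    """Keep genes with a value > 0 in at least one sample.

    Gene ids absent from the matrix are dropped with a warning. An empty
    result is a warning, not an error.
    """
    gene_set = list(gene_set)
    present = [g for g in gene_set if g in matrix.index]
    missing = set(gene_set) - set(present)
    if missing:
        logger.warning("filter_unexpressed: %d ids absent from matrix", len(missing))
    sub = matrix.loc[present]
    kept = [g for g, any_pos in (sub > 0).any(axis=1).items() if any_pos]
    if not kept:
        logger.warning("filter_unexpressed: no gene has nonzero expression")
    return kept


def per_gene_summary(matrix: pd.DataFrame, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene mean and CV (= 100 * sample sd / mean) across the samples.

    CV is NaN where the mean is zero. Requires >= 2 samples.
    """
    sub = matrix if samples is None else matrix[list(samples)]
    if sub.shape[1] < 2:
        raise ValueError("CV requires at least 2 samples")
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean.where(mean > 0)
    return pd.DataFrame({"mean": mean, "cv": cv})


# ---------------------------------------------------------------------------
# tests


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration when the pooled sample is small (n <= 12) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections. Returns (rank-sum of x with midranks, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # degenerate: every observation identical; no evidence either way
        w = x.size * (pooled.size + 1) / 2.0
        return w, 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_WILCOXON_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return w, float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, capped at 1, order-stable."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# eRRG vs random gene sets


def compare_to_random_sets(
    matrix: pd.DataFrame,
    errg_set: Iterable[str],
    universe: Iterable[str] | None = None,
    n_sets: int = 100,
    seed: int = 0,
    samples: Sequence[str] | None = None,
) -> dict:
    """Contrast per-gene mean and CV of eRRGs against random size-matched sets.

    ``n_sets`` random sets of |eRRG| genes are drawn without replacement
    from the universe (default: all matrix genes passing
    :func:`filter_unexpressed`); the per-gene values of all draws are
    pooled and compared to the eRRG values with the rank-sum test.
    """
    errg = sorted(set(errg_set))
    if universe is None:
        universe = filter_unexpressed(matrix, matrix.index)
    universe = sorted(set(universe))
    if len(universe) < len(errg):
        raise ValueError(f"universe ({len(universe)}) smaller than eRRG set ({len(errg)})")
    missing = [g for g in errg if g not in matrix.index]
    if missing:
        raise ValueError(f"eRRG genes absent from matrix: {missing[:5]}...")

    summary = per_gene_summary(matrix, samples)
    rng = np.random.default_rng(seed)
    pooled_idx: list[str] = []
    for _ in range(n_sets):
        pooled_idx.extend(rng.choice(universe, size=len(errg), replace=False))

    errg_mean = summary.loc[errg, "mean"]
    rand_mean = summary.loc[pooled_idx, "mean"]
    errg_cv = summary.loc[errg, "cv"].dropna()
    rand_cv = summary.loc[pooled_idx, "cv"].dropna()
    _, p_mean = wilcoxon_rank_sum(errg_mean.values, rand_mean.values)
    _, p_cv = wilcoxon_rank_sum(errg_cv.values, rand_cv.values)
    return {
        "n_errgs": len(errg),
        "n_sets": n_sets,
        "errg_mean": float(errg_mean.mean()),
        "random_mean": float(rand_mean.mean()),
        "p_mean": p_mean,
        "errg_cv": float(errg_cv.mean()),
        "random_cv": float(rand_cv.mean()),
        "p_cv": p_cv,
    }


# ---------------------------------------------------------------------------
# differential expression


def de_stats(
    counts: pd.DataFrame,
    groups: pd.Series,
    pseudocount: float = 1.0,
    group_labels: tuple[str, str] = ("tumor", "normal"),
) -> pd.DataFrame:
    """Built-in per-gene two-group statistics on log2(CPM + pseudocount).

    Per gene: two-sided rank-sum p; log2 fold change of group CPM means
    with the pseudocount; BH FDR. This is a deliberately simple substitute
    for a negative-binomial count model — supply an external table for
    real analyses.
    """
    case, control = group_labels
    case_samples = [s for s in counts.columns if groups.get(s) == case]
    control_samples = [s for s in counts.columns if groups.get(s) == control]
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("each group needs >=2 samples")
    norm = cpm(counts)
    log_norm = np.log2(norm + pseudocount)
    case_log = log_norm[case_samples].values
    control_log = log_norm[control_samples].values
    pvals = np.empty(len(counts.index))
    for i in range(len(counts.index)):
        _, pvals[i] = wilcoxon_rank_sum(case_log[i], control_log[i])
    log2fc = np.log2(
        (norm[case_samples].mean(axis=1) + pseudocount)
        / (norm[control_samples].mean(axis=1) + pseudocount)
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "fdr": bh_adjust(pvals)}, index=counts.index
    )


def read_external_de(path: str | Path) -> pd.DataFrame:
    """Load a differential-expression table (gene_id, log2fc, pvalue, fdr)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"log2fc", "fdr"}
    if not required <= set(df.columns):
        raise ValueError(f"external DE table needs columns {sorted(required)}")
    if "pvalue" not in df.columns:
        df["pvalue"] = np.nan
    return df


def apply_de_thresholds(
    table: pd.DataFrame,
    fc_cut: float = DEFAULT_FC_CUT,
    fdr_cut: float = DEFAULT_FDR_CUT,
) -> tuple[pd.DataFrame, int, int]:
    """Call up/down/ns with strict cutoffs: FDR < fdr_cut and |log2FC| > fc_cut."""
    table = table.copy()
    sig = table["fdr"] < fdr_cut
    call = np.where(
        sig & (table["log2fc"] > fc_cut),
        "up",
        np.where(sig & (table["log2fc"] < -fc_cut), "down", "ns"),
    )
    table["call"] = call
    n_up = int((table["call"] == "up").sum())
    n_down = int((table["call"] == "down").sum())
    return table, n_up, n_down


@dataclass
class ResampleResult:
    mean_up: float
    mean_down: float
    up_counts: np.ndarray
    down_counts: np.ndarray


def resample_de_counts(
    calls: pd.Series,
    universe: Sequence[str],
    set_size: int,
    n_reps: int = 1000,
    seed: int = 0,
) -> ResampleResult:
    """Random-gene null for DE counts.

    For each of ``n_reps`` seeded draws of ``set_size`` genes from the
    universe without replacement, count how many are called up / down;
    report the means and the full count distributions. Genes without a
    call are treated as not significant.
    """
    universe = list(universe)
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    codes = np.array(
        [{"up": 1, "down": 2}.get(calls.get(g, "ns"), 0) for g in universe], dtype=np.int8
    )
    rng = np.random.default_rng(seed)
    up = np.empty(n_reps, dtype=np.int64)
    down = np.empty(n_reps, dtype=np.int64)
    n = len(universe)
    for r in range(n_reps):
        idx = rng.choice(n, size=set_size, replace=False)
        picked = codes[idx]
        up[r] = int((picked == 1).sum())
        down[r] = int((picked == 2).sum())
    return ResampleResult(float(up.mean()), float(down.mean()), up, down)
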