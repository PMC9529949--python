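"""High-risk vs low-risk multi-omics contrasts.

Covers three layers of the comparison between risk groups:

* **DNA methylation** — differentially methylated probes (DMPs) on 450k-style
  beta values. Delta-beta is mean(high) - mean(low); a probe is called
  hyper/hypomethylated in the high-risk group when FDR < 0.05 and
  |delta-beta| > 0.15 (both strict). The per-probe test is Welch's t on the
  beta values with BH adjustment — a documented substitute for the
  unexported internals of array-processing toolkits.
* **Somatic mutations** — a binary gene x sample mutation matrix (silent
  variants excluded by default), per-gene differential mutation between
  groups by Fisher's exact test at raw p < 0.05 (a BH column is emitted
  additionally for transparency), and per-sample burden summaries by
  variant class, variant type (SNP/INS/DEL), pyrimidine-collapsed SNV class
  and VAF, compared between groups with the rank-sum test.
* **Co-occurrence / exclusivity** — for the top-K most frequently mutated
  genes, each unordered pair gets a 2x2 Fisher test over samples
  (both / only i / only j / neither); odds ratio > 1 labels the pair
  co-occurring, otherwise mutually exclusive.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

DEFAULT_DBETA_CUT = 0.15
DEFAULT_FDR_CUT = 0.05
DEFAULT_MUT_P_CUT = 0.05
DEFAULT_MIN_MUTATED = 5

SILENT_CLASSES = frozenset({"Silent"})
KNOWN_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Silent",
        "Splice_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)
SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

MAF_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
)


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene_id: str
    chrom: str
    position: int
    ref: str
    alt: str
    variant_class: str
    variant_type: str
    vaf: float | None = None


def read_maf(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-like TSV of per-variant somatic mutation records.

    VAF is derived from t_alt_count / t_depth when both columns are present.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file missing columns {missing}")
    has_vaf = {"t_alt_count", "t_depth"} <= set(df.columns)
    records = []
    for row in df.itertuples(index=False):
        vaf = None
        if has_vaf and getattr(row, "t_depth") > 0:
            vaf = float(getattr(row, "t_alt_count")) / float(getattr(row, "t_depth"))
        records.append(
            MutationRecord(
                sample_id=str(row.Tumor_Sample_Barcode),
                gene_id=str(row.Hugo_Symbol),
                chrom=str(row.Chromosome),
                position=int(row.Start_Position),
                ref=str(row.Reference_Allele),
                alt=str(row.Tumor_Seq_Allele2),
                variant_class=str(row.Variant_Classification),
                variant_type=str(row.Variant_Type),
                vaf=vaf,
            )
        )
    return records


# ---------------------------------------------------------------------------
# methylation


def call_dmps(
    beta: pd.DataFrame,
    groups: pd.Series,
    probe_map: pd.DataFrame | None = None,
    dbeta_cut: float = DEFAULT_DBETA_CUT,
    fdr_cut: float = DEFAULT_FDR_CUT,
    group_labels: tuple[str, str] = ("high", "low"),
) -> pd.DataFrame:
    """Call differentially methylated probes between two groups.

    Delta-beta = mean(high) - mean(low), so "hypo" means hypomethylated in
    the high-risk group. Probes with zero variance in both groups get p = 1.
    """
    vals = beta.values
    if np.isnan(vals).any():
        raise ValueError("beta matrix contains missing values; impute first")
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("beta values must lie in [0, 1]")
    high_label, low_label = group_labels
    high = [s for s in beta.columns if groups.get(s) == high_label]
    low = [s for s in beta.columns if groups.get(s) == low_label]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs >=2 samples")
    a, b = beta[high].values, beta[low].values
    delta = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # constant probes carry no evidence
    fdr = bh_adjust(pvals)
    call = np.where(
        (fdr < fdr_cut) & (delta > dbeta_cut),
        "hyper",
        np.where((fdr < fdr_cut) & (delta < -dbeta_cut), "hypo", "ns"),
    )
    out = pd.DataFrame(
        {"delta_beta": delta, "pvalue": pvals, "fdr": fdr, "call": call}, index=beta.index
    )
    if probe_map is not None and "gene_id" in probe_map.columns:
        out = out.join(probe_map["gene_id"], how="left")
    return out


# ---------------------------------------------------------------------------
# mutations


def snv_class(ref: str, alt: str) -> str | None:
    """Pyrimidine-collapsed substitution class, or None for non-SNVs.

    Purine-reference SNVs are mapped to the reverse complement, so e.g.
    G>A collapses to C>T.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        return None
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class MutationTables:
    """Binary mutation matrix plus per-sample burden summaries."""

    gene_sample: pd.DataFrame  # genes x samples, 0/1
    class_counts: pd.DataFrame  # samples x variant_class
    type_counts: pd.DataFrame  # samples x {SNP, INS, DEL}
    snv_counts: pd.DataFrame  # samples x six SNV classes
    vaf_mean: pd.Series  # per-sample mean VAF (NaN where no VAF)


def mutation_matrix(
    records: Sequence[MutationRecord],
    samples: Sequence[str],
    include_silent: bool = False,
) -> MutationTables:
    """Binarized gene x sample mutation status plus burden summaries.

    A matrix entry is 1 iff the gene has >=1 qualifying record in that
    sample; silent variants do not qualify unless ``include_silent``.
    Unknown variant classes qualify (with a warning). Entries are invariant
    to record order and duplication.
    """
    samples = list(samples)
    sample_set = set(samples)
    unknown_sample = {r.sample_id for r in records} - sample_set
    if unknown_sample:
        raise ValueError(f"records reference samples outside the sample list: {sorted(unknown_sample)[:5]}")
    unknown_classes = {r.variant_class for r in records} - KNOWN_VARIANT_CLASSES
    if unknown_classes:
        logger.warning("unknown variant classes treated as qualifying: %s", sorted(unknown_classes))

    qualifying = [
        r for r in records if include_silent or r.variant_class not in SILENT_CLASSES
    ]
    genes = sorted({r.gene_id for r in qualifying})
    matrix = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int8)
    for r in qualifying:
        matrix.at[r.gene_id, r.sample_id] = 1

    classes = sorted({r.variant_class for r in records})
    class_counts = pd.DataFrame(0, index=samples, columns=classes, dtype=np.int64)
    type_counts = pd.DataFrame(0, index=samples, columns=["SNP", "INS", "DEL"], dtype=np.int64)
    snv_counts = pd.DataFrame(0, index=samples, columns=list(SNV_CLASSES), dtype=np.int64)
    vaf_sums: dict[str, list[float]] = {s: [] for s in samples}
    for r in records:
        class_counts.at[r.sample_id, r.variant_class] += 1
        if r.variant_type in type_counts.columns:
            type_counts.at[r.sample_id, r.variant_type] += 1
        cls = snv_class(r.ref, r.alt)
        if cls is not None:
            snv_counts.at[r.sample_id, cls] += 1
        if r.vaf is not None:
            vaf_sums[r.sample_id].append(r.vaf)
    vaf_mean = pd.Series(
        {s: (float(np.mean(v)) if v else np.nan) for s, v in vaf_sums.items()}, name="vaf_mean"
    )
    return MutationTables(matrix, class_counts, type_counts, snv_counts, vaf_mean)


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Two-sided p sums hypergeometric probabilities <= that of the observed
    table. The odds ratio is the sample cross-product ratio a*d / (b*c):
    inf when b*c = 0 with a*d > 0, NaN when both products are 0.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.nan if ad == 0 else math.inf
    else:
        odds = ad / bc
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def differential_mutation(
    matrix: pd.DataFrame,
    groups: pd.Series,
    min_mutated: int = DEFAULT_MIN_MUTATED,
    p_cut: float = DEFAULT_MUT_P_CUT,
    group_labels: tuple[str, str] = ("high", "low"),
) -> pd.DataFrame:
    """Per-gene differential mutation between groups by Fisher's exact test.

    Genes with fewer than ``min_mutated`` mutated samples overall are not
    tested. Calls use the raw p at ``p_cut`` (an adjusted column is emitted
    additionally). Odds ratio > 1 means enriched in the high-risk group.
    """
    high_label, low_label = group_labels
    high = [s for s in matrix.columns if groups.get(s) == high_label]
    low = [s for s in matrix.columns if groups.get(s) == low_label]
    if not high or not low:
        raise ValueError("both groups must be non-empty")
    rows = []
    for gene in matrix.index:
        mut_high = int(matrix.loc[gene, high].sum())
        mut_low = int(matrix.loc[gene, low].sum())
        if mut_high + mut_low < min_mutated:
            continue
        odds, p = fisher_exact(
            [[mut_high, mut_low], [len(high) - mut_high, len(low) - mut_low]]
        )
        rows.append((gene, mut_high, mut_low, odds, p))
    out = pd.DataFrame(
        rows, columns=["gene_id", "n_mut_high", "n_mut_low", "odds_ratio", "pvalue"]
    ).set_index("gene_id")
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].values)
        out["call"] = np.where(out["pvalue"] < p_cut, "diff", "ns")
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["call"] = pd.Series(dtype=object)
    return out


def group_burden_comparison(
    tables: MutationTables, groups: pd.Series, group_labels: tuple[str, str] = ("high", "low")
) -> pd.DataFrame:
    """Rank-sum comparison of per-sample mutation burdens between groups.

    One row per metric: each variant class, each SNV class, SNP/INS/DEL
    counts, and mean VAF.
    """
    high_label, low_label = group_labels
    samples = tables.gene_sample.columns
    high = [s for s in samples if groups.get(s) == high_label]
    low = [s for s in samples if groups.get(s) == low_label]
    metrics: dict[str, pd.Series] = {}
    for col in tables.class_counts.columns:
        metrics[f"class:{col}"] = tables.class_counts[col]
    for col in tables.snv_counts.columns:
        metrics[f"snv:{col}"] = tables.snv_counts[col]
    for col in tables.type_counts.columns:
        metrics[f"type:{col}"] = tables.type_counts[col]
    metrics["vaf_mean"] = tables.vaf_mean
    rows = []
    for name, series in metrics.items():
        x = series.loc[high].dropna().values
        y = series.loc[low].dropna().values
        if len(x) == 0 or len(y) == 0:
            continue
        stat, p = wilcoxon_rank_sum(x, y)
        rows.append((name, float(np.median(x)), float(np.median(y)), stat, p))
    return pd.DataFrame(
        rows, columns=["metric", "median_high", "median_low", "statistic", "pvalue"]
    ).set_index("metric")


def cooccurrence(
    matrix: pd.DataFrame,
    top_k: int = 25,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise co-occurrence / mutual exclusivity of mutated genes.

    Takes the top-K genes by mutation frequency (ties broken by name)
    unless an explicit gene list is given. For each unordered pair, a 2x2
    Fisher test over samples; odds ratio > 1 labels the pair co-occurring,
    otherwise exclusive. Significance tiers at p < 0.05 (*) and p < 0.01 (**).
    """
    if genes is None:
        freq = matrix.sum(axis=1)
        order = sorted(matrix.index, key=lambda g: (-freq[g], g))
        genes = order[:top_k]
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for pairwise analysis")
    n_samples = matrix.shape[1]
    rows = []
    for gi, gj in itertools.combinations(genes, 2):
        vi = matrix.loc[gi].values.astype(bool)
        vj = matrix.loc[gj].values.astype(bool)
        both = int((vi & vj).sum())
        only_i = int((vi & ~vj).sum())
        only_j = int((~vi & vj).sum())
        neither = n_samples - both - only_i - only_j
        odds, p = fisher_exact([[both, only_i], [only_j, neither]])
        label = "co-occurring" if odds > 1 else "exclusive"
        tier = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows.append((gi, gj, both, only_i, only_j, neither, odds, p, label, tier))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_i",
            "gene_j",
            "both",
            "only_i",
            "only_j",
            "neither",
            "odds_ratio",
            "pvalue",
            "label",
            "sig",
        ],
    )
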