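"""Synthetic multi-omics data with planted ground truth.

Generates every input the eRRG pipeline consumes — gene annotation,
per-resource enhancer BEDs, tumor/normal count matrices, beta-value
matrices with a probe map, MAF-like mutation tables, a gene signature and
a survival table — from a single :class:`SimConfig`, as a pure function of
its seed.

The genome is laid out in fixed-size blocks, each holding at most one gene
and at most one enhancer, spaced so that contact-domain windows never
reach a neighboring block's gene. Block roles:

* **target** — a gene plus a "shared" enhancer present in every resource
  (with small per-resource coordinate jitter), placed so its eRNA region
  is gene-free but its contact-domain window covers the gene. These genes
  are the planted final eRRGs.
* **decoy** — a gene plus an enhancer private to one resource; its gene
  becomes an eRRG of that resource only and drops out of the intersection.
* **filtered** — a gene with an enhancer whose midpoint lies inside it, so
  the eRNA region overlaps the gene and is removed by the overlap filter.
* **background** — a gene with no enhancer.
* **desert** — a private enhancer with no gene in reach.

Ground-truth eRRG sets are computed by an internal all-pairs double loop
over (enhancer, gene) — deliberately independent of the pipeline's
interval-index implementation, so it can serve as its oracle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import EnhancerRecord, GeneRecord, GenomicInterval, write_gene_table

DEFAULT_RESOURCES = ("ensembl", "fantom", "roadmap", "encode")

_VARIANT_CLASS_MIX = (
    ("Missense_Mutation", 0.55),
    ("Silent", 0.15),
    ("Splice_Site", 0.10),
    ("Frame_Shift_Del", 0.08),
    ("Frame_Shift_Ins", 0.07),
    ("Nonsense_Mutation", 0.05),
)
_SNV_CLASS_MIX = (
    ("C>T", 0.45),
    ("C>A", 0.11),
    ("C>G", 0.11),
    ("T>A", 0.11),
    ("T>C", 0.11),
    ("T>G", 0.11),
)
_PYRIMIDINE_PAIRS = {
    "C>A": ("C", "A"),
    "C>G": ("C", "G"),
    "C>T": ("C", "T"),
    "T>A": ("T", "A"),
    "T>C": ("T", "C"),
    "T>G": ("T", "G"),
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """All knobs of the generator; generation is a pure function of this."""

    seed: int = 0
    # genome / annotation
    n_chromosomes: int = 4
    chrom_length: int = 12_500_000
    block_size: int = 250_000
    n_genes: int = 160
    pcg_fraction: float = 0.55
    resources: tuple[str, ...] = DEFAULT_RESOURCES
    n_enhancers: int = 40  # per resource
    resource_overlap: float = 0.5  # fraction of each resource's enhancers shared by all
    half_width: int = 3_000
    domain_length: int = 185_000
    # expression
    n_tumor: int = 120
    n_normal: int = 40
    errg_expression_boost: float = 7.0  # baseline-mean multiplier for planted eRRGs
    de_up_fraction: float = 0.35  # of planted eRRGs
    de_down_fraction: float = 0.20
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    # methylation
    n_probes: int = 1_200
    n_planted_dmp: int = 40
    dmp_delta_beta: float = 0.30
    dmp_hypo_fraction: float = 0.90  # hypomethylated in the high-risk group
    beta_sd: float = 0.05
    # mutations
    mutation_rate: float = 0.15  # background per gene per sample
    n_planted_mut_genes: int = 5
    mut_rate_high: float = 0.40
    mut_rate_low: float = 0.05
    # survival
    signature_size: int = 12
    survival_effect: float = 1.0  # log-hazard per SD of risk score
    baseline_hazard: float = math.log(2) / 730.0  # median OS ~2 years at null
    censoring_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "pcg_fraction",
            "resource_overlap",
            "de_up_fraction",
            "de_down_fraction",
            "dmp_hypo_fraction",
            "mutation_rate",
            "mut_rate_high",
            "mut_rate_low",
            "censoring_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_chromosomes",
            "chrom_length",
            "block_size",
            "n_genes",
            "n_enhancers",
            "half_width",
            "domain_length",
            "n_tumor",
            "n_normal",
            "n_probes",
            "signature_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.de_up_fraction + self.de_down_fraction > 1.0:
            raise ValueError("de_up_fraction + de_down_fraction must be <= 1")


@dataclass
class GroundTruth:
    """Planted truth, derivable without running the pipeline."""

    errg_per_resource: dict[str, set[str]]
    errg_final: set[str]
    target_genes: list[str]
    de_up: set[str]
    de_down: set[str]
    dmp_probes: dict[str, str]  # probe -> {hyper, hypo}
    diff_mut_genes: set[str]
    signature: dict[str, float]
    risk_groups: dict[str, str]  # tumor sample -> {high, low}


@dataclass
class SimBundle:
    config: SimConfig
    genes: list[GeneRecord]
    enhancers: dict[str, list[EnhancerRecord]]
    counts: pd.DataFrame  # genes x (tumor + normal)
    groups: pd.Series  # sample -> {tumor, normal}
    beta: pd.DataFrame  # probes x tumor samples
    probe_map: pd.DataFrame  # probe -> chrom, position, gene_id
    mutations: pd.DataFrame  # MAF-like table
    survival: pd.DataFrame  # sample, time, event (indexed by sample)
    signature: pd.Series
    risk_groups: pd.Series  # tumor sample -> {high, low}
    truth: GroundTruth


# ---------------------------------------------------------------------------
# annotation


def brute_force_errgs(
    enhancers_by_resource: Mapping[str, Sequence[EnhancerRecord]],
    genes: Sequence[GeneRecord],
    half_width: int,
    domain_length: int,
) -> tuple[dict[str, set[str]], set[str], set[tuple[str, str, str]]]:
    """All-pairs reference implementation of eRRG identification.

    Pure double loops over (enhancer, gene); returns per-resource gene
    sets, the final intersection, and the (enhancer_id, resource, gene_id)
    pair set. Used both for planted truth and as the oracle in tests.
    """

    def ovl(chrom_a, s_a, e_a, chrom_b, s_b, e_b):
        return chrom_a == chrom_b and s_a < e_b and s_b < e_a

    per_resource: dict[str, set[str]] = {}
    pairs: set[tuple[str, str, str]] = set()
    for resource, enhancers in enhancers_by_resource.items():
        found: set[str] = set()
        for enh in enhancers:
            mid = (enh.interval.start + enh.interval.end) // 2
            r_start, r_end = max(0, mid - half_width), mid + half_width
            overlapped = False
            for g in genes:
                if ovl(enh.interval.chrom, r_start, r_end, g.interval.chrom, g.interval.start, g.interval.end):
                    overlapped = True
                    break
            if overlapped:
                continue
            half = domain_length // 2
            w_start, w_end = max(0, mid - half), mid + (domain_length - half)
            for g in genes:
                if ovl(enh.interval.chrom, w_start, w_end, g.interval.chrom, g.interval.start, g.interval.end):
                    found.add(g.gene_id)
                    pairs.add((enh.enhancer_id, resource, g.gene_id))
        per_resource[resource] = found
    final = set.intersection(*per_resource.values()) if per_resource else set()
    return per_resource, final, pairs


def gen_annotation(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[GeneRecord], dict[str, list[EnhancerRecord]], dict[str, set[str]], set[str], list[str]]:
    """Place genes and enhancers on the block grid; compute truth by double loop."""
    R = len(config.resources)
    n_shared = round(config.resource_overlap * config.n_enhancers)
    n_private = config.n_enhancers - n_shared
    n_decoy = int(round(0.6 * n_private))
    n_filtered = int(round(0.2 * n_private))
    n_desert = n_private - n_decoy - n_filtered

    n_gene_blocks_needed = n_shared + R * (n_decoy + n_filtered)
    n_background = config.n_genes - n_gene_blocks_needed
    if n_background < 0:
        raise ValueError(
            f"infeasible packing: {n_gene_blocks_needed} enhancer-linked gene blocks "
            f"but only {config.n_genes} genes configured"
        )
    blocks_per_chrom = config.chrom_length // config.block_size
    total_blocks = config.n_chromosomes * blocks_per_chrom
    n_blocks_needed = config.n_genes + R * n_desert
    if n_blocks_needed > total_blocks:
        raise ValueError(
            f"infeasible packing: need {n_blocks_needed} blocks, genome has {total_blocks}"
        )

    roles: list[tuple[str, str | None]] = []  # (role, resource-or-None)
    roles += [("target", None)] * n_shared
    for res in config.resources:
        roles += [("decoy", res)] * n_decoy
        roles += [("filtered", res)] * n_filtered
        roles += [("desert", res)] * n_desert
    roles += [("background", None)] * n_background
    block_ids = rng.permutation(total_blocks)[: len(roles)]

    genes: list[GeneRecord] = []
    enhancers: dict[str, list[EnhancerRecord]] = {res: [] for res in config.resources}
    target_genes: list[str] = []
    gene_counter = 0
    enh_counter = {res: 0 for res in config.resources}

    def new_gene(chrom: str, start: int, length: int) -> GeneRecord:
        nonlocal gene_counter
        gene_counter += 1
        gid = f"G{gene_counter:04d}"
        biotype = "protein_coding" if rng.random() < config.pcg_fraction else "lncRNA"
        strand = "+" if rng.random() < 0.5 else "-"
        return GeneRecord(GenomicInterval(chrom, start, start + length), gid, gid, strand, biotype)

    def new_enhancer(resource: str, chrom: str, start: int, end: int, tag: str) -> EnhancerRecord:
        enh_counter[resource] += 1
        eid = f"{tag}{enh_counter[resource]:04d}"
        return EnhancerRecord(GenomicInterval(chrom, start, end), eid, resource)

    for (role, res), block in zip(roles, block_ids):
        chrom = f"chr{block // blocks_per_chrom + 1}"
        base = int(block % blocks_per_chrom) * config.block_size
        gene_len = int(rng.integers(2_000, 20_000))
        gene_start = base + 50_000
        enh_len = int(rng.integers(200, 1_500))
        if role in ("target", "decoy", "filtered", "background"):
            gene = new_gene(chrom, gene_start, gene_len)
            genes.append(gene)
        if role == "target":
            target_genes.append(gene.gene_id)
            # midpoint 12 kb past the gene end: eRNA region (+-3 kb) is
            # gene-free, the +-92.5 kb domain window covers the gene
            mid = gene.interval.end + 12_000
            for resource in config.resources:
                jitter = int(rng.integers(-200, 201))
                m = mid + jitter
                enhancers[resource].append(
                    new_enhancer(resource, chrom, m - enh_len // 2, m - enh_len // 2 + enh_len, "se")
                )
        elif role == "decoy":
            mid = gene.interval.end + 12_000
            enhancers[res].append(
                new_enhancer(res, chrom, mid - enh_len // 2, mid - enh_len // 2 + enh_len, "pe")
            )
        elif role == "filtered":
            # enhancer midpoint inside the gene -> its eRNA region overlaps
            mid = gene.interval.start + gene_len // 2
            enhancers[res].append(
                new_enhancer(res, chrom, mid - enh_len // 2, mid - enh_len // 2 + enh_len, "fe")
            )
        elif role == "desert":
            mid = base + config.block_size // 2
            enhancers[res].append(
                new_enhancer(res, chrom, mid - enh_len // 2, mid - enh_len // 2 + enh_len, "de")
            )

    per_resource, final, _ = brute_force_errgs(
        enhancers, genes, config.half_width, config.domain_length
    )
    return genes, enhancers, per_resource, final, target_genes


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    config: SimConfig,
    genes: Sequence[GeneRecord],
    errg_final: set[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series, set[str], set[str]]:
    """Negative-binomial counts with boosted eRRG baselines and planted DE.

    Baseline per-gene means are log-normal; planted final eRRGs get an
    elevated baseline (for the mean/CV contrast) and a seeded subset of
    them carries a tumor-vs-normal log2 fold change (for DE recovery).
    """
    gene_ids = [g.gene_id for g in genes]
    tumor = [f"T{i + 1:03d}" for i in range(config.n_tumor)]
    normal = [f"N{i + 1:03d}" for i in range(config.n_normal)]
    base_mean = rng.lognormal(mean=np.log(15.0), sigma=1.0, size=len(gene_ids))
    errg_idx = [i for i, g in enumerate(gene_ids) if g in errg_final]
    base_mean[errg_idx] *= config.errg_expression_boost

    errgs_sorted = sorted(errg_final)
    n_up = int(round(config.de_up_fraction * len(errgs_sorted)))
    n_down = int(round(config.de_down_fraction * len(errgs_sorted)))
    shuffled = list(rng.permutation(errgs_sorted))
    de_up = set(shuffled[:n_up])
    de_down = set(shuffled[n_up : n_up + n_down])

    lfc = np.zeros(len(gene_ids))
    for i, g in enumerate(gene_ids):
        if g in de_up:
            lfc[i] = config.de_log2fc
        elif g in de_down:
            lfc[i] = -config.de_log2fc

    n_nb = 1.0 / config.nb_dispersion  # NB size parameter
    mean_tumor = base_mean * (2.0 ** lfc)

    def draw(mu: np.ndarray, n_samples: int) -> np.ndarray:
        mu_mat = np.tile(mu[:, None], (1, n_samples))
        p = n_nb / (n_nb + mu_mat)
        return rng.negative_binomial(n_nb, p)

    counts = pd.DataFrame(
        np.hstack([draw(mean_tumor, config.n_tumor), draw(base_mean, config.n_normal)]),
        index=gene_ids,
        columns=tumor + normal,
    )
    groups = pd.Series(
        ["tumor"] * config.n_tumor + ["normal"] * config.n_normal, index=tumor + normal, name="group"
    )
    return counts, groups, de_up, de_down


# ---------------------------------------------------------------------------
# methylation + mutations


def gen_methylation(
    config: SimConfig,
    genes: Sequence[GeneRecord],
    risk_groups: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Beta matrix with planted differential probes, plus a probe map.

    Null probes share a per-probe base mean in both groups; planted probes
    shift the high-risk mean by +-delta-beta (mostly hypo, mirroring a
    predominantly hypomethylated high-risk group). Betas are normals
    clipped to [0, 1].
    """
    samples = list(risk_groups.index)
    high = risk_groups.values == "high"
    probe_ids = [f"cg{i + 1:06d}" for i in range(config.n_probes)]
    gene_pool = list(genes)
    chosen = [gene_pool[i] for i in rng.integers(0, len(gene_pool), size=config.n_probes)]
    positions = np.array(
        [int(rng.integers(g.interval.start, g.interval.end)) for g in chosen]
    )
    probe_map = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": [g.interval.chrom for g in chosen],
            "position": positions,
            "gene_id": [g.gene_id for g in chosen],
        }
    ).set_index("probe_id")

    planted_idx = rng.permutation(config.n_probes)[: config.n_planted_dmp]
    n_hypo = int(round(config.dmp_hypo_fraction * len(planted_idx)))
    dmp_truth: dict[str, str] = {}
    base = rng.uniform(0.10, 0.90, size=config.n_probes)
    mean_high = base.copy()
    mean_low = base.copy()
    for k, idx in enumerate(planted_idx):
        direction = "hypo" if k < n_hypo else "hyper"
        dmp_truth[probe_ids[idx]] = direction
        # keep the shifted mean inside (0, 1) with headroom for noise
        b = rng.uniform(0.35, 0.65)
        mean_low[idx] = b
        mean_high[idx] = b - config.dmp_delta_beta if direction == "hypo" else b + config.dmp_delta_beta
    means = np.where(high[None, :], mean_high[:, None], mean_low[:, None])
    beta = np.clip(rng.normal(means, config.beta_sd), 0.0, 1.0)
    return pd.DataFrame(beta, index=probe_ids, columns=samples), probe_map, dmp_truth


def _variant_fields(cls: str, gene: GeneRecord, rng: np.random.Generator) -> tuple[str, str, str]:
    """(ref, alt, variant_type) consistent with the variant class."""
    if cls in ("Missense_Mutation", "Silent", "Nonsense_Mutation", "Splice_Site"):
        snv = _weighted_choice(_SNV_CLASS_MIX, rng)
        ref, alt = _PYRIMIDINE_PAIRS[snv]
        if rng.random() < 0.5:  # report on the purine strand half the time
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        return ref, alt, "SNP"
    if cls == "Frame_Shift_Del":
        ref = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        return ref, "-", "DEL"
    # Frame_Shift_Ins
    alt = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
    return "-", alt, "INS"


def _weighted_choice(mix: Sequence[tuple[str, float]], rng: np.random.Generator) -> str:
    labels = [m[0] for m in mix]
    weights = np.array([m[1] for m in mix], dtype=float)
    return labels[int(rng.choice(len(labels), p=weights / weights.sum()))]


def gen_mutations(
    config: SimConfig,
    genes: Sequence[GeneRecord],
    risk_groups: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, set[str]]:
    """MAF-like mutation table with planted per-gene group rate differences."""
    gene_list = sorted(genes, key=lambda g: g.gene_id)
    planted = [
        gene_list[i]
        for i in rng.permutation(len(gene_list))[: config.n_planted_mut_genes]
    ]
    planted_ids = {g.gene_id for g in planted}
    rows = []
    for g in gene_list:
        for sample, grp in risk_groups.items():
            if g.gene_id in planted_ids:
                rate = config.mut_rate_high if grp == "high" else config.mut_rate_low
            else:
                rate = config.mutation_rate
            if rng.random() >= rate:
                continue
            for _ in range(1 + int(rng.poisson(0.3))):
                cls = _weighted_choice(_VARIANT_CLASS_MIX, rng)
                ref, alt, vtype = _variant_fields(cls, g, rng)
                pos = int(rng.integers(g.interval.start, g.interval.end))
                depth = int(rng.integers(40, 200))
                vaf = rng.uniform(0.05, 0.9)
                rows.append(
                    (
                        sample,
                        g.gene_id,
                        g.interval.chrom,
                        pos + 1,  # MAF positions are 1-based
                        ref,
                        alt,
                        cls,
                        vtype,
                        int(round(vaf * depth)),
                        depth,
                    )
                )
    maf = pd.DataFrame(
        rows,
        columns=[
            "Tumor_Sample_Barcode",
            "Hugo_Symbol",
            "Chromosome",
            "Start_Position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "Variant_Classification",
            "Variant_Type",
            "t_alt_count",
            "t_depth",
        ],
    )
    return maf, planted_ids


def gen_methylation_mutations(
    config: SimConfig,
    genes: Sequence[GeneRecord],
    risk_groups: pd.Series,
    rng: np.random.Generator,
):
    """Convenience wrapper generating both omics layers for the risk groups."""
    beta, probe_map, dmp_truth = gen_methylation(config, genes, risk_groups, rng)
    maf, diff_mut = gen_mutations(config, genes, risk_groups, rng)
    return beta, probe_map, dmp_truth, maf, diff_mut


# ---------------------------------------------------------------------------
# survival


def gen_survival(
    config: SimConfig, linear_predictor: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential survival times with hazard proportional to exp(risk).

    The linear predictor is standardized, so ``survival_effect`` is the
    log hazard ratio per SD of risk score. A configured fraction of
    samples is censored uniformly before their event time.
    """
    lp = linear_predictor.astype(float)
    sd = lp.std(ddof=0)
    z = (lp - lp.mean()) / sd if sd > 0 else lp * 0.0
    hazard = config.baseline_hazard * np.exp(config.survival_effect * z.values)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(len(lp)) < config.censoring_fraction
    time = np.where(censored, rng.uniform(0, 1, size=len(lp)) * t_event, t_event)
    time = np.maximum(time, 1e-3)  # strictly positive
    return pd.DataFrame(
        {"time": time, "event": (~censored).astype(int)}, index=lp.index
    ).rename_axis("sample")


# ---------------------------------------------------------------------------
# bundle


def generate_bundle(config: SimConfig | None = None) -> SimBundle:
    """Generate the complete synthetic study from one config."""
    from .expression_stats import log2_cpm
    from .signature_survival import median_split, risk_score

    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    genes, enhancers, per_resource, errg_final, target_genes = gen_annotation(config, rng)
    counts, groups, de_up, de_down = gen_expression(config, genes, errg_final, rng)

    # signature over planted eRRGs (fall back to all genes if none)
    pool = sorted(errg_final) or sorted(g.gene_id for g in genes)
    size = min(config.signature_size, len(pool))
    sig_genes = [pool[i] for i in sorted(rng.permutation(len(pool))[:size])]
    signature = pd.Series(rng.normal(0.0, 0.4, size=size), index=sig_genes, name="beta")

    tumor_samples = groups.index[groups == "tumor"]
    log_expr = log2_cpm(counts[tumor_samples])
    lp = risk_score(log_expr, signature)
    risk_groups = median_split(lp)

    beta, probe_map, dmp_truth, maf, diff_mut = gen_methylation_mutations(
        config, genes, risk_groups, rng
    )
    survival = gen_survival(config, lp, rng)

    truth = GroundTruth(
        errg_per_resource={r: set(s) for r, s in per_resource.items()},
        errg_final=set(errg_final),
        target_genes=target_genes,
        de_up=de_up,
        de_down=de_down,
        dmp_probes=dmp_truth,
        diff_mut_genes=diff_mut,
        signature=dict(signature),
        risk_groups=dict(risk_groups),
    )
    return SimBundle(
        config=config,
        genes=genes,
        enhancers=enhancers,
        counts=counts,
        groups=groups,
        beta=beta,
        probe_map=probe_map,
        mutations=maf,
        survival=survival,
        signature=signature,
        risk_groups=risk_groups,
        truth=truth,
    )


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every input file the CLI consumes, plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genes"] = out / "genes.tsv"
    write_gene_table(bundle.genes, paths["genes"])
    for resource, records in bundle.enhancers.items():
        p = out / f"enhancers_{resource}.bed"
        with open(p, "w") as fh:
            for rec in records:
                fh.write(
                    f"{rec.interval.chrom}\t{rec.interval.start}\t{rec.interval.end}\t{rec.enhancer_id}\n"
                )
        paths[f"enhancers:{resource}"] = p

    paths["counts"] = out / "counts.tsv"
    bundle.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    paths["groups"] = out / "groups.tsv"
    bundle.groups.rename_axis("sample").to_frame().to_csv(paths["groups"], sep="\t")
    paths["beta"] = out / "beta.tsv"
    bundle.beta.rename_axis("probe_id").to_csv(paths["beta"], sep="\t", float_format="%.6f")
    paths["probe_map"] = out / "probe_map.tsv"
    bundle.probe_map.to_csv(paths["probe_map"], sep="\t")
    paths["mutations"] = out / "mutations.tsv"
    bundle.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    paths["survival"] = out / "survival.tsv"
    bundle.survival.reset_index().to_csv(paths["survival"], sep="\t", index=False, float_format="%.4f")
    paths["signature"] = out / "signature.tsv"
    bundle.signature.rename_axis("gene_id").to_frame().to_csv(
        paths["signature"], sep="\t", float_format="%.6f"
    )
    paths["risk_groups"] = out / "risk_groups.tsv"
    bundle.risk_groups.rename_axis("sample").to_frame().to_csv(paths["risk_groups"], sep="\t")

    truth = bundle.truth
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "errg_per_resource": {r: sorted(s) for r, s in truth.errg_per_resource.items()},
                "errg_final": sorted(truth.errg_final),
                "target_genes": truth.target_genes,
                "de_up": sorted(truth.de_up),
                "de_down": sorted(truth.de_down),
                "dmp_probes": truth.dmp_probes,
                "diff_mut_genes": sorted(truth.diff_mut_genes),
                "signature": truth.signature,
                "risk_groups": truth.risk_groups,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    paths["config"] = out / "sim_config.json"
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=1, sort_keys=True)
    return paths
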