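"""Co-occurrence of 5mC and 5gmC and their association with transcription.

Covers the positional overlap between the two modifications (shared versus
exclusive sites and their level contrasts), expression-quartile grouping,
metagene profiles over scaled gene bodies, rank correlation between
region-level modification and expression, and the proportions of
differentially expressed genes with and without 5gmC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GeneModel
from .landscape import AnnotationConfig, annotate_features

__all__ = [
    "OverlapReport",
    "MetageneConfig",
    "MetageneProfile",
    "site_overlap",
    "expression_quartiles",
    "metagene_profile",
    "segment_correlation",
    "genes_with_gmc",
    "de_proportions",
]

SITE_KEY = ["chrom", "pos", "strand"]
GENE_REGIONS = ("promoter", "body_first_third", "body_middle_third", "body_last_third", "downstream", "gene_body")


def _summary(r: np.ndarray) -> dict[str, float]:
    if r.size == 0:
        return {"n": 0, "mean": float("nan"), "sd": float("nan"), "median": float("nan")}
    return {
        "n": int(r.size),
        "mean": float(np.nanmean(r)),
        "sd": float(np.nanstd(r, ddof=1)) if r.size > 1 else 0.0,
        "median": float(np.nanmedian(r)),
    }


@dataclass
class OverlapReport:
    n_gmc: int
    n_mc: int
    n_shared: int
    jaccard: float
    gmc_exclusive_fraction: float
    mc_exclusive_fraction: float
    ratio_summaries: pd.DataFrame
    breakdown: pd.DataFrame | None = None

    @property
    def n_gmc_exclusive(self) -> int:
        return self.n_gmc - self.n_shared

    @property
    def n_mc_exclusive(self) -> int:
        return self.n_mc - self.n_shared


def site_overlap(
    gmc_sites: pd.DataFrame,
    mc_sites: pd.DataFrame,
    genes: list[GeneModel] | None = None,
    config: AnnotationConfig | None = None,
) -> OverlapReport:
    """Exact-position intersection of confident 5gmC and 5mC site sets.

    Reports shared/exclusive counts (the accounting closes exactly:
    shared + exclusive = total per modification), Jaccard, and modification
    ratio summaries computed separately for shared and exclusive sites.
    When gene models are given, a context-by-feature breakdown of shared vs
    exclusive sites is added.
    """
    kg = pd.MultiIndex.from_frame(gmc_sites[SITE_KEY]) if len(gmc_sites) else pd.MultiIndex.from_arrays([[], [], []], names=SITE_KEY)
    km = pd.MultiIndex.from_frame(mc_sites[SITE_KEY]) if len(mc_sites) else pd.MultiIndex.from_arrays([[], [], []], names=SITE_KEY)
    shared_g = kg.isin(km)
    shared_m = km.isin(kg)
    n_shared = int(shared_g.sum())
    n_g, n_m = len(kg), len(km)
    union = n_g + n_m - n_shared
    jaccard = n_shared / union if union else float("nan")

    rows = []
    for mod, sites, shared_mask in (("5gmC", gmc_sites, shared_g), ("5mC", mc_sites, shared_m)):
        if "ratio" not in sites.columns:
            continue
        r = sites["ratio"].to_numpy(dtype=float)
        for group, mask in (("shared", shared_mask), ("exclusive", ~shared_mask)):
            s = _summary(r[mask])
            rows.append((mod, group, s["n"], s["mean"], s["sd"], s["median"]))
    summaries = pd.DataFrame(rows, columns=["modification", "group", "n", "mean", "sd", "median"])

    breakdown = None
    if genes is not None:
        parts = []
        for mod, sites, shared_mask in (("5gmC", gmc_sites, shared_g), ("5mC", mc_sites, shared_m)):
            if not len(sites):
                continue
            feats = annotate_features(sites, genes, config)
            df = pd.DataFrame(
                {
                    "modification": mod,
                    "group": np.where(shared_mask, "shared", "exclusive"),
                    "context": sites["context"].to_numpy(),
                    "feature": feats.to_numpy(),
                }
            )
            parts.append(df)
        if parts:
            breakdown = (
                pd.concat(parts)
                .groupby(["modification", "group", "context", "feature"], observed=True)
                .size()
                .rename("n_sites")
                .reset_index()
            )
    return OverlapReport(
        n_gmc=n_g,
        n_mc=n_m,
        n_shared=n_shared,
        jaccard=jaccard,
        gmc_exclusive_fraction=(n_g - n_shared) / n_g if n_g else float("nan"),
        mc_exclusive_fraction=(n_m - n_shared) / n_m if n_m else float("nan"),
        ratio_summaries=summaries,
        breakdown=breakdown,
    )


def expression_quartiles(expression: pd.DataFrame, q: float = 0.25) -> tuple[list[str], list[str]]:
    """Top-q and bottom-q gene groups by FPKM (ties broken by gene id).

    Returns ``(top_ids, bottom_ids)``, each of size floor(n * q).
    """
    if not 0.0 < q <= 0.5:
        raise ValueError("q must lie in (0, 0.5]")
    n = len(expression)
    k = int(np.floor(n * q))
    df = expression.sort_values(["fpkm", "gene_id"], ascending=[False, True], kind="stable")
    top = df["gene_id"].head(k).tolist()
    df = expression.sort_values(["fpkm", "gene_id"], ascending=[True, True], kind="stable")
    bottom = df["gene_id"].head(k).tolist()
    return top, bottom


# ---------------------------------------------------------------------------
# Metagene profiles


@dataclass
class MetageneConfig:
    flank_bp: int = 1000
    flank_bin_bp: int = 50
    body_bins: int = 60

    @property
    def flank_bins(self) -> int:
        return self.flank_bp // self.flank_bin_bp

    @property
    def total_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


@dataclass
class MetageneProfile:
    """Mean modification ratio over fixed flanks and a scaled gene body."""

    group: str
    values: np.ndarray  # length total_bins; NaN where no covered cytosine
    counts: np.ndarray
    config: MetageneConfig
    n_genes: int
    n_skipped: int


def metagene_profile(
    records: pd.DataFrame,
    genes: list[GeneModel],
    groups: dict[str, list[str]],
    config: MetageneConfig | None = None,
) -> dict[str, MetageneProfile]:
    """Average modification ratio around TSS, scaled gene body, and TES.

    Gene bodies are linearly rescaled to ``body_bins`` bins; flanks use
    fixed-width bins.  Minus-strand genes are reversed so every profile
    reads 5' to 3'.  Per bin, the mean ratio over all covered cytosines of
    all genes in the group is reported.  Genes shorter than the body bin
    count are skipped and counted.
    """
    cfg = config or MetageneConfig()
    by_id = {g.gene_id: g for g in genes}
    by_chrom: dict[str, pd.DataFrame] = {
        c: blk.sort_values("pos") for c, blk in records.groupby("chrom")
    }
    out = {}
    fb, bb = cfg.flank_bins, cfg.body_bins
    for label, gene_ids in groups.items():
        sums = np.zeros(cfg.total_bins)
        counts = np.zeros(cfg.total_bins, dtype=np.int64)
        n_used = n_skipped = 0
        for gid in gene_ids:
            g = by_id.get(gid)
            if g is None:
                continue
            if g.length < bb:
                n_skipped += 1
                continue
            blk = by_chrom.get(g.chrom)
            if blk is None:
                n_used += 1
                continue
            pos = blk["pos"].to_numpy() - 1
            ratio = blk["ratio"].to_numpy(dtype=float)
            lo, hi = g.start - cfg.flank_bp, g.end + cfg.flank_bp
            i, j = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
            p = pos[i:j]
            r = ratio[i:j]
            ok = ~np.isnan(r)
            p, r = p[ok], r[ok]
            if p.size == 0:
                n_used += 1
                continue
            bins = np.empty(p.size, dtype=np.int64)
            up = p < g.start
            down = p >= g.end
            body = ~up & ~down
            bins[up] = fb - 1 - (g.start - 1 - p[up]) // cfg.flank_bin_bp
            bins[body] = fb + (p[body] - g.start) * bb // g.length
            bins[down] = fb + bb + (p[down] - g.end) // cfg.flank_bin_bp
            if g.strand == "-":
                bins = cfg.total_bins - 1 - bins
            np.add.at(sums, bins, r)
            np.add.at(counts, bins, 1)
            n_used += 1
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[label] = MetageneProfile(label, values, counts, cfg, n_used, n_skipped)
    return out


# ---------------------------------------------------------------------------
# Region-level correlation with expression


def _gene_regions(g: GeneModel, config: AnnotationConfig) -> dict[str, tuple[int, int]]:
    """0-based half-open genomic windows of each transcript region."""
    L = g.length
    t1, t2 = g.start + L // 3, g.start + (2 * L) // 3
    if g.strand == "+":
        regions = {
            "promoter": (g.start - config.promoter_bp, g.start),
            "body_first_third": (g.start, t1),
            "body_middle_third": (t1, t2),
            "body_last_third": (t2, g.end),
            "downstream": (g.end, g.end + config.downstream_bp),
        }
    else:
        regions = {
            "promoter": (g.end, g.end + config.promoter_bp),
            "body_first_third": (t2, g.end),
            "body_middle_third": (t1, t2),
            "body_last_third": (g.start, t1),
            "downstream": (g.start - config.downstream_bp, g.start),
        }
    regions["gene_body"] = (g.start, g.end)
    return {k: (max(s, 0), e) for k, (s, e) in regions.items()}


def segment_correlation(
    records: pd.DataFrame,
    genes: list[GeneModel],
    expression: pd.DataFrame,
    config: AnnotationConfig | None = None,
    method: str = "spearman",
    min_genes: int = 10,
) -> pd.DataFrame:
    """Rank correlation between expression and region-level modification.

    Each transcript is divided into promoter, thirds of the gene body,
    downstream window (plus the whole body); per gene and region the
    modification is summarized both as the max and as the mean ratio over
    covered cytosines (0 where the region has none).  Correlation against
    FPKM is computed across genes.  Degenerate (constant) summaries and
    runs with fewer than ``min_genes`` genes are flagged unstable.
    """
    cfg = config or AnnotationConfig()
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    by_chrom = {c: blk.sort_values("pos") for c, blk in records.groupby("chrom")}
    expr = expression.set_index("gene_id")["fpkm"]
    rows_per_gene = []
    for g in genes:
        if g.gene_id not in expr.index:
            continue
        blk = by_chrom.get(g.chrom)
        summaries = {}
        for region, (lo, hi) in _gene_regions(g, cfg).items():
            if blk is None or hi <= lo:
                summaries[region] = (0.0, 0.0)
                continue
            pos = blk["pos"].to_numpy() - 1
            i, j = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
            r = blk["ratio"].to_numpy(dtype=float)[i:j]
            r = r[~np.isnan(r)]
            if r.size == 0:
                summaries[region] = (0.0, 0.0)
            else:
                summaries[region] = (float(r.max()), float(r.mean()))
        rows_per_gene.append((g.gene_id, float(expr[g.gene_id]), summaries))

    n = len(rows_per_gene)
    out = []
    fpkm = np.array([r[1] for r in rows_per_gene])
    for region in GENE_REGIONS:
        for stat_name, idx in (("max", 0), ("mean", 1)):
            x = np.array([r[2][region][idx] for r in rows_per_gene])
            unstable = n < min_genes
            if n < 2 or np.all(x == x[0]) or np.all(fpkm == fpkm[0]):
                rho, pval, unstable = float("nan"), float("nan"), True
            else:
                rho, pval = corr(x, fpkm)
                rho, pval = float(rho), float(pval)
            out.append((region, stat_name, rho, pval, n, unstable))
    return pd.DataFrame(
        out, columns=["region", "statistic", "rho", "p_value", "n_genes", "unstable"]
    )


# ---------------------------------------------------------------------------
# Differential expression and 5gmC


def genes_with_gmc(
    gmc_sites: pd.DataFrame,
    genes: list[GeneModel],
    config: AnnotationConfig | None = None,
) -> set[str]:
    """Genes containing >= 1 confident 5gmC site in their promoter, exonic,
    intronic or downstream windows (the gene-assignment universe used for
    the functional-region analyses)."""
    cfg = config or AnnotationConfig()
    hit: set[str] = set()
    pos_by_chrom = {
        c: np.sort(blk["pos"].to_numpy() - 1) for c, blk in gmc_sites.groupby("chrom")
    }
    for g in genes:
        pos = pos_by_chrom.get(g.chrom)
        if pos is None:
            continue
        if g.strand == "+":
            lo, hi = g.start - cfg.promoter_bp, g.end + cfg.downstream_bp
        else:
            lo, hi = g.start - cfg.downstream_bp, g.end + cfg.promoter_bp
        i, j = np.searchsorted(pos, max(lo, 0)), np.searchsorted(pos, hi)
        if j > i:
            hit.add(g.gene_id)
    return hit


def de_proportions(
    genes_with: list[str],
    genes_without: list[str],
    de_table: pd.DataFrame,
) -> pd.DataFrame:
    """Fractions of up/down-regulated genes among genes with vs without 5gmC.

    The two groups must partition disjointly.  Returns one row per group
    with down/up fractions (NaN-flagged for empty groups) plus a
    two-proportion exact test on the downregulated fraction stored in
    ``result.attrs['p_value_down']``.
    """
    overlap = set(genes_with) & set(genes_without)
    if overlap:
        raise ValueError(f"genes in both groups: {sorted(overlap)[:5]} ...")
    status = de_table.set_index("gene_id")["status"]
    rows = []
    tallies = []
    for label, members in (("with_5gmC", genes_with), ("without_5gmC", genes_without)):
        st = status.reindex(members).dropna()
        n = len(st)
        n_down = int((st == "down").sum())
        n_up = int((st == "up").sum())
        frac_down = n_down / n if n else float("nan")
        frac_up = n_up / n if n else float("nan")
        rows.append((label, n, n_down, n_up, frac_down, frac_up, n == 0))
        tallies.append((n_down, n - n_down))
    df = pd.DataFrame(
        rows,
        columns=["group", "n_genes", "n_down", "n_up", "fraction_down", "fraction_up", "undefined"],
    )
    if all(a + b > 0 for a, b in tallies):
        _, pval = stats.fisher_exact(tallies)
        df.attrs["p_value_down"] = float(pval)
    else:
        df.attrs["p_value_down"] = float("nan")
    return df
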