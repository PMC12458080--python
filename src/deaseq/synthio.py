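"""Synthetic data generation for the 5gmC profiling pipeline.

Generates GC-rich genomes with gene/TE/histone annotation, plants ground-truth
5mC (CpG-preferential) and sparse 5gmC (CHH-preferential, ppm-scale, largely
exclusive of 5mC), simulates per-cytosine conversion counts under the DEA,
WGBS and TET-BS chemistries, builds the spike-in control set, and links gene
expression to gene-body modification, so every downstream stage of the
pipeline can be exercised against a known truth.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import landscape
from .chemistry import CONTEXTS, ChemistryProfile
from .formats import GeneModel, GenomeRef, IntervalSet, _finalize_table

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SpikeinSet",
    "SPIKEIN_TEMPLATE",
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "simulate_reference",
    "plant_modifications",
    "simulate_counts",
    "ko_truth",
    "inject_noise_sites",
    "make_spikeins",
    "simulate_spikein_counts",
    "simulate_expression",
    "simulate_de_calls",
]


class SimConfigError(ValueError):
    """Infeasible or invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and chemistry.

    Defaults emulate the profiled system: a GC-rich (~64%) genome sized so
    that it carries about one million cytosines, 5mC planted preferentially
    at CpG, 5gmC planted at ~10 sites per million cytosines with a CHH and
    intron preference and mostly (60%) exclusive of 5mC, ~100x sequencing
    depth, and gene expression positively linked to first-third gene-body
    5gmC and negatively to gene 5mC.
    """

    # genome
    genome_length: int = 1_562_500
    n_chromosomes: int = 2
    gc_fraction: float = 0.64
    # genes
    n_genes: int = 200
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (100, 400)
    intron_length_range: tuple[int, int] = (100, 500)
    # intervals
    te_density: float = 0.04
    te_length_range: tuple[int, int] = (500, 3000)
    histone_mark_density: dict[str, float] = field(
        default_factory=lambda: {"H3K9me1": 0.05, "H3K4me3": 0.05, "H3K9me3": 0.02}
    )
    mark_length_range: tuple[int, int] = (500, 2500)
    # 5mC planting
    mc_prob: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.03, "CHG": 0.008, "CHH": 0.004}
    )
    mc_f_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CG": (8.0, 2.0), "CHG": (4.0, 4.0), "CHH": (2.0, 6.0)}
    )
    mc_mark_boost: dict[str, float] = field(default_factory=lambda: {"H3K9me1": 5.0})
    mc_mark_level_exponent: float = 0.5  # f -> f**e inside boosted marks (e<1 raises levels)
    mc_gene_level_jitter: float = 0.25  # per-gene uniform shift of 5mC levels (+/- half-width)
    mc_te_boost: float = 2.0
    # 5gmC planting
    gmc_ppm: float = 10.0
    gmc_context_weights: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.15, "CHG": 0.15, "CHH": 0.70}
    )
    gmc_intron_boost: float = 3.0
    gmc_exclusive_fraction: float = 0.6
    gmc_high_share: float = 1.0  # share of 5gmC sites with true fraction > 0.5
    # depth model
    depth_mean: float = 100.0
    depth_shape: float = 20.0
    # expression link
    expr_log_mean: float = 3.0
    expr_gmc_coef: float = 1.5
    expr_mc_coef: float = -1.5
    expr_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        probs = [self.gc_fraction, self.gmc_exclusive_fraction, self.gmc_high_share]
        probs += list(self.mc_prob.values()) + list(self.gmc_context_weights.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SimConfigError("probabilities must lie in [0, 1]")
        if self.gmc_ppm < 0:
            raise SimConfigError("gmc_ppm must be >= 0")
        if self.genome_length < 1000 or self.n_chromosomes < 1:
            raise SimConfigError("genome too small")

    @classmethod
    def for_association(cls) -> "SimConfig":
        """Scaled-down genome for expression-association analyses.

        Shrinks the genome to 500 genes while keeping the *absolute* number
        of 5gmC-bearing genes near its full-genome value (a few hundred
        sites), so the expression link is carried by a realistic number of
        genes rather than vanishing with the downsampled null mass.
        """
        return cls(genome_length=2_400_000, n_chromosomes=2, n_genes=500, gmc_ppm=200.0)


_CODE_TO_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _CODE_TO_ASCII[codes].tobytes().decode("ascii")


def _make_genes(
    chrom: str, length: int, n: int, rng: np.random.Generator, cfg: SimConfig, first_id: int
) -> list[GeneModel]:
    structures = []
    for _ in range(n):
        n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        ex = rng.integers(cfg.exon_length_range[0], cfg.exon_length_range[1] + 1, n_ex)
        inl = rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1, max(n_ex - 1, 0))
        structures.append((ex, inl))
    total = sum(int(ex.sum() + inl.sum()) for ex, inl in structures)
    free = length - total
    if n and free < n + 1:
        raise SimConfigError(
            f"cannot pack {n} genes ({total} bp) into chromosome of {length} bp"
        )
    gaps = rng.multinomial(free, np.ones(n + 1) / (n + 1)) if n else []
    genes = []
    pos = 0
    for i, (ex, inl) in enumerate(structures):
        pos += int(gaps[i])
        start = pos
        exons = []
        p = start
        for j, el in enumerate(ex):
            exons.append((p, p + int(el)))
            p += int(el)
            if j < len(inl):
                p += int(inl[j])
        end = p
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{first_id + i:05d}", chrom, strand, start, end, exons))
        pos = end
    return genes


def _random_intervals(
    chrom: str, length: int, density: float, len_range: tuple[int, int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    mean_len = (len_range[0] + len_range[1]) / 2
    n = int(round(density * length / mean_len))
    out = []
    for _ in range(n):
        l = int(rng.integers(len_range[0], len_range[1] + 1))
        if l >= length:
            continue
        s = int(rng.integers(0, length - l))
        out.append((s, s + l))
    return out


def simulate_reference(
    config: SimConfig, seed: int
) -> tuple[GenomeRef, list[GeneModel], dict[str, IntervalSet]]:
    """Generate a genome, non-overlapping gene models, and TE/histone intervals."""
    rng = np.random.default_rng(seed)
    n_chrom = config.n_chromosomes
    base = config.genome_length // n_chrom
    lengths = [base] * n_chrom
    lengths[-1] += config.genome_length - base * n_chrom

    sequences = {}
    genes: list[GeneModel] = []
    te: dict[str, list[tuple[int, int]]] = {}
    marks: dict[str, dict[str, list[tuple[int, int]]]] = {
        m: {} for m in config.histone_mark_density
    }
    genes_per_chrom = rng.multinomial(config.n_genes, np.array(lengths) / sum(lengths))
    next_id = 0
    for i, length in enumerate(lengths):
        chrom = f"chr{i + 1}"
        sequences[chrom] = _random_sequence(length, config.gc_fraction, rng)
        chrom_genes = _make_genes(chrom, length, int(genes_per_chrom[i]), rng, config, next_id)
        next_id += len(chrom_genes)
        genes.extend(chrom_genes)
        te[chrom] = _random_intervals(chrom, length, config.te_density, config.te_length_range, rng)
        for mark, dens in config.histone_mark_density.items():
            marks[mark][chrom] = _random_intervals(
                chrom, length, dens, config.mark_length_range, rng
            )
    intervals = {"TE": IntervalSet("TE", {c: v for c, v in te.items() if v})}
    for mark, d in marks.items():
        intervals[mark] = IntervalSet(mark, {c: v for c, v in d.items() if v})
    return GenomeRef(sequences), genes, intervals


# ---------------------------------------------------------------------------
# Ground-truth modification planting

TRUTH_COLUMNS = [
    "chrom", "pos", "strand", "context", "trinucleotide",
    "state", "f", "f_mc2", "in_intron",
]


def _membership(cyt: pd.DataFrame, ivset: IntervalSet | None) -> np.ndarray:
    mask = np.zeros(len(cyt), dtype=bool)
    if ivset is None:
        return mask
    pos0 = cyt["pos"].to_numpy() - 1
    chroms = cyt["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        m = chroms == chrom
        mask[m] = ivset.contains_points(chrom, pos0[m])
    return mask


def plant_modifications(
    genome: GenomeRef,
    genes: list[GeneModel],
    intervals: dict[str, IntervalSet] | None,
    config: SimConfig,
    seed: int,
) -> pd.DataFrame:
    """Plant true modification states on every cytosine of the genome.

    Returns one row per cytosine (both strands) with ``state`` in
    {C, 5mC, 5gmC}, the true modified fraction ``f`` of that state, and
    ``f_mc2``, the 5mC fraction carried by the remaining molecules at
    non-exclusive 5gmC sites (0 elsewhere).  5mC is drawn per context with a
    CpG preference (optionally boosted inside TEs and configured histone
    marks); 5gmC sites are drawn at ``gmc_ppm`` per million cytosines with
    CHH/intron preference, a configured fraction of them exclusive of 5mC.
    """
    rng = np.random.default_rng(seed)
    intervals = intervals or {}
    cyt = landscape.enumerate_cytosines(genome)
    n = len(cyt)
    if n == 0:
        raise SimConfigError("genome contains no cytosines")
    ctx = cyt["context"].to_numpy()

    # --- 5mC
    p_mc = np.zeros(n)
    for c, p in config.mc_prob.items():
        p_mc[ctx == c] = p
    boosted = np.zeros(n, dtype=bool)
    if config.mc_te_boost != 1.0 and "TE" in intervals:
        in_te = _membership(cyt, intervals["TE"])
        p_mc[in_te] *= config.mc_te_boost
        boosted |= in_te
    for mark, boost in config.mc_mark_boost.items():
        if mark in intervals:
            in_mark = _membership(cyt, intervals[mark])
            p_mc[in_mark] *= boost
            boosted |= in_mark
    np.clip(p_mc, 0.0, 0.95, out=p_mc)
    mc_mask = rng.random(n) < p_mc
    f_mc = np.zeros(n)
    for c, (a, b) in config.mc_f_beta.items():
        m = mc_mask & (ctx == c)
        f_mc[m] = rng.beta(a, b, int(m.sum()))
    m_ambig = mc_mask & (ctx == "AMBIG")
    if m_ambig.any():
        a, b = config.mc_f_beta["CHH"]
        f_mc[m_ambig] = rng.beta(a, b, int(m_ambig.sum()))
    # repressive-chromatin pattern: higher 5mC levels inside boosted regions
    lift = mc_mask & boosted
    f_mc[lift] = f_mc[lift] ** config.mc_mark_level_exponent
    # genes are differentially methylated: shift 5mC levels coherently per gene
    if config.mc_gene_level_jitter > 0 and genes:
        pos0 = cyt["pos"].to_numpy() - 1
        chrom_arr = cyt["chrom"].to_numpy()
        order_by_chrom = {
            c: np.flatnonzero(chrom_arr == c) for c in np.unique(chrom_arr)
        }
        j = config.mc_gene_level_jitter
        for g in genes:
            shift = rng.uniform(-j, j)
            idx = order_by_chrom.get(g.chrom)
            if idx is None:
                continue
            p = pos0[idx]
            i0, i1 = np.searchsorted(p, g.start), np.searchsorted(p, g.end)
            sel = idx[i0:i1]
            sel = sel[mc_mask[sel]]
            f_mc[sel] = np.clip(f_mc[sel] + shift, 0.02, 0.98)

    # --- 5gmC
    intron_ivs: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        for s, e in g.introns:
            intron_ivs.setdefault(g.chrom, []).append((s, e))
    intron_set = IntervalSet("introns", intron_ivs) if intron_ivs else None
    in_intron = _membership(cyt, intron_set)

    w = np.zeros(n)
    for c, cw in config.gmc_context_weights.items():
        w[ctx == c] = cw
    w[in_intron] *= config.gmc_intron_boost

    target = int(round(config.gmc_ppm * n / 1e6))
    eligible = w > 0
    if target > int(eligible.sum()):
        raise SimConfigError(
            f"requested 5gmC density ({config.gmc_ppm} ppm -> {target} sites) exceeds "
            f"the {int(eligible.sum())} cytosines eligible under the context weights"
        )
    n_shared = int(round((1.0 - config.gmc_exclusive_fraction) * target))
    n_excl = target - n_shared

    pool_shared = np.flatnonzero(eligible & mc_mask)
    pool_excl = np.flatnonzero(eligible & ~mc_mask)
    if n_shared > pool_shared.size:
        warnings.warn(
            "fewer 5mC sites than requested shared 5gmC sites; shifting remainder to exclusive"
        )
        n_excl += n_shared - pool_shared.size
        n_shared = pool_shared.size
    if n_excl > pool_excl.size:
        raise SimConfigError("not enough unmethylated eligible cytosines for exclusive 5gmC")

    def _draw(pool: np.ndarray, k: int) -> np.ndarray:
        if k == 0 or pool.size == 0:
            return np.array([], dtype=np.int64)
        pw = w[pool] / w[pool].sum()
        return rng.choice(pool, size=k, replace=False, p=pw)

    shared_idx = _draw(pool_shared, n_shared)
    excl_idx = _draw(pool_excl, n_excl)
    gmc_idx = np.concatenate([shared_idx, excl_idx])

    f_gmc = np.zeros(n)
    if gmc_idx.size:
        high = rng.random(gmc_idx.size) < config.gmc_high_share
        draw = np.where(
            high,
            rng.uniform(0.5, 0.95, gmc_idx.size),
            rng.uniform(0.1, 0.5, gmc_idx.size),
        )
        f_gmc[gmc_idx] = draw

    state = np.full(n, "C", dtype=object)
    f = np.zeros(n)
    f_mc2 = np.zeros(n)
    state[mc_mask] = "5mC"
    f[mc_mask] = f_mc[mc_mask]
    state[gmc_idx] = "5gmC"
    f[gmc_idx] = f_gmc[gmc_idx]
    if shared_idx.size:
        f_mc2[shared_idx] = np.minimum(f_mc[shared_idx], 1.0 - f_gmc[shared_idx])

    truth = cyt.copy()
    truth["state"] = state
    truth["f"] = f
    truth["f_mc2"] = f_mc2
    truth["in_intron"] = in_intron
    return truth[TRUTH_COLUMNS]


def ko_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Truth table for a methyltransferase-knockout sample: no 5mC, no 5gmC."""
    ko = truth.copy()
    ko["state"] = "C"
    ko["f"] = 0.0
    ko["f_mc2"] = 0.0
    return ko


# ---------------------------------------------------------------------------
# Count simulation


def _draw_depths(n: int, rng: np.random.Generator, mean: float, shape: float) -> np.ndarray:
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=n)


def simulate_counts(
    truth: pd.DataFrame,
    profile: ChemistryProfile,
    config: SimConfig | None = None,
    seed: int = 0,
    depth: np.ndarray | int | None = None,
) -> pd.DataFrame:
    """Simulate a per-cytosine conversion-count table under one chemistry.

    Depth is drawn per site from a negative binomial (mean ``depth_mean``,
    shape ``depth_shape``) unless given explicitly; unconverted counts are
    Binomial(depth, p) with

    ``p = f_unmod * P(C|C) + f_mc * P(C|5mC) + f_gmc * P(C|5gmC)``

    where the molecule fractions come from the truth table (including the
    secondary 5mC fraction at shared sites).  When the profile declares
    locus-level escape dispersion, the per-site P(C|5mC) is Beta-distributed
    around the context mean.  AMBIG contexts use the CHH parameters.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    n = len(truth)
    if depth is None:
        d = _draw_depths(n, rng, config.depth_mean, config.depth_shape)
    else:
        d = np.full(n, depth, dtype=np.int64) if np.isscalar(depth) else np.asarray(depth)

    ctx = truth["context"].to_numpy()
    ctx_eff = np.where(ctx == "AMBIG", "CHH", ctx)
    state = truth["state"].to_numpy()
    f = truth["f"].to_numpy(dtype=float)
    f_mc2 = truth["f_mc2"].to_numpy(dtype=float)

    f_gmc = np.where(state == "5gmC", f, 0.0)
    f_mc = np.where(state == "5mC", f, 0.0) + f_mc2
    f_un = 1.0 - f_gmc - f_mc
    if (f_un < -1e-9).any():
        raise ValueError("molecule fractions exceed 1 at some site")
    f_un = np.clip(f_un, 0.0, 1.0)

    p_c_un = np.empty(n)
    p_c_mc = np.empty(n)
    p_c_gmc = np.empty(n)
    for c in CONTEXTS:
        m = ctx_eff == c
        if not m.any():
            continue
        p_c_un[m] = profile.p_read_c("C", c)
        p_c_gmc[m] = profile.p_read_c("5gmC", c)
        mean_escape = profile.p_read_c("5mC", c)
        if profile.escape_dispersion and 0.0 < mean_escape < 1.0:
            a = profile.escape_dispersion
            b = a * (1.0 - mean_escape) / mean_escape
            p_c_mc[m] = rng.beta(a, b, int(m.sum()))
        else:
            p_c_mc[m] = mean_escape

    p = f_un * p_c_un + f_mc * p_c_mc + f_gmc * p_c_gmc
    if (p < 0).any() or (p > 1).any():
        raise ValueError("chemistry profile produced a probability outside [0, 1]")
    n_unc = rng.binomial(d, p)
    rec = truth[["chrom", "pos", "strand", "context", "trinucleotide"]].copy()
    rec["n_unconverted"] = n_unc
    rec["n_converted"] = d - n_unc
    return _finalize_table(rec)


def inject_noise_sites(
    records: pd.DataFrame,
    n_sites: int,
    seed: int,
    ratio_range: tuple[float, float] = (0.3, 0.9),
) -> pd.DataFrame:
    """Inject technical noise at random sites (e.g. into a KO sample).

    Raises the unconverted count at ``n_sites`` random positions with
    sufficient depth so they would pass typical calling thresholds,
    exercising knockout-based background subtraction downstream.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    deep = np.flatnonzero(out["depth"].to_numpy() >= 30)
    if n_sites > deep.size:
        raise ValueError("not enough deep sites to inject noise into")
    pick = rng.choice(deep, size=n_sites, replace=False)
    ratios = rng.uniform(*ratio_range, size=n_sites)
    d = out["depth"].to_numpy()[pick]
    n_unc = np.maximum(np.round(ratios * d).astype(np.int64), 11)
    out.iloc[pick, out.columns.get_loc("n_unconverted")] = n_unc
    out.iloc[pick, out.columns.get_loc("n_converted")] = d - n_unc
    out["depth"] = out["n_unconverted"] + out["n_converted"]
    out["ratio"] = np.where(out["depth"] > 0, out["n_unconverted"] / out["depth"], np.nan)
    return out


# ---------------------------------------------------------------------------
# Spike-ins

FORWARD_PRIMER = "GAATTCTTGCAGCACTAGTGCATC"
REVERSE_PRIMER = "CTTTGCAACTTTTAAATCAC"

#: The 480-bp synthetic template of the fully-5mC PCR amplicon spike-in.
SPIKEIN_TEMPLATE = (
    "GAATTCTTGCAGCACTAGTGCATCTATAAGTTATCTCAAATCAAGAAATCAGTCTAATGAGAATTTCAAT"
    "AACTTCAGCAATTTAAGCTGCATGCATCAGTGTCATCGTTATTTTTTTTTTGAGACGTAGTCATGCTCTG"
    "TTGCTGAGTCTGCAGTACAGTGACGAGATATCGACTCAGCACAACATCTGCATCACATGTTCAAGCGATT"
    "CTCATGCTTCAGCTTGCAGAGTAGCTGTCACTACAGACACTGAGCAGCATGCGTGACTAATTTTTGTATT"
    "TTTAGTAGAGAGTGCATTTCGTCATGTTGTACAGTCTAGTTTCAAACTCATGACTTCAGTTGATCTAACT"
    "GACACGATCTCAGAATTTACTGTCATTACAGTACTGTCACACAGTGACAGTCATTTTTCTTAATTTTTAA"
    "AAATATTAAAGTTTTATCTCATTCGTGTTGAAGCATATTCGTGATTTAAAAGTTGCAAAG"
)

AMPLICON_CHROM = "spikein_mc480"
LAMBDA_CHROM = "spikein_lambda"


@dataclass
class SpikeinSet:
    """Spike-in control fragments with their known modification states.

    The fully-5mC amplicon is PCR-amplified with 5-methyl-dCTP, so every
    cytosine on both strands is 5mC at fraction 1.  The unmodified control is
    a lambda-like fragment with every cytosine unmodified.
    """

    sequences: dict[str, str]
    class_of_chrom: dict[str, str]

    def genome(self) -> GenomeRef:
        return GenomeRef(dict(self.sequences))

    @property
    def template(self) -> str:
        return self.sequences[AMPLICON_CHROM]

    def truth(self) -> pd.DataFrame:
        cyt = landscape.enumerate_cytosines(self.genome())
        state = np.where(
            cyt["chrom"].map(self.class_of_chrom).to_numpy() == "fully-5mC", "5mC", "C"
        )
        cyt["state"] = state
        cyt["f"] = np.where(state == "5mC", 1.0, 0.0)
        cyt["f_mc2"] = 0.0
        cyt["in_intron"] = False
        return cyt[TRUTH_COLUMNS]


def make_spikeins(lambda_length: int = 5000) -> SpikeinSet:
    """Build the spike-in set: the 480-bp fully-5mC amplicon template and an
    unmodified lambda-like control fragment (deterministic across calls)."""
    rng = np.random.default_rng(20480)  # fixed: the control fragment is a constant
    lam = _random_sequence(lambda_length, 0.50, rng)
    return SpikeinSet(
        sequences={AMPLICON_CHROM: SPIKEIN_TEMPLATE, LAMBDA_CHROM: lam},
        class_of_chrom={AMPLICON_CHROM: "fully-5mC", LAMBDA_CHROM: "unmodified"},
    )


def simulate_spikein_counts(
    spikeins: SpikeinSet,
    profile: ChemistryProfile,
    target_observations_per_class: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate conversion counts over the spike-ins under one chemistry.

    Per-class constant depth is chosen so that each spike-in class
    contributes approximately ``target_observations_per_class`` cytosine
    observations in total.
    """
    truth = spikeins.truth()
    klass = truth["chrom"].map(spikeins.class_of_chrom)
    depth = np.empty(len(truth), dtype=np.int64)
    for k in klass.unique():
        m = (klass == k).to_numpy()
        depth[m] = max(1, int(np.ceil(target_observations_per_class / m.sum())))
    return simulate_counts(truth, profile, seed=seed, depth=depth)


# ---------------------------------------------------------------------------
# Expression linked to gene-body modification


def _gene_region_levels(truth: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Per gene: mean 5gmC fraction in the first third of the gene body
    (transcription orientation) and mean 5mC fraction over the gene body."""
    gmc = truth[truth["state"] == "5gmC"]
    mc = truth[truth["state"] == "5mC"]
    by_chrom_gmc = {c: g.sort_values("pos") for c, g in gmc.groupby("chrom")}
    by_chrom_mc = {c: g.sort_values("pos") for c, g in mc.groupby("chrom")}

    def region_mean(block: pd.DataFrame | None, lo0: int, hi0: int) -> float:
        if block is None or hi0 <= lo0:
            return 0.0
        pos = block["pos"].to_numpy() - 1
        i = np.searchsorted(pos, lo0, side="left")
        j = np.searchsorted(pos, hi0, side="left")
        if j <= i:
            return 0.0
        return float(block["f"].to_numpy()[i:j].mean())

    rows = []
    for g in genes:
        third = max(g.length // 3, 1)
        if g.strand == "+":
            lo, hi = g.start, g.start + third
        else:
            lo, hi = g.end - third, g.end
        gmc_first = region_mean(by_chrom_gmc.get(g.chrom), lo, hi)
        mc_gene = region_mean(by_chrom_mc.get(g.chrom), g.start, g.end)
        rows.append((g.gene_id, gmc_first, mc_gene))
    return pd.DataFrame(rows, columns=["gene_id", "gmc_first_third", "mc_gene"])


def simulate_expression(
    truth: pd.DataFrame, genes: list[GeneModel], config: SimConfig, seed: int
) -> pd.DataFrame:
    """Generate FPKM values linked to gene-body modification.

    log FPKM = mean + gmc_coef * (mean 5gmC fraction, first third of body)
             + mc_coef * (mean 5mC fraction, gene body) + Gaussian noise.

    The default coefficients make 5gmC in the upstream third of the gene
    body expression-promoting and gene-body 5mC repressive.
    """
    rng = np.random.default_rng(seed)
    levels = _gene_region_levels(truth, genes)
    logf = (
        config.expr_log_mean
        + config.expr_gmc_coef * levels["gmc_first_third"].to_numpy()
        + config.expr_mc_coef * levels["mc_gene"].to_numpy()
        + rng.normal(0.0, config.expr_noise_sd, len(levels))
    )
    levels["fpkm"] = np.exp(logf)
    return levels[["gene_id", "fpkm", "gmc_first_third", "mc_gene"]]


def simulate_de_calls(
    gene_ids: list[str],
    has_gmc: np.ndarray,
    seed: int,
    p_down_with: float = 0.20,
    p_down_without: float = 0.14,
    p_up_with: float = 0.005,
    p_up_without: float = 0.05,
) -> pd.DataFrame:
    """Simulate a differential-expression call table for a CMD1-KO contrast.

    Genes carrying 5gmC are downregulated upon CMD1 depletion with
    probability ``p_down_with`` (and almost never upregulated); genes
    without 5gmC with probability ``p_down_without``.
    """
    rng = np.random.default_rng(seed)
    has_gmc = np.asarray(has_gmc, dtype=bool)
    u = rng.random(len(gene_ids))
    p_down = np.where(has_gmc, p_down_with, p_down_without)
    p_up = np.where(has_gmc, p_up_with, p_up_without)
    status = np.where(u < p_down, "down", np.where(u < p_down + p_up, "up", "ns"))
    return pd.DataFrame({"gene_id": gene_ids, "status": status})
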