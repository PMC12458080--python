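"""Cytosine context classification and genomic-landscape annotation.

Places modified-cytosine sites into the frameworks used to describe the
5mC/5gmC landscape: CG/CHG/CHH context, functional region (promoter, exon,
intron, downstream, distal intergenic), distance to the nearest TSS,
transposable-element zones (inside / 1-kb flank / outside) and histone-mark
intervals, plus k-mer context enrichment around sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import GeneModel, GenomeRef, IntervalSet

__all__ = [
    "AnnotationConfig",
    "FEATURE_CATEGORIES",
    "classify_context",
    "enumerate_cytosines",
    "annotate_feature",
    "annotate_features",
    "tss_distance_profile",
    "te_overlap",
    "te_zone_lengths",
    "mark_overlap",
    "kmer_context_freq",
]

FEATURE_CATEGORIES = ("promoter", "exon", "intron", "downstream", "distal_intergenic")


@dataclass
class AnnotationConfig:
    """Genomic distance constants used throughout the landscape analyses.

    Defaults: 2000-bp promoter upstream of the TSS, 300-bp downstream window
    past the TES, +/-3000-bp TSS-distance window, 1000-bp TE flank, and
    feature precedence promoter > exon > intron > downstream > distal.
    """

    promoter_bp: int = 2000
    downstream_bp: int = 300
    tss_window_bp: int = 3000
    tss_bin_bp: int = 100
    te_flank_bp: int = 1000
    precedence: tuple[str, ...] = FEATURE_CATEGORIES

    def __post_init__(self) -> None:
        for name in ("promoter_bp", "downstream_bp", "tss_window_bp", "tss_bin_bp", "te_flank_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if sorted(self.precedence) != sorted(FEATURE_CATEGORIES):
            raise ValueError("precedence must be a total order over the feature categories")


# ---------------------------------------------------------------------------
# Context classification

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_A, _C, _G, _T, _N = 0, 1, 2, 3, 4

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_TRI_LOOKUP = np.array(
    ["".join("ACGTN"[c] for c in (i // 25, (i // 5) % 5, i % 5)) for i in range(125)]
)


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _context_from_codes(n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Context from the codes of the two bases 3' of the C on its strand."""
    ctx = np.full(n1.shape, "AMBIG", dtype=object)
    is_h1 = (n1 == _A) | (n1 == _C) | (n1 == _T)
    is_h2 = (n2 == _A) | (n2 == _C) | (n2 == _T)
    ctx[n1 == _G] = "CG"
    ctx[is_h1 & (n2 == _G)] = "CHG"
    ctx[is_h1 & is_h2] = "CHH"
    return ctx


def classify_context(genome: GenomeRef | str, chrom: str | None, pos: int, strand: str):
    """Classify one cytosine: returns ``(context, trinucleotide)``.

    ``pos`` is the 0-based offset of the C on the plus strand of the
    sequence (for minus-strand cytosines this is the position of the G read
    on the plus strand).  Context comes from the two bases 3' of the C on
    its own strand: CG if the next base is G, CHG if H then G, CHH if H
    then H, AMBIG when an N or the chromosome end intervenes.
    """
    seq = genome if isinstance(genome, str) else genome[chrom]
    code = _encode(seq)
    n = len(code)
    if not 0 <= pos < n:
        raise IndexError(f"position {pos} outside sequence of length {n}")
    if strand == "+":
        if code[pos] != _C:
            raise ValueError(f"base at +{pos} is {seq[pos]!r}, not C")
        n1 = code[pos + 1] if pos + 1 < n else _N
        n2 = code[pos + 2] if pos + 2 < n else _N
        tri_codes = [code[pos], n1, n2]
    elif strand == "-":
        if code[pos] != _G:
            raise ValueError(f"base at +{pos} is {seq[pos]!r}, not C on the minus strand")
        n1 = _COMP[code[pos - 1]] if pos - 1 >= 0 else _N
        n2 = _COMP[code[pos - 2]] if pos - 2 >= 0 else _N
        tri_codes = [_C, n1, n2]
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    ctx = _context_from_codes(np.array([n1]), np.array([n2]))[0]
    tri = _TRI_LOOKUP[tri_codes[0] * 25 + tri_codes[1] * 5 + tri_codes[2]]
    return ctx, tri


def enumerate_cytosines(genome: GenomeRef) -> pd.DataFrame:
    """All cytosines of a genome, both strands, with context and trinucleotide.

    Positions are 1-based plus-strand reference coordinates (the CX-report
    convention for both strands).  Vectorized; suitable for megabase genomes.
    """
    frames = []
    for chrom, seq in genome.sequences.items():
        code = _encode(seq)
        padded = np.concatenate([[_N, _N], code, [_N, _N]])
        for strand, base in (("+", _C), ("-", _G)):
            idx = np.flatnonzero(code == base)
            if idx.size == 0:
                continue
            if strand == "+":
                n1 = padded[idx + 3]
                n2 = padded[idx + 4]
                c0 = np.full(idx.shape, _C, dtype=np.uint8)
            else:
                n1 = _COMP[padded[idx + 1]]
                n2 = _COMP[padded[idx]]
                c0 = np.full(idx.shape, _C, dtype=np.uint8)
            ctx = _context_from_codes(n1, n2)
            tri = _TRI_LOOKUP[c0.astype(int) * 25 + n1.astype(int) * 5 + n2.astype(int)]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx + 1,
                        "strand": strand,
                        "context": ctx.astype(str),
                        "trinucleotide": tri,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Functional-region annotation


def _category_intervals(genes: list[GeneModel], config: AnnotationConfig):
    """Per-category IntervalSet over all genes (orientation-aware windows)."""
    ivs: dict[str, dict[str, list[tuple[int, int]]]] = {
        c: {} for c in ("promoter", "exon", "intron", "downstream")
    }

    def add(cat: str, chrom: str, s: int, e: int) -> None:
        if e > s:
            ivs[cat].setdefault(chrom, []).append((max(s, 0), e))

    for g in genes:
        if g.strand == "+":
            add("promoter", g.chrom, g.start - config.promoter_bp, g.start)
            add("downstream", g.chrom, g.end, g.end + config.downstream_bp)
        else:
            add("promoter", g.chrom, g.end, g.end + config.promoter_bp)
            add("downstream", g.chrom, g.start - config.downstream_bp, g.start)
        for s, e in g.exons:
            add("exon", g.chrom, s, e)
        for s, e in g.introns:
            add("intron", g.chrom, s, e)
    return {cat: IntervalSet(cat, d) for cat, d in ivs.items() if d}


def annotate_features(
    sites: pd.DataFrame, genes: list[GeneModel], config: AnnotationConfig | None = None
) -> pd.Series:
    """Assign each site exactly one feature category by precedence.

    Promoter is the ``promoter_bp`` window upstream of the TSS in
    transcription orientation; downstream the ``downstream_bp`` window past
    the TES.  Sites matching nothing are distal intergenic.
    """
    config = config or AnnotationConfig()
    cats = _category_intervals(genes, config)
    out = np.full(len(sites), "distal_intergenic", dtype=object)
    unassigned = np.ones(len(sites), dtype=bool)
    pos0 = sites["pos"].to_numpy() - 1
    chroms = sites["chrom"].to_numpy()
    for cat in config.precedence:
        if cat == "distal_intergenic" or cat not in cats:
            continue
        hit = np.zeros(len(sites), dtype=bool)
        for chrom in np.unique(chroms):
            m = chroms == chrom
            hit[m] = cats[cat].contains_points(chrom, pos0[m])
        take = hit & unassigned
        out[take] = cat
        unassigned &= ~take
    return pd.Series(out, index=sites.index, name="feature")


def annotate_feature(
    chrom: str, pos: int, genes: list[GeneModel], config: AnnotationConfig | None = None
) -> str:
    """Feature category of a single site (``pos`` 1-based)."""
    df = pd.DataFrame({"chrom": [chrom], "pos": [pos]})
    return annotate_features(df, genes, config).iloc[0]


# ---------------------------------------------------------------------------
# TSS distance profile


@dataclass
class TssProfile:
    table: pd.DataFrame
    within_window_fraction: float
    n_sites: int

    @property
    def defined(self) -> bool:
        return self.n_sites > 0


def tss_distance_profile(
    sites: pd.DataFrame, genes: list[GeneModel], config: AnnotationConfig | None = None
) -> TssProfile:
    """Signed distance of each site to its nearest TSS, binned.

    Distances are orientation-aware (positive downstream of the TSS in the
    gene's direction).  Fractions are over all sites; the fraction within
    the +/-window is the headline scalar.  Raises if no genes are given.
    """
    config = config or AnnotationConfig()
    if not genes:
        raise ValueError("TSS distance profile undefined without gene models")
    w, bw = config.tss_window_bp, config.tss_bin_bp
    edges = np.arange(-w, w + bw, bw)
    if sites.empty:
        table = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": 0, "fraction": np.nan})
        return TssProfile(table, float("nan"), 0)

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, 1 if g.strand == "+" else -1))
    dist = np.full(len(sites), np.iinfo(np.int64).max, dtype=np.int64)
    pos0 = sites["pos"].to_numpy() - 1
    chroms = sites["chrom"].to_numpy()
    for chrom, tss_list in by_chrom.items():
        m = chroms == chrom
        if not m.any():
            continue
        tss_list.sort()
        tss = np.array([t for t, _ in tss_list])
        sign = np.array([s for _, s in tss_list])
        p = pos0[m]
        right = np.searchsorted(tss, p)
        left = np.clip(right - 1, 0, len(tss) - 1)
        right = np.clip(right, 0, len(tss) - 1)
        d_left = np.abs(p - tss[left])
        d_right = np.abs(p - tss[right])
        use_left = d_left <= d_right
        nearest = np.where(use_left, left, right)
        dist[m] = (p - tss[nearest]) * sign[nearest]
    within = np.abs(dist) <= w
    counts, _ = np.histogram(dist[within], bins=edges)
    n = len(sites)
    table = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts, "fraction": counts / n}
    )
    return TssProfile(table, float(within.mean()), n)


# ---------------------------------------------------------------------------
# Transposable-element zones


def _te_zone(sites: pd.DataFrame, te: IntervalSet, flank_bp: int) -> np.ndarray:
    zones = np.full(len(sites), "outside", dtype=object)
    merged = te.merged()
    pos0 = sites["pos"].to_numpy() - 1
    chroms = sites["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        ivs = merged.intervals.get(chrom, [])
        m = chroms == chrom
        if not ivs:
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        p = pos0[m]
        idx = np.searchsorted(starts, p, side="right") - 1
        prev_end = np.where(idx >= 0, ends[np.clip(idx, 0, None)], -np.inf)
        inside = (idx >= 0) & (p < prev_end)
        nxt = np.clip(idx + 1, 0, len(starts) - 1)
        dist_next = np.where(idx + 1 < len(starts), starts[nxt] - p, np.inf)
        dist_prev = np.where(idx >= 0, p - (prev_end - 1), np.inf)
        flank = ~inside & ((dist_next <= flank_bp) | (dist_prev <= flank_bp))
        z = np.full(p.shape, "outside", dtype=object)
        z[flank] = "flank"
        z[inside] = "inside"
        zones[m] = z
    return zones


def te_overlap(
    sites: pd.DataFrame, te: IntervalSet, config: AnnotationConfig | None = None
) -> pd.DataFrame:
    """Zone each site relative to (merged) TEs: inside, <=flank bp, outside.

    Returns one row per zone with the site fraction and the mean and median
    modification ratio in that zone (NaN where the zone is empty or the
    input has no ``ratio`` column).
    """
    config = config or AnnotationConfig()
    zones = _te_zone(sites, te, config.te_flank_bp)
    rows = []
    n = len(sites)
    ratio = sites["ratio"].to_numpy() if "ratio" in sites.columns else None
    for zone in ("inside", "flank", "outside"):
        m = zones == zone
        cnt = int(m.sum())
        mean = med = np.nan
        if ratio is not None and cnt:
            mean = float(np.nanmean(ratio[m]))
            med = float(np.nanmedian(ratio[m]))
        rows.append((zone, cnt, cnt / n if n else np.nan, mean, med))
    return pd.DataFrame(rows, columns=["zone", "n_sites", "fraction", "mean_ratio", "median_ratio"])


def te_zone_lengths(te: IntervalSet, chrom_lengths: dict[str, int], flank_bp: int = 1000) -> dict[str, int]:
    """Base-pair extent of inside/flank/outside zones (merged TEs)."""
    merged = te.merged()
    out = {"inside": 0, "flank": 0, "outside": 0}
    for chrom, length in chrom_lengths.items():
        ivs = merged.intervals.get(chrom, [])
        inside = sum(min(e, length) - max(s, 0) for s, e in ivs)
        flank_iv = IntervalSet(
            "flank",
            {chrom: [(max(s - flank_bp, 0), min(e + flank_bp, length)) for s, e in ivs]}
            if ivs
            else {},
        ).merged()
        flank_total = sum(e - s for s, e in flank_iv.intervals.get(chrom, []))
        flank = flank_total - inside
        out["inside"] += inside
        out["flank"] += flank
        out["outside"] += length - inside - flank
    return out


# ---------------------------------------------------------------------------
# Histone-mark overlap


def mark_overlap(sites: pd.DataFrame, marks: dict[str, IntervalSet]) -> pd.DataFrame:
    """Per histone mark: fraction and count of sites inside marked regions,
    with mean/median modification ratio inside versus outside."""
    rows = []
    n = len(sites)
    pos0 = sites["pos"].to_numpy() - 1
    chroms = sites["chrom"].to_numpy()
    ratio = sites["ratio"].to_numpy() if "ratio" in sites.columns else None
    for name, ivset in marks.items():
        inside = np.zeros(n, dtype=bool)
        for chrom in np.unique(chroms):
            m = chroms == chrom
            inside[m] = ivset.contains_points(chrom, pos0[m])
        cnt = int(inside.sum())
        stats_row = [np.nan] * 4
        if ratio is not None:
            if cnt:
                stats_row[0] = float(np.nanmean(ratio[inside]))
                stats_row[1] = float(np.nanmedian(ratio[inside]))
            if n - cnt:
                stats_row[2] = float(np.nanmean(ratio[~inside]))
                stats_row[3] = float(np.nanmedian(ratio[~inside]))
        rows.append((name, cnt, cnt / n if n else np.nan, *stats_row))
    return pd.DataFrame(
        rows,
        columns=[
            "mark",
            "n_inside",
            "fraction_inside",
            "mean_ratio_inside",
            "median_ratio_inside",
            "mean_ratio_outside",
            "median_ratio_outside",
        ],
    )


# ---------------------------------------------------------------------------
# k-mer context enrichment


def _genome_kmer_background(genome: GenomeRef, k: int) -> np.ndarray:
    """Counts of C-centred k-mers over both strands of the genome."""
    h = k // 2
    counts = np.zeros(4**k, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1)
    for seq in genome.sequences.values():
        code = _encode(seq).astype(np.int64)
        if len(code) < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(code, k)
        valid = ~(win == _N).any(axis=1)
        for center_base, flip in ((_C, False), (_G, True)):
            sel = valid & (win[:, h] == center_base)
            if not sel.any():
                continue
            w = win[sel]
            if flip:
                w = (3 - w)[:, ::-1]
            codes = w @ weights
            counts += np.bincount(codes, minlength=4**k)
    return counts


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_context_freq(
    sites: pd.DataFrame, genome: GenomeRef, k: int = 5, fdr: float = 0.05
) -> pd.DataFrame:
    """k-mer frequencies around sites vs the genome-wide C-centred background.

    Windows of width ``k`` are centred on each site's C, read on the site's
    strand.  Enrichment per observed k-mer is an exact one-sided binomial
    test against the background frequency, Benjamini-Hochberg adjusted.
    Windows running off the chromosome or containing N are skipped (the
    skipped count is stored in ``df.attrs['n_skipped']``).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd so the window centres on the C")
    h = k // 2
    bg = _genome_kmer_background(genome, k)
    bg_total = bg.sum()
    obs: dict[int, int] = {}
    skipped = 0
    weights = 4 ** np.arange(k - 1, -1, -1)
    for row in sites.itertuples(index=False):
        seq = genome[row.chrom]
        p0 = int(row.pos) - 1
        if p0 - h < 0 or p0 + h >= len(seq):
            skipped += 1
            continue
        code = _encode(seq[p0 - h : p0 + h + 1]).astype(np.int64)
        if (code == _N).any():
            skipped += 1
            continue
        if row.strand == "-":
            code = (3 - code)[::-1]
        key = int(code @ weights)
        obs[key] = obs.get(key, 0) + 1
    n_valid = sum(obs.values())
    rows = []
    for key, cnt in sorted(obs.items()):
        p_bg = bg[key] / bg_total if bg_total else np.nan
        expected = n_valid * p_bg
        pval = float(stats.binom.sf(cnt - 1, n_valid, p_bg)) if p_bg > 0 else 0.0
        rows.append((_decode_kmer(key, k), cnt, expected, p_bg, pval))
    df = pd.DataFrame(rows, columns=["kmer", "n_sites", "expected", "background_freq", "p_value"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["enriched"] = (df["q_value"] < fdr) & (df["n_sites"] > df["expected"])
    else:
        df["q_value"] = []
        df["enriched"] = []
    df.attrs["n_skipped"] = skipped
    df.attrs["n_valid"] = n_valid
    return df
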