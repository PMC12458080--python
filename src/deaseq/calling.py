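"""Confident 5gmC site calling and WGBS deconvolution of 5mC.

Sites are retained when the count of unconverted cytosines strictly exceeds
the count bound and the modification ratio strictly exceeds the ratio bound
(defaults: > 10 and > 17%).  Background is removed by excluding positions
also called in a methyltransferase-knockout sample.  Thresholds can be
selected by gradient testing: evaluating a grid of (count, ratio) cut-offs
for cross-method overlap and resulting abundance.  Because plain bisulfite
leaves both 5mC and 5gmC as C, confident 5mC is obtained by subtracting the
5gmC ratio from the WGBS ratio per position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CallThresholds",
    "GradientGridResult",
    "call_gmc_sites",
    "subtract_ko",
    "retained",
    "gradient_select",
    "abundance_ppm",
    "deconvolve_mc",
    "call_mc_sites",
]

SITE_KEY = ["chrom", "pos", "strand"]


@dataclass(frozen=True)
class CallThresholds:
    """Hard thresholds for confident site calling (both bounds strict)."""

    min_unconverted_count: int = 10
    min_ratio: float = 0.17
    min_depth: int = 1

    def __post_init__(self) -> None:
        if self.min_unconverted_count < 0:
            raise ValueError("count bound must be a non-negative integer")
        if not 0.0 <= self.min_ratio <= 1.0:
            raise ValueError("ratio bound must lie in [0, 1]")


def call_gmc_sites(records: pd.DataFrame, thresholds: CallThresholds | None = None) -> pd.DataFrame:
    """Retain records with n_unconverted > count bound AND ratio > ratio bound.

    Both inequalities are strict.  Zero-depth records are skipped and
    counted in ``result.attrs['n_zero_depth']``, never treated as errors.
    The returned site table carries ``passed_thresholds`` / ``removed_by_ko``
    provenance flags (the latter all False until KO subtraction).
    """
    t = thresholds or CallThresholds()
    rec = records
    n_zero = int((rec["depth"] == 0).sum())
    evaluable = rec[rec["depth"] >= max(t.min_depth, 1)]
    mask = (evaluable["n_unconverted"] > t.min_unconverted_count) & (
        evaluable["ratio"] > t.min_ratio
    )
    sites = evaluable[mask].copy()
    sites["passed_thresholds"] = True
    sites["removed_by_ko"] = False
    sites = sites.sort_values(SITE_KEY, kind="stable").reset_index(drop=True)
    sites.attrs["n_zero_depth"] = n_zero
    return sites


def subtract_ko(
    candidates: pd.DataFrame,
    ko_records: pd.DataFrame | None,
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    """Flag candidate sites also called in the knockout sample.

    The same thresholds are applied to the KO records; any candidate whose
    (chrom, pos, strand) is called there is flagged ``removed_by_ko`` —
    flagged, not dropped, so the audit table stays complete.  Use
    :func:`retained` for the surviving set.  A missing KO sample passes
    candidates through with a prominent warning.
    """
    out = candidates.copy()
    if ko_records is None:
        warnings.warn(
            "no knockout control sample given: background subtraction skipped, "
            "5gmC calls may contain non-conversion noise",
            stacklevel=2,
        )
        return out
    ko_sites = call_gmc_sites(ko_records, thresholds)
    if ko_sites.empty:
        return out
    key = pd.MultiIndex.from_frame(out[SITE_KEY])
    ko_key = pd.MultiIndex.from_frame(ko_sites[SITE_KEY])
    out["removed_by_ko"] = key.isin(ko_key)
    return out


def retained(sites: pd.DataFrame) -> pd.DataFrame:
    """Sites surviving all filters (thresholds passed, not KO-flagged)."""
    if "removed_by_ko" in sites.columns:
        return sites[~sites["removed_by_ko"]].reset_index(drop=True)
    return sites.reset_index(drop=True)


def abundance_ppm(called_sites: pd.DataFrame, all_records: pd.DataFrame) -> float:
    """Mass-based 5gmC abundance in parts per million of total cytosines.

    ppm = 1e6 * (sum of unconverted counts over called sites) /
    (sum of depth over all cytosine records) — the sequencing analogue of a
    mass-spectrometry mole fraction.
    """
    total_depth = int(all_records["depth"].sum())
    if total_depth == 0:
        raise ValueError("abundance undefined: zero total cytosine depth")
    mass = int(called_sites["n_unconverted"].sum()) if len(called_sites) else 0
    return 1e6 * mass / total_depth


def abundance_ppm_sites(called_sites: pd.DataFrame, all_records: pd.DataFrame) -> float:
    """Site-count abundance variant (called sites per million covered cytosines)."""
    n_covered = int((all_records["depth"] > 0).sum())
    if n_covered == 0:
        raise ValueError("abundance undefined: no covered cytosines")
    return 1e6 * len(called_sites) / n_covered


@dataclass
class GradientGridResult:
    """Full audit of a gradient threshold search plus the selected point."""

    grid: pd.DataFrame
    selected: CallThresholds
    in_window: bool
    expected_ppm: float
    ppm_window: tuple[float, float] = field(default=(0.5, 2.0))


def gradient_select(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    grid: list[tuple[int, float]],
    expected_ppm: float,
    ppm_window: tuple[float, float] = (0.5, 2.0),
) -> GradientGridResult:
    """Gradient testing of (count, ratio) cut-offs over two methods.

    Every grid point is evaluated on both samples (same specimen, different
    chemistries): called-site counts, abundance in ppm, exact-position
    overlap and Jaccard.  The selected point maximizes Jaccard among points
    whose mean abundance lies within ``ppm_window`` (multiplicative) of
    ``expected_ppm``; if no point qualifies, the best-overlap point overall
    is returned with ``in_window=False`` and a warning.
    """
    if not grid:
        raise ValueError("empty threshold grid")
    rows = []
    for count, ratio in grid:
        t = CallThresholds(count, ratio)
        sa = call_gmc_sites(records_a, t)
        sb = call_gmc_sites(records_b, t)
        ka = pd.MultiIndex.from_frame(sa[SITE_KEY])
        kb = pd.MultiIndex.from_frame(sb[SITE_KEY])
        n_overlap = int(ka.isin(kb).sum())
        union = len(ka) + len(kb) - n_overlap
        jaccard = n_overlap / union if union else 0.0
        ppm_a = abundance_ppm(sa, records_a)
        ppm_b = abundance_ppm(sb, records_b)
        rows.append((count, ratio, len(sa), len(sb), n_overlap, jaccard, ppm_a, ppm_b))
    df = pd.DataFrame(
        rows,
        columns=[
            "min_count", "min_ratio", "n_sites_a", "n_sites_b",
            "n_overlap", "jaccard", "ppm_a", "ppm_b",
        ],
    )
    df["ppm_mean"] = (df["ppm_a"] + df["ppm_b"]) / 2
    lo, hi = expected_ppm * ppm_window[0], expected_ppm * ppm_window[1]
    ok = (df["ppm_mean"] >= lo) & (df["ppm_mean"] <= hi)
    if len(grid) == 1:
        best = 0
        in_window = bool(ok.iloc[0])
    elif ok.any():
        best = int(df.loc[ok, "jaccard"].idxmax())
        in_window = True
    else:
        warnings.warn(
            f"no grid point yields abundance within [{lo:.3g}, {hi:.3g}] ppm; "
            "returning the best-overlap point out of window"
        )
        best = int(df["jaccard"].idxmax())
        in_window = False
    sel = CallThresholds(int(df.loc[best, "min_count"]), float(df.loc[best, "min_ratio"]))
    df["selected"] = df.index == best
    return GradientGridResult(df, sel, in_window, expected_ppm, ppm_window)


# ---------------------------------------------------------------------------
# WGBS deconvolution


def deconvolve_mc(
    wgbs_records: pd.DataFrame,
    gmc_sites: pd.DataFrame,
    min_depth: int = 1,
) -> pd.DataFrame:
    """Per-position 5mC ratio as WGBS ratio minus confident 5gmC ratio.

    WGBS cannot distinguish 5mC from 5gmC, so at every WGBS-covered position
    ``mc_ratio = clamp(wgbs_ratio - gmc_ratio, 0, 1)``, where ``gmc_ratio``
    is 0 wherever no confident 5gmC site was called.  Positions below
    ``min_depth`` are excluded.  5gmC sites absent from WGBS coverage are
    emitted with ``wgbs_missing=True`` (ratios NaN).  Negative differences
    are clamped to 0; the clamped mass is tallied in
    ``result.attrs['negative_mass']`` as a residual-noise estimate.
    """
    w = wgbs_records[wgbs_records["depth"] >= min_depth]
    cols = ["chrom", "pos", "strand"]
    base = w[cols + ["context", "depth"]].copy()
    base["wgbs_ratio"] = w["ratio"].to_numpy()
    g = gmc_sites[cols + ["ratio"]].rename(columns={"ratio": "gmc_ratio"})
    out = base.merge(g, on=cols, how="left")
    out["gmc_ratio"] = out["gmc_ratio"].fillna(0.0)
    out["wgbs_missing"] = False

    missing_mask = ~pd.MultiIndex.from_frame(g[cols]).isin(pd.MultiIndex.from_frame(base[cols]))
    if missing_mask.any():
        miss = gmc_sites.loc[g.index[missing_mask]]
        add = miss[cols + ["context"]].copy()
        add["depth"] = 0
        add["wgbs_ratio"] = np.nan
        add["gmc_ratio"] = miss["ratio"].to_numpy()
        add["wgbs_missing"] = True
        out = pd.concat([out, add], ignore_index=True)

    diff = out["wgbs_ratio"] - out["gmc_ratio"]
    out["mc_ratio"] = np.clip(diff, 0.0, 1.0)
    out = out.sort_values(cols, kind="stable").reset_index(drop=True)
    out.attrs["negative_mass"] = float(-diff[diff < 0].sum()) if len(out) else 0.0
    return out


def call_mc_sites(
    wgbs_records: pd.DataFrame,
    gmc_sites: pd.DataFrame,
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    """Confident 5mC sites from deconvolved WGBS (the BS-minus-5gmC track).

    Applies the same hard thresholds to the deconvolved signal: the
    5mC-attributable unconverted count (depth * mc_ratio) must strictly
    exceed the count bound and mc_ratio the ratio bound.
    """
    t = thresholds or CallThresholds()
    dec = deconvolve_mc(wgbs_records, gmc_sites, min_depth=max(t.min_depth, 1))
    dec = dec[~dec["wgbs_missing"]]
    mc_count = dec["depth"].to_numpy() * dec["mc_ratio"].to_numpy()
    mask = (mc_count > t.min_unconverted_count) & (dec["mc_ratio"] > t.min_ratio)
    sites = dec[mask].copy()
    sites["ratio"] = sites["mc_ratio"]
    return sites.reset_index(drop=True)
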