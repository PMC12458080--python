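"""Conversion chemistry profiles and spike-in conversion-rate estimation.

Three chemistries are modelled by their probability of reading T after
treatment and PCR, per true cytosine state and context:

* ``DEA``      — a DNA deaminase converts C and 5mC to U/T with a small
  residual non-conversion (~0.2%), uniform across contexts; 5gmC resists.
* ``TET-BS``   — TET oxidation then bisulfite; ~3% of 5mC escapes conversion,
  with context-dependent variation and locus-level heterogeneity; 5gmC
  resists both steps.
* ``WGBS``     — plain bisulfite; both 5mC and 5gmC are fully protected
  (P(T | 5mC) = P(T | 5gmC) = 0 by definition), unmodified C converts.

Spike-ins of known state (unmodified lambda-like DNA; a fully-5mC PCR
amplicon) calibrate the realized conversion rate per chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "STATES",
    "CONTEXTS",
    "ChemistryProfile",
    "dea_profile",
    "wgbs_profile",
    "tetbs_profile",
    "estimate_conversion",
    "compare_profiles",
]

STATES = ("C", "5mC", "5gmC")
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class ChemistryProfile:
    """Per-(true state, context) probability of reading T after conversion.

    ``p_read_t[(state, context)]`` must cover all three states and the three
    unambiguous contexts.  ``escape_dispersion`` optionally declares
    locus-level heterogeneity of the 5mC escape: when set, the per-site
    probability of a 5mC molecule *escaping* conversion (reading C) is drawn
    from a Beta distribution with this alpha and the context mean implied by
    ``p_read_t``, instead of being the same at every site.
    """

    name: str
    p_read_t: dict[tuple[str, str], float] = field(default_factory=dict)
    escape_dispersion: float | None = None

    def __post_init__(self) -> None:
        for state in STATES:
            for ctx in CONTEXTS:
                if (state, ctx) not in self.p_read_t:
                    raise ValueError(f"{self.name}: profile missing ({state}, {ctx})")
        for key, p in self.p_read_t.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: P(T | {key}) = {p} outside [0, 1]")
        if self.name == "WGBS":
            for state in ("5mC", "5gmC"):
                for ctx in CONTEXTS:
                    if self.p_read_t[(state, ctx)] != 0.0:
                        raise ValueError("WGBS must fully protect 5mC and 5gmC")

    def p_t(self, state: str, context: str) -> float:
        return self.p_read_t[(state, context)]

    def p_read_c(self, state: str, context: str) -> float:
        return 1.0 - self.p_read_t[(state, context)]


def dea_profile(non_conversion: float = 0.002, gmc_loss: float = 0.0) -> ChemistryProfile:
    """Deaminase chemistry: uniform residual non-conversion for C and 5mC.

    ``gmc_loss`` is the probability that a true 5gmC is nevertheless
    deaminated (read T); mass spectrometry shows essentially none, so the
    default is 0.
    """
    p = {}
    for ctx in CONTEXTS:
        p[("C", ctx)] = 1.0 - non_conversion
        p[("5mC", ctx)] = 1.0 - non_conversion
        p[("5gmC", ctx)] = gmc_loss
    return ChemistryProfile("DEA", p)


def wgbs_profile(non_conversion: float = 0.002) -> ChemistryProfile:
    """Bisulfite chemistry: 5mC and 5gmC both read as C."""
    p = {}
    for ctx in CONTEXTS:
        p[("C", ctx)] = 1.0 - non_conversion
        p[("5mC", ctx)] = 0.0
        p[("5gmC", ctx)] = 0.0
    return ChemistryProfile("WGBS", p)


#: Context multipliers for the TET-BS 5mC escape around its 3% mean.
TETBS_CONTEXT_MULTIPLIER = {"CG": 1.0, "CHG": 1.5, "CHH": 0.75}


def tetbs_profile(
    c_non_conversion: float = 0.002,
    mc_escape_mean: float = 0.03,
    context_multiplier: dict[str, float] | None = None,
    escape_dispersion: float | None = 0.25,
    gmc_loss: float = 0.0,
) -> ChemistryProfile:
    """TET-oxidation + bisulfite chemistry with context-dependent 5mC escape.

    The two-step conversion leaves ~3% of 5mC unchanged on average; realized
    escape varies between loci (secondary structure, oxidation efficiency),
    which is what lets occasional sites pass a hard ratio filter and inflate
    false 5gmC calls at methylated CpGs.  ``escape_dispersion`` is the Beta
    alpha of that locus-level distribution (None = homogeneous).
    """
    mult = TETBS_CONTEXT_MULTIPLIER if context_multiplier is None else context_multiplier
    p = {}
    for ctx in CONTEXTS:
        p[("C", ctx)] = 1.0 - c_non_conversion
        p[("5mC", ctx)] = 1.0 - mc_escape_mean * mult[ctx]
        p[("5gmC", ctx)] = gmc_loss
    return ChemistryProfile("TET-BS", p, escape_dispersion=escape_dispersion)


# ---------------------------------------------------------------------------
# Spike-in conversion-rate estimation

REPORT_COLUMNS = [
    "sample",
    "chemistry",
    "spikein_class",
    "context",
    "n_converted",
    "n_unconverted",
    "rate",
    "ci_low",
    "ci_high",
    "no_data",
]


def estimate_conversion(
    records: pd.DataFrame,
    class_of_chrom: dict[str, str],
    sample: str = "sample",
    chemistry: str = "",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Estimate C-to-T conversion rates from spike-in aligned records.

    ``class_of_chrom`` maps spike-in chromosome names to a class label
    (``unmodified`` or ``fully-5mC``).  Strands are pooled.  Returns one row
    per (class, context) plus a pooled ``all`` context row, with
    conversion rate = converted / (converted + unconverted) and an exact
    Clopper-Pearson confidence interval.  Strata with zero total depth are
    flagged ``no_data`` (rate NaN), never reported as 0.
    """
    unmapped = set(records["chrom"]) - set(class_of_chrom)
    if unmapped:
        raise ValueError(f"records on chromosomes without a spike-in class: {sorted(unmapped)}")
    rec = records.copy()
    rec["spikein_class"] = rec["chrom"].map(class_of_chrom)

    rows = []
    for klass in sorted(set(class_of_chrom.values())):
        sub = rec[rec["spikein_class"] == klass]
        strata = [("all", sub)] + [
            (ctx, sub[sub["context"] == ctx]) for ctx in CONTEXTS
        ]
        for ctx, block in strata:
            n_conv = int(block["n_converted"].sum())
            n_unc = int(block["n_unconverted"].sum())
            total = n_conv + n_unc
            if total == 0:
                rows.append(
                    (sample, chemistry, klass, ctx, 0, 0, np.nan, np.nan, np.nan, True)
                )
                continue
            rate = n_conv / total
            lo, hi = proportion_confint(n_conv, total, alpha=alpha, method="beta")
            rows.append((sample, chemistry, klass, ctx, n_conv, n_unc, rate, lo, hi, False))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def non_conversion_rate(report: pd.DataFrame, spikein_class: str) -> float:
    """Pooled non-conversion rate (1 - conversion) for one spike-in class."""
    row = report[(report["spikein_class"] == spikein_class) & (report["context"] == "all")]
    if row.empty or bool(row["no_data"].iloc[0]):
        raise ValueError(f"no data for spike-in class {spikein_class!r}")
    return 1.0 - float(row["rate"].iloc[0])


def compare_profiles(
    report_a: pd.DataFrame,
    report_b: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare per-context conversion rates of two chemistries.

    Rows are aligned on (spike-in class, context); each row carries the rate
    difference and a two-proportion exact (Fisher) test.  ``flagged`` marks
    contexts where the rates differ significantly; ``higher`` names the
    chemistry with the greater conversion.  Strata missing data on either
    side are marked ``incomparable``.
    """
    key = ["spikein_class", "context"]
    a = report_a.set_index(key)
    b = report_b.set_index(key)
    if set(a.index) != set(b.index):
        raise ValueError("mismatched (class, context) strata between reports")
    rows = []
    for idx in a.index:
        ra, rb = a.loc[idx], b.loc[idx]
        klass, ctx = idx
        if bool(ra["no_data"]) or bool(rb["no_data"]):
            rows.append((klass, ctx, np.nan, np.nan, np.nan, False, None, True))
            continue
        table = [
            [int(ra["n_converted"]), int(ra["n_unconverted"])],
            [int(rb["n_converted"]), int(rb["n_unconverted"])],
        ]
        _, pval = stats.fisher_exact(table)
        diff = float(ra["rate"]) - float(rb["rate"])
        flagged = pval < alpha
        higher = None
        if flagged:
            higher = str(report_a["chemistry"].iloc[0]) if diff > 0 else str(
                report_b["chemistry"].iloc[0]
            )
        rows.append((klass, ctx, float(ra["rate"]), float(rb["rate"]), pval, flagged, higher, False))
    return pd.DataFrame(
        rows,
        columns=[
            "spikein_class",
            "context",
            "rate_a",
            "rate_b",
            "p_value",
            "flagged",
            "higher",
            "incomparable",
        ],
    )
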