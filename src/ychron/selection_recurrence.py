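"""Frequency-spectrum selection tests and mutation-recurrence summaries.

Purifying selection keeps damaging alleles rare: if nonsynonymous variants
flagged damaging by a predictor are under selection, singletons
(derived-allele count 1) should be overrepresented among them relative to
the data set as a whole. The test is a 2x2 chi-square with Yates'
continuity correction — damaging variants (singleton / not) against the
full data-set background — with Fisher's exact test available behind a
flag.

Recurrence summaries count sites needing more than one mutational event on
the tree and the fraction of those events at CpG dinucleotides, where
methylation-driven deamination elevates the substitution rate; a site is
CpG when its reference context reads CG on either strand.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import FormatError
from .phylogeny import SiteCompatibilityReport

__all__ = ["AnnotatedVariant", "read_annotated_variants", "yates_chi2",
           "singleton_enrichment", "EnrichmentReport", "recurrence_summary",
           "RecurrenceSummary", "compare_recurrence_rates", "is_cpg_context"]

CONSEQUENCES = ("synonymous", "nonsynonymous", "noncoding")


@dataclass(frozen=True)
class AnnotatedVariant:
    site_id: str
    consequence: str
    derived_count: int
    gene: str | None = None
    damaging: Mapping[str, bool] = None  # predictor name -> flag
    cpg: bool | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise FormatError(f"unknown consequence {self.consequence!r}")
        if self.derived_count < 0:
            raise FormatError("derived count must be >= 0")
        dmg = dict(self.damaging or {})
        if any(dmg.values()) and self.consequence != "nonsynonymous":
            raise FormatError("damaging flag on a non-nonsynonymous variant")
        object.__setattr__(self, "damaging", dmg)

    @property
    def singleton(self) -> bool:
        return self.derived_count == 1


def read_annotated_variants(path) -> list[AnnotatedVariant]:
    """TSV schema: site_id, gene, consequence, derived_count, then one
    boolean column per predictor (e.g. sift, polyphen2)."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    fixed = {"site_id", "gene", "consequence", "derived_count"}
    predictors = [c for c in df.columns if c not in fixed]
    out = []
    for _, row in df.iterrows():
        out.append(AnnotatedVariant(
            site_id=row["site_id"],
            gene=row.get("gene") or None,
            consequence=row["consequence"],
            derived_count=int(row["derived_count"]),
            damaging={p: bool(row[p]) for p in predictors}))
    return out


# ---------------------------------------------------------------------------
# Yates-corrected chi-square
# ---------------------------------------------------------------------------

def yates_chi2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """2x2 chi-square with the continuity correction,
    chi2 = sum (max(|O-E|-0.5, 0))^2 / E, p from the 1-df upper tail.

    The correction is floored at zero so tiny |O-E| cannot contribute.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero marginal")
    expected = np.outer(rows, cols) / t.sum()
    d = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    chi2 = float((d ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def plain_chi2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Uncorrected 2x2 chi-square (for cross-checks and the variant of the
    cross-study comparison computed without the continuity correction)."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table),
                                           correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Singleton enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentReport:
    predictor: str
    table: np.ndarray        # [[dmg singletons, dmg non-singletons],
                             #  [bg singletons, bg non-singletons]]
    statistic: float
    p_value: float
    direction: str           # "enriched" | "depleted" | "none"
    test: str


def singleton_enrichment(variants: Iterable[AnnotatedVariant],
                         predictor: str,
                         background: tuple[int, int],
                         test: str = "yates") -> EnrichmentReport:
    """Is the singleton proportion among predictor-damaging variants higher
    than the data-set-wide proportion?

    ``background`` is (singletons, total) for the whole data set; the
    comparison row of the 2x2 is that background unchanged.
    """
    singletons_bg, total_bg = background
    if not (0 <= singletons_bg <= total_bg):
        raise ValueError("inconsistent background (singletons > total)")
    dmg = [v for v in variants if v.damaging.get(predictor)]
    if not dmg:
        raise ValueError(f"no variant flagged damaging by {predictor!r}")
    a = sum(v.singleton for v in dmg)
    b = len(dmg) - a
    table = np.array([[a, b], [singletons_bg, total_bg - singletons_bg]])
    if test == "yates":
        chi2, p = yates_chi2(table)
    elif test == "fisher":
        chi2, p = stats.fisher_exact(table)
        chi2 = float(chi2)  # odds ratio stands in for the statistic
    else:
        raise ValueError("test must be 'yates' or 'fisher'")
    frac_dmg = a / len(dmg)
    frac_bg = singletons_bg / total_bg
    direction = ("enriched" if frac_dmg > frac_bg
                 else "depleted" if frac_dmg < frac_bg else "none")
    return EnrichmentReport(predictor=predictor, table=table,
                            statistic=float(chi2), p_value=float(p),
                            direction=direction, test=test)


# ---------------------------------------------------------------------------
# Recurrence
# ---------------------------------------------------------------------------

def is_cpg_context(context: str) -> bool:
    """A site is CpG when its reference trinucleotide (prev, site, next)
    contains the CG dinucleotide through the site on either strand:
    site C followed by G, or site G preceded by C."""
    if len(context) != 3:
        raise FormatError(f"need a trinucleotide context, got {context!r}")
    a, b, c = context.upper()
    return (b == "C" and c == "G") or (a == "C" and b == "G")


@dataclass
class RecurrenceSummary:
    n_sites: int
    n_recurrent: int
    total_events: int          # events at recurrent sites
    cpg_events: int | None = None

    @property
    def fraction_recurrent(self) -> float:
        return self.n_recurrent / self.n_sites if self.n_sites else 0.0

    @property
    def cpg_fraction(self) -> float | None:
        if self.cpg_events is None:
            return None
        return self.cpg_events / self.total_events if self.total_events \
            else 0.0


def recurrence_summary(report: SiteCompatibilityReport,
                       context: Mapping[str, str] | Mapping[str, bool]
                       | None = None) -> RecurrenceSummary:
    """Counts of recurrent sites, their events, and the CpG share of those
    events. ``context`` maps site id -> trinucleotide (or precomputed CpG
    flag); required only for the CpG breakdown and must then cover every
    recurrent site."""
    t = report.table
    rec = t[~t["compatible"]]
    total_events = int(rec["n_events"].sum())
    cpg_events = None
    if context is not None:
        cpg_events = 0
        for site_id, row in rec.iterrows():
            try:
                ctx = context[site_id]
            except KeyError:
                raise FormatError(
                    f"no context for recurrent site {site_id}") from None
            flag = ctx if isinstance(ctx, (bool, np.bool_)) \
                else is_cpg_context(ctx)
            if flag:
                cpg_events += int(row["n_events"])
    return RecurrenceSummary(n_sites=len(t), n_recurrent=len(rec),
                             total_events=total_events,
                             cpg_events=cpg_events)


def compare_recurrence_rates(a: tuple[int, int], b: tuple[int, int],
                             correction: bool = True
                             ) -> tuple[float, float, np.ndarray]:
    """Chi-square comparison of recurrent-site fractions between two
    studies; ``a`` and ``b`` are (recurrent, total) pairs."""
    (ra, ta), (rb, tb) = a, b
    if ta <= 0 or tb <= 0 or not (0 <= ra <= ta and 0 <= rb <= tb):
        raise ValueError("invalid (recurrent, total) pair")
    table = np.array([[ra, ta - ra], [rb, tb - rb]])
    chi2, p = yates_chi2(table) if correction else plain_chi2(table)
    return chi2, p, table
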