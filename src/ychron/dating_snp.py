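"""SNP-based TMRCA estimation with the rho statistic.

For a clade with n tips, rho is the mean number of mutations from a tip to
the clade's root node, computed over branches as

    rho = (1/n) * sum_b l_b * n_b

where l_b is the mutation count of branch b and n_b its number of
descendant tips within the clade. Its standard deviation (Saillard et al.'s
estimator, treating branch counts as independent Poisson draws) is

    sigma = sqrt( sum_b l_b * (n_b / n)^2 ).

TMRCA in years is rho times the years-per-mutation scaling 1/(mu * L);
with the default rate mu = 1.0e-9 mutations/bp/year over the
L = 3,724,156 bp target this is one mutation per 268.5 years. Uncertainty
in the published mutation rate is propagated by rescaling the point
estimate to the rate CI bounds (3.0e-10 - 2.5e-9), reported as a TMRCA
range; the sampling sigma is reported separately.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from math import sqrt

from .formats import MutationTree

__all__ = ["RateModel", "CladeEstimate", "rho_sigma", "tmrca_snp",
           "rescale_estimate", "round_ka"]

#: Per-locus single-step mutation rates per generation. The evolutionary
#: rate is a single calibrated mean; the pedigree per-locus values are
#: synthetic placeholders (the published source gives only the bracket
#: 2.797e-3 - 4.238e-3 for the subset means, which these satisfy).
EVOLUTIONARY_RATE = 6.9e-4
PEDIGREE_LOCUS_RATES: dict[str, float] = {
    "DYS19": 2.2e-3, "DYS389I": 2.5e-3, "DYS389II": 3.6e-3,
    "DYS390": 2.1e-3, "DYS391": 2.6e-3, "DYS392": 0.5e-3, "DYS393": 1.1e-3,
    "DYS437": 1.3e-3, "DYS438": 0.4e-3, "DYS439": 5.6e-3, "DYS448": 1.4e-3,
    "DYS456": 4.8e-3, "DYS458": 7.2e-3, "DYS635": 3.5e-3, "GATAH4": 2.8e-3,
    "DYS481": 5.0e-3, "DYS533": 4.1e-3, "DYS549": 4.3e-3, "DYS570": 12.4e-3,
    "DYS576": 13.5e-3, "DYS643": 1.6e-3,
}


def _default_str_rates() -> dict[str, dict[str, float]]:
    from .formats import STR_SUBSETS
    evo = {name: EVOLUTIONARY_RATE for name in STR_SUBSETS}
    ped = {name: sum(PEDIGREE_LOCUS_RATES[l] for l in loci) / len(loci)
           for name, loci in STR_SUBSETS.items()}
    return {"evolutionary": evo, "pedigree": ped}


@dataclass
class RateModel:
    """Mutation-rate constants for SNP and STR dating.

    snp_rate is per nucleotide per year; str_rates maps rate regime ->
    subset -> mean per-locus rate per generation. generation_time (years)
    applies only to STR dating: the SNP rate is already per year.
    """
    snp_rate: float = 1.0e-9
    snp_rate_ci: tuple[float, float] = (3.0e-10, 2.5e-9)
    target_length: int = 3_724_156
    generation_time: float = 30.0
    str_rates: dict[str, dict[str, float]] = field(
        default_factory=_default_str_rates)

    def __post_init__(self) -> None:
        lo, hi = self.snp_rate_ci
        if not (0 < lo <= self.snp_rate <= hi):
            raise ValueError("require 0 < mu_lo <= mu <= mu_hi")
        if self.target_length <= 0 or self.generation_time <= 0:
            raise ValueError("target length and generation time must be > 0")

    @property
    def years_per_mutation(self) -> float:
        return 1.0 / (self.snp_rate * self.target_length)

    def mean_str_rate(self, regime: str, subset: str) -> float:
        try:
            return self.str_rates[regime][subset]
        except KeyError:
            raise KeyError(
                f"no STR rate for regime={regime!r}, subset={subset!r}"
            ) from None


@dataclass
class CladeEstimate:
    clade_id: str
    n_tips: int
    rho: float
    sigma: float
    tmrca_years: float
    tmrca_range_years: tuple[float, float]  # from the mutation-rate CI
    method: str = "rho-snp"

    @property
    def tmrca_ka(self) -> float:
        return round_ka(self.tmrca_years / 1000.0)

    @property
    def tmrca_range_ka(self) -> tuple[float, float]:
        lo, hi = self.tmrca_range_years
        return round_ka(lo / 1000.0), round_ka(hi / 1000.0)


def round_ka(x: float) -> float:
    """Round to 0.1 ka, half away from zero (printed-table style)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"),
                                           rounding=ROUND_HALF_UP))


def rho_sigma(tree: MutationTree, clade: str | None = None
              ) -> tuple[float, float]:
    """rho and its Saillard standard deviation for a clade (default: root).

    Branch sums run over all branches strictly within the clade; mutations
    on the stem above the clade's root node do not count.
    """
    clade = tree.root if clade is None else clade
    if clade not in tree.nodes:
        raise KeyError(f"unknown node {clade!r}")
    n = sum(1 for _ in tree.tips(clade))
    if n == 0:
        raise ValueError(f"clade {clade!r} has no tips")
    # descendant-tip counts within the clade
    n_desc: dict[str, int] = {}
    for node in tree.postorder(clade):
        n_desc[node.id] = 1 if node.is_tip else sum(
            n_desc[c] for c in node.children)
    rho = 0.0
    var = 0.0
    for node in tree.postorder(clade):
        if node.id == clade:
            continue
        w = n_desc[node.id] / n
        rho += node.n_mut * w
        var += node.n_mut * w * w
    return rho, sqrt(var)


def tmrca_snp(rho: float, sigma: float, rates: RateModel,
              clade_id: str = "", n_tips: int = 0) -> CladeEstimate:
    """Scale rho to years and propagate the mutation-rate CI.

    The range is rho/(mu_hi*L) .. rho/(mu_lo*L): a faster rate means a
    younger clade.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    L = rates.target_length
    mu_lo, mu_hi = rates.snp_rate_ci
    point = rho / (rates.snp_rate * L)
    return CladeEstimate(
        clade_id=clade_id, n_tips=n_tips, rho=rho, sigma=sigma,
        tmrca_years=point,
        tmrca_range_years=(rho / (mu_hi * L), rho / (mu_lo * L)))


def date_clade(tree: MutationTree, clade: str, rates: RateModel
               ) -> CladeEstimate:
    """Convenience: rho_sigma + tmrca_snp for a named clade."""
    rho, sigma = rho_sigma(tree, clade)
    n = sum(1 for _ in tree.tips(clade))
    return tmrca_snp(rho, sigma, rates, clade_id=clade, n_tips=n)


def rescale_estimate(point_ka: float, from_rate: float,
                     to_rate: float) -> float:
    """Re-express a TMRCA computed at one rate under another (inverse-rate
    scaling, as the printed CI ranges are)."""
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("rates must be positive")
    return point_ka * from_rate / to_rate
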