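"""Branch-length heterogeneity testing.

Tips of a haploid tree accumulate mutations independently, so differences
in mean mutations-to-root between groups (tissue sources, haplogroups)
indicate rate heterogeneity or somatic artefacts. Two protocols:

* a one-way ANOVA across tissue sources;
* a subsampled pairwise Mann-Whitney protocol across haplogroups: groups
  larger than k are subsampled (without replacement) to k in each of R
  replicates to neutralize sample-size imbalance; per replicate every pair
  is tested and Bonferroni-corrected, and a pair is flagged "of interest"
  when more than half of its replicate p-values stay significant.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["mw_u_test", "anova_one_way", "subsampled_pairwise_test",
           "HeterogeneityResult", "mc_power"]


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mw_u_test(x: Sequence[float], y: Sequence[float],
              method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    method="auto" enumerates exactly when both samples have n <= 8 and the
    pooled data are tie-free, else uses the tie-corrected normal
    approximation with continuity correction. method="exact" forces a
    permutation-exact test (full enumeration where feasible) even with
    ties; method="asymptotic" forces the approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if method == "auto":
        scipy_method = ("exact" if x.size <= 8 and y.size <= 8
                        and not _has_ties(x, y) else "asymptotic")
    elif method == "exact":
        if _has_ties(x, y):
            scipy_method = stats.PermutationMethod(
                n_resamples=200_000, rng=0)
        else:
            scipy_method = "exact"
    elif method == "asymptotic":
        scipy_method = "asymptotic"
    else:
        raise ValueError("method must be auto|exact|asymptotic")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method=scipy_method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def anova_one_way(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA F test across >=2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    n_total = sum(a.size for a in arrays)
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if n_total <= len(arrays):
        raise ValueError("need total n > number of groups")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


@dataclass
class HeterogeneityResult:
    """Outcome of the subsampled Mann-Whitney protocol for one group pair."""
    pair: tuple[str, str]
    k: int
    replicates: int
    p_values: np.ndarray          # per-replicate uncorrected p-values
    bonferroni_m: int
    proportion_significant: float  # after Bonferroni, at level alpha

    @property
    def flagged(self) -> bool:
        return self.proportion_significant > 0.5


def subsampled_pairwise_test(
        counts: Sequence[float], labels: Sequence[str], k: int = 10,
        replicates: int = 100, alpha: float = 0.05,
        bonferroni_m: int | None = None, seed: int = 0,
        mw_method: str = "asymptotic") -> list[HeterogeneityResult]:
    """Pairwise group comparison of mutations-to-root with subsampling.

    Groups with more than ``k`` members are subsampled without replacement
    to ``k`` in each replicate; smaller groups enter whole. The Bonferroni
    divisor defaults to the number of pairs actually tested
    (overridable via ``bonferroni_m``). Deterministic under a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels)
    if counts.shape != labels.shape:
        raise ValueError("counts and labels must align")
    groups = {g: counts[labels == g] for g in np.unique(labels)}
    groups = {g: v for g, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("need >=2 labels with >=2 samples each")
    pairs = list(combinations(sorted(groups), 2))
    m = bonferroni_m if bonferroni_m is not None else len(pairs)
    rng = np.random.default_rng(seed)
    pvals = {pair: np.empty(replicates) for pair in pairs}
    for r in range(replicates):
        drawn = {
            g: (rng.choice(v, size=k, replace=False) if v.size > k else v)
            for g, v in groups.items()}
        for pair in pairs:
            _, p = mw_u_test(drawn[pair[0]], drawn[pair[1]],
                             method=mw_method)
            pvals[pair][r] = p
    out = []
    for pair in pairs:
        prop = float(np.mean(pvals[pair] * m < alpha))
        out.append(HeterogeneityResult(
            pair=pair, k=k, replicates=replicates, p_values=pvals[pair],
            bonferroni_m=m, proportion_significant=prop))
    return out


def mc_power(n1: int, n2: int, base_mean: float, shift: float,
             alpha: float = 0.05, replicates: int = 2000,
             seed: int = 0) -> float:
    """Monte-Carlo power of a Mann-Whitney test to detect a mean shift
    between two Poisson mutation-count samples."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(replicates):
        a = rng.poisson(base_mean, n1)
        b = rng.poisson(base_mean + shift, n2)
        _, p = mw_u_test(a, b, method="asymptotic")
        hits += p < alpha
    return hits / replicates
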