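import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ychron.formats import FormatError
from ychron.phylogeny import SiteCompatibilityReport
from ychron.selection_recurrence import (AnnotatedVariant,
                                         compare_recurrence_rates,
                                         is_cpg_context,
                                         recurrence_summary,
                                         singleton_enrichment, yates_chi2)

# whole-data-set background: 7,782 singletons among 13,261 SNPs
BACKGROUND = (7_782, 13_261)


def variants(n_damaging, n_damaging_singletons, predictor="sift"):
    out = []
    for i in range(n_damaging):
        out.append(AnnotatedVariant(
            site_id=f"v{i}", consequence="nonsynonymous",
            derived_count=1 if i < n_damaging_singletons else 2,
            damaging={predictor: True}))
    return out


class TestYatesChi2:
    def test_balanced_table_is_null(self):
        chi2, p = yates_chi2([[5, 5], [5, 5]])
        assert chi2 == 0.0 and p == 1.0

    def test_symmetry_under_row_and_column_swaps(self):
        t = [[16, 1], [7766, 5478]]
        base = yates_chi2(t)
        assert yates_chi2([t[1], t[0]]) == base
        assert yates_chi2([r[::-1] for r in t]) == base

    def test_matches_scipy_on_ordinary_tables(self):
        for t in ([[12, 7], [5, 22]], [[100, 40], [60, 90]]):
            chi2, p = yates_chi2(t)
            s_chi2, s_p, _, _ = stats.chi2_contingency(np.array(t),
                                                       correction=True)
            assert chi2 == pytest.approx(s_chi2)
            assert p == pytest.approx(s_p)

    def test_correction_floored_at_zero(self):
        # |O-E| < 0.5 everywhere: corrected statistic must be exactly 0
        chi2, p = yates_chi2([[3, 4], [4, 3]])
        assert chi2 == 0.0 and p == 1.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            yates_chi2([[0, 0], [5, 5]])


class TestSingletonEnrichment:
    def test_sift_like_counts_reproduce_published_p(self):
        r = singleton_enrichment(variants(17, 16), "sift", BACKGROUND)
        assert r.direction == "enriched"
        assert r.p_value == pytest.approx(0.0065, abs=5e-4)

    def test_polyphen_like_counts_marginally_nonsignificant(self):
        r = singleton_enrichment(variants(15, 13, "pp2"), "pp2", BACKGROUND)
        assert r.direction == "enriched"
        assert r.p_value == pytest.approx(0.0527, abs=5e-4)

    def test_background_fraction_gives_null(self):
        # damaging singleton fraction == background fraction (1/2 vs 1/2)
        r = singleton_enrichment(variants(8, 4), "sift", (50, 100))
        assert r.direction == "none"
        assert r.p_value > 0.5

    def test_fisher_variant_available(self):
        r = singleton_enrichment(variants(17, 16), "sift", BACKGROUND,
                                 test="fisher")
        assert r.test == "fisher" and r.p_value < 0.01

    def test_inconsistent_background_rejected(self):
        with pytest.raises(ValueError):
            singleton_enrichment(variants(3, 2), "sift", (10, 5))

    def test_null_calibration_is_level(self):
        """Random damaging flags: the corrected test rejects at most ~5%
        of the time (the continuity correction makes it conservative)."""
        rng = np.random.default_rng(3)
        singletons, total = BACKGROUND
        hits = 0
        reps = 1000
        for _ in range(reps):
            picked_singletons = int(
                stats.hypergeom.rvs(total, singletons, 17,
                                    random_state=rng))
            r = singleton_enrichment(
                variants(17, picked_singletons), "sift", BACKGROUND)
            hits += r.p_value < 0.05
        assert hits / reps <= 0.065
        assert hits / reps >= 0.005


def make_report(event_counts):
    df = pd.DataFrame({
        "site_id": [f"s{i}" for i in range(len(event_counts))],
        "compatible": [c == 1 for c in event_counts],
        "n_events": event_counts}).set_index("site_id")
    return SiteCompatibilityReport(df)


class TestRecurrenceSummary:
    def test_published_cpg_fraction(self):
        # 123 recurrent sites carrying 294 events, 66 at CpG sites:
        # 48 two-event sites + 75 sites sharing 198 further events; mark
        # CpG context on sites covering exactly 66 events
        counts = [2] * 117 + [10] * 6 + [1] * (13_261 - 123)
        rep = make_report(counts)
        context = {}
        cpg_sites = [f"s{i}" for i in range(33)]            # 33*2 = 66
        for sid in rep.table.index:
            context[sid] = "ACG" if sid in cpg_sites else "TAT"
        s = recurrence_summary(rep, context)
        assert (s.n_recurrent, s.total_events) == (123, 294)
        assert round(100 * s.fraction_recurrent, 2) == 0.93
        assert s.cpg_events == 66
        assert round(100 * s.cpg_fraction) == 22

    def test_no_recurrence_gives_zeros(self):
        s = recurrence_summary(make_report([1, 1, 1]))
        assert (s.n_recurrent, s.total_events) == (0, 0)
        assert s.fraction_recurrent == 0.0

    def test_missing_context_for_recurrent_site_rejected(self):
        with pytest.raises(FormatError, match="context"):
            recurrence_summary(make_report([2, 1]), {"s1": "TAT"})

    def test_cpg_elevated_simulation_enriches_recurrent_events(self):
        """With a 10x CpG rate class on 2% of sites, the CpG share of
        recurrent events greatly exceeds the 2% site share."""
        from ychron.phylogeny import build_tree
        from ychron.synthetic import SimConfig, simulate_dataset
        ds = simulate_dataset(SimConfig(
            seed=8, n=25, sites_model="finite", finite_sites=30_000))
        _, compat = build_tree(ds.matrix)
        s = recurrence_summary(compat, ds.context)
        assert s.n_recurrent > 10
        assert s.cpg_fraction > 0.05


class TestCpgContext:
    @pytest.mark.parametrize("ctx,expected", [
        ("ACG", True),   # site C followed by G
        ("CGT", True),   # site G preceded by C (CpG on the other strand)
        ("TAT", False), ("GCA", False), ("CAG", False),
    ])
    def test_both_strand_convention(self, ctx, expected):
        assert is_cpg_context(ctx) is expected

    def test_bad_context_rejected(self):
        with pytest.raises(FormatError):
            is_cpg_context("ACGT")


class TestCrossStudyRecurrence:
    def test_lower_than_wgs_study(self):
        chi2, p, _ = compare_recurrence_rates((123, 13_261), (172, 5_865))
        assert p < 0.0001

    def test_higher_than_capture_study(self):
        # the printed bound is met by the uncorrected statistic; the
        # Yates-corrected p sits just above it
        _, p_plain, _ = compare_recurrence_rates(
            (123, 13_261), (4, 2_386), correction=False)
        assert p_plain < 0.0002
        _, p_yates, _ = compare_recurrence_rates((123, 13_261), (4, 2_386))
        assert p_yates < 0.00025

    def test_identical_rates_are_null(self):
        _, p, _ = compare_recurrence_rates((10, 1000), (10, 1000))
        assert p == 1.0

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            compare_recurrence_rates((5, 0), (1, 10))


class TestAnnotatedVariant:
    def test_damaging_requires_nonsynonymous(self):
        with pytest.raises(FormatError):
            AnnotatedVariant(site_id="x", consequence="synonymous",
                             derived_count=1, damaging={"sift": True})

    def test_singleton_flag_tracks_count(self):
        v = AnnotatedVariant(site_id="x", consequence="noncoding",
                             derived_count=1)
        assert v.singleton
        assert not AnnotatedVariant(site_id="y", consequence="noncoding",
                                    derived_count=3).singleton
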