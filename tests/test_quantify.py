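"""Isoform/site aggregation, the Fisher exact test, and qPCR summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from edcas.editing_model import EditingCode, SITE_ORDER
from edcas.quantify import (
    compare_sites,
    fisher_exact_2x2,
    qpcr_fold_change,
    site_frequencies,
    tabulate_isoforms,
)
from edcas.site_calling import SiteCalls
from edcas.synthetic_data import simulate_qpcr, table1_counts


def calls_from_counts(counts_by_group):
    """Expand {group: {sites: n}} into classified SiteCalls records."""
    out = []
    i = 0
    for group, counts in counts_by_group.items():
        for sites, n in counts.items():
            code = EditingCode.from_sites(sites.replace("-", ""))
            call_map = {
                s: ("edited" if f else "unedited") for s, f in zip(SITE_ORDER, code.flags)
            }
            for _ in range(n):
                out.append(SiteCalls(f"r{i}", group, dict(call_map), "classified"))
                i += 1
    return out


@pytest.fixture(scope="module")
def published_calls():
    return calls_from_counts(table1_counts())


class TestTabulateIsoforms:
    def test_published_counts_reproduced(self, published_calls):
        table = tabulate_isoforms(published_calls)
        assert table.grand_total == 20951
        row = table.row("ABD")
        assert (row["count_lean"], row["count_obob"], row["count_total"]) == (3607, 3429, 7036)
        assert f"{row['pct_total']:.2f}" == "33.58"
        assert f"{row['pct_obob']:.2f}" == "16.37"

    @pytest.mark.parametrize(
        "sites,pct_total",
        [("AB", "19.31"), ("ABCD", "11.32"), ("", "6.24")],
    )
    def test_published_combined_percentages(self, published_calls, sites, pct_total):
        table = tabulate_isoforms(published_calls)
        assert f"{table.row(sites)['pct_total']:.2f}" == pct_total

    def test_zero_rows_retained(self, published_calls):
        table = tabulate_isoforms(published_calls)
        assert len(table.to_frame()) == 32
        assert table.row("BECD")["count_total"] == 0

    def test_single_read(self):
        table = tabulate_isoforms(calls_from_counts({"lean": {"-": 1}}))
        row = table.row("")
        assert (row["count_lean"], row["count_obob"]) == (1, 0)
        assert row["pct_total"] == 100.0

    def test_empty_input_renders_zero_percent(self):
        table = tabulate_isoforms([])
        assert table.grand_total == 0
        assert (table.to_frame()["pct_total"] == 0.0).all()

    def test_unknown_group_rejected(self):
        calls = calls_from_counts({"fat": {"-": 1}})
        with pytest.raises(ValueError, match="group"):
            tabulate_isoforms(calls)

    def test_grand_total_conservation(self, published_calls):
        table = tabulate_isoforms(published_calls)
        assert table.to_frame()["count_total"].sum() == len(published_calls)


class TestSiteFrequencies:
    def test_published_call_set_site_percentages(self, published_calls):
        freq = site_frequencies(published_calls)
        a = freq.row("A")
        assert (a["edited_lean"], a["total_lean"]) == (9258, 10574)
        assert a["pct_lean"] == pytest.approx(87.55, abs=0.005)
        d = freq.row("D")
        assert d["pct_lean"] == pytest.approx(55.26, abs=0.005)

    def test_all_unedited_and_all_edited(self):
        assert (site_frequencies(calls_from_counts({"lean": {"-": 5}})).to_frame()["pct_lean"] == 0).all()
        assert (site_frequencies(calls_from_counts({"lean": {"ABECD": 5}})).to_frame()["pct_lean"] == 100).all()

    def test_zero_denominator_flagged_not_zero(self):
        freq = site_frequencies(calls_from_counts({"lean": {"-": 3}}))
        assert freq.to_frame()["pct_obob"].isna().all()

    def test_site_tally_keeps_unambiguous_sites_of_rejected_reads(self):
        calls = calls_from_counts({"lean": {"ABECD": 2}})
        partial = {s: "edited" for s in SITE_ORDER}
        partial["D"] = "ambiguous"
        calls.append(SiteCalls("rx", "lean", partial, "rejected", "ambiguous:D"))
        read_level = site_frequencies(calls, tally="read")
        site_level = site_frequencies(calls, tally="site")
        assert read_level.row("A")["total_lean"] == 2
        assert site_level.row("A")["total_lean"] == 3
        assert site_level.row("D")["total_lean"] == 2

    def test_delta_antisymmetry_under_group_swap(self, published_calls):
        freq = compare_sites(site_frequencies(published_calls))
        swapped_calls = [
            SiteCalls(sc.read_id, {"lean": "obob", "obob": "lean"}[sc.group],
                      dict(sc.calls), sc.status, sc.reject_reason)
            for sc in published_calls
        ]
        swapped = compare_sites(site_frequencies(swapped_calls))
        for site in SITE_ORDER:
            assert swapped.row(site)["delta_pct"] == pytest.approx(-freq.row(site)["delta_pct"])
            assert swapped.row(site)["p_value"] == pytest.approx(freq.row(site)["p_value"])


def fisher_enumeration_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p: enumerate every table with the
    observed margins and sum the probabilities <= that of the observed."""
    n, r, k = a + b + c + d, a + b, a + c
    denom = math.comb(n, k)
    pmf = {
        x: math.comb(r, x) * math.comb(n - r, k - x) / denom
        for x in range(max(0, k - (n - r)), min(r, k) + 1)
    }
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_homogeneous_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_two_sided == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        # both extreme tables are equally probable: p = 2 / C(20, 10)
        res = fisher_exact_2x2([[10, 0], [0, 10]])
        assert res.p_two_sided == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    def test_empty_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 0], [3, 4]]).p_two_sided == 1.0

    def test_symmetry_under_simultaneous_swap(self):
        p1 = fisher_exact_2x2([[7, 2], [3, 9]]).p_two_sided
        p2 = fisher_exact_2x2([[9, 3], [2, 7]]).p_two_sided
        assert p1 == pytest.approx(p2, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*(st.integers(0, 8) for _ in range(4))))
    def test_matches_enumeration_oracle_small_tables(self, cells):
        a, b, c, d = cells
        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
            return
        p = fisher_exact_2x2([[a, b], [c, d]]).p_two_sided
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), rel=1e-9)

    @pytest.mark.parametrize(
        "table",
        [[[9258, 1316], [9348, 1029]], [[5843, 4731], [5265, 5112]], [[373, 10201], [288, 10089]]],
    )
    def test_matches_scipy_at_study_scale(self, table):
        ours = fisher_exact_2x2(table).p_two_sided
        ref = scipy_fisher(table)[1]
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_consistent_with_normal_approximation_at_scale(self):
        # order-of-magnitude agreement with the two-proportion z-test
        from scipy.stats import norm

        el, tl, eo, to = 9258, 10574, 9348, 10377
        p1, p2 = el / tl, eo / to
        pooled = (el + eo) / (tl + to)
        z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / tl + 1 / to))
        p_norm = 2 * norm.sf(abs(z))
        p_fisher = fisher_exact_2x2([[el, tl - el], [eo, to - eo]]).p_two_sided
        assert abs(math.log10(p_fisher) - math.log10(p_norm)) < 1.0


class TestCompareSites:
    def test_identical_proportions_p_one(self):
        calls = calls_from_counts({"lean": {"ABD": 5, "-": 5}, "obob": {"ABD": 5, "-": 5}})
        table = compare_sites(site_frequencies(calls))
        assert (table.to_frame()["p_value"] == 1.0).all()
        assert (table.to_frame()["p_adjusted"] == 1.0).all()

    def test_published_counts_significance_pattern(self, published_calls):
        """Sites A and D were reported as the differentially edited sites;
        their reconstructed-count p-values stay below the Bonferroni-corrected
        threshold and within two orders of magnitude of the reported values."""
        table = compare_sites(site_frequencies(published_calls))
        p_a = table.row("A")["p_value"]
        p_d = table.row("D")["p_value"]
        assert p_a < 0.05 / 5 and p_d < 0.05 / 5
        assert 2.07e-10 <= p_a <= 2.07e-6  # reported 2.07e-8
        assert 4.47e-13 <= p_d <= 4.47e-9  # reported 4.47e-11

    def test_adjustment_is_bonferroni_over_five_sites(self, published_calls):
        table = compare_sites(site_frequencies(published_calls)).to_frame()
        for _, row in table.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, 5 * row["p_value"]))


class TestQpcr:
    def test_dct_zero_gives_unit_expression(self):
        recs = simulate_qpcr({("lean", "g"): 0.0}, sigma=0.0, n_per_group=3)
        out = qpcr_fold_change(recs)
        assert out["mean_rel_expr"].iloc[0] == pytest.approx(1.0)

    def test_known_fold_change_noiseless(self):
        # dCt lean 5, obob 4 -> obob expresses 2^1 = 2x the lean level
        recs = simulate_qpcr({("lean", "g"): 5.0, ("obob", "g"): 4.0}, sigma=0.0, n_per_group=4)
        out = qpcr_fold_change(recs)
        fc = out.set_index("group")["fold_change"]
        assert fc["lean"] == pytest.approx(1.0)
        assert fc["obob"] == pytest.approx(2.0)

    def test_halving_expression(self):
        recs = simulate_qpcr({("lean", "g"): 0.0, ("obob", "g"): 1.0}, sigma=0.0, n_per_group=4)
        out = qpcr_fold_change(recs)
        assert out.set_index("group")["fold_change"]["obob"] == pytest.approx(0.5)

    def test_noisy_recovery_within_ten_percent(self):
        recs = simulate_qpcr(
            {("lean", "g"): 5.0, ("obob", "g"): 4.0}, sigma=0.2, n_per_group=8, seed=42
        )
        out = qpcr_fold_change(recs)
        assert out.set_index("group")["fold_change"]["obob"] == pytest.approx(2.0, rel=0.1)

    def test_bonferroni_across_genes(self):
        recs = simulate_qpcr(
            {(g, gene): dct for gene, dct in [("g1", 5.0), ("g2", 3.0)] for g in ("lean", "obob")},
            sigma=0.1,
            n_per_group=5,
            seed=7,
        )
        out = qpcr_fold_change(recs)
        assert np.allclose(out["p_adjusted"], np.minimum(1.0, out["p_value"] * 2))

    def test_missing_reference_group_errors(self):
        recs = simulate_qpcr({("obob", "g"): 4.0}, sigma=0.0, n_per_group=3)
        with pytest.raises(ValueError, match="reference group"):
            qpcr_fold_change(recs)
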