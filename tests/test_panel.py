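"""SNP filtering, haplotype assignment, Mann-Whitney and LP-allele pyramiding."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lintseg.panel import (
    HaplotypeCall,
    PanelAccession,
    SnpFilterSpec,
    assign_haplotypes,
    calls_by_accession,
    filter_snps,
    mann_whitney,
    pyramiding_analysis,
    stratified_group_means,
)
from lintseg.simulate import simulate_panel


def brute_force_mw(x, y):
    """Independent oracle: U by pairwise comparison counting, p by label permutation."""
    x, y = list(x), list(y)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    pooled = x + y
    n1, n = len(x), len(x) + len(y)
    us = []
    for combo in itertools.combinations(range(n), n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in range(n) if i not in combo]
        us.append(sum((a > b) + 0.5 * (a == b) for a in g1 for b in g2))
    us = np.array(us)
    eps = 1e-9
    p = 2 * min(np.mean(us <= u_obs + eps), np.mean(us >= u_obs - eps))
    return u_obs, min(1.0, p)


class TestFilterSnps:
    def test_all_pass(self):
        t = pd.DataFrame(
            {"maf": [0.10], "mean_depth": [20], "quality": [30], "missing_rate": [0.05]}
        )
        assert len(filter_snps(t)) == 1

    def test_low_maf_dropped(self):
        t = pd.DataFrame(
            {"maf": [0.04], "mean_depth": [20], "quality": [30], "missing_rate": [0.05]}
        )
        assert len(filter_snps(t)) == 0

    def test_one_failure_per_rule_enumeration(self):
        # one site failing each rule (maf, depth-low, depth-high, quality, missingness)
        # plus one clean site -> exactly the clean site retained, order preserved
        t = pd.DataFrame(
            {
                "maf": [0.04, 0.2, 0.2, 0.2, 0.2, 0.2],
                "mean_depth": [20, 2, 60, 20, 20, 20],
                "quality": [30, 30, 30, 10, 30, 30],
                "missing_rate": [0.05, 0.05, 0.05, 0.05, 0.5, 0.05],
            }
        )
        kept = filter_snps(t)
        assert list(kept.index) == [5]

    def test_boundaries_inclusive(self):
        t = pd.DataFrame(
            {"maf": [0.05], "mean_depth": [3], "quality": [20], "missing_rate": [0.20]}
        )
        assert len(filter_snps(t)) == 1

    def test_empty_table_and_spec_validation(self):
        with pytest.raises(ValueError):
            filter_snps(pd.DataFrame(columns=["maf", "mean_depth", "quality", "missing_rate"]))
        with pytest.raises(ValueError):
            SnpFilterSpec(min_depth=60, max_depth=50)


class TestMannWhitney:
    def test_disjoint_groups_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20

    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        x=st.lists(st.integers(0, 6), min_size=1, max_size=5),
        y=st.lists(st.integers(0, 6), min_size=1, max_size=5),
    )
    def test_matches_exhaustive_enumeration(self, x, y):
        u, p = mann_whitney(x, y)
        u_b, p_b = brute_force_mw(x, y)
        assert u == pytest.approx(u_b)
        assert p == pytest.approx(p_b)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 50)
        u, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_large_sample_with_ties_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(1, 6, 25).astype(float)
        u, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_power_against_configured_shift(self):
        # +2.5 lint% shift, noise 4, n=300/300 -> p < 0.001 in >=95% of replicates
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(100):
            lp = rng.normal(33.5, 4.0, 300)
            lp_low = rng.normal(31.0, 4.0, 300)
            _, p = mann_whitney(lp, lp_low)
            hits += p < 0.001
        assert hits >= 95

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def _acc(i, gene_codes, lint, fuzz="fuzzy"):
    return PanelAccession(
        id=f"a{i}", genotypes={g: np.array(c, dtype=np.int8) for g, c in gene_codes.items()},
        lint_pct=lint, fuzz_status=fuzz,
    )


class TestAssignHaplotypes:
    def test_two_clean_patterns_lp_by_mean(self):
        panel = [
            _acc(1, {"g": [0, 0, 0]}, 32.3),
            _acc(2, {"g": [0, 0, 0]}, 32.4),
            _acc(3, {"g": [2, 2, 2]}, 29.9),
            _acc(4, {"g": [2, 2, 2]}, 29.8),
        ]
        calls = {c.accession_id: c.call for c in assign_haplotypes(panel, "g")}
        assert calls == {"a1": "LP", "a2": "LP", "a3": "lp", "a4": "lp"}

    def test_monomorphic_gene_warns_no_calls(self):
        panel = [_acc(i, {"g": [0, 0]}, 30.0) for i in range(5)]
        with pytest.warns(UserWarning, match="no polymorphic"):
            assert assign_haplotypes(panel, "g") == []

    def test_het_fraction_threshold(self):
        panel = [
            _acc(1, {"g": [0, 0, 0, 0]}, 32.0),
            _acc(2, {"g": [0, 0, 0, 0]}, 32.0),
            _acc(3, {"g": [2, 2, 2, 2]}, 29.0),
            _acc(4, {"g": [2, 2, 2, 2]}, 29.0),
            _acc(5, {"g": [1, 1, 1, 1]}, 30.0),  # fully het
            _acc(6, {"g": [0, 0, 0, 1]}, 31.0),  # 25% het sites -> HET
        ]
        calls = {c.accession_id: c.call for c in assign_haplotypes(panel, "g")}
        assert calls["a5"] == "HET" and calls["a6"] == "HET"

    def test_minor_pattern_hamming_assignment(self):
        panel = [
            _acc(1, {"g": [0, 0, 0, 0]}, 32.0),
            _acc(2, {"g": [0, 0, 0, 0]}, 33.0),
            _acc(3, {"g": [2, 2, 2, 2]}, 29.0),
            _acc(4, {"g": [2, 2, 2, 2]}, 28.0),
            _acc(5, {"g": [2, 2, 2, 0]}, 30.0),  # nearer lp major
        ]
        calls = {c.accession_id: c.call for c in assign_haplotypes(panel, "g")}
        assert calls["a5"] == "lp"

    def test_generator_truth_recovered_without_noise(self):
        panel = simulate_panel(
            300, ["g1"], lp_freqs=0.4, het_rate=0.1,
            group_means={"g1": {"LP": 3.0, "lp": 0.0}}, noise_sd=0.5, seed=11,
        )
        calls = {c.accession_id: c.call for c in assign_haplotypes(panel, "g1")}
        for acc in panel:
            assert calls[acc.id] == acc.true_haplotypes["g1"]

    def test_label_negation_swaps_lp(self):
        panel = [
            _acc(1, {"g": [0, 0]}, 32.0),
            _acc(2, {"g": [0, 0]}, 33.0),
            _acc(3, {"g": [2, 2]}, 29.0),
            _acc(4, {"g": [2, 2]}, 28.0),
        ]
        flipped = [
            PanelAccession(id=a.id, genotypes=a.genotypes, lint_pct=66.0 - a.lint_pct)
            for a in panel
        ]
        c1 = {c.accession_id: c.call for c in assign_haplotypes(panel, "g")}
        c2 = {c.accession_id: c.call for c in assign_haplotypes(flipped, "g")}
        swap = {"LP": "lp", "lp": "LP", "HET": "HET"}
        assert c2 == {k: swap[v] for k, v in c1.items()}

    def test_membership_stable_under_id_relabeling(self):
        panel = [
            _acc(1, {"g": [0, 0]}, 32.0),
            _acc(2, {"g": [2, 2]}, 29.0),
            _acc(3, {"g": [0, 0]}, 31.0),
            _acc(4, {"g": [2, 2]}, 28.5),
        ]
        renamed = [
            PanelAccession(id=f"zz{a.id}", genotypes=a.genotypes, lint_pct=a.lint_pct)
            for a in panel
        ]
        c1 = [c.call for c in assign_haplotypes(panel, "g")]
        c2 = [c.call for c in assign_haplotypes(renamed, "g")]
        assert c1 == c2


class TestStratifiedMeans:
    def test_fuzzless_penalty_visible_per_haplotype(self):
        panel = simulate_panel(
            800, ["g1", "g2"], lp_freqs=0.4, het_rate=0.05, fuzzless_fraction=0.3,
            fuzzless_penalty=12.0, noise_sd=1.0, seed=12,
        )
        calls = {g: assign_haplotypes(panel, g) for g in ("g1", "g2")}
        table = stratified_group_means(panel, calls)
        for gene in ("g1", "g2"):
            sub = table[table["gene"] == gene].set_index("fuzz_status")
            for hap in ("lp", "LP"):
                assert sub.loc["fuzzless", f"mean_{hap}"] < sub.loc["fuzzy", f"mean_{hap}"]

    def test_proportions_sum_to_100(self):
        panel = simulate_panel(400, ["g1"], het_rate=0.1, seed=13)
        calls = {"g1": assign_haplotypes(panel, "g1")}
        table = stratified_group_means(panel, calls)
        for _, row in table.iterrows():
            if row["n"]:
                assert row[["pct_lp", "pct_HET", "pct_LP"]].sum() == pytest.approx(100.0)

    def test_single_accession_stratum(self):
        panel = [
            _acc(1, {"g": [0, 0]}, 26.0, fuzz="fuzzless"),
            _acc(2, {"g": [0, 0]}, 32.0),
            _acc(3, {"g": [2, 2]}, 29.0),
            _acc(4, {"g": [2, 2]}, 28.0),
        ]
        table = stratified_group_means(panel, {"g": assign_haplotypes(panel, "g")})
        row = table[(table["gene"] == "g") & (table["fuzz_status"] == "fuzzless")].iloc[0]
        assert row["mean_LP"] == 26.0


def _calls_for_counts(counts_by_k, genes=("g1", "g2", "g3", "g4")):
    """Panel + calls with a prescribed number of accessions per LP count."""
    panel, calls = [], {g: [] for g in genes}
    i = 0
    for k, (n, lint) in counts_by_k.items():
        for _ in range(n):
            i += 1
            acc = PanelAccession(id=f"a{i}", genotypes={}, lint_pct=lint)
            panel.append(acc)
            for j, g in enumerate(genes):
                calls[g].append(HaplotypeCall(acc.id, g, "LP" if j < k else "lp"))
    return panel, calls


class TestPyramiding:
    def test_expected_percentages_are_binomial(self):
        panel, calls = _calls_for_counts({0: (1, 30.0), 4: (1, 33.0)})
        res = pyramiding_analysis(panel, calls)
        assert res.table["expected_pct"].tolist() == pytest.approx([6.25, 25, 37.5, 25, 6.25])
        assert res.table["expected_pct"].sum() == pytest.approx(100.0)

    def test_observed_zero_lp_worked_example(self):
        # 641 accessions, 29 with no LP allele -> 4.52%
        counts = {0: (29, 31.27), 1: (101, 32.34), 2: (295, 31.92), 3: (184, 32.69), 4: (32, 33.38)}
        panel, calls = _calls_for_counts(counts)
        res = pyramiding_analysis(panel, calls)
        assert res.n_analyzable == 641
        assert res.table.loc[0, "observed_pct"] == pytest.approx(4.52, abs=0.005)
        assert res.table["observed_pct"].sum() == pytest.approx(100.0)

    def test_het_policies(self):
        genes = ("g1", "g2")
        panel = [
            PanelAccession(id="a1", genotypes={}, lint_pct=30.0),
            PanelAccession(id="a2", genotypes={}, lint_pct=31.0),
        ]
        calls = {
            "g1": [HaplotypeCall("a1", "g1", "LP"), HaplotypeCall("a2", "g1", "HET")],
            "g2": [HaplotypeCall("a1", "g2", "LP"), HaplotypeCall("a2", "g2", "LP")],
        }
        counting = pyramiding_analysis(panel, calls, "count_het_as_non_LP")
        assert counting.n_analyzable == 2
        assert counting.table.loc[1, "n"] == 1  # a2: HET counts as non-LP
        excluding = pyramiding_analysis(panel, calls, "exclude_het_accessions")
        assert excluding.n_analyzable == 1

    def test_monotone_means_with_additive_generator(self):
        genes = ["g1", "g2", "g3", "g4"]
        panel = simulate_panel(
            2000, genes, lp_freqs=0.5, het_rate=0.0, noise_sd=0.0, fuzzless_fraction=0.0,
            group_means={g: {"LP": 0.5, "lp": 0.0} for g in genes}, seed=14,
        )
        calls = {g: assign_haplotypes(panel, g) for g in genes}
        res = pyramiding_analysis(panel, calls)
        means = res.table["mean_lint_pct"].to_numpy()
        assert all(b >= a for a, b in zip(means, means[1:]))
        # pairwise Mann-Whitney p-values present for all non-empty pairs
        assert (0, 4) in res.pairwise_p and res.pairwise_p[(0, 4)] < 0.001

    def test_no_analyzable_is_error(self):
        panel = [PanelAccession(id="a1", genotypes={}, lint_pct=30.0)]
        calls = {"g1": [HaplotypeCall("a1", "g1", "HET")]}
        with pytest.raises(ValueError, match="no analyzable"):
            pyramiding_analysis(panel, calls, "exclude_het_accessions")

    def test_calls_by_accession_reindex(self):
        calls = {"g": [HaplotypeCall("a1", "g", "LP")], "h": [HaplotypeCall("a1", "h", "lp")]}
        assert calls_by_accession(calls) == {"a1": {"g": "LP", "h": "lp"}}
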