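"""Transmission counting, trio phasing, haplotype scans and replication."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from scipy import stats

from conftest import make_trio
from nipkit import simulate, tdt
from nipkit.pedigree import Cohort, Marker
from nipkit.tdt import (
    AMBIGUOUS,
    ComparisonError,
    Haplotype,
    TdtResult,
    TdtStat,
    TransmissionCount,
    bonferroni,
    count_snp_transmissions,
    enumerate_marker_windows,
    haplotype_tdt,
    phase_trio_haplotypes,
    replication_check,
    run_gene_scan,
    tdt_statistic,
)


class TestTdtStatistic:
    def test_mcnemar_form(self):
        stat = tdt_statistic(55, 31)
        assert stat.chi_square == pytest.approx((55 - 31) ** 2 / 86)
        assert stat.p_value == pytest.approx(stats.chi2.sf(stat.chi_square, 1))

    def test_tie_gives_p_one(self):
        stat = tdt_statistic(10, 10)
        assert stat.chi_square == 0.0
        assert stat.p_value == 1.0

    def test_zero_information_is_no_test(self):
        assert tdt_statistic(0, 0) is None

    @pytest.mark.parametrize("t,u", [(5, 3), (100, 70), (0, 8)])
    def test_symmetry(self, t, u):
        assert tdt_statistic(t, u).chi_square == tdt_statistic(u, t).chi_square

    def test_p_monotone_in_chi_square(self):
        stats_seq = [tdt_statistic(10 + k, 10) for k in range(0, 30, 5)]
        chis = [s.chi_square for s in stats_seq]
        ps = [s.p_value for s in stats_seq]
        assert chis == sorted(chis)
        assert ps == sorted(ps, reverse=True)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, n, expected", [(0.0008, 3, 0.0024), (0.5, 10, 1.0), (0.01, 1, 0.01)]
    )
    def test_values(self, p, n, expected):
        assert bonferroni(p, n) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)


class TestCountSnpTransmissions:
    def test_single_informative_meiosis(self, biallelic_marker):
        fam = make_trio([("A", "a")], [("A", "A")], [("A", "A")], [biallelic_marker])
        counts = count_snp_transmissions(fam, biallelic_marker, "CD")
        assert (counts["a"].T, counts["a"].U) == (0, 1)
        assert (counts["A"].T, counts["A"].U) == (1, 0)

    def test_double_het_child_het_counts_both(self, biallelic_marker):
        fam = make_trio([("A", "a")], [("A", "a")], [("A", "a")], [biallelic_marker])
        counts = count_snp_transmissions(fam, biallelic_marker, "CD")
        assert (counts["a"].T, counts["a"].U) == (1, 1)
        assert (counts["A"].T, counts["A"].U) == (1, 1)

    def test_homozygous_parents_uninformative(self, biallelic_marker):
        fam = make_trio([("A", "A")], [("A", "A")], [("A", "A")], [biallelic_marker])
        counts = count_snp_transmissions(fam, biallelic_marker, "CD")
        assert all(c.T == c.U == 0 for c in counts.values())

    def test_unaffected_child_not_counted(self, biallelic_marker):
        fam = make_trio(
            [("A", "a")], [("A", "A")], [("A", "A")], [biallelic_marker],
            child_diagnosis="UC",
        )
        counts = count_snp_transmissions(fam, biallelic_marker, "CD")
        assert all(c.T == c.U == 0 for c in counts.values())

    def test_mendel_violation_skips_family(self, biallelic_marker, caplog):
        fam = make_trio([("A", "A")], [("A", "A")], [("a", "a")], [biallelic_marker])
        with caplog.at_level("INFO"):
            counts = count_snp_transmissions(fam, biallelic_marker, "CD")
        assert all(c.T == c.U == 0 for c in counts.values())

    def test_x_linked_maternal_only(self):
        x = Marker("rsx", "LDOC1", "X", 0, ("A", "a"))
        # heterozygous mother, hemizygous father; affected son receives "a"
        fam = make_trio([("A", "A")], [("A", "a")], [("a", "a")], [x], child_sex=1)
        counts = count_snp_transmissions(fam, x, "CD")
        assert (counts["a"].T, counts["a"].U) == (1, 0)
        assert (counts["A"].T, counts["A"].U) == (0, 1)

    def test_allele_balance_invariant(self, biallelic_marker):
        """Summing T over both alleles equals summing U (one of each per meiosis)."""
        rng = np.random.default_rng(5)
        gts = [("A", "A"), ("A", "a"), ("a", "a")]
        total_T = total_U = 0
        for i in range(100):
            f, m = gts[rng.integers(3)], gts[rng.integers(3)]
            c = tuple(sorted((f[rng.integers(2)], m[rng.integers(2)])))
            fam = make_trio([f], [m], [c], [biallelic_marker], family_id=f"F{i}")
            counts = count_snp_transmissions(fam, biallelic_marker, "CD")
            total_T += sum(x.T for x in counts.values())
            total_U += sum(x.U for x in counts.values())
        assert total_T == total_U > 0


class TestEnumerateWindows:
    def _panel(self, n):
        return [Marker(f"rs{i}", "G", "autosome", i) for i in range(n)]

    @pytest.mark.parametrize(
        "n, sizes, expected",
        [(4, {2}, 6), (2, {3}, 0), (3, {1, 2, 3}, 7), (5, {1}, 5)],
    )
    def test_counts(self, n, sizes, expected):
        assert len(enumerate_marker_windows(self._panel(n), sizes)) == expected

    def test_order_preserved_and_deterministic(self):
        panel = self._panel(3)
        windows = enumerate_marker_windows(panel, {1, 2})
        assert windows == enumerate_marker_windows(panel, {2, 1})
        for w in windows:
            positions = [m.position_index for m in w]
            assert positions == sorted(positions)


GT = [("1", "1"), ("1", "2"), ("2", "2")]


def brute_force_phase(father, mother, child):
    """Independent oracle: enumerate ordered splits and transmissions directly."""

    def ordered_splits(gt):
        per = [[(a, b), (b, a)] for a, b in gt]
        out = []
        for choice in product(*per):
            h1 = tuple(c[0] for c in choice)
            h2 = tuple(c[1] for c in choice)
            out.append((h1, h2))
        return out

    child_sorted = [tuple(sorted(g)) for g in child]
    contributions = set()
    for fh in ordered_splits(father):
        for mh in ordered_splits(mother):
            for fi in (0, 1):
                for mi in (0, 1):
                    ft, fu = fh[fi], fh[1 - fi]
                    mt, mu = mh[mi], mh[1 - mi]
                    if all(
                        tuple(sorted((ft[k], mt[k]))) == child_sorted[k]
                        for k in range(len(child))
                    ):
                        contributions.add(tuple(sorted(((ft, fu), (mt, mu)))))
    if not contributions:
        return None
    if len(contributions) > 1:
        return AMBIGUOUS
    return sorted(next(iter(contributions)))


class TestPhaseTrioHaplotypes:
    def test_exhaustive_two_snp_configurations(self):
        """All 3^6 two-SNP trio genotype configurations match the oracle."""
        for fg in product(GT, repeat=2):
            for mg in product(GT, repeat=2):
                for cg in product(GT, repeat=2):
                    expected = brute_force_phase(fg, mg, cg)
                    got = phase_trio_haplotypes(fg, mg, cg)
                    if isinstance(got, list):
                        got = sorted(got)
                    assert got == expected, (fg, mg, cg)

    def test_single_snp_reduces_to_allele_counting(self):
        got = phase_trio_haplotypes([("1", "2")], [("1", "2")], [("1", "2")])
        assert sorted(got) == [(("1",), ("2",)), (("2",), ("1",))]

    def test_all_double_het_is_ambiguous(self):
        dh = [("1", "2"), ("1", "2")]
        assert phase_trio_haplotypes(dh, dh, dh) == AMBIGUOUS

    def test_phase_resolved_by_homozygous_mother(self):
        father = [("1", "2"), ("1", "2")]
        mother = [("1", "1"), ("1", "1")]
        child = [("1", "2"), ("1", "1")]
        got = phase_trio_haplotypes(father, mother, child)
        assert (("2", "1"), ("1", "2")) in got  # father transmitted 2-1

    def test_inconsistent_trio_excluded(self):
        assert phase_trio_haplotypes([("1", "1")], [("1", "1")], [("2", "2")]) is None


class TestHaplotypeTdt:
    def _random_cohort(self, seed, tau=0.5, n=120):
        cfg = simulate.CohortSimConfig(
            seed=seed, n_cd_nod2_mutated=0, n_cd_nod2_wildtype=n, n_uc=0, n_mixed=0,
            transmission_probability=tau,
        )
        return simulate.simulate_cohort(cfg)

    def test_window_size_one_equals_snp_counting(self):
        """Haplotype machinery on 1-SNP windows equals allele-level counting."""
        for seed in range(3):
            cohort = self._random_cohort(seed)
            marker = cohort.markers[0]
            results = haplotype_tdt(cohort, [marker], "CD", min_freq=0.0)
            hap_counts = {r.unit.alleles[0]: (r.count.T, r.count.U) for r in results}
            total = {a: [0, 0] for a in marker.alleles}
            for fam in cohort.families:
                counts = count_snp_transmissions(fam, marker, "CD")
                for allele, c in counts.items():
                    total[allele][0] += c.T
                    total[allele][1] += c.U
            for allele, (t, u) in total.items():
                if t + u:
                    assert hap_counts[allele] == (t, u)

    def test_null_counts_within_binomial_band(self):
        """τ=0.5, 500 trios: every haplotype's |T-U| within the 99.9% band."""
        cohort = self._random_cohort(0, n=500)
        panels = {"GENE1": list(cohort.markers)}
        table = run_gene_scan(cohort, panels, subgroups=["CD"])
        z999 = stats.norm.isf(0.0005)
        for _, row in table.iterrows():
            n = row["T"] + row["U"]
            assert abs(row["T"] - row["U"]) <= z999 * np.sqrt(n) + 1e-9

    def test_engineered_distortion_flagged(self):
        """A strong risk-haplotype distortion is flagged after correction,
        and every flagged row's window carries the risk haplotype's alleles."""
        panel_cfg = simulate.PanelSimConfig(risk_haplotype=3)
        cfg = simulate.CohortSimConfig(
            seed=7, n_cd_nod2_mutated=0, n_cd_nod2_wildtype=250, n_uc=0, n_mixed=0,
            transmission_probability=0.8, panels=(panel_cfg,),
        )
        cohort = simulate.simulate_cohort(cfg)
        table = run_gene_scan(cohort, {"GENE1": list(cohort.markers)}, subgroups=["CD"])
        risk = panel_cfg.haplotypes[3]
        marker_ids = [m.id for m in panel_cfg.markers]
        full = table[(table.window == ";".join(marker_ids)) & (table.haplotype == "|".join(risk))]
        assert len(full) == 1 and bool(full.iloc[0].flag)
        assert full.iloc[0]["T"] > full.iloc[0]["U"]
        for _, row in table[table.flag].iterrows():
            window_ids = row.window.split(";")
            alleles = row.haplotype.split("|")
            risk_sub = [risk[marker_ids.index(w)] for w in window_ids]
            over = alleles if row["T"] > row["U"] else None
            # over-transmitted flagged haplotypes are the risk sub-haplotypes
            if over is not None:
                assert over == risk_sub

    def test_empty_subgroup_yields_no_rows(self):
        cohort = self._random_cohort(1, n=10)
        table = run_gene_scan(cohort, {"GENE1": list(cohort.markers)}, subgroups=["UC"])
        assert table.empty

    def test_n_tests_counts_filtered_haplotypes(self):
        cohort = self._random_cohort(2)
        table = run_gene_scan(cohort, {"GENE1": list(cohort.markers)}, subgroups=["CD"])
        assert (table.n_tests == len(table)).all()
        assert (table.p_corrected >= table.p).all()
        assert (table.p_corrected <= 1.0).all()


class TestTypeIAndPower:
    def test_transmission_level_type_i_error(self):
        """2,000 null replicates of 200 informative transmissions: the raw
        rejection rate at alpha=0.05 stays within the binomial tolerance band."""
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(2000):
            T, U = simulate.simulate_transmissions(200, 0.5, rng)
            stat = tdt_statistic(T, U)
            rejections += stat.p_value < 0.05
        assert 0.04 <= rejections / 2000 <= 0.06

    def test_power_stable_across_seeds(self):
        """τ=0.64 with 86 informative meioses: power at alpha=0.01 varies
        across seeds by no more than 3 binomial SD."""
        powers = []
        n_rep = 1000
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(n_rep):
                T, U = simulate.simulate_transmissions(86, 0.64, rng)
                hits += tdt_statistic(T, U).p_value < 0.01
            powers.append(hits / n_rep)
        p_bar = np.mean(powers)
        se = np.sqrt(p_bar * (1 - p_bar) / n_rep)
        assert max(powers) - min(powers) <= 2 * 3 * se


class TestReplicationCheck:
    def _result(self, gene, window, alleles, T, U):
        stat = tdt_statistic(T, U)
        hap = Haplotype(window, alleles)
        return TdtResult(
            gene=gene, window=window, unit=hap, subgroup="CD",
            haplotype_frequency=0.3, count=TransmissionCount(hap, T, U), stat=stat,
        )

    def test_same_haplotype_replicates(self):
        primary = self._result("VIM", ("rs1", "rs2"), ("1", "2"), 30, 9)
        rep = self._result("VIM", ("rs1", "rs2"), ("1", "2"), 35, 19)
        assert replication_check(primary, [rep]) == "replicated"

    def test_different_haplotype_is_not_replication(self):
        primary = self._result("VIM", ("rs1", "rs2"), ("1", "2"), 30, 9)
        other = self._result("VIM", ("rs1",), ("2",), 35, 19)
        assert replication_check(primary, [other]) == "different_haplotype"

    def test_weak_replication_rejected(self):
        primary = self._result("VIM", ("rs1",), ("1",), 30, 9)
        rep = self._result("VIM", ("rs1",), ("1",), 22, 18)  # p ≈ 0.53
        assert replication_check(primary, [rep]) == "not_replicated"

    def test_gene_mismatch_raises(self):
        primary = self._result("VIM", ("rs1",), ("1",), 30, 9)
        rep = self._result("DOCK7", ("rs1",), ("1",), 35, 19)
        with pytest.raises(ComparisonError):
            replication_check(primary, [rep])
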