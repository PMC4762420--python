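"""QC and harmonization: HWE against a closed-form oracle, filter
predicates against brute force, allele alignment and flip invariance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prscog import (
    PrscogError,
    QCThresholds,
    SummaryStatTable,
    apply_variant_qc,
    harmonize,
    hwe_test,
    is_strand_ambiguous,
)
from prscog.variant_qc import hwe_test_vectorized

from conftest import make_dataset


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent closed-form chi-square HWE test."""
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    e = np.array([n * p * p, 2 * n * p * q, n * q * q])
    if np.any(e == 0):
        return 1.0
    o = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = ((o - e) ** 2 / e).sum()
    return float(sps.chi2.sf(chi2, 1))


class TestHWE:
    def test_exact_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_maximal_disequilibrium(self):
        assert hwe_test(100, 0, 100) < 1e-10

    def test_against_closed_form_oracle(self):
        # (30,40,30): allele frequency is exactly 0.5, expected (25,50,25)
        assert hwe_test(30, 40, 30) == pytest.approx(hwe_oracle(30, 40, 30), abs=1e-10)

    def test_random_triples_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            c = rng.integers(0, 200, size=3)
            if c.sum() == 0:
                continue
            assert hwe_test(*c) == pytest.approx(hwe_oracle(*c), abs=1e-10)

    def test_monomorphic_returns_one(self):
        assert hwe_test(50, 0, 0) == 1.0

    def test_all_zero_is_domain_error(self):
        with pytest.raises(PrscogError):
            hwe_test(0, 0, 0)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(7)
        c = rng.integers(0, 100, size=(50, 3))
        c = c[c.sum(axis=1) > 0]
        vec = hwe_test_vectorized(c[:, 0], c[:, 1], c[:, 2])
        for i in range(len(c)):
            assert vec[i] == pytest.approx(hwe_test(*c[i]), abs=1e-12)


class TestVariantQC:
    def test_low_call_rate_removed(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.4, size=(100, 2)).astype(float)
        dos[:3, 0] = np.nan  # 3% missing < 0.98 call rate
        ds = make_dataset(dos)
        kept, report = apply_variant_qc(ds, QCThresholds())
        assert list(kept.variants["id"]) == ["rs2"]
        assert ("rs1", "call_rate") in set(zip(report["variant"], report["filter"]))

    def test_monomorphic_removed_for_maf(self):
        dos = np.zeros((50, 1))
        dos = np.column_stack([dos, np.random.default_rng(1).binomial(2, 0.4, 50)])
        ds = make_dataset(dos.astype(float))
        kept, report = apply_variant_qc(ds, QCThresholds())
        assert "rs1" not in list(kept.variants["id"])
        assert ("rs1", "maf") in set(zip(report["variant"], report["filter"]))

    def test_engineered_failures_match_predicate_oracle(self):
        rng = np.random.default_rng(5)
        n = 200
        cols = []
        for j in range(20):
            p = rng.uniform(0.005, 0.5)
            col = rng.binomial(2, p, size=n).astype(float)
            if j % 4 == 0:
                col[: rng.integers(1, 10)] = np.nan
            if j % 5 == 0:  # inject HWE failure: het deficit
                col[col == 1] = rng.choice([0, 2], size=(col == 1).sum())
            cols.append(col)
        ds = make_dataset(np.column_stack(cols))
        thr = QCThresholds()
        kept, _ = apply_variant_qc(ds, thr)

        expected = []
        for j in range(20):
            col = ds.dosages[:, j]
            obs = col[~np.isnan(col)]
            call = len(obs) / n
            f = obs.mean() / 2
            maf = min(f, 1 - f)
            n2, n1, n0 = (obs == 2).sum(), (obs == 1).sum(), (obs == 0).sum()
            p_hwe = hwe_oracle(n2, n1, n0)
            if call >= thr.call_rate_min and maf >= thr.maf_min and p_hwe >= thr.hwe_p_min:
                expected.append(f"rs{j + 1}")
        assert list(kept.variants["id"]) == expected

    def test_retained_set_order_independent(self):
        rng = np.random.default_rng(9)
        dos = rng.binomial(2, rng.uniform(0.005, 0.5, 15), size=(150, 15)).astype(float)
        dos[rng.random(dos.shape) < 0.02] = np.nan
        ds = make_dataset(dos)
        perm = rng.permutation(15)
        shuffled = ds.take_variants(perm)
        kept1, _ = apply_variant_qc(ds)
        kept2, _ = apply_variant_qc(shuffled)
        assert set(kept1.variants["id"]) == set(kept2.variants["id"])


class TestStrandAmbiguity:
    def test_at_pair_is_ambiguous(self):
        assert is_strand_ambiguous("A", "T") is True

    def test_ag_pair_is_not(self):
        assert is_strand_ambiguous("A", "G") is False

    def test_enumeration_of_all_ordered_pairs(self):
        pairs = [p for p in itertools.permutations("ACGT", 2)]
        flagged = [p for p in pairs if is_strand_ambiguous(*p)]
        assert len(pairs) == 12
        assert set(flagged) == {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

    def test_non_acgt_rejected(self):
        with pytest.raises(PrscogError):
            is_strand_ambiguous("A", "N")


def summary_table(rows, label="ALL_ISCHEMIC"):
    return SummaryStatTable(
        phenotype_label=label,
        records=pd.DataFrame(rows, columns=["id", "a1", "a2", "beta", "p"]),
    )


class TestHarmonize:
    def make_ds(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.3, size=(100, 4)).astype(float)
        return make_dataset(
            dos, alleles=[("A", "G"), ("A", "T"), ("C", "T"), ("G", "A")]
        )

    def test_allele_swap_negates_beta(self):
        ds = self.make_ds()
        t = summary_table([("rs1", "G", "A", 0.2, 0.5)])
        eff = harmonize(ds, t)
        assert list(eff.table["id"]) == ["rs1"]
        assert eff.table["beta"].iloc[0] == pytest.approx(-0.2)

    def test_matching_alleles_keep_beta(self):
        ds = self.make_ds()
        t = summary_table([("rs1", "A", "G", 0.2, 0.5)])
        eff = harmonize(ds, t)
        assert eff.table["beta"].iloc[0] == pytest.approx(0.2)

    def test_ambiguous_variant_always_dropped(self):
        ds = self.make_ds()
        t = summary_table([("rs2", "A", "T", 0.9, 0.01)])
        eff = harmonize(ds, t)
        assert eff.n_variants == 0
        assert eff.report["ambiguous"] == 1

    def test_mismatched_allele_pair_dropped_and_counted(self):
        ds = self.make_ds()
        t = summary_table([("rs3", "A", "G", 0.1, 0.5)])  # dataset has C/T
        eff = harmonize(ds, t)
        assert eff.n_variants == 0
        assert eff.report["allele_mismatch"] == 1

    def test_absent_from_stats_dropped(self):
        ds = self.make_ds()
        t = summary_table([("rs999", "A", "G", 0.1, 0.5)])
        eff = harmonize(ds, t)
        assert eff.n_variants == 0
        assert eff.report["not_in_stats"] == 4

    def test_low_cohort_maf_dropped(self):
        rng = np.random.default_rng(3)
        dos = np.column_stack(
            [
                rng.binomial(2, 0.01, 500),  # cohort maf ~1% < 2% floor
                rng.binomial(2, 0.3, 500),
            ]
        ).astype(float)
        ds = make_dataset(dos, alleles=[("A", "G"), ("C", "T")])
        t = summary_table([("rs1", "A", "G", 0.1, 0.5), ("rs2", "C", "T", 0.1, 0.5)])
        eff = harmonize(ds, t)
        assert list(eff.table["id"]) == ["rs2"]
        assert eff.report["low_maf"] == 1

    def test_swap_invariance_of_output(self):
        """Swapping (a1, a2, -beta) in any non-ambiguous record is a no-op."""
        ds = self.make_ds()
        rows = [("rs1", "A", "G", 0.2, 0.5), ("rs4", "G", "A", -0.4, 0.1)]
        swapped = [(i, a2, a1, -b, p) for (i, a1, a2, b, p) in rows]
        e1 = harmonize(ds, summary_table(rows))
        e2 = harmonize(ds, summary_table(swapped))
        pd.testing.assert_frame_equal(e1.table, e2.table)
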