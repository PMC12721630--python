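"""Genotype I/O, association, GRS construction and LD/EM estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from redoxmr import (
    GenotypeMatrix,
    build_grs,
    em_haplotype_freqs,
    ld_stats,
    read_genotypes,
    snp_association,
    write_genotypes,
)
from redoxmr._errors import DataError
from redoxmr.genetics import MISSING, two_locus_loglik


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


VCF_TEXT = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=6>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
6\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
6\t200\trsB\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0
"""


class TestGenotypeIO:
    def test_vcf_gt_mapping(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(VCF_TEXT)
        gm = read_genotypes(p)
        assert gm.subject_ids == ["S1", "S2", "S3"]
        assert gm.rsids == ["rsA", "rsB"]
        assert gm.dosage[:, 0].tolist() == [0, 1, 2]
        assert gm.dosage[:, 1].tolist() == [1, MISSING, 0]
        assert gm.missing_fraction.tolist() == [0.0, pytest.approx(1 / 3)]

    def test_multiallelic_rejected_by_rsid(self, tmp_path):
        bad = VCF_TEXT.replace("rsB\tC\tT", "rsB\tC\tT,G")
        p = tmp_path / "bad.vcf"
        p.write_text(bad)
        with pytest.raises(DataError, match="rsB"):
            read_genotypes(p)

    @pytest.mark.parametrize("fmt", ["vcf", "tsv"])
    def test_write_read_roundtrip(self, tmp_path, fmt, rng):
        dosage = rng.integers(0, 3, size=(20, 4)).astype(np.int16)
        dosage[3, 1] = MISSING
        gm = GenotypeMatrix([f"P{i}" for i in range(20)],
                            [f"rs{j}" for j in range(4)], dosage)
        path = tmp_path / f"gm.{fmt}"
        write_genotypes(gm, path, fmt)
        back = read_genotypes(path, fmt)
        assert back.subject_ids == gm.subject_ids
        assert back.rsids == gm.rsids
        assert np.array_equal(back.dosage, gm.dosage)

    def test_missing_excluded_from_association_denominator(self):
        dosage = np.array([[0], [0], [1], [1], [MISSING]], dtype=np.int16)
        gm = GenotypeMatrix([f"P{i}" for i in range(5)], ["rs1"], dosage)
        res, _ = snp_association(gm, np.exp([1.0, 1.0, 2.0, 2.0, 99.0]))
        assert res[0].n == 4


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------


class TestSnpAssociation:
    def test_closed_form_perfect_fit(self):
        dosage = np.array([[0], [0], [1], [1]], dtype=np.int16)
        gm = GenotypeMatrix(["a", "b", "c", "d"], ["rs1"], dosage)
        res, selected = snp_association(gm, np.exp([1.0, 1.0, 2.0, 2.0]))
        assert res[0].beta == pytest.approx(1.0)
        assert res[0].p < 5e-8
        assert selected == ["rs1"]

    def test_monomorphic_flagged_not_aborted(self):
        dosage = np.column_stack([[0, 0, 0, 0], [0, 1, 2, 1]]).astype(np.int16)
        gm = GenotypeMatrix(["a", "b", "c", "d"], ["mono", "poly"], dosage)
        res, _ = snp_association(gm, [1.0, 2.0, 3.0, 2.0])
        assert res[0].excluded and res[0].reason == "monomorphic"
        assert not res[1].excluded

    def test_null_permutations_select_nothing(self, rng):
        """Level of the genome-wide threshold under the null: permuted
        phenotype yields an empty selected set in >=999/1000 runs."""
        n = 200
        dosage = rng.integers(0, 3, size=(n, 7)).astype(np.int16)
        gm = GenotypeMatrix([str(i) for i in range(n)],
                            [f"rs{j}" for j in range(7)], dosage)
        lpa = np.exp(rng.normal(2.5, 1.0, n))
        hits = 0
        for _ in range(1000):
            _, selected = snp_association(gm, rng.permutation(lpa))
            hits += bool(selected)
        assert hits <= 1

    def test_default_cohort_selects_all_seven(self, cohort20k):
        gm, pheno, _ = cohort20k
        _, selected = snp_association(gm, pheno["lpa"].to_numpy())
        assert sorted(selected) == sorted(gm.rsids)

    def test_q_dominates_p(self, cohort20k):
        gm, pheno, _ = cohort20k
        res, _ = snp_association(gm, pheno["lpa"].to_numpy())
        for r in res:
            assert r.q >= r.p


# ---------------------------------------------------------------------------
# GRS
# ---------------------------------------------------------------------------


def _gm_from_rows(rows):
    dosage = np.asarray(rows, dtype=np.int16)
    return GenotypeMatrix([f"P{i}" for i in range(dosage.shape[0])],
                          [f"rs{j}" for j in range(dosage.shape[1])], dosage)


class TestBuildGrs:
    def test_all_zero_matrix_is_all_reference(self):
        gm = _gm_from_rows(np.zeros((5, 7)))
        res = build_grs(gm, gm.rsids)
        assert (res.group == "reference").all()
        assert res.group_sizes["alternative"] == 0

    def test_three_carried_variants_is_alternative(self):
        gm = _gm_from_rows([[1, 0, 2, 0, 1, 0, 0], [0] * 7])
        res = build_grs(gm, gm.rsids)
        assert res.carrier_count[0] == 3
        assert res.group[0] == "alternative"

    def test_single_carrier_unassigned(self):
        gm = _gm_from_rows([[1, 0, 0, 0, 0, 0, 0], [0] * 7])
        res = build_grs(gm, gm.rsids)
        assert res.group[0] == "unassigned"

    def test_missing_call_blocks_reference_assignment(self):
        row = [0, 0, 0, 0, 0, 0, MISSING]
        gm = _gm_from_rows([row, [0] * 7])
        res = build_grs(gm, gm.rsids)
        assert res.group[0] == "unassigned" and not res.complete[0]
        assert res.group[1] == "reference"

    def test_continuous_score_unit_sd_in_stratum(self, cohort20k):
        _, _, grs = cohort20k
        vals = grs.continuous_score[np.isfinite(grs.continuous_score)]
        assert vals.std(ddof=1) == pytest.approx(1.0)
        assert (grs.carrier_count[np.isfinite(grs.continuous_score)] >= 2).all()

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.integers(0, 3, size=(12, 7)).astype(np.int16)
        gm = _gm_from_rows(dosage)
        res = build_grs(gm, gm.rsids)
        perm_s = rng.permutation(12)
        perm_v = rng.permutation(7)
        gm2 = GenotypeMatrix([gm.subject_ids[i] for i in perm_s],
                             [gm.rsids[j] for j in perm_v],
                             dosage[np.ix_(perm_s, perm_v)])
        res2 = build_grs(gm2, gm.rsids)  # same instrument order as before
        for i, s in enumerate(perm_s):
            assert res2.carrier_count[i] == res.carrier_count[s]
            assert res2.group[i] == res.group[s]


# ---------------------------------------------------------------------------
# EM haplotypes & LD
# ---------------------------------------------------------------------------


def _grid_search_pab(g1, g2, step=1e-5):
    """Oracle: maximize the observed-data likelihood over pAB with the
    allele-frequency margins fixed at their MLEs."""
    g1 = np.asarray(g1); g2 = np.asarray(g2)
    n = len(g1)
    pA = g1.sum() / (2 * n)
    pB = g2.sum() / (2 * n)
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    grid = np.arange(lo, hi + step, step)
    best, best_ll = None, -np.inf
    for pab_ in grid:
        hap = np.array([pab_, pA - pab_, pB - pab_, 1 - pA - pB + pab_])
        if hap.min() < -1e-12:
            continue
        ll = two_locus_loglik(np.clip(hap, 0, 1), counts)
        if ll > best_ll:
            best, best_ll = hap, ll
    return best


class TestEmHaplotypes:
    def test_no_double_heterozygotes_equals_counting(self):
        g1 = np.array([0, 0, 2, 2, 1, 0])
        g2 = np.array([0, 0, 2, 2, 0, 1])  # no (1,1) pair: phase known
        pair = em_haplotype_freqs(g1, g2)
        # direct gamete counting: 12 gametes
        # subj: (0,0)x2 -> ab,ab each; (2,2)x2 -> AB,AB; (1,0) -> Ab,ab; (0,1) -> aB,ab
        expect = np.array([4, 1, 1, 6]) / 12
        assert np.asarray(pair.hap_freqs) == pytest.approx(expect, abs=1e-9)
        assert pair.converged

    def test_symmetric_table_gives_quarter_freqs(self):
        g1 = np.repeat([2, 2, 0, 0], 25)
        g2 = np.tile(np.repeat([2, 0], 25), 2)
        pair = em_haplotype_freqs(g1, g2)
        assert np.asarray(pair.hap_freqs) == pytest.approx([0.25] * 4, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hap_true = rng.dirichlet([2, 1, 1, 3])
        n = 300
        haps = rng.choice(4, size=(n, 2), p=hap_true)
        a = np.isin(haps, [0, 1]).sum(axis=1)  # haplotypes carrying allele A
        b = np.isin(haps, [0, 2]).sum(axis=1)
        pair = em_haplotype_freqs(a, b)
        oracle = _grid_search_pab(a, b)
        assert pair.hap_freqs[0] == pytest.approx(oracle[0], abs=2e-5)

    def test_loglik_monotone_over_iterations(self, rng):
        g1 = rng.integers(0, 3, 200)
        g2 = np.clip(g1 + rng.integers(-1, 2, 200), 0, 2)
        pair = em_haplotype_freqs(g1, g2)
        diffs = np.diff(pair.loglik_trace)
        assert np.all(diffs >= -1e-9)

    def test_all_double_heterozygous_flagged(self):
        pair = em_haplotype_freqs([1, 1, 1, 1], [1, 1, 1, 1])
        assert pair.non_identifiable


class TestLdStats:
    def test_complete_ld(self):
        pair = ld_stats([0.5, 0.0, 0.0, 0.5])
        assert pair.D == pytest.approx(0.25)
        assert pair.D_prime == pytest.approx(1.0)
        assert pair.r2 == pytest.approx(1.0)

    def test_independent_loci(self):
        pA, pB = 0.3, 0.6
        pair = ld_stats([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
        assert pair.D == pytest.approx(0.0, abs=1e-12)
        assert pair.D_prime == pytest.approx(0.0)
        assert pair.r2 == pytest.approx(0.0, abs=1e-12)

    def test_formula_example(self):
        pair = ld_stats([0.05, 0.05, 0.15, 0.75])
        assert pair.D == pytest.approx(0.03)
        assert pair.D_prime == pytest.approx(0.375)
        assert pair.r2 == pytest.approx(0.0625)

    def test_monomorphic_errors(self):
        with pytest.raises(DataError):
            ld_stats([0.5, 0.5, 0.0, 0.0])

    def test_r2_one_implies_dprime_one(self, rng):
        for _ in range(200):
            hap = rng.dirichlet([1, 1, 1, 1])
            try:
                pair = ld_stats(hap)
            except DataError:
                continue
            if pair.r2 > 1 - 1e-9:
                assert pair.D_prime == pytest.approx(1.0, abs=1e-6)
            assert -1e-12 <= pair.D_prime <= 1 + 1e-12
            assert -1e-12 <= pair.r2 <= 1 + 1e-12
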