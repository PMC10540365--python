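"""Genotype readers, SNP QC, dosage encodings, phenotype preparation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from adqtl.genotype_io import (
    MISSING,
    GenotypeMatrix,
    GenotypeParseError,
    PhenotypeVector,
    SnpRecord,
    adjust_phenotype,
    allele_frequencies,
    encode_additive,
    encode_heterozygote,
    inverse_normal_transform,
    qc_filter,
    read_genotypes,
)


def _matrix(calls, chroms=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snps = [
        SnpRecord(
            id=f"s{j}",
            chromosome=(chroms[j] if chroms else "1"),
            position=(j + 1) * 1000,
        )
        for j in range(m)
    ]
    return GenotypeMatrix.from_calls([f"i{i}" for i in range(n)], snps, calls)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def test_tsv_dosage_round_trip_with_missing(tmp_path):
    path = tmp_path / "geno.tsv"
    path.write_text(
        "sample\tsnpA\tsnpB\n"
        "i0\t0\t2\n"
        "i1\t1\tNA\n"
        "i2\t2\t0\n"
    )
    g = read_genotypes(path, "tsv-dosage")
    assert g.samples == ["i0", "i1", "i2"]
    assert g.snp_ids == ["snpA", "snpB"]
    expected = np.array([[0, 2], [1, MISSING], [2, 0]])
    assert np.array_equal(g.calls, expected)
    assert g.snps[1].missing_rate == pytest.approx(1 / 3)


def test_tsv_dosage_duplicate_snp_id_errors(tmp_path):
    path = tmp_path / "geno.tsv"
    path.write_text("sample\tsnpA\tsnpA\ni0\t0\t1\ni1\t1\t2\ni2\t2\t2\n")
    with pytest.raises(GenotypeParseError, match="duplicate"):
        read_genotypes(path, "tsv-dosage")


def test_tsv_dosage_bad_value_errors(tmp_path):
    path = tmp_path / "geno.tsv"
    path.write_text("sample\tsnpA\ni0\t3\ni1\t1\ni2\t0\n")
    with pytest.raises(GenotypeParseError):
        read_genotypes(path, "tsv-dosage")


def test_plink_text_round_trip(tmp_path):
    (tmp_path / "toy.map").write_text("1 snpA 0 100\n2 snpB 0 200\n")
    # snpA alleles A(major)/G(minor): dosage counts G
    # snpB: C/T with T minor; third sample missing at snpB
    (tmp_path / "toy.ped").write_text(
        "f1 i0 0 0 1 0 A A C C\n"
        "f1 i1 0 0 1 0 A G C T\n"
        "f1 i2 0 0 1 0 G G 0 0\n"
    )
    g = read_genotypes(tmp_path / "toy", "plink-text")
    assert g.samples == ["i0", "i1", "i2"]
    assert [s.chromosome for s in g.snps] == ["1", "2"]
    assert np.array_equal(g.calls, [[0, 0], [1, 1], [2, MISSING]])
    assert g.snps[0].alleles == ("A", "G")


def test_plink_text_field_count_mismatch(tmp_path):
    (tmp_path / "bad.map").write_text("1 snpA 0 100\n")
    (tmp_path / "bad.ped").write_text("f1 i0 0 0 1 0 A\n")
    with pytest.raises(GenotypeParseError, match="bad.ped:1"):
        read_genotypes(tmp_path / "bad", "plink-text")


def test_plink_binary_round_trip(tmp_path):
    # hand-packed SNP-major .bed: codes 00=2 copies A1, 10=het, 11=0, 01=NA
    (tmp_path / "toy.fam").write_text(
        "f1 i0 0 0 1 -9\nf1 i1 0 0 1 -9\nf1 i2 0 0 1 -9\n"
    )
    (tmp_path / "toy.bim").write_text(
        "1\tsnpA\t0\t100\tG\tA\n2\tsnpB\t0\t200\tT\tC\n"
    )
    # snpA calls (A1=G dosage): i0=2, i1=1, i2=0 -> codes 00,10,11 ->
    # byte 0b__111000 ; snpB: i0=0, i1=NA, i2=1 -> codes 11,01,10
    bed = bytes([0x6C, 0x1B, 0x01, 0b00111000, 0b00100111])
    (tmp_path / "toy.bed").write_bytes(bed)
    g = read_genotypes(tmp_path / "toy", "plink-binary")
    assert np.array_equal(g.calls, [[2, 0], [1, MISSING], [0, 1]])
    assert g.snps[0].alleles == ("A", "G")


def test_plink_binary_bad_magic(tmp_path):
    (tmp_path / "x.fam").write_text("f1 i0 0 0 1 -9\n")
    (tmp_path / "x.bim").write_text("1\tsnpA\t0\t100\tG\tA\n")
    (tmp_path / "x.bed").write_bytes(b"\x00\x00\x01\x00")
    with pytest.raises(GenotypeParseError, match="magic"):
        read_genotypes(tmp_path / "x", "plink-binary")


def test_unknown_format_rejected(tmp_path):
    with pytest.raises(ValueError, match="format"):
        read_genotypes(tmp_path / "x.tsv", "vcf")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def _hwe_column(p, n, rng):
    return rng.binomial(2, p, size=n).astype(np.int8)


def test_qc_removes_low_maf_and_reports_reason():
    rng = np.random.default_rng(0)
    n = 400
    low = np.array([1] * 32 + [0] * (n - 32), dtype=np.int8)  # maf 0.04
    calls = np.column_stack([low, _hwe_column(0.3, n, rng)])
    g = _matrix(calls)
    assert g.snps[0].maf < 0.05 <= g.snps[1].maf
    filtered, report = qc_filter(g)
    kept_ids = filtered.snp_ids
    assert "s1" in kept_ids and "s0" not in kept_ids
    row = report.set_index("snp_id").loc["s0"]
    assert row["removed"] and "maf" in row["reasons"]


def test_qc_rarest_genotype_boundary():
    # 9 copies of the rarest genotype -> removed; 10 -> kept
    import warnings as _warnings

    for rare_count, expect_kept in [(9, False), (10, True)]:
        calls = np.array([2] * rare_count + [1] * 60 + [0] * 60, dtype=np.int8)
        g = _matrix(calls[:, None])
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            filtered, report = qc_filter(g)
        assert (filtered.n_snps == 1) is expect_kept
        assert report.loc[0, "rarest_count"] == rare_count


def test_qc_keeps_clean_snp_and_flags_missing():
    rng = np.random.default_rng(1)
    col = _hwe_column(0.35, 400, rng)
    col[:20] = MISSING  # missing rate 0.05
    g = _matrix(col[:, None])
    filtered, report = qc_filter(g)
    assert filtered.n_snps == 1
    bad = col.copy()
    bad[:80] = MISSING  # missing rate 0.2
    g2 = _matrix(bad[:, None])
    with pytest.warns(UserWarning, match="no SNPs"):
        filtered2, report2 = qc_filter(g2)
    assert filtered2.n_snps == 0
    assert "missing" in report2.loc[0, "reasons"]


def test_qc_no_survivors_warns_returns_empty():
    calls = np.array([[0], [0], [1]], dtype=np.int8)
    g = _matrix(calls)
    with pytest.warns(UserWarning, match="no SNPs"):
        filtered, _ = qc_filter(g)
    assert filtered.n_snps == 0


@given(st.integers(0, 2**31 - 1))
def test_qc_idempotent(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.01, 0.5, size=8)
    calls = rng.binomial(2, p, size=(60, 8)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.05] = MISSING
    g = _matrix(calls)
    once, _ = qc_filter(g, min_genotype_count=3)
    twice, report = qc_filter(once, min_genotype_count=3)
    assert once.snp_ids == twice.snp_ids
    assert not report["removed"].any()


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------


def test_additive_mapping_and_imputation():
    g = _matrix(np.array([[0, 0], [2, 1], [MISSING, 2]]))
    x = encode_additive(g)
    assert np.allclose(x[:, 0], [0, 2, 1.0])  # mean of (0, 2)
    assert np.allclose(x[:, 1], [0, 1, 2])


def test_heterozygote_mapping_and_imputation():
    g = _matrix(np.array([[1, 0], [1, 1], [MISSING, 2]]))
    h = encode_heterozygote(g)
    assert np.allclose(h[:, 0], [1, 1, 1.0])
    assert np.allclose(h[:, 1], [0, 1, 0])


def test_all_homozygote_column_encodes_to_zeros():
    g = _matrix(np.zeros((4, 1), dtype=np.int8))
    assert np.all(encode_additive(g) == 0)
    assert np.all(encode_heterozygote(g) == 0)


def test_all_missing_column_errors():
    g = _matrix(np.full((4, 1), MISSING, dtype=np.int8))
    with pytest.raises(ValueError, match="missing"):
        encode_additive(g)


@given(st.integers(0, 2**31 - 1))
def test_encodings_commute_with_sample_permutation(seed):
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 3, size=(20, 6)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = MISSING
    g = _matrix(calls)
    perm = rng.permutation(20)
    gp = g.subset_samples(perm)
    assert np.allclose(encode_additive(g)[perm], encode_additive(gp))
    assert np.allclose(encode_heterozygote(g)[perm], encode_heterozygote(gp))


def test_allele_frequencies_ignore_missing():
    g = _matrix(np.array([[2, 0], [2, 1], [MISSING, 1]]))
    assert np.allclose(allele_frequencies(g), [1.0, 1 / 3])


# ---------------------------------------------------------------------------
# Phenotype adjustment and the inverse normal transform
# ---------------------------------------------------------------------------


def test_outlier_beyond_5sd_is_removed_before_regression():
    rng = np.random.default_rng(3)
    vals = rng.standard_normal(200)
    mu, sd = vals.mean(), vals.std()
    vals[0] = mu + 5.5 * sd
    out = adjust_phenotype(PhenotypeVector(vals, "t"))
    assert np.isnan(out.values[0])
    assert (~np.isnan(out.values[1:])).all()


def test_adjust_standardises_and_orthogonalises():
    rng = np.random.default_rng(4)
    cov = pd.DataFrame({"age": rng.normal(50, 10, 150), "sexM": rng.integers(0, 2, 150)})
    y = 0.5 * cov["age"].to_numpy() + rng.standard_normal(150)
    out = adjust_phenotype(PhenotypeVector(y, "t"), covariates=cov)
    v = out.values[~np.isnan(out.values)]
    assert abs(v.mean()) < 1e-10
    assert abs(v.var() - 1) < 1e-10
    for col in cov.columns:
        c = cov[col].to_numpy(float)[~np.isnan(out.values)]
        assert abs(np.dot(v, c - c.mean())) < 1e-8


def test_adjust_no_covariates_is_zscore():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    out = adjust_phenotype(PhenotypeVector(y, "t"))
    z = (y - y.mean()) / y.std()
    assert np.allclose(out.values, z)


def test_adjust_rank_deficient_covariates_warn():
    rng = np.random.default_rng(5)
    a = rng.standard_normal(50)
    cov = pd.DataFrame({"a": a, "b": 2 * a})
    with pytest.warns(UserWarning, match="redundant"):
        adjust_phenotype(PhenotypeVector(rng.standard_normal(50), "t"), covariates=cov)


def test_adjust_too_few_values_errors():
    with pytest.raises(ValueError, match="fewer than 3"):
        adjust_phenotype(PhenotypeVector(np.array([1.0, np.nan, 2.0]), "t"))


def test_blom_transform_of_three_values():
    # Blom fractions for n=3: (0.625, 1.625, 2.625)/3.25
    got = inverse_normal_transform([1.0, 2.0, 3.0])
    expected = stats.norm.ppf(np.array([0.625, 1.625, 2.625]) / 3.25)
    assert np.allclose(got, expected)
    assert got[1] == pytest.approx(0.0)
    assert got[0] == pytest.approx(-got[2])
    assert got[2] == pytest.approx(0.8694, abs=1e-4)


def test_transform_preserves_order_and_handles_ties():
    got = inverse_normal_transform([3.0, 1.0, 1.0, 7.0, np.nan])
    assert np.isnan(got[4])
    assert got[1] == got[2] < got[0] < got[3]


def test_transform_near_identity_on_normal_sample():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(10_000)
    z = inverse_normal_transform(x)
    assert np.corrcoef(x, z)[0, 1] > 0.99


def test_transform_constant_vector_errors():
    with pytest.raises(ValueError, match="constant"):
        inverse_normal_transform([2.0, 2.0, 2.0])
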