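"""Genotype and phenotype input, SNP quality control, and dosage encodings.

Genotypes are biallelic SNP calls stored as integers: 0/1/2 copies of the
counted allele, with :data:`MISSING` (-1) for no-calls.  Three on-disk
dialects are supported: PLINK text (.ped/.map), PLINK binary
(.bed/.bim/.fam, SNP-major), and a plain TSV dosage matrix (header row of
SNP ids, first column the sample id, ``NA`` for missing).

The two encodings used throughout the package are the additive dosage
(AA/AB/BB -> 0/1/2) and the heterozygote dosage (AA/AB/BB -> 0/1/0);
missing calls are mean-imputed per column so the sample size is constant
across SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeMatrix",
    "PhenotypeVector",
    "read_genotypes",
    "qc_filter",
    "encode_additive",
    "encode_heterozygote",
    "allele_frequencies",
    "adjust_phenotype",
    "inverse_normal_transform",
    "read_phenotypes",
]


class GenotypeParseError(ValueError):
    """Malformed genotype file."""


@dataclass
class SnpRecord:
    """Per-SNP metadata.

    ``alleles`` is ``(other, counted)``: the dosage counts copies of the
    second allele.  ``maf``, ``genotype_counts`` and ``missing_rate`` are
    computed from non-missing calls only.
    """

    id: str
    chromosome: str
    position: int
    alleles: tuple[str, str] = ("A", "B")
    maf: float = float("nan")
    genotype_counts: tuple[int, int, int] = (0, 0, 0)
    missing_rate: float = 0.0


@dataclass
class GenotypeMatrix:
    """Samples x SNPs integer genotype calls plus per-SNP metadata."""

    samples: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray  # (n_samples, n_snps), values in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        n, m = self.calls.shape
        if n != len(self.samples):
            raise ValueError(
                f"calls have {n} rows but {len(self.samples)} sample ids"
            )
        if m != len(self.snps):
            raise ValueError(f"calls have {m} columns but {len(self.snps)} SNPs")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).loc[lambda s: s.duplicated()].unique()
            raise GenotypeParseError(f"duplicate SNP id(s): {list(dup)[:5]}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype call {self.calls[i, j]} at sample "
                f"{self.samples[i]}, SNP {self.snps[j].id}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [s.id for s in self.snps],
                "chrom": [s.chromosome for s in self.snps],
                "pos": [s.position for s in self.snps],
                "maf": [s.maf for s in self.snps],
                "missing_rate": [s.missing_rate for s in self.snps],
            }
        )

    def subset_snps(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in index],
            calls=self.calls[:, index].copy(),
        )

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        calls = self.calls[index, :]
        samples = [self.samples[i] for i in index]
        g = GenotypeMatrix(samples=samples, snps=list(self.snps), calls=calls.copy())
        return _with_recomputed_stats(g)

    @classmethod
    def from_calls(
        cls,
        samples: Sequence[str],
        snps: Sequence[SnpRecord],
        calls: np.ndarray,
    ) -> "GenotypeMatrix":
        """Build a matrix and (re)compute maf / counts / missing rate."""
        g = cls(samples=list(samples), snps=list(snps), calls=calls)
        return _with_recomputed_stats(g)


def _with_recomputed_stats(g: GenotypeMatrix) -> GenotypeMatrix:
    calls = g.calls
    n = calls.shape[0]
    for j, rec in enumerate(g.snps):
        col = calls[:, j]
        present = col != MISSING
        n_present = int(present.sum())
        counts = tuple(int((col[present] == k).sum()) for k in (0, 1, 2))
        rec.genotype_counts = counts
        rec.missing_rate = 1.0 - n_present / n if n else 0.0
        if n_present:
            freq = col[present].mean() / 2.0  # counted-allele frequency
            rec.maf = float(min(freq, 1.0 - freq))
        else:
            rec.maf = float("nan")
    return g


@dataclass
class PhenotypeVector:
    """One trait over the sample list; NaN marks an absent value."""

    values: np.ndarray
    trait_name: str = "trait"
    samples: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str | Path,
    format: str = "tsv-dosage",
    snp_map: str | Path | None = None,
) -> GenotypeMatrix:
    """Read genotypes in one of the supported dialects.

    ``path`` is the file for ``tsv-dosage`` and the fileset *prefix* (or any
    member file) for the PLINK dialects.  ``snp_map`` optionally supplies
    chromosome/position for the dosage dialect (TSV: snp_id, chrom, pos).
    """
    path = Path(path)
    if format == "tsv-dosage":
        return _read_tsv_dosage(path, snp_map)
    if format == "plink-text":
        return _read_plink_text(path)
    if format == "plink-binary":
        return _read_plink_binary(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_tsv_dosage(path: Path, snp_map: str | Path | None) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = pd.Series(header).loc[lambda s: s.duplicated()].unique()
        raise GenotypeParseError(f"{path}: duplicate SNP id(s): {list(dup)[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    snp_ids = list(df.columns)
    vals = df.to_numpy()
    calls = np.full(vals.shape, MISSING, dtype=np.int8)
    ok = (vals != "NA") & (vals != "nan") & ~pd.isna(vals)
    try:
        parsed = vals[ok].astype(float)
    except ValueError as exc:
        raise GenotypeParseError(f"{path}: non-numeric dosage entry ({exc})")
    if parsed.size and (~np.isin(parsed, (0.0, 1.0, 2.0))).any():
        bad = parsed[~np.isin(parsed, (0.0, 1.0, 2.0))][0]
        raise GenotypeParseError(f"{path}: dosage {bad} not in {{0,1,2,NA}}")
    calls[ok] = parsed.astype(np.int8)

    meta: dict[str, tuple[str, int]] = {}
    if snp_map is not None:
        mp = pd.read_csv(snp_map, sep="\t", dtype={"snp_id": str, "chrom": str})
        meta = {r.snp_id: (r.chrom, int(r.pos)) for r in mp.itertuples()}
    snps = []
    for j, sid in enumerate(snp_ids):
        chrom, pos = meta.get(sid, ("0", j + 1))
        snps.append(SnpRecord(id=sid, chromosome=chrom, position=pos))
    return GenotypeMatrix.from_calls(list(df.index.astype(str)), snps, calls)


def _plink_prefix(path: Path, exts: tuple[str, ...]) -> Path:
    if path.suffix in exts:
        return path.with_suffix("")
    return path


def _read_plink_text(path: Path) -> GenotypeMatrix:
    prefix = _plink_prefix(path, (".ped", ".map"))
    ped, mp = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    for f in (ped, mp):
        if not f.exists():
            raise FileNotFoundError(f)
    snps: list[SnpRecord] = []
    with open(mp) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) not in (3, 4):
                raise GenotypeParseError(f"{mp}:{lineno}: expected 3-4 columns")
            chrom, sid = parts[0], parts[1]
            pos = int(parts[-1])
            snps.append(SnpRecord(id=sid, chromosome=chrom, position=pos))
    m = len(snps)
    samples: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            samples.append(parts[1])
            allele_rows.append(parts[6:])
    n = len(samples)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    alleles_arr = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2), object)
    for j, rec in enumerate(snps):
        a = alleles_arr[:, j, :]
        flat = a.ravel()
        observed = sorted(set(flat) - {"0"})
        if len(observed) > 2:
            raise GenotypeParseError(
                f"{ped}: SNP {rec.id} has more than two alleles: {observed}"
            )
        if not observed:
            rec.alleles = ("0", "0")
            continue
        if len(observed) == 1:
            counted, other = observed[0], "0"
            rec.alleles = (other, counted)
            dos = (a == counted).sum(axis=1)
        else:
            x, y = observed
            nx, ny = (flat == x).sum(), (flat == y).sum()
            # counted allele = minor (ties -> lexicographically later)
            if nx == ny:
                counted, other = max(x, y), min(x, y)
            elif nx < ny:
                counted, other = x, y
            else:
                counted, other = y, x
            rec.alleles = (other, counted)
            dos = (a == counted).sum(axis=1)
        missing = (a == "0").any(axis=1)
        calls[:, j] = np.where(missing, MISSING, dos)
    return GenotypeMatrix.from_calls(samples, snps, calls)


def _read_plink_binary(path: Path) -> GenotypeMatrix:
    prefix = _plink_prefix(path, (".bed", ".bim", ".fam"))
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    samples = list(fam_df[1])
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    snps = [
        SnpRecord(
            id=r[1],
            chromosome=str(r[0]),
            position=int(r[3]),
            alleles=(str(r[5]), str(r[4])),  # A1 is the counted allele
        )
        for r in bim_df.itertuples(index=False)
    ]
    n, m = len(samples), len(snps)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise GenotypeParseError(f"{bed}: not a PLINK .bed file (bad magic)")
    if raw[2] != 0x01:
        raise GenotypeParseError(f"{bed}: only SNP-major .bed is supported")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise GenotypeParseError(
            f"{bed}: expected {bytes_per_snp * m} data bytes, found {body.size}"
        )
    body = body.reshape(m, bytes_per_snp)
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(m, -1)[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
    calls = lut[two_bit].T.copy()
    return GenotypeMatrix.from_calls(samples, snps, calls)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype/covariate TSV: first column sample id, one column per trait."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# QC and encodings
# ---------------------------------------------------------------------------


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.1,
    min_genotype_count: int = 10,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the SNP QC: MAF floor, missing-rate cap, rarest-genotype floor.

    Returns the filtered matrix and a report with one row per SNP listing the
    failing rule(s) for each removed SNP.
    """
    if not (0 <= maf_min <= 0.5 and 0 <= missing_max <= 1 and min_genotype_count >= 0):
        raise ValueError("QC thresholds out of range")
    rows = []
    keep: list[int] = []
    for j, rec in enumerate(g.snps):
        rarest = min(rec.genotype_counts)
        reasons = []
        if not (rec.maf >= maf_min):  # NaN maf (all-missing) also fails
            reasons.append("maf")
        if rec.missing_rate > missing_max:
            reasons.append("missing")
        if rarest < min_genotype_count:
            reasons.append("rarest_genotype")
        if not reasons:
            keep.append(j)
        rows.append(
            {
                "snp_id": rec.id,
                "maf": rec.maf,
                "missing_rate": rec.missing_rate,
                "rarest_count": rarest,
                "removed": bool(reasons),
                "reasons": ",".join(reasons),
            }
        )
    report = pd.DataFrame(rows)
    if not keep:
        warnings.warn("qc_filter: no SNPs passed quality control", stacklevel=2)
    return g.subset_snps(keep), report


def _encode(g: GenotypeMatrix, mapping: np.ndarray) -> np.ndarray:
    calls = g.calls
    out = np.empty(calls.shape, dtype=float)
    miss = calls == MISSING
    clipped = np.where(miss, 0, calls)
    out = mapping[clipped].astype(float)
    if miss.any():
        all_missing = miss.all(axis=0)
        if all_missing.any():
            j = int(np.argmax(all_missing))
            raise ValueError(f"SNP {g.snps[j].id}: all calls missing, cannot impute")
        out[miss] = np.nan
        col_mean = np.nanmean(out, axis=0)
        out = np.where(np.isnan(out), col_mean[None, :], out)
    return out


def encode_additive(g: GenotypeMatrix) -> np.ndarray:
    """AA/AB/BB -> 0/1/2 dosage of the counted allele; missing -> column mean."""
    if g.n_snps == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    return _encode(g, np.array([0.0, 1.0, 2.0]))


def encode_heterozygote(g: GenotypeMatrix) -> np.ndarray:
    """AA/AB/BB -> 0/1/0 heterozygote dosage; missing -> column mean."""
    if g.n_snps == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    return _encode(g, np.array([0.0, 1.0, 0.0]))


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """In-sample frequency of the counted allele, from non-missing calls."""
    calls = g.calls
    present = calls != MISSING
    with np.errstate(invalid="ignore"):
        freqs = np.where(present, calls, 0).sum(axis=0) / (2.0 * present.sum(axis=0))
    return freqs


# ---------------------------------------------------------------------------
# Phenotype preparation
# ---------------------------------------------------------------------------


def adjust_phenotype(
    y: PhenotypeVector,
    covariates: pd.DataFrame | np.ndarray | None = None,
    sd_clip: float = 5.0,
) -> PhenotypeVector:
    """Clip outliers, regress out covariates, standardise the residuals.

    Values more than ``sd_clip`` standard deviations from the raw-trait mean
    are set absent *before* the covariate regression.  Covariates (numeric
    columns used as-is, non-numeric dummy-coded) are removed by OLS with an
    intercept; redundant columns are dropped with a warning.  Residuals are
    returned with mean 0 and variance 1 over the present values.
    """
    vals = np.asarray(y.values, dtype=float).copy()
    present = ~np.isnan(vals)
    mu, sd = vals[present].mean(), vals[present].std()
    if sd > 0:
        vals[present & (np.abs(vals - mu) > sd_clip * sd)] = np.nan
    present = ~np.isnan(vals)
    if present.sum() < 3:
        raise ValueError("fewer than 3 present phenotype values after clipping")

    if covariates is None:
        X = np.ones((int(present.sum()), 1))
    else:
        if isinstance(covariates, np.ndarray):
            cov = pd.DataFrame(np.asarray(covariates, dtype=float))
        else:
            cov = covariates.copy()
        if len(cov) != len(vals):
            raise ValueError("covariate rows do not align with samples")
        cov = pd.get_dummies(cov, drop_first=True, dtype=float)
        X = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])[present]
        # drop rank-deficient columns
        q, r, piv = _qr_pivot(X)
        rank = int((np.abs(np.diag(r)) > 1e-10 * abs(r[0, 0])).sum()) if r.size else 0
        if rank < X.shape[1]:
            warnings.warn(
                f"adjust_phenotype: dropping {X.shape[1] - rank} redundant "
                "covariate column(s)",
                stacklevel=2,
            )
            X = X[:, sorted(piv[:rank])]
    yy = vals[present]
    beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ beta
    s = resid.std()
    if s == 0:
        raise ValueError("residuals are constant; cannot standardise")
    resid = (resid - resid.mean()) / s
    out = np.full_like(vals, np.nan)
    out[present] = resid
    return PhenotypeVector(values=out, trait_name=y.trait_name, samples=y.samples)


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def inverse_normal_transform(v: np.ndarray | Sequence[float]) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    z_i = Phi^{-1}((rank_i - 3/8) / (n + 1/4)), ties sharing the average
    rank; NaNs are preserved.
    """
    v = np.asarray(v, dtype=float)
    out = np.full(v.shape, np.nan)
    present = ~np.isnan(v)
    x = v[present]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 present values")
    if np.ptp(x) == 0:
        raise ValueError("constant vector cannot be normal-transformed")
    ranks = stats.rankdata(x, method="average")
    out[present] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out
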