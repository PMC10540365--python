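"""Additive and dominance genetic relationship matrices (GRMs) and pruning.

The additive GRM uses the column-standardised coding
``z = (x - 2p) / sqrt(2pq)`` and the dominance GRM the orthogonal
dominance-deviation coding (genotype 0/1/2 -> 0 / 2p / 4p-2, centred by
2p^2, scaled by 2pq), so that under Hardy-Weinberg equilibrium the two
codings are uncorrelated and the additive and dominance variance components
are separable.  Both matrices are ``(1/m) Z Z'`` over m SNPs.

Close relatives inflate mixed-model variance estimates in these stocks;
pairs whose additive relatedness exceeds a threshold (default 0.7) are
randomly downsampled to single individuals, after which the caller rebuilds
the GRMs on the retained samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, allele_frequencies, encode_additive

__all__ = [
    "GrmPair",
    "additive_grm",
    "dominance_grm",
    "build_grms",
    "prune_related",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_gcta_grm",
    "read_gcta_grm",
]


@dataclass
class GrmPair:
    """Additive (K_a) and dominance (K_d) GRMs over a shared sample list."""

    samples: list[str]
    K_a: np.ndarray
    K_d: np.ndarray
    n_snps_used: int

    def __post_init__(self) -> None:
        n = len(self.samples)
        for name, K in (("K_a", self.K_a), ("K_d", self.K_d)):
            K = np.asarray(K, dtype=float)
            if K.shape != (n, n):
                raise ValueError(f"{name} shape {K.shape} != ({n}, {n})")
            if np.abs(K - K.T).max() > 1e-10:
                raise ValueError(f"{name} is not symmetric")
        if not (np.isfinite(np.diag(self.K_a)).all() and np.isfinite(np.diag(self.K_d)).all()):
            raise ValueError("GRM diagonals must be finite")


def _check_freqs(freqs: np.ndarray, m: int) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (m,):
        raise ValueError(f"expected {m} allele frequencies, got {freqs.shape}")
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError(
            "monomorphic SNP (p in {0,1}); run QC (MAF filter) before building GRMs"
        )
    return freqs


def additive_grm(x_add: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """K_a = (1/m) Z Z' with z = (x - 2p)/sqrt(2p(1-p)) per SNP."""
    x_add = np.asarray(x_add, dtype=float)
    n, m = x_add.shape
    p = _check_freqs(freqs, m)
    z = (x_add - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return (z @ z.T) / m


def dominance_grm(g: GenotypeMatrix | np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Dominance GRM from the orthogonal 0 / 2p / 4p-2 recode.

    Accepts a :class:`GenotypeMatrix` or a raw integer call matrix (values
    in {0,1,2,MISSING}).  Missing calls contribute 0 after centring.  The
    standardised codes are (-2p^2, 2pq, -2q^2)/(2pq) for genotypes 0/1/2.
    """
    calls = g.calls if isinstance(g, GenotypeMatrix) else np.asarray(g)
    n, m = calls.shape
    p = _check_freqs(freqs, m)
    q = 1.0 - p
    codes = np.empty((n, m), dtype=float)
    # per-genotype dominance deviations, centred by 2p^2
    c0, c1, c2 = -2.0 * p**2, 2.0 * p * q, -2.0 * q**2
    codes = np.select(
        [calls == 0, calls == 1, calls == 2],
        [np.broadcast_to(c0, (n, m)), np.broadcast_to(c1, (n, m)), np.broadcast_to(c2, (n, m))],
        default=0.0,  # missing: contributes 0 after centring
    )
    w = codes / (2.0 * p * q)
    return (w @ w.T) / m


def build_grms(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> GrmPair:
    """Build K_a and K_d from a QC'd genotype matrix (in-sample frequencies)."""
    if freqs is None:
        freqs = allele_frequencies(g)
    x = encode_additive(g)
    K_a = additive_grm(x, freqs)
    K_d = dominance_grm(g, freqs)
    return GrmPair(samples=list(g.samples), K_a=K_a, K_d=K_d, n_snps_used=g.n_snps)


def prune_related(
    K_a: np.ndarray,
    threshold: float = 0.7,
    seed: int = 0,
    samples: list[str] | None = None,
) -> list:
    """Randomly downsample pairs with |additive relatedness| above threshold.

    While any retained pair has ``|K_a[i, j]| > threshold``, pick a uniformly
    random offending pair and drop a uniformly random member.  Returns the
    retained sample identifiers (or indices if ``samples`` is None), in the
    original order.  Seed-deterministic.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    K = np.asarray(K_a, dtype=float)
    n = K.shape[0]
    rng = np.random.default_rng(seed)
    retained = np.ones(n, dtype=bool)
    while True:
        idx = np.flatnonzero(retained)
        sub = np.abs(K[np.ix_(idx, idx)])
        np.fill_diagonal(sub, 0.0)
        ii, jj = np.nonzero(np.triu(sub > threshold, k=1))
        if ii.size == 0:
            break
        k = rng.integers(ii.size)
        pair = (idx[ii[k]], idx[jj[k]])
        retained[pair[rng.integers(2)]] = False
    kept = np.flatnonzero(retained)
    if samples is not None:
        return [samples[i] for i in kept]
    return list(kept)


# ---------------------------------------------------------------------------
# GRM input/output
# ---------------------------------------------------------------------------


def write_grm_tsv(path: str | Path, K: np.ndarray, samples: list[str]) -> None:
    pd.DataFrame(K, index=samples, columns=samples).to_csv(path, sep="\t")


def read_grm_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(s) for s in df.index]


def write_gcta_grm(prefix: str | Path, K: np.ndarray, samples: list[str], n_snps: int) -> None:
    """GCTA-compatible binary GRM: .grm.bin (float32 lower triangle,
    row-major including the diagonal), .grm.N.bin, .grm.id."""
    prefix = Path(prefix)
    n = len(samples)
    tril = K[np.tril_indices(n)].astype(np.float32)
    tril.tofile(Path(str(prefix) + ".grm.bin"))
    np.full(tril.shape, n_snps, dtype=np.float32).tofile(Path(str(prefix) + ".grm.N.bin"))
    with open(Path(str(prefix) + ".grm.id"), "w") as fh:
        for s in samples:
            fh.write(f"{s}\t{s}\n")


def read_gcta_grm(prefix: str | Path) -> tuple[np.ndarray, list[str], int]:
    prefix = Path(prefix)
    ids = pd.read_csv(Path(str(prefix) + ".grm.id"), sep="\t", header=None)
    samples = [str(s) for s in ids[1]]
    n = len(samples)
    tril = np.fromfile(Path(str(prefix) + ".grm.bin"), dtype=np.float32)
    if tril.size != n * (n + 1) // 2:
        raise ValueError("GRM binary size does not match id file")
    K = np.zeros((n, n))
    K[np.tril_indices(n)] = tril
    K = K + np.tril(K, -1).T
    counts = np.fromfile(Path(str(prefix) + ".grm.N.bin"), dtype=np.float32)
    n_snps = int(counts[0]) if counts.size else 0
    return K, samples, n_snps
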