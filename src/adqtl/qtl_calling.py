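"""Significance thresholds, peak calling, LOD-drop intervals, dominance classes.

Two Bonferroni-style thresholds are used: suggestive (1/N_SNP, one false
positive expected per genome scan) and genome-wide (0.05/N_SNP).  Printed
threshold values are the exact -log10 values floored to one decimal;
significance calls always compare the exact values.

QTLs are called per chromosome by iterative peak-picking on -log10 p of the
AD-model 2-df test: take the strongest remaining SNP above threshold, span
its 2-LOD-drop interval, assign the contained SNPs to that QTL, repeat.
Each call is classified by the degree-of-dominance ratio |t_Dom/t_Add|
(A < 0.2 <= PD < 0.8 <= CD < 1.2 <= OD) and annotated with the classical
single-locus variance partition at the peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .varcomp import single_locus_partition

__all__ = [
    "ThresholdSet",
    "DominanceClass",
    "QtlCall",
    "significance_thresholds",
    "classify_dominance",
    "lod_drop_interval",
    "call_qtls",
    "qtl_table",
]


@dataclass
class ThresholdSet:
    n_snp: int
    suggestive_logp: float  # -log10(1/N)
    genomewide_logp: float  # -log10(0.05/N)

    @staticmethod
    def _display(x: float) -> float:
        return math.floor(x * 10.0) / 10.0

    @property
    def suggestive_display(self) -> float:
        return self._display(self.suggestive_logp)

    @property
    def genomewide_display(self) -> float:
        return self._display(self.genomewide_logp)

    def logp(self, level: str) -> float:
        if level == "suggestive":
            return self.suggestive_logp
        if level == "genomewide":
            return self.genomewide_logp
        raise ValueError(f"unknown significance level {level!r}")


def significance_thresholds(n_snp: int, alpha: float = 0.05) -> ThresholdSet:
    """Suggestive (1/N) and genome-wide (alpha/N) -log10 p thresholds."""
    if n_snp < 1:
        raise ValueError("n_snp must be >= 1")
    return ThresholdSet(
        n_snp=n_snp,
        suggestive_logp=math.log10(n_snp),
        genomewide_logp=math.log10(n_snp / alpha),
    )


@dataclass
class DominanceClass:
    label: str  # A / PD / CD / OD
    ratio: float  # |t_Dom / t_Add|
    log2_ratio: float
    degenerate: bool = False


def classify_dominance(t_add: float, t_dom: float) -> DominanceClass:
    """Degree-of-dominance class from the AD-model t-statistics.

    Bands on the raw ratio |t_dom|/|t_add|, left-closed:
    A: < 0.2, PD: [0.2, 0.8), CD: [0.8, 1.2), OD: >= 1.2.
    A zero additive statistic with nonzero dominance gives an infinite
    ratio (OD); both zero degenerates to A with a flag.
    """
    ta, td = abs(t_add), abs(t_dom)
    if ta == 0 and td == 0:
        return DominanceClass("A", 0.0, -math.inf, degenerate=True)
    ratio = math.inf if ta == 0 else td / ta
    log2r = math.log2(ratio) if 0 < ratio < math.inf else (-math.inf if ratio == 0 else math.inf)
    if ratio < 0.2:
        label = "A"
    elif ratio < 0.8:
        label = "PD"
    elif ratio < 1.2:
        label = "CD"
    else:
        label = "OD"
    return DominanceClass(label, ratio, log2r)


def lod_drop_interval(
    chrom_scan: pd.DataFrame,
    peak_index: int,
    drop: float = 2.0,
    logp_column: str = "logp",
) -> tuple[int, int]:
    """2-LOD-drop interval around a peak on one chromosome.

    ``chrom_scan`` must be position-ordered with a -log10 p column.  Walking
    outward from the peak, the boundary is the last SNP (inclusive) before
    the first SNP whose score falls below ``peak - drop``; if none falls
    below, the chromosome's terminal SNP bounds the interval.  Returns
    (start bp, end bp).
    """
    lo, hi = _lod_drop_bounds(
        chrom_scan[logp_column].to_numpy(dtype=float), peak_index, drop
    )
    pos = chrom_scan["pos"].to_numpy()
    return int(pos[lo]), int(pos[hi])


def _lod_drop_bounds(logp: np.ndarray, peak_index: int, drop: float) -> tuple[int, int]:
    m = logp.size
    if not 0 <= peak_index < m:
        raise IndexError(f"peak index {peak_index} out of range for {m} SNPs")
    cutoff = logp[peak_index] - drop
    lo = peak_index
    while lo - 1 >= 0 and logp[lo - 1] >= cutoff:
        lo -= 1
    hi = peak_index
    while hi + 1 < m and logp[hi + 1] >= cutoff:
        hi += 1
    return lo, hi


@dataclass
class QtlCall:
    trait: str
    peak_snp: str
    chromosome: str
    peak_pos: int
    peak_logp: float
    interval: tuple[str, int, int]  # (chrom, start bp, end bp)
    dominance: DominanceClass
    beta_a: float
    beta_d: float
    t_add: float
    t_dom: float
    freq: float
    logp_A: float
    logp_AvsAD: float
    v_a_qtl: float
    v_d_qtl: float
    novel_vs_A: bool
    n_snps_in_interval: int = 0


def _neglog10(p: np.ndarray | float) -> np.ndarray | float:
    return -np.log10(np.clip(p, 1e-300, None))


def call_qtls(
    scan: pd.DataFrame,
    thresholds: ThresholdSet,
    level: str = "suggestive",
    trait: str = "trait",
    drop: float = 2.0,
    p_column: str = "p_AD",
) -> list[QtlCall]:
    """Iterative peak-picking of independent QTLs from a scan table.

    Per chromosome: take the strongest remaining SNP with
    ``-log10 p >= threshold``, form its LOD-drop interval over the remaining
    SNPs, assign contained SNPs to the call, and repeat.  Intervals are
    disjoint by construction.  ``novel_vs_A`` marks peaks not significant
    under the A model at the same level.
    """
    if scan.empty:
        return []
    cut = thresholds.logp(level)
    calls: list[QtlCall] = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        sub = sub.sort_values("pos").reset_index(drop=True)
        logp = np.asarray(_neglog10(sub[p_column].to_numpy(dtype=float)))
        remaining = np.ones(len(sub), dtype=bool)
        while True:
            idx = np.flatnonzero(remaining)
            if idx.size == 0:
                break
            rel = logp[idx]
            if rel.max() < cut:
                break
            peak_rel = int(np.argmax(rel))
            peak = idx[peak_rel]
            # restrict the walk to the contiguous unassigned run around the
            # peak so intervals never span a previously called QTL
            seg_lo = peak_rel
            while seg_lo - 1 >= 0 and idx[seg_lo - 1] == idx[seg_lo] - 1:
                seg_lo -= 1
            seg_hi = peak_rel
            while seg_hi + 1 < idx.size and idx[seg_hi + 1] == idx[seg_hi] + 1:
                seg_hi += 1
            seg = rel[seg_lo : seg_hi + 1]
            lo_rel, hi_rel = _lod_drop_bounds(seg, peak_rel - seg_lo, drop)
            members = idx[seg_lo + lo_rel : seg_lo + hi_rel + 1]
            row = sub.iloc[peak]
            dom = classify_dominance(row["t_add"], row["t_dom"])
            try:
                va, vd = single_locus_partition(row["beta_a"], row["beta_d"], row["freq"])
            except ValueError:
                va = vd = float("nan")
            logp_a = float(_neglog10(row["p_A"]))
            calls.append(
                QtlCall(
                    trait=trait,
                    peak_snp=str(row["snp_id"]),
                    chromosome=str(chrom),
                    peak_pos=int(row["pos"]),
                    peak_logp=float(logp[peak]),
                    interval=(
                        str(chrom),
                        int(sub["pos"].iloc[members[0]]),
                        int(sub["pos"].iloc[members[-1]]),
                    ),
                    dominance=dom,
                    beta_a=float(row["beta_a"]),
                    beta_d=float(row["beta_d"]),
                    t_add=float(row["t_add"]),
                    t_dom=float(row["t_dom"]),
                    freq=float(row["freq"]),
                    logp_A=logp_a,
                    logp_AvsAD=float(_neglog10(row["p_AvsAD"])),
                    v_a_qtl=float(va),
                    v_d_qtl=float(vd),
                    novel_vs_A=bool(logp_a < cut),
                    n_snps_in_interval=int(members.size),
                )
            )
            remaining[members] = False
    calls.sort(key=lambda c: -c.peak_logp)
    return calls


_QTL_TABLE_COLUMNS = [
    "trait", "chrom", "peak_snp", "peak_pos", "interval_start", "interval_end",
    "peak_logp_AD", "logp_A", "logp_AvsAD", "beta_a", "beta_d", "t_add",
    "t_dom", "ratio", "log2_ratio", "class", "freq", "v_a_qtl", "v_d_qtl",
    "novel_vs_A",
]


def qtl_table(calls: list[QtlCall]) -> pd.DataFrame:
    """Flatten QTL calls into the standard results table."""
    rows = []
    for c in calls:
        rows.append(
            {
                "trait": c.trait,
                "chrom": c.chromosome,
                "peak_snp": c.peak_snp,
                "peak_pos": c.peak_pos,
                "interval_start": c.interval[1],
                "interval_end": c.interval[2],
                "peak_logp_AD": c.peak_logp,
                "logp_A": c.logp_A,
                "logp_AvsAD": c.logp_AvsAD,
                "beta_a": c.beta_a,
                "beta_d": c.beta_d,
                "t_add": c.t_add,
                "t_dom": c.t_dom,
                "ratio": c.dominance.ratio,
                "log2_ratio": c.dominance.log2_ratio,
                "class": c.dominance.label,
                "freq": c.freq,
                "v_a_qtl": c.v_a_qtl,
                "v_d_qtl": c.v_d_qtl,
                "novel_vs_A": c.novel_vs_A,
            }
        )
    return pd.DataFrame(rows, columns=_QTL_TABLE_COLUMNS)
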