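"""Expression-QTL layers: cis/trans annotation, dominance enrichment,
hotspots, cross-tissue colocalisation, and isoform-level analyses.

An eQTL is a QTL call whose trait is the expression of a gene or isoform.
It is cis-acting when the peak SNP lies on the target's chromosome within
2 Mb of the gene span (distance 0 inside the span), otherwise trans.  For
enrichment the four dominance classes are collapsed to generalized groups:
G-Add (A + PD) versus G-Dom (CD + OD); dominance-by-regulation enrichment
uses the two-sided Fisher exact test, isoform-count enrichment the Pearson
chi-squared test without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, PhenotypeVector, inverse_normal_transform
from .qtl_calling import QtlCall, ThresholdSet, call_qtls, significance_thresholds
from .relatedness import GrmPair
from .scan import genome_scan
from .varcomp import VarianceComponents, reml_fit

__all__ = [
    "FeatureAnnotation",
    "EqtlCall",
    "Hotspot",
    "read_annotation",
    "classify_cis_trans",
    "generalized_group",
    "dominance_cis_trans_enrichment",
    "fisher_exact_2x2",
    "detect_hotspots",
    "cross_tissue_coloc",
    "sum_isoforms",
    "classify_isoform_pair",
    "multi_isoform_enrichment",
    "map_eqtls",
    "eqtl_table",
]

CIS_WINDOW = 2_000_000  # bp


@dataclass
class FeatureAnnotation:
    feature_id: str
    gene_id: str
    chromosome: str
    start: int
    end: int
    n_isoforms: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.feature_id}: start > end")


@dataclass
class EqtlCall:
    qtl: QtlCall
    target: FeatureAnnotation
    regulation: str  # cis / trans
    generalized: str  # G-Add / G-Dom

    @property
    def interval(self) -> tuple[str, int, int]:
        return self.qtl.interval

    @property
    def n_isoforms(self) -> int:
        return self.target.n_isoforms


@dataclass
class Hotspot:
    chromosome: str
    start: int
    end: int
    members: list[EqtlCall]
    n_trans: int
    n_distinct_targets: int


def read_annotation(path: str | Path) -> list[FeatureAnnotation]:
    """BED-like TSV: feature_id, gene_id, chrom, start, end[, n_isoforms]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    feats = [
        FeatureAnnotation(
            feature_id=str(r.feature_id),
            gene_id=str(r.gene_id),
            chromosome=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            n_isoforms=int(getattr(r, "n_isoforms", 1)),
        )
        for r in df.itertuples()
    ]
    return annotate_isoform_counts(feats)


def annotate_isoform_counts(features: list[FeatureAnnotation]) -> list[FeatureAnnotation]:
    """Set n_isoforms to the number of features sharing each gene_id."""
    counts: dict[str, int] = {}
    for f in features:
        counts[f.gene_id] = counts.get(f.gene_id, 0) + 1
    for f in features:
        f.n_isoforms = counts[f.gene_id]
    return features


def classify_cis_trans(
    peak_chrom: str,
    peak_pos: int,
    target: FeatureAnnotation,
    window: int = CIS_WINDOW,
) -> str:
    """cis iff same chromosome and min boundary distance < window.

    The distance is 0 (cis for any positive window) when the peak lies
    inside the gene span; invariant to swapping the start/end labels.
    """
    if str(peak_chrom) != str(target.chromosome):
        return "trans"
    lo, hi = min(target.start, target.end), max(target.start, target.end)
    if lo <= peak_pos <= hi:
        dist = 0
    else:
        dist = min(abs(peak_pos - lo), abs(peak_pos - hi))
    return "cis" if dist < window else "trans"


def generalized_group(label: str) -> str:
    """Collapse A/PD -> G-Add and CD/OD -> G-Dom."""
    if label in ("A", "PD"):
        return "G-Add"
    if label in ("CD", "OD"):
        return "G-Dom"
    raise ValueError(f"unknown dominance class {label!r}")


# ---------------------------------------------------------------------------
# Enrichment tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (odds ratio, p)."""
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def dominance_cis_trans_enrichment(
    eqtls: list[EqtlCall],
) -> tuple[float, float, pd.DataFrame]:
    """Fisher exact test of (G-Add, G-Dom) x (cis, trans) counts."""
    table = pd.DataFrame(
        0, index=["G-Add", "G-Dom"], columns=["cis", "trans"], dtype=int
    )
    for e in eqtls:
        table.loc[e.generalized, e.regulation] += 1
    counts = table.to_numpy()
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        empty_rows = [i for i, s in zip(table.index, counts.sum(axis=1)) if s == 0]
        empty_cols = [c for c, s in zip(table.columns, counts.sum(axis=0)) if s == 0]
        raise ValueError(
            f"empty margin in enrichment table (rows: {empty_rows}, cols: {empty_cols})"
        )
    odds, p = fisher_exact_2x2(counts)
    return odds, p, table


def multi_isoform_enrichment(
    eqtls: list[EqtlCall],
) -> tuple[float, float, pd.DataFrame, dict]:
    """Pearson chi-squared (1 df, no continuity correction) of
    (G-Add, G-Dom) x (single-isoform, multi-isoform) counts.

    Also reports the G-Dom : G-Add ratio per isoform stratum.  A warning
    string is attached in the extras dict when an expected cell is < 1.
    """
    table = pd.DataFrame(
        0, index=["G-Add", "G-Dom"], columns=["single", "multi"], dtype=int
    )
    for e in eqtls:
        table.loc[e.generalized, "multi" if e.n_isoforms > 1 else "single"] += 1
    counts = table.to_numpy()
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("one isoform-count stratum is empty")
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    extras = {
        "ratio_single": _safe_ratio(table.loc["G-Dom", "single"], table.loc["G-Add", "single"]),
        "ratio_multi": _safe_ratio(table.loc["G-Dom", "multi"], table.loc["G-Add", "multi"]),
    }
    if (expected < 1).any():
        extras["warning"] = "expected cell count below 1; chi-squared unreliable"
    return float(chi2), float(p), table, extras


def _safe_ratio(num: float, den: float) -> float:
    return float(num) / float(den) if den else float("inf")


# ---------------------------------------------------------------------------
# Hotspots and colocalisation
# ---------------------------------------------------------------------------


def detect_hotspots(eqtls: list[EqtlCall] | list[QtlCall], min_members: int = 5) -> list[Hotspot]:
    """Connected components of the interval-overlap graph, per chromosome.

    Because genomic-interval overlap components are exactly the merged runs
    of a sorted sweep, components are found by sorting member intervals and
    cutting wherever the next interval starts after the running maximum end.
    Components with >= min_members become hotspots spanning the union of
    member intervals.
    """
    by_chrom: dict[str, list] = {}
    for e in eqtls:
        chrom, start, end = e.interval
        by_chrom.setdefault(str(chrom), []).append((start, end, e))
    hotspots: list[Hotspot] = []
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: (t[0], t[1]))
        cluster: list = []
        max_end = None
        for start, end, e in items + [(None, None, None)]:
            if start is None or (max_end is not None and start > max_end):
                if len(cluster) >= min_members:
                    members = [c[2] for c in cluster]
                    trans = sum(
                        1 for m in members if getattr(m, "regulation", "trans") == "trans"
                    )
                    targets = {
                        getattr(getattr(m, "target", None), "gene_id", id(m))
                        for m in members
                    }
                    hotspots.append(
                        Hotspot(
                            chromosome=chrom,
                            start=min(c[0] for c in cluster),
                            end=max(c[1] for c in cluster),
                            members=members,
                            n_trans=trans,
                            n_distinct_targets=len(targets),
                        )
                    )
                cluster = []
                max_end = None
            if start is None:
                break
            cluster.append((start, end, e))
            max_end = end if max_end is None else max(max_end, end)
    hotspots.sort(key=lambda h: (h.chromosome, h.start))
    return hotspots


def _intervals_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    return str(a[0]) == str(b[0]) and a[1] <= b[2] and b[1] <= a[2]


def cross_tissue_coloc(
    eqtls_t1: list[EqtlCall], eqtls_t2: list[EqtlCall]
) -> pd.DataFrame:
    """Pairs of eQTLs with overlapping intervals across two tissues.

    tissue-consistent (tc) when both regulate the same gene, otherwise
    tissue-specific (ts).
    """
    rows = []
    for e1 in eqtls_t1:
        for e2 in eqtls_t2:
            if not _intervals_overlap(e1.interval, e2.interval):
                continue
            label = "tissue-consistent" if e1.target.gene_id == e2.target.gene_id else "tissue-specific"
            rows.append(
                {
                    "chrom": e1.interval[0],
                    "gene_t1": e1.target.gene_id,
                    "gene_t2": e2.target.gene_id,
                    "feature_t1": e1.target.feature_id,
                    "feature_t2": e2.target.feature_id,
                    "peak_t1": e1.qtl.peak_snp,
                    "peak_t2": e2.qtl.peak_snp,
                    "label": label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "gene_t1", "gene_t2", "feature_t1", "feature_t2",
            "peak_t1", "peak_t2", "label",
        ],
    )


# ---------------------------------------------------------------------------
# Isoform-level analyses
# ---------------------------------------------------------------------------


def sum_isoforms(
    iso_expr: pd.DataFrame, annot: list[FeatureAnnotation]
) -> pd.DataFrame:
    """Gene expression = row-wise sum of constituent isoform columns."""
    gene_of = {f.feature_id: f.gene_id for f in annot}
    unknown = [c for c in iso_expr.columns if c not in gene_of]
    if unknown:
        raise KeyError(f"isoform(s) with no annotated gene: {unknown[:5]}")
    groups = iso_expr.T.groupby([gene_of[c] for c in iso_expr.columns]).sum().T
    groups.index = iso_expr.index
    return groups


def classify_isoform_pair(
    eqtl_a: EqtlCall, eqtl_b: EqtlCall
) -> str:
    """antagonistic / synergistic / independent for two isoform eQTLs.

    Isoforms whose eQTL intervals do not overlap are independent; otherwise
    the pair is antagonistic when the signed additive effects at the
    respective peaks have opposite signs, synergistic when the same sign.
    """
    for e in (eqtl_a, eqtl_b):
        if e.qtl.beta_a is None or np.isnan(e.qtl.beta_a):
            raise ValueError(f"{e.target.feature_id}: missing effect estimate")
    if not _intervals_overlap(eqtl_a.interval, eqtl_b.interval):
        return "independent"
    return "antagonistic" if eqtl_a.qtl.beta_a * eqtl_b.qtl.beta_a < 0 else "synergistic"


# ---------------------------------------------------------------------------
# End-to-end eQTL mapping
# ---------------------------------------------------------------------------


def map_eqtls(
    expr: pd.DataFrame,
    g: GenotypeMatrix,
    grms: GrmPair,
    annot: list[FeatureAnnotation],
    level: str = "suggestive",
    thresholds: ThresholdSet | None = None,
    vc: VarianceComponents | None = None,
    quantile_normalize: bool = True,
    drop: float = 2.0,
) -> list[EqtlCall]:
    """Scan every expression feature and return annotated eQTL calls.

    Expression columns are features (genes or isoforms), rows samples
    aligned with ``g``.  Each feature is quantile-normal transformed (the
    standard preparation for RNA expression), variance components are
    fitted per feature unless a shared ``vc`` is supplied, and QTLs are
    called with the usual iterative peak-picking, then annotated cis/trans
    and G-Add/G-Dom.
    """
    ann_by_feature = {f.feature_id: f for f in annot}
    missing = [c for c in expr.columns if c not in ann_by_feature]
    if missing:
        raise KeyError(f"feature(s) without annotation: {missing[:5]}")
    if thresholds is None:
        thresholds = significance_thresholds(g.n_snps)
    calls: list[EqtlCall] = []
    for feature in expr.columns:
        vals = expr[feature].to_numpy(dtype=float)
        if quantile_normalize:
            vals = inverse_normal_transform(vals)
        y = PhenotypeVector(values=vals, trait_name=str(feature))
        feature_vc = vc if vc is not None else reml_fit(y, grms)
        scan = genome_scan(y, g, feature_vc, grms)
        for q in call_qtls(scan, thresholds, level=level, trait=str(feature), drop=drop):
            target = ann_by_feature[feature]
            calls.append(
                EqtlCall(
                    qtl=q,
                    target=target,
                    regulation=classify_cis_trans(q.chromosome, q.peak_pos, target),
                    generalized=generalized_group(q.dominance.label),
                )
            )
    return calls


def eqtl_table(calls: list[EqtlCall]) -> pd.DataFrame:
    from .qtl_calling import qtl_table

    base = qtl_table([c.qtl for c in calls])
    if base.empty:
        for col in ("target_id", "gene_id", "regulation", "generalized", "n_isoforms"):
            base[col] = []
        return base
    base["target_id"] = [c.target.feature_id for c in calls]
    base["gene_id"] = [c.target.gene_id for c in calls]
    base["regulation"] = [c.regulation for c in calls]
    base["generalized"] = [c.generalized for c in calls]
    base["n_isoforms"] = [c.n_isoforms for c in calls]
    return base
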