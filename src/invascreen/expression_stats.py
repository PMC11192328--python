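"""Expression-cohort statistics: normalization, stratification, DE and correlation.

Covers the downstream stages run on patient and knockdown expression
matrices: CPM normalized to a reference gene subset (e.g. all chromosome-10
genes), RPKM, quartile stratification of a target gene's expression,
a Welch-t differential-expression stage on log2 counts with
Benjamini-Hochberg adjustment, the DEG filter (|log2FC| > 1, adjusted
p < 0.05, group-mean RPKM >= 1 in either group), a genome-wide Pearson
correlation screen against a target gene, and DEG-set intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BIOTYPES = ("coding", "noncoding")


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample abundance grid with its unit and optional metadata.

    ``genes`` (indexed by gene_id) may carry chromosome, start, end,
    length (bp, 1-based inclusive coordinates) and biotype; ``samples``
    (indexed by sample_id) may carry a cohort label.
    """

    values: pd.DataFrame
    unit: str = "counts"
    genes: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("expression values must be non-negative")
        if self.genes is not None and "length" in self.genes.columns:
            if (self.genes["length"] <= 0).any():
                raise ExpressionError("gene lengths must be positive")

    def with_values(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, unit=unit, genes=self.genes, samples=self.samples)

    def cohort_samples(self, label: str) -> list[str]:
        if self.samples is None or "cohort" not in self.samples.columns:
            raise ExpressionError("no sample cohort metadata attached")
        return self.samples.index[self.samples["cohort"] == label].tolist()


def cpm_subset_normalize(em: ExpressionMatrix, reference_genes) -> ExpressionMatrix:
    """Counts per million normalized to the read total of a gene subset.

    cpm(g, s) = count(g, s) / sum_{r in reference} count(r, s) * 1e6.
    The reference is typically all genes on the target's chromosome, which
    makes the unit robust to library-wide composition differences.
    """
    reference = pd.Index(reference_genes)
    if len(reference) == 0:
        raise ExpressionError("reference gene subset is empty")
    missing = reference.difference(em.values.index)
    if len(missing):
        raise ExpressionError(f"reference genes absent from matrix: {missing.tolist()[:10]}")
    totals = em.values.loc[reference].sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ExpressionError(f"zero reference total in sample(s): {zero.index.tolist()}")
    return em.with_values(em.values.div(totals, axis=1) * 1e6, unit="CPM")


def rpkm(em: ExpressionMatrix, total_reads) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million assigned reads."""
    if em.genes is None or "length" not in em.genes.columns:
        raise ExpressionError("RPKM requires gene lengths in the gene metadata")
    lengths = em.genes["length"].reindex(em.values.index)
    if lengths.isna().any():
        raise ExpressionError(
            f"missing length for genes: {lengths.index[lengths.isna()].tolist()[:10]}"
        )
    totals = pd.Series(total_reads).reindex(em.values.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ExpressionError("total_reads must be positive for every sample")
    kb = lengths / 1e3
    millions = totals / 1e6
    values = em.values.div(kb, axis=0).div(millions, axis=1)
    return em.with_values(values, unit="RPKM")


def quantile_split(values, lower_q: float = 0.25, upper_q: float = 0.75) -> pd.Series:
    """Label observations low / mid / high by empirical quantiles.

    ``high`` is strictly above the upper quantile and ``low`` strictly below
    the lower quantile (linear-interpolation quantiles); boundary ties fall
    into ``mid`` so the split is deterministic.
    """
    values = pd.Series(values, dtype=float)
    if len(values) < 8:
        raise ExpressionError("quantile_split requires at least 8 values")
    if not 0 < lower_q < upper_q < 1:
        raise ExpressionError("need 0 < lower_q < upper_q < 1")
    lo = float(np.quantile(values, lower_q, method="linear"))
    hi = float(np.quantile(values, upper_q, method="linear"))
    labels = pd.Series("mid", index=values.index, dtype=object)
    if lo == hi:
        logger.warning("degenerate quantiles (constant vector?); all labels mid")
        return labels
    labels[values < lo] = "low"
    labels[values > hi] = "high"
    return labels


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample p-values with degenerate-variance handling."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    p = np.ones(a.shape[0])
    degenerate = se2 == 0
    # zero variance in both groups: p = 1 when the means agree, else 0
    p[degenerate & (ma != mb)] = 0.0
    ok = ~degenerate
    t = (ma[ok] - mb[ok]) / np.sqrt(se2[ok])
    df = se2[ok] ** 2 / (
        (va[ok] / na) ** 2 / (na - 1) + (vb[ok] / nb) ** 2 / (nb - 1)
    )
    p[ok] = 2 * stats.t.sf(np.abs(t), df)
    return p


def two_group_de(
    em: ExpressionMatrix,
    group_a,
    group_b,
    offset: float = 0.5,
) -> pd.DataFrame:
    """Welch-t differential expression on log2(x + offset) values.

    Returns a table with per-gene log2fc (mean log2 in A minus mean log2 in
    B), Welch p, BH-adjusted p, and the group mean abundances on the input
    unit.  ``passes_filter`` is filled in by :func:`deg_filter`.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ExpressionError("each group needs at least 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ExpressionError(f"samples in both groups: {sorted(overlap)[:5]}")
    la = np.log2(em.values[group_a].to_numpy(dtype=float) + offset)
    lb = np.log2(em.values[group_b].to_numpy(dtype=float) + offset)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    p = _welch_rows(la, lb)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adj": bh_adjust(p),
            "mean_a": em.values[group_a].mean(axis=1),
            "mean_b": em.values[group_b].mean(axis=1),
            "passes_filter": False,
        },
        index=em.values.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ExpressionError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_filter(
    deg: pd.DataFrame,
    rpkm_em: ExpressionMatrix | None = None,
    group_a=None,
    group_b=None,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    min_rpkm: float = 1.0,
    coding_only: bool = False,
) -> list[str]:
    """Genes passing |log2fc| > lfc_threshold, p_adj < alpha and the RPKM rule.

    The abundance rule requires group-mean RPKM >= min_rpkm in *either*
    group; when ``coding_only`` is set, the RPKM matrix's biotype metadata
    restricts the result to coding genes.  Returns the sorted passing gene
    list and marks ``passes_filter`` on the input table in place.
    """
    passes = (deg["log2fc"].abs() > lfc_threshold) & (deg["p_adj"] < alpha)
    if rpkm_em is not None:
        if group_a is None or group_b is None:
            raise ExpressionError("RPKM rule needs group_a and group_b sample lists")
        mean_a = rpkm_em.values[list(group_a)].mean(axis=1).reindex(deg.index)
        mean_b = rpkm_em.values[list(group_b)].mean(axis=1).reindex(deg.index)
        passes &= (mean_a >= min_rpkm) | (mean_b >= min_rpkm)
    if coding_only:
        if rpkm_em is None or rpkm_em.genes is None or "biotype" not in rpkm_em.genes.columns:
            raise ExpressionError("coding_only needs biotype gene metadata")
        biotype = rpkm_em.genes["biotype"].reindex(deg.index)
        passes &= biotype == "coding"
    passes = passes.fillna(False)
    deg["passes_filter"] = passes
    return sorted(deg.index[passes])


def correlation_screen(
    em: ExpressionMatrix,
    target_gene: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of every gene with the target gene.

    p is two-sided from the t distribution with n-2 degrees of freedom;
    genes with zero variance get undefined r and are reported
    non-significant with ``zero_variance`` set.  The target itself is
    excluded from the output.
    """
    if target_gene not in em.values.index:
        raise ExpressionError(f"target gene {target_gene!r} not in matrix")
    n = em.values.shape[1]
    if n < 4:
        raise ExpressionError("correlation screen requires >= 4 samples")
    x = em.values.to_numpy(dtype=float)
    t = em.values.loc[target_gene].to_numpy(dtype=float)
    tc = t - t.mean()
    t_ss = (tc**2).sum()
    if t_ss == 0:
        raise ExpressionError("target gene has zero variance")
    xc = x - x.mean(axis=1, keepdims=True)
    x_ss = (xc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ tc) / np.sqrt(x_ss * t_ss)
    r = np.clip(r, -1.0, 1.0)
    zero_var = x_ss == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    p[zero_var] = np.nan
    out = pd.DataFrame(
        {
            "r": r,
            "p": p,
            "significant": (p < alpha) & ~zero_var,
            "direction": np.where(r > 0, "positive", "negative"),
            "zero_variance": zero_var,
        },
        index=em.values.index,
    )
    out.loc[zero_var, "direction"] = "undefined"
    return out.drop(index=target_gene)


def intersect_deg_sets(set_a, set_b) -> dict:
    """Exact intersection of two DEG sets on case-normalized gene symbols."""
    a = {str(g).upper() for g in set_a}
    b = {str(g).upper() for g in set_b}
    overlap = sorted(a & b)
    return {
        "overlap": overlap,
        "n_overlap": len(overlap),
        "n_only_a": len(a - b),
        "n_only_b": len(b - a),
        "n_a": len(a),
        "n_b": len(b),
    }
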