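"""Invasion-screen statistics: sgRNA phenotypes, gene scores and hit calling.

The screen compares sgRNA abundance between the starting population (T0)
and the non-invading cells harvested from the top of a Matrigel chamber
at the endpoint.  Per sgRNA, the *phenotype* is the log2 ratio of
reads-per-million (pseudocount-stabilised), centred so the median of the
non-targeting controls (NTCs) is zero; a positive phenotype means the
knockdown decreased invasion (the sgRNA was enriched among non-invaders).

Genes are scored as the signed mean phenotype of their top-3 sgRNAs by
absolute phenotype, multiplied by -log10 of a two-sided Mann-Whitney p
comparing the gene's sgRNA phenotypes with all NTC phenotypes.  An
empirical false-discovery rate comes from "pseudo-genes" assembled out of
randomly sampled NTC sgRNAs and scored identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .library_io import CountMatrix, LibraryTable

logger = logging.getLogger(__name__)

# Exact Mann-Whitney is used when the permutation distribution is small
# enough to enumerate; beyond that the tie/continuity-corrected normal
# approximation is accurate.
EXACT_MIN_N = 8
EXACT_MAX_PRODUCT = 10_000


class ScreenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float            # U statistic of the first sample (ties count 0.5)
    p_two_sided: float
    method: str         # "exact" | "approx"


def _u_doubled(x: np.ndarray, y: np.ndarray) -> int:
    """2*U of x vs y as an integer (each tie contributes 1 instead of 0.5)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return int(2 * gt + eq)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact p from the permutation distribution of U, ties handled.

    Dynamic programme over tie groups of the pooled sample: processing
    distinct values in increasing order, choosing j of a group's m copies
    to belong to x adds 2*j*(y's below) + j*(m-j) to 2U.  Counts are exact
    in double precision for the enumerable sizes this is used at.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    width = 2 * n1 * n2 + 1
    # dp[k] = distribution of accumulated 2U given k x's placed so far
    dp = [np.zeros(width) for _ in range(n1 + 1)]
    dp[0][0] = 1.0
    t_below = 0
    for m in counts:
        new = [np.zeros(width) for _ in range(n1 + 1)]
        for k in range(min(t_below, n1) + 1):
            row = dp[k]
            if not row.any():
                continue
            y_below = t_below - k
            if y_below > n2:
                continue
            for j in range(min(m, n1 - k) + 1):
                if y_below + (m - j) > n2:
                    continue  # assignment would overdraw the y sample
                # j x's at this value beat the (t_below - k) y's below and
                # tie with the (m - j) y's at this value
                shift = 2 * j * y_below + j * (m - j)
                weight = math.comb(m, j)
                if shift:
                    new[k + j][shift:] += weight * row[: width - shift]
                else:
                    new[k + j] += weight * row
        dp = new
        t_below += m
    dist = dp[n1]
    total = dist.sum()
    u2 = _u_doubled(x, y)
    centre = n1 * n2  # = 2 * (n1*n2/2)
    dev = abs(u2 - centre)
    support = np.arange(width)
    p = dist[np.abs(support - centre) >= dev].sum() / total
    return u2 / 2.0, min(1.0, float(p))


def _approx_two_sided_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = max(0.0, abs(u - mu) - 0.5) / math.sqrt(var)
    return u, min(1.0, 2.0 * stats.norm.sf(z))


def mann_whitney(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two samples.

    ``mode`` is ``exact`` (full permutation distribution of U, ties allowed),
    ``approx`` (tie- and continuity-corrected normal approximation) or
    ``auto`` (exact when min(n) <= 8 and n1*n2 <= 10,000).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ScreenError("mann_whitney requires two nonempty samples")
    if mode not in ("exact", "approx", "auto"):
        raise ScreenError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = (
            "exact"
            if min(x.size, y.size) <= EXACT_MIN_N and x.size * y.size <= EXACT_MAX_PRODUCT
            else "approx"
        )
    if mode == "exact":
        u, p = _exact_two_sided_p(x, y)
    else:
        u, p = _approx_two_sided_p(x, y)
    return MannWhitneyResult(u=u, p_two_sided=p, method=mode)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeTable:
    """Per-sgRNA invasion phenotypes (log2 units), one column per replicate.

    ``table`` is indexed by sgrna_id with columns ``is_ntc``,
    ``phenotype_mean`` and ``phenotype_rep{r}`` for each replicate r.
    """

    table: pd.DataFrame
    replicates: tuple[int, ...]

    @property
    def ntc_values(self) -> np.ndarray:
        return self.table.loc[self.table["is_ntc"], "phenotype_mean"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def compute_phenotypes(
    counts: CountMatrix,
    library: LibraryTable,
    pseudocount: float = 1.0,
    replicate: int | None = None,
) -> PhenotypeTable:
    """NTC-median-centred log2 reads-per-million ratio for one replicate.

    raw = log2((endpoint_rpm + pc) / (T0_rpm + pc)); the per-replicate
    phenotype subtracts the median raw value over NTC sgRNAs, so the NTC
    median phenotype is zero by construction and the statistic is invariant
    to sequencing depth.
    """
    if pseudocount <= 0:
        raise ScreenError("pseudocount must be positive")
    if replicate is None:
        reps = counts.replicates
        if len(reps) != 1:
            raise ScreenError(
                f"counts contain replicates {reps}; pass replicate= to pick one"
            )
        replicate = reps[0]
    pair = counts.select_replicate(replicate)
    for name in pair.counts.columns:
        if name in pair.unusable_samples:
            raise ScreenError(f"sample {name} has zero total counts")
    missing = library.sgrna_ids.difference(pair.counts.index)
    if len(missing):
        raise ScreenError(f"counts missing library sgRNAs: {missing.tolist()[:10]}")
    sub = pair.counts.loc[library.sgrna_ids]
    t0 = sub[f"T0_r{replicate}"].to_numpy(dtype=float)
    end = sub[f"endpoint_r{replicate}"].to_numpy(dtype=float)
    t0_rpm = t0 / t0.sum() * 1e6
    end_rpm = end / end.sum() * 1e6
    raw = np.log2((end_rpm + pseudocount) / (t0_rpm + pseudocount))
    is_ntc = library.records["is_ntc"].to_numpy()
    phen = raw - np.median(raw[is_ntc])
    table = pd.DataFrame(
        {
            "is_ntc": is_ntc,
            f"phenotype_rep{replicate}": phen,
            "phenotype_mean": phen,
        },
        index=pd.Index(library.sgrna_ids, name="sgrna_id"),
    )
    return PhenotypeTable(table=table, replicates=(replicate,))


def average_replicates(tables: list[PhenotypeTable]) -> PhenotypeTable:
    """Arithmetic mean of per-replicate phenotypes; per-replicate columns kept."""
    if len(tables) < 2:
        raise ScreenError("averaging requires at least two replicate tables")
    base = tables[0].table
    merged = base[["is_ntc"]].copy()
    reps: list[int] = []
    for t in tables:
        if not t.table.index.equals(base.index):
            raise ScreenError("replicate tables have mismatched sgRNA sets")
        if not t.table["is_ntc"].equals(base["is_ntc"]):
            raise ScreenError("replicate tables disagree on NTC flags")
        for r in t.replicates:
            col = f"phenotype_rep{r}"
            if r in reps:
                raise ScreenError(f"replicate {r} supplied twice")
            merged[col] = t.table[col]
            reps.append(r)
    merged["phenotype_mean"] = merged[[f"phenotype_rep{r}" for r in reps]].mean(axis=1)
    return PhenotypeTable(table=merged, replicates=tuple(reps))


# ---------------------------------------------------------------------------
# Gene scores
# ---------------------------------------------------------------------------

GENE_SCORE_COLUMNS = [
    "n_sgrnas", "avg_top3_phenotype", "mw_p", "screen_score", "hit", "is_pseudo",
]


@dataclass(frozen=True)
class HitCall:
    """Volcano thresholds: p cutoff and minimum |top-3 phenotype| in log2 units.

    The default effect threshold log2(4/3) ~= 0.415 corresponds to the ~25%
    minimum effect size the screen's volcano cutoffs select.
    """

    p_threshold: float = 0.05
    effect_threshold: float = math.log2(4.0 / 3.0)

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ScreenError("p_threshold must be in (0, 1)")
        if self.effect_threshold < 0:
            raise ScreenError("effect_threshold must be >= 0")


def _score_one(values: np.ndarray, ids: np.ndarray, ntc_values: np.ndarray,
               mode: str) -> tuple[float, float, float]:
    order = np.lexsort((ids, -np.abs(values)))
    top = values[order[: min(3, len(values))]]
    avg_top3 = float(top.mean())
    p = mann_whitney(values, ntc_values, mode=mode).p_two_sided
    score = avg_top3 * (-math.log10(p)) if p < 1 else 0.0
    return avg_top3, p, score


def gene_scores(
    phen: PhenotypeTable,
    library: LibraryTable,
    mode: str = "auto",
) -> pd.DataFrame:
    """Score every targeting gene against the NTC phenotype distribution.

    Per gene: Mann-Whitney p of all the gene's sgRNA ``phenotype_mean``
    values vs all NTC values; top-3 sgRNAs selected by |phenotype| (ties
    broken by sgrna_id), averaged with sign; screen_score = avg_top3 *
    (-log10 p).  Genes with fewer than 2 scoreable sgRNAs are excluded
    with a warning.
    """
    ntc_values = phen.ntc_values
    if len(ntc_values) < 10:
        raise ScreenError(f"need >= 10 NTC sgRNAs, found {len(ntc_values)}")
    gene_map = library.gene_map()
    tab = phen.table.join(gene_map.rename("gene_id"))
    rows = []
    targeting = tab.loc[~tab["is_ntc"]]
    for gene, grp in targeting.groupby("gene_id", sort=True):
        values = grp["phenotype_mean"].to_numpy()
        ok = np.isfinite(values)
        if ok.sum() < 2:
            logger.warning("gene %s has < 2 scoreable sgRNAs; excluded", gene)
            continue
        avg_top3, p, score = _score_one(
            values[ok], grp.index.to_numpy()[ok], ntc_values, mode
        )
        rows.append(
            {
                "gene_id": gene, "n_sgrnas": int(ok.sum()),
                "avg_top3_phenotype": avg_top3, "mw_p": p,
                "screen_score": score, "hit": False, "is_pseudo": False,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id"] + GENE_SCORE_COLUMNS).set_index("gene_id")


def pseudo_gene_scores(
    phen: PhenotypeTable,
    n_pseudo: int,
    sgrnas_per_pseudo: int = 10,
    seed: int = 0,
    mode: str = "auto",
) -> pd.DataFrame:
    """Score pseudo-genes drawn from the NTC pool, for the empirical null.

    Each pseudo-gene is ``sgrnas_per_pseudo`` NTC sgRNAs sampled without
    replacement (with replacement across pseudo-genes) and scored exactly
    like a real gene.  Its own sgRNAs are excluded from the NTC comparison
    set — a real gene's sgRNAs are never part of the control pool, and
    leaving them in makes the pseudo-gene p-values conservative.
    """
    if n_pseudo <= 0:
        raise ScreenError("n_pseudo must be positive")
    ntc_tab = phen.table.loc[phen.table["is_ntc"]]
    ntc_values = ntc_tab["phenotype_mean"].to_numpy()
    ntc_ids = ntc_tab.index.to_numpy()
    if len(ntc_values) < sgrnas_per_pseudo:
        raise ScreenError("fewer NTC sgRNAs than sgrnas_per_pseudo")
    rng = np.random.default_rng(seed)
    rows = []
    width = len(str(n_pseudo))
    all_idx = np.arange(len(ntc_values))
    for i in range(n_pseudo):
        idx = rng.choice(len(ntc_values), size=sgrnas_per_pseudo, replace=False)
        rest = ntc_values[np.setdiff1d(all_idx, idx, assume_unique=True)]
        avg_top3, p, score = _score_one(ntc_values[idx], ntc_ids[idx], rest, mode)
        rows.append(
            {
                "gene_id": f"pseudo_{i + 1:0{width}d}", "n_sgrnas": sgrnas_per_pseudo,
                "avg_top3_phenotype": avg_top3, "mw_p": p,
                "screen_score": score, "hit": False, "is_pseudo": True,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id"] + GENE_SCORE_COLUMNS).set_index("gene_id")


def _passes(scores: pd.DataFrame, call: HitCall) -> pd.Series:
    return (scores["mw_p"] <= call.p_threshold) & (
        scores["avg_top3_phenotype"].abs() >= call.effect_threshold
    )


def call_hits(
    scores: pd.DataFrame,
    pseudo: pd.DataFrame | None,
    call: HitCall = HitCall(),
) -> tuple[pd.DataFrame, dict]:
    """Flag hits at the volcano thresholds and estimate the empirical FDR.

    empirical_fdr = (fraction of pseudo-genes passing) / (fraction of real
    genes passing), clipped to [0, 1]; reported as None when no pseudo-genes
    are supplied or no real gene passes (unavailable, never zero).  A
    positive-phenotype hit means the knockdown decreased invasion, i.e. the
    gene is necessary for invasion.
    """
    flagged = scores.copy()
    flagged["hit"] = _passes(flagged, call)
    n_pos = int((flagged["hit"] & (flagged["avg_top3_phenotype"] > 0)).sum())
    n_neg = int((flagged["hit"] & (flagged["avg_top3_phenotype"] < 0)).sum())
    real_rate = flagged["hit"].mean() if len(flagged) else 0.0
    empirical_fdr = None
    if pseudo is not None and len(pseudo) and real_rate > 0:
        pseudo_rate = _passes(pseudo, call).mean()
        empirical_fdr = float(np.clip(pseudo_rate / real_rate, 0.0, 1.0))
    summary = {
        "n_genes": int(len(flagged)),
        "n_hits": int(flagged["hit"].sum()),
        "n_hits_positive": n_pos,
        "n_hits_negative": n_neg,
        "p_threshold": call.p_threshold,
        "effect_threshold": call.effect_threshold,
        "empirical_fdr": empirical_fdr,
    }
    return flagged, summary


def volcano_table(scores: pd.DataFrame, pseudo: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per (pseudo-)gene with the volcano-plot coordinates."""
    parts = [scores] if pseudo is None else [scores, pseudo]
    combined = pd.concat(parts)
    out = pd.DataFrame(
        {
            "avg_top3_phenotype": combined["avg_top3_phenotype"],
            "neg_log10_p": -np.log10(combined["mw_p"]),
            "screen_score": combined["screen_score"],
            "hit": combined["hit"],
            "is_pseudo": combined["is_pseudo"],
        },
        index=combined.index,
    )
    return out
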