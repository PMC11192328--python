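"""Seeded generators for every pipeline stage, with known ground truth.

Each generator is a pure function of its configuration and seed and emits
data in the containers the analysis modules consume, so the whole pipeline
is exercisable end to end without any external download:

* :func:`simulate_screen` — a pooled CRISPRi screen: negative-binomial
  sgRNA counts at a configurable coverage (default 1000 reads/sgRNA), a
  library of 2,307 genes x 10 sgRNAs plus 247 non-targeting controls,
  log-normal per-sgRNA abundance heterogeneity, planted log2 invasion
  effects with per-sgRNA knockdown-efficacy multipliers, two replicates.
* :func:`simulate_expression` — a gene x sample matrix, log-normal on the
  log2 scale, with planted Pearson correlations to a target gene (Gaussian
  copula on the log scale) and planted two-cohort fold changes.
* :func:`simulate_survival` — a cohort whose log hazard is piecewise
  linear in expression with a knot; exponential event times and
  independent exponential censoring calibrated to a requested fraction.
* :func:`simulate_qpcr` — Ct values with replicate noise around known
  fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .expression_stats import ExpressionMatrix
from .library_io import CountMatrix, LibraryTable, sample_name

DNA = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Design parameters of the simulated screen (defaults mirror the assay:
    2,307 lncRNA targets x 10 sgRNAs, 247 NTCs, 1000x coverage, 2 replicates).

    ``effect_range`` is the |log2 effect| interval for planted hits;
    ``hit_sign`` draws each hit's sign at random by default.  Per-sgRNA
    knockdown efficacy multiplies the planted effect and is Beta(5, 2)
    distributed (mean ~0.71, modelling partial knockdown); ``None`` means
    full efficacy for every sgRNA.  Counts are
    Gamma-Poisson (negative binomial) with dispersion ``nb_dispersion``;
    per-sgRNA T0 abundance is log-normal with ``abundance_sigma`` on the
    natural-log scale.
    """

    n_genes: int = 2307
    sgrnas_per_gene: int = 10
    n_ntc: int = 247
    n_hits: int = 0
    effect_range: tuple[float, float] = (0.4, 1.5)
    hit_sign: str = "random"          # "random" | "positive" | "negative"
    efficacy_beta: tuple[float, float] | None = (5.0, 2.0)
    coverage: float = 1000.0
    nb_dispersion: float = 0.01
    abundance_sigma: float = 0.5
    n_replicates: int = 2
    protospacer_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.sgrnas_per_gene, self.n_ntc, self.n_replicates) <= 0:
            raise SimulationError("library/replicate counts must be positive")
        if self.sgrnas_per_gene < 2:
            raise SimulationError("need >= 2 sgRNAs per gene for gene scoring")
        if not 0 <= self.n_hits <= self.n_genes:
            raise SimulationError("n_hits must lie in [0, n_genes]")
        lo, hi = self.effect_range
        if not 0 <= lo <= hi:
            raise SimulationError("effect_range must satisfy 0 <= lo <= hi")
        if self.hit_sign not in ("random", "positive", "negative"):
            raise SimulationError(f"unknown hit_sign {self.hit_sign!r}")
        if self.coverage <= 0 or self.nb_dispersion < 0:
            raise SimulationError("coverage must be > 0 and nb_dispersion >= 0")


@dataclass(frozen=True)
class ScreenSim:
    library: LibraryTable
    counts: CountMatrix
    truth: pd.DataFrame        # per gene: true_effect, is_hit
    config: ScreenSimConfig = field(repr=False, default=None)


def _random_protospacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in DNA[block]:
            seq = "".join(row)
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
    return out


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws via the Gamma-Poisson mixture.

    The Gamma multipliers are drawn before the Poisson step, so with a
    common seed the overdispersion noise is shared across configurations
    that differ only in their planted effects.
    """
    if dispersion > 0:
        g = rng.gamma(shape=1.0 / dispersion, scale=dispersion, size=mean.shape)
    else:
        g = np.ones_like(mean)
    return rng.poisson(mean * g)


def simulate_screen(cfg: ScreenSimConfig) -> ScreenSim:
    """Simulate library, T0/endpoint counts per replicate, and ground truth.

    Endpoint expected abundance of sgRNA i targeting gene g is the T0
    abundance times 2^(true_effect_g * efficacy_i); NTCs and non-hit genes
    have zero true effect.  Sample totals are coverage * number of sgRNAs.
    """
    rng = np.random.default_rng(cfg.seed)
    gw = len(str(cfg.n_genes))
    genes = [f"G{i + 1:0{gw}d}" for i in range(cfg.n_genes)]
    n_targeting = cfg.n_genes * cfg.sgrnas_per_gene
    n_total = n_targeting + cfg.n_ntc

    records = []
    for g in genes:
        for j in range(cfg.sgrnas_per_gene):
            records.append((f"{g}_sg{j + 1:02d}", g))
    for j in range(cfg.n_ntc):
        records.append((f"NTC_sg{j + 1:03d}", "NTC"))
    lib_df = pd.DataFrame(records, columns=["sgrna_id", "gene_id"])
    lib_df["protospacer"] = _random_protospacers(rng, n_total, cfg.protospacer_length)
    library = LibraryTable(lib_df)

    # fixed draw order keeps noise identical across effect settings at a seed
    abundance = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n_total)
    if cfg.efficacy_beta is None:
        efficacy = np.ones(n_total)
    else:
        efficacy = rng.beta(*cfg.efficacy_beta, size=n_total)
    hit_idx = rng.choice(cfg.n_genes, size=cfg.n_hits, replace=False)
    magnitudes = rng.uniform(*cfg.effect_range, size=cfg.n_hits)
    if cfg.hit_sign == "random":
        signs = rng.choice([-1.0, 1.0], size=cfg.n_hits)
    else:
        signs = np.full(cfg.n_hits, 1.0 if cfg.hit_sign == "positive" else -1.0)
    gene_effect = np.zeros(cfg.n_genes)
    gene_effect[hit_idx] = signs * magnitudes

    sgrna_effect = np.zeros(n_total)
    sgrna_effect[:n_targeting] = np.repeat(gene_effect, cfg.sgrnas_per_gene)
    sgrna_effect *= efficacy

    total_reads = cfg.coverage * n_total
    t0_mean = abundance / abundance.sum() * total_reads
    end_rel = abundance * np.exp2(sgrna_effect)
    end_mean = end_rel / end_rel.sum() * total_reads

    columns = {}
    for r in range(1, cfg.n_replicates + 1):
        columns[sample_name("T0", r)] = _nb_counts(rng, t0_mean, cfg.nb_dispersion)
        columns[sample_name("endpoint", r)] = _nb_counts(rng, end_mean, cfg.nb_dispersion)
    counts = CountMatrix(pd.DataFrame(columns, index=pd.Index(lib_df["sgrna_id"],
                                                              name="sgrna_id")))
    truth = pd.DataFrame(
        {"true_effect": gene_effect, "is_hit": gene_effect != 0.0},
        index=pd.Index(genes, name="gene_id"),
    )
    return ScreenSim(library=library, counts=counts, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    n_genes: int = 1000,
    n_samples: int = 169,
    target_r: tuple[float, ...] = (),
    planted_log2fc: tuple[float, ...] = (),
    sigma: float = 0.5,
    baseline_range: tuple[float, float] = (3.0, 8.0),
    target_gene: str = "TARGET",
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix with planted correlations and two-cohort fold changes.

    Log2 abundances are Normal(mu_g, sigma); genes carrying a planted
    correlation share a Gaussian copula with the target gene on the log
    scale (partner = r*z_target + sqrt(1-r^2)*noise), then values are
    exponentiated to abundances.  ``planted_log2fc`` values are added, on
    the log2 scale, to the second half of the samples (cohort ``treated``
    vs ``control``), on genes disjoint from the correlation partners.
    Returns the matrix and a per-gene truth table (true_r, true_log2fc).
    """
    target_r = tuple(target_r)
    planted_log2fc = tuple(planted_log2fc)
    if any(abs(r) >= 1 for r in target_r):
        raise SimulationError("planted correlations must lie in (-1, 1)")
    if len(target_r) + len(planted_log2fc) > n_genes:
        raise SimulationError("more planted genes than n_genes")
    if n_samples < 4:
        raise SimulationError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    gw = len(str(n_genes))
    genes = [f"g{i + 1:0{gw}d}" for i in range(n_genes)]
    mu = rng.uniform(*baseline_range, size=n_genes)
    z = rng.standard_normal((n_genes, n_samples))
    z_target = rng.standard_normal(n_samples)

    true_r = np.zeros(n_genes)
    true_lfc = np.zeros(n_genes)
    r_arr = np.array(target_r)
    k = len(target_r)
    true_r[:k] = r_arr
    z[:k] = r_arr[:, None] * z_target[None, :] + np.sqrt(1 - r_arr**2)[:, None] * z[:k]
    true_lfc[k : k + len(planted_log2fc)] = planted_log2fc

    half = n_samples // 2
    cohort = np.array(["control"] * half + ["treated"] * (n_samples - half))
    log2v = mu[:, None] + sigma * z
    log2v[:, cohort == "treated"] += true_lfc[:, None]

    mu_t = float(rng.uniform(*baseline_range))
    log2_target = mu_t + sigma * z_target

    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    values = pd.DataFrame(
        np.exp2(np.vstack([log2_target, log2v])),
        index=pd.Index([target_gene] + genes, name="gene_id"),
        columns=samples,
    )
    sample_meta = pd.DataFrame({"cohort": cohort}, index=pd.Index(samples, name="sample_id"))
    em = ExpressionMatrix(values=values, unit="TPM", samples=sample_meta)
    truth = pd.DataFrame(
        {"true_r": true_r, "true_log2fc": true_lfc},
        index=pd.Index(genes, name="gene_id"),
    )
    return em, truth


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def _default_expression(rng: np.random.Generator, n: int) -> np.ndarray:
    # lognormal matched to the observed glioma cohort: median 1.65 CPM,
    # interquartile range 0.72-3.09
    return rng.lognormal(mean=np.log(1.65), sigma=1.08, size=n)


def simulate_survival(
    n: int = 600,
    knot: float = 2.5,
    beta_below: float = np.log(1.99),
    beta_above: float = 0.0,
    baseline_rate: float = 1.0 / 400.0,
    censor_rate: float = 0.3,
    expression: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Cohort with piecewise-linear log hazard in expression.

    Event times are exponential with hazard baseline_rate *
    exp(beta_below*min(x, knot) + beta_above*max(x-knot, 0)); censoring is
    independent exponential with its rate solved so the expected censored
    fraction equals ``censor_rate``.  Default betas reproduce a hazard
    ratio of 1.99 per CPM below a 2.5-CPM knot and a flat hazard above it.
    """
    if baseline_rate <= 0 or not 0 <= censor_rate < 1:
        raise SimulationError("baseline_rate must be > 0 and censor_rate in [0, 1)")
    rng = np.random.default_rng(seed)
    x = _default_expression(rng, n) if expression is None else np.asarray(expression, float)
    if len(x) != n:
        raise SimulationError("expression vector length must equal n")
    hazard = baseline_rate * np.exp(
        beta_below * np.minimum(x, knot) + beta_above * np.maximum(x - knot, 0.0)
    )
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        def expected_censored(mu: float) -> float:
            return float(np.mean(mu / (mu + hazard))) - censor_rate
        lo, hi = 1e-12, 1e6 * hazard.max()
        mu = optimize.brentq(expected_censored, lo, hi)
        censor_time = rng.exponential(1.0 / mu, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    cohort = pd.DataFrame(
        {"time_days": time, "event": event, "expression_cpm": x}
    )
    truth = {
        "knot": knot, "beta_below": beta_below, "beta_above": beta_above,
        "baseline_rate": baseline_rate, "censor_rate": censor_rate, "seed": seed,
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    fold_changes: dict[str, float] | float = 0.5,
    ct_noise_sd: float = 0.2,
    n_replicates: int = 3,
    housekeeping_ct: float = 18.0,
    baseline_dct: float = 6.0,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR plate with known fold changes relative to an implicit control.

    Housekeeping Ct ~ Normal(housekeeping_ct, ct_noise_sd); target Ct =
    housekeeping + baseline_dct - log2(fold_change) + noise.  The control
    group has fold change 1; ``fold_changes`` maps treated group names to
    their true fold changes (a scalar means one group named ``treated``).
    """
    if np.isscalar(fold_changes):
        fold_changes = {"treated": float(fold_changes)}
    if any(fc <= 0 for fc in fold_changes.values()):
        raise SimulationError("fold changes must be positive")
    if ct_noise_sd < 0 or n_replicates < 2:
        raise SimulationError("ct_noise_sd must be >= 0 and n_replicates >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for group, fc in [("control", 1.0), *sorted(fold_changes.items())]:
        for i in range(n_replicates):
            hk = housekeeping_ct + rng.normal(0.0, ct_noise_sd)
            target = hk + baseline_dct - np.log2(fc) + rng.normal(0.0, ct_noise_sd)
            rows.append(
                {"sample_id": f"{group}_{i + 1}", "group": group,
                 "target_ct": target, "housekeeping_ct": hk}
            )
    return pd.DataFrame(rows)
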