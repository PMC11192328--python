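"""Statistics for the wet-lab validation assays.

Four assay readouts back up a screen hit: RT-qPCR relative expression by
the delta-delta-Ct method (normalized to a housekeeping gene such as
RPLP0), Boyden-chamber invasion counts (multiple microscope fields per
experiment, the experiment being the inference unit), MTT proliferation
(OD570 minus OD650 background), and 3D spheroid invasion area.  Group
comparisons use Welch's unequal-variance t-test throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXPECTED_EXPERIMENTS = 3
EXPECTED_FIELDS = 9


class AssayError(ValueError):
    pass


def welch_t(a, b) -> tuple[float, float]:
    """Welch two-sample t with degenerate-variance handling.

    Identical constant groups give p = 1 (no evidence of a difference);
    distinct constant groups give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AssayError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _split_groups(df: pd.DataFrame, control_group: str, treated_group: str | None):
    groups = df["group"].astype(str)
    if control_group not in set(groups):
        raise AssayError(f"control group {control_group!r} absent")
    if treated_group is None:
        others = sorted(set(groups) - {control_group})
        if len(others) != 1:
            raise AssayError(f"ambiguous treated group; found {others}")
        treated_group = others[0]
    elif treated_group not in set(groups):
        raise AssayError(f"treated group {treated_group!r} absent")
    return df[groups == control_group], df[groups == treated_group], treated_group


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def validate_qpcr_plate(plate: pd.DataFrame) -> pd.DataFrame:
    for col in ("group", "target_ct", "housekeeping_ct"):
        if col not in plate.columns:
            raise AssayError(f"qPCR plate missing column {col!r}")
    if plate["housekeeping_ct"].isna().any():
        raise AssayError("missing housekeeping Ct well(s)")
    if plate["target_ct"].isna().any():
        raise AssayError("missing target Ct well(s)")
    ct = plate[["target_ct", "housekeeping_ct"]].to_numpy(dtype=float)
    if ((ct <= 0) | (ct >= 45)).any():
        raise AssayError("Ct values must lie in (0, 45) cycles")
    sizes = plate.groupby("group").size()
    if (sizes < 2).any():
        raise AssayError(f"groups with < 2 replicate wells: "
                         f"{sizes.index[sizes < 2].tolist()}")
    return plate


@dataclass(frozen=True)
class DdctResult:
    ddct: float
    relative_expression: float   # 2^(-ddct)
    percent_change: float        # (2^(-ddct) - 1) * 100; negative = knockdown
    p: float
    n_control: int
    n_treated: int


def ddct_knockdown(plate: pd.DataFrame, control_group: str = "control",
                   treated_group: str | None = None) -> DdctResult:
    """Relative expression of the treated group by the delta-delta-Ct method.

    Per well, dCt = target_ct - housekeeping_ct; ddCt = mean dCt(treated) -
    mean dCt(control); relative expression = 2^(-ddCt).  The p-value is a
    Welch t on the per-well dCt values.
    """
    plate = validate_qpcr_plate(plate)
    control, treated, _ = _split_groups(plate, control_group, treated_group)
    dct_c = (control["target_ct"] - control["housekeeping_ct"]).to_numpy(dtype=float)
    dct_t = (treated["target_ct"] - treated["housekeeping_ct"]).to_numpy(dtype=float)
    ddct = float(dct_t.mean() - dct_c.mean())
    rel = float(2.0 ** (-ddct))
    _, p = welch_t(dct_t, dct_c)
    return DdctResult(ddct=ddct, relative_expression=rel,
                      percent_change=(rel - 1.0) * 100.0, p=p,
                      n_control=len(dct_c), n_treated=len(dct_t))


# ---------------------------------------------------------------------------
# Boyden-chamber invasion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InvasionResult:
    experiment_means: pd.DataFrame   # group, experiment_id, mean cell count
    mean_control: float
    mean_treated: float
    sem_control: float               # SEM over experiment means (n = experiments)
    sem_treated: float
    percent_decrease: float          # (1 - treated/control) * 100
    p: float
    inference_unit: str


def invasion_summary(exp: pd.DataFrame, control_group: str = "control",
                     treated_group: str | None = None,
                     inference_unit: str = "experiment") -> InvasionResult:
    """Summarise per-field invasion counts with the experiment as inference unit.

    Fields are averaged within each experiment first; the mean +/- SEM and
    the Welch t are computed over experiment means (the design expects
    3 experiments x 9 fields per group; deviations are logged, not fatal).
    A field-level t is available for sensitivity analysis.
    """
    for col in ("experiment_id", "group", "cell_count"):
        if col not in exp.columns:
            raise AssayError(f"invasion table missing column {col!r}")
    if (exp["cell_count"] < 0).any():
        raise AssayError("cell counts must be non-negative")
    control, treated, treated_group = _split_groups(exp, control_group, treated_group)
    for label, part in ((control_group, control), (treated_group, treated)):
        n_exp = part["experiment_id"].nunique()
        fields = part.groupby("experiment_id").size()
        if n_exp != EXPECTED_EXPERIMENTS or (fields != EXPECTED_FIELDS).any():
            logger.info("group %s deviates from the %dx%d design: %d experiments, "
                        "fields per experiment %s", label, EXPECTED_EXPERIMENTS,
                        EXPECTED_FIELDS, n_exp, fields.tolist())
        if n_exp < 2:
            raise AssayError(f"group {label!r} has fewer than 2 experiments")
    means = (
        exp.groupby(["group", "experiment_id"])["cell_count"].mean()
        .rename("mean_count").reset_index()
    )
    mc = means.loc[means["group"] == control_group, "mean_count"].to_numpy()
    mt = means.loc[means["group"] == treated_group, "mean_count"].to_numpy()
    if mc.mean() == 0:
        raise AssayError("control mean is zero; percent decrease undefined")
    if inference_unit == "experiment":
        _, p = welch_t(mt, mc)
    elif inference_unit == "field":
        _, p = welch_t(treated["cell_count"], control["cell_count"])
    else:
        raise AssayError(f"unknown inference unit {inference_unit!r}")
    return InvasionResult(
        experiment_means=means,
        mean_control=float(mc.mean()), mean_treated=float(mt.mean()),
        sem_control=float(stats.sem(mc)), sem_treated=float(stats.sem(mt)),
        percent_decrease=float((1.0 - mt.mean() / mc.mean()) * 100.0),
        p=p, inference_unit=inference_unit,
    )


# ---------------------------------------------------------------------------
# MTT proliferation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MttResult:
    signals: pd.DataFrame        # group, signal (OD570 - OD650) per well
    mean_control: float
    mean_treated: float
    p: float
    no_change: bool              # operationalised as p >= 0.05


def mtt_signal(wells: pd.DataFrame, control_group: str = "control",
               treated_group: str | None = None, alpha: float = 0.05) -> MttResult:
    """Background-subtracted MTT viability signal with a Welch group comparison."""
    for col in ("group", "od570", "od650"):
        if col not in wells.columns:
            raise AssayError(f"MTT table missing column {col!r}")
    signals = wells.assign(signal=wells["od570"] - wells["od650"])
    control, treated, _ = _split_groups(signals, control_group, treated_group)
    _, p = welch_t(treated["signal"], control["signal"])
    return MttResult(
        signals=signals[["group", "signal"]],
        mean_control=float(control["signal"].mean()),
        mean_treated=float(treated["signal"].mean()),
        p=p, no_change=bool(p >= alpha),
    )


# ---------------------------------------------------------------------------
# Spheroid invasion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpheroidResult:
    mean_control: float
    mean_treated: float
    percent_decrease: float
    p: float


def spheroid_invasion(areas: pd.DataFrame, control_group: str = "control",
                      treated_group: str | None = None) -> SpheroidResult:
    """Percent decrease of invaded spheroid area vs control, Welch t on areas."""
    for col in ("group", "area"):
        if col not in areas.columns:
            raise AssayError(f"spheroid table missing column {col!r}")
    if (areas["area"] <= 0).any():
        raise AssayError("spheroid areas must be positive")
    sizes = areas.groupby("group").size()
    if (sizes < 3).any():
        raise AssayError(f"groups with < 3 spheroids: {sizes.index[sizes < 3].tolist()}")
    control, treated, _ = _split_groups(areas, control_group, treated_group)
    mc = control["area"].to_numpy(dtype=float)
    mt = treated["area"].to_numpy(dtype=float)
    _, p = welch_t(mt, mc)
    return SpheroidResult(
        mean_control=float(mc.mean()), mean_treated=float(mt.mean()),
        percent_decrease=float((1.0 - mt.mean() / mc.mean()) * 100.0), p=p,
    )
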