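"""Stance-phase outcome metrics and repeated-measures statistics.

Per trial, load curves are clipped to stance (heel strike to toe off,
detected from the vertical ground reaction), resampled to 101 points,
normalized (%BW for forces, %BW*BH for moments) and summarized as peak and
impulse (time integral over stance seconds).  Per-patient means (n trials)
and group means (n patients) feed one-way repeated-measures ANOVAs with
Bonferroni-corrected paired post-hoc comparisons against baseline shod
walking, plus the "individually selected best alteration" contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CONDITION_ORDER = ("shod", "insole_0", "insole_5", "insole_10",
                   "toe_in", "toe_out", "wide")


def compute_bmi(mass_kg: float, height_cm: float) -> float:
    """Body mass index, reported to two decimals."""
    if mass_kg <= 0 or height_cm <= 0:
        raise ValueError("mass and height must be positive")
    return round(mass_kg / (height_cm / 100.0) ** 2, 2)


def detect_stance(grf_force: np.ndarray, force_rate: float,
                  threshold: float = 20.0) -> tuple[float, float]:
    """Heel-strike and toe-off times from the vertical force channel.

    First rising and last falling crossing of ``threshold`` (N), with a
    small hysteresis band (10% of threshold) to ignore noise chatter.
    """
    fz = np.asarray(grf_force, dtype=float)
    if fz.ndim == 2:
        fz = fz[:, 2]
    if np.all(fz < threshold):
        raise ValueError("vertical force never crosses the stance threshold")
    # hysteresis: require the signal to clear 110% of the threshold at least
    # once between the first rising and last falling crossing
    hi = fz >= threshold
    if not np.any(fz >= 1.1 * threshold):
        raise ValueError("vertical force never clears the hysteresis band")
    above = np.where(hi)[0]
    start = above[0]
    end = min(above[-1] + 1, len(fz) - 1)
    return start / force_rate, end / force_rate


@dataclass
class StanceCurve:
    variable: str
    values: np.ndarray           # 101 points over 0-100% stance
    stance_duration: float       # s

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (101,):
            raise ValueError("stance curve must hold exactly 101 samples")
        if self.stance_duration <= 0:
            raise ValueError("stance duration must be positive")


def resample_stance(time: np.ndarray, values: np.ndarray,
                    events: tuple[float, float], variable: str = "") -> StanceCurve:
    """Linear resampling of a time series onto 101 points over stance."""
    t0, t1 = events
    time = np.asarray(time, dtype=float)
    if t0 < time[0] - 1e-9 or t1 > time[-1] + 1e-9 or t1 <= t0:
        raise ValueError(f"stance events [{t0}, {t1}] outside series "
                         f"[{time[0]}, {time[-1]}]")
    grid = np.linspace(t0, t1, 101)
    return StanceCurve(variable=variable,
                       values=np.interp(grid, time, np.asarray(values, dtype=float)),
                       stance_duration=float(t1 - t0))


@dataclass
class OutcomeMetrics:
    peak: float         # max of the normalized curve over stance
    impulse: float      # trapezoidal integral over stance seconds


def compute_metrics(curve: StanceCurve, body_weight: float | None = None,
                    body_height: float | None = None,
                    kind: str = "force") -> OutcomeMetrics:
    """Peak and impulse of a stance curve, normalized.

    Forces are scaled to %BW; moments to %BW*BH (height in m).  The impulse
    integrates the normalized variable over real stance time (units %BW*s or
    %BW*BH*s).
    """
    vals = curve.values
    if body_weight is not None:
        if kind == "force":
            vals = 100.0 * vals / body_weight
        elif kind == "moment":
            vals = 100.0 * vals / (body_weight * body_height)
        else:
            raise ValueError(kind)
    t = np.linspace(0.0, curve.stance_duration, 101)
    return OutcomeMetrics(peak=float(np.max(vals)),
                          impulse=float(np.trapezoid(vals, t)))


def aggregate(values) -> tuple[float, float]:
    """Sample mean and SD (n-1 denominator)."""
    x = np.asarray(list(values), dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two values to aggregate")
    return float(x.mean()), float(x.std(ddof=1))


@dataclass
class AlterationSelection:
    choice: str                 # condition name or "none"
    tie: bool = False


def select_best_alteration(per_condition_means: dict,
                           baseline: str = "shod") -> AlterationSelection:
    """The alteration with the greatest mean load reduction vs baseline.

    Returns "none" when no alteration falls below the baseline mean.  Exact
    ties break toward the canonical condition order and are flagged.
    """
    missing = [c for c in CONDITION_ORDER if c not in per_condition_means]
    if missing:
        raise KeyError(f"missing conditions: {missing}")
    base = per_condition_means[baseline]
    alts = [c for c in CONDITION_ORDER if c != baseline]
    vals = np.array([per_condition_means[c] for c in alts])
    best = float(vals.min())
    if best >= base:
        return AlterationSelection("none")
    winners = [c for c, x in zip(alts, vals) if x == best]
    return AlterationSelection(winners[0], tie=len(winners) > 1)


def paired_difference_table(per_patient: pd.DataFrame,
                            baseline: str = "shod",
                            selections: dict | None = None) -> pd.DataFrame:
    """Mean paired difference (baseline - condition) and its SE per contrast.

    ``per_patient`` is patients x conditions (one mean value per cell;
    balanced).  With ``selections`` (patient -> condition), an extra row
    "individual" contrasts each patient's own selected alteration.  For
    balanced data the mean paired difference equals the difference of the
    condition means.
    """
    if per_patient.isna().any().any():
        raise ValueError("unbalanced data: missing per-patient cells")
    rows = []
    for cond in [c for c in per_patient.columns if c != baseline]:
        diff = per_patient[baseline] - per_patient[cond]
        rows.append({"contrast": cond, "mean_difference": diff.mean(),
                     "se": diff.std(ddof=1) / np.sqrt(len(diff)), "n": len(diff)})
    if selections is not None:
        chosen = []
        for pat in per_patient.index:
            sel = selections[pat]
            sel = baseline if sel == "none" else sel
            chosen.append(per_patient.loc[pat, baseline] - per_patient.loc[pat, sel])
        chosen = pd.Series(chosen, index=per_patient.index)
        rows.append({"contrast": "individual", "mean_difference": chosen.mean(),
                     "se": chosen.std(ddof=1) / np.sqrt(len(chosen)),
                     "n": len(chosen)})
    return pd.DataFrame(rows).set_index("contrast")


def shapiro_wilk(differences) -> tuple[float, float]:
    """Shapiro-Wilk normality test of a paired-difference sample."""
    x = np.asarray(list(differences), dtype=float)
    if not 3 <= len(x) <= 50:
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 50")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def rm_anova(data: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA (subjects as blocks).

    ``data`` is (n subjects, k conditions), or (reps, n, k) for a vectorized
    batch.  F = MS_condition / MS_error with df (k-1), (k-1)(n-1).
    """
    x = np.asarray(data, dtype=float)
    batch = x.ndim == 3
    if not batch:
        x = x[None]
    if np.isnan(x).any():
        raise ValueError("missing cells in repeated-measures design")
    _, n, k = x.shape
    grand = x.mean(axis=(1, 2), keepdims=True)
    cond_means = x.mean(axis=1, keepdims=True)
    subj_means = x.mean(axis=2, keepdims=True)
    ss_cond = n * ((cond_means - grand) ** 2).sum(axis=(1, 2))
    resid = x - cond_means - subj_means + grand
    ss_err = (resid ** 2).sum(axis=(1, 2))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_cond / ms_err
    p = sps.f.sf(F, df1, df2)
    degenerate = ms_err == 0
    if batch:
        return {"F": F, "df": (df1, df2), "p": p, "degenerate": degenerate}
    return {"F": float(F[0]), "df": (df1, df2), "p": float(p[0]),
            "degenerate": bool(degenerate[0])}


def bonferroni_posthoc(pairs: dict, alpha: float = 0.05,
                       n_comparisons: int | None = None) -> pd.DataFrame:
    """Paired-t post-hoc rows with Bonferroni-adjusted p and simultaneous CI.

    ``pairs`` maps contrast name -> (x, y) paired samples.  Adjusted
    p = min(1, raw p * m); the CI uses the t quantile at alpha/m so the set
    of intervals holds jointly at level 1 - alpha.
    """
    m = n_comparisons if n_comparisons is not None else len(pairs)
    rows = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 2:
            raise ValueError(f"contrast {name}: need >= 2 complete pairs")
        diff = x - y
        n = len(diff)
        mean = diff.mean()
        se = diff.std(ddof=1) / np.sqrt(n)
        if se == 0:
            raw_p, tstat = (1.0, 0.0) if mean == 0 else (0.0, np.inf)
        else:
            tstat, raw_p = sps.ttest_rel(x, y)
        adj_p = min(1.0, float(raw_p) * m)
        tcrit = sps.t.ppf(1 - alpha / (2 * m), n - 1)
        rows.append({"contrast": name, "mean_difference": mean, "se": se,
                     "t": float(tstat), "p_raw": float(raw_p), "p_adj": adj_p,
                     "ci_low": mean - tcrit * se, "ci_high": mean + tcrit * se,
                     "significant": adj_p < alpha})
    return pd.DataFrame(rows).set_index("contrast")


@dataclass
class StatsReport:
    shapiro: pd.DataFrame
    anova: dict                  # (metric, model) -> rm_anova result
    posthoc: dict                # (metric, model) -> bonferroni table
    alpha: float = 0.05
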