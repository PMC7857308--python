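"""Model/Results interface for per-trial analysis and the cohort study.

`GaitTrialModel` wraps one motion trial plus a personalized model; its
``fit()`` runs the marker-tracking kinematics, inverse-dynamics muscle
recruitment and knee-load decomposition, returning a `GaitTrialResults`
with the stance-resampled load curves, outcome metrics and diagnostics.

`CohortStudy` reproduces the study design end to end on the synthetic
cohort: five subjects x seven conditions x three trials, analyzed under
both personalization routes (marker-based linear scaling and geometric
morphing), aggregated into group tables, best-alteration selections and
repeated-measures statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import outcomes as oc
from .dynamics import InverseDynamics
from .kneeloads import KneeLoadTrajectory, knee_loads_from_dynamics
from .scaling import morph_model, optimize_linear_scaling
from .synth import (COHORT_DEMOGRAPHICS, MarkerNoise, SyntheticSubject,
                    default_conditions, generate_standing_trial, generate_subject,
                    generate_trial)
from .template import TemplateModel

METRIC_KINDS = {"MCF": "force", "LCF": "force", "TCF": "force",
                "KAM": "moment", "KFM": "moment"}


class GaitTrialModel:
    """One trial + one personalized model, ready to fit."""

    def __init__(self, trial, model, stance_threshold: float = 20.0,
                 filter_cutoff_hz: float | None = 6.0,
                 residual_weight: float = 1e3, clamp: bool = True):
        self.trial = trial
        self.model = model
        self.stance_threshold = stance_threshold
        self.filter_cutoff_hz = filter_cutoff_hz
        self.residual_weight = residual_weight
        self.clamp = clamp

    def fit(self) -> "GaitTrialResults":
        trial, model = self.trial, self.model
        hs, to = oc.detect_stance(trial.grf["plate2"]["force"], trial.force_rate,
                                  self.stance_threshold)
        km = kin.KinematicModel.from_model(model)
        rate = trial.marker_rate
        n_total = trial.n_frames
        f0 = max(int(np.floor(hs * rate)), 0)
        f1 = min(int(np.ceil(to * rate)) + 1, n_total)
        # solve a window around stance: margin for filtering/differentiation
        margin = 15
        w0 = max(f0 - margin, 0)
        w1 = min(f1 + margin, n_total)
        traj = kin.solve_trajectory(km, trial, filter_cutoff_hz=self.filter_cutoff_hz,
                                    frames=slice(w0, w1))
        frames = np.arange(f0 - w0, f1 - w0)
        dyn = InverseDynamics(model, residual_weight=self.residual_weight)
        dyn_out = dyn.run(km, traj, trial, frames)
        loads = knee_loads_from_dynamics(dyn_out, model, traj, model.tested_leg,
                                         clamp=self.clamp)
        return GaitTrialResults(model=self, trajectory=traj, loads=loads,
                                stance=(hs, to), dyn=dyn_out)


@dataclass
class GaitTrialResults:
    model: GaitTrialModel
    trajectory: kin.JointAngleTrajectory
    loads: KneeLoadTrajectory
    stance: tuple
    dyn: dict

    def stance_curves(self) -> dict:
        hs, to = self.stance
        t = self.loads.time
        out = {}
        for var in ("MCF", "LCF", "TCF", "KAM", "KFM", "KFA"):
            out[var] = oc.resample_stance(t, getattr(self.loads, var),
                                          (max(hs, t[0]), min(to, t[-1])), var)
        return out

    def metrics(self) -> dict:
        """Peak and impulse per variable, normalized (%BW, %BW*BH)."""
        bw = self.model.model.body_weight
        bh = self.model.model.height / 100.0
        out = {}
        for var, curve in self.stance_curves().items():
            kind = METRIC_KINDS.get(var)
            if kind is None:
                out[var] = oc.compute_metrics(curve)
            else:
                out[var] = oc.compute_metrics(curve, bw, bh, kind=kind)
        return out

    def summary(self) -> str:
        m = self.metrics()
        lines = [
            "Gait trial analysis",
            f"  condition: {self.model.trial.condition.name}",
            f"  model: {self.model.model.provenance}",
            f"  stance: {self.stance[0]:.3f}-{self.stance[1]:.3f} s",
            f"  marker residual RMS: {1e3 * self.trajectory.residual_rms.mean():.2f} mm",
            f"  peak MCF: {m['MCF'].peak:.2f} %BW   impulse: {m['MCF'].impulse:.2f} %BW*s",
            f"  peak KAM: {m['KAM'].peak:.2f} %BW*BH impulse: {m['KAM'].impulse:.2f} %BW*BH*s",
            f"  peak residual force: {np.abs(self.dyn['residuals'][:, :3]).max():.1f} N",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        curves = self.stance_curves()
        if ax is None:
            _, ax = plt.subplots()
        x = np.linspace(0, 100, 101)
        bw = self.model.model.body_weight
        for var in ("MCF", "LCF", "TCF"):
            ax.plot(x, 100 * curves[var].values / bw, label=var)
        ax.set_xlabel("stance [%]")
        ax.set_ylabel("contact force [%BW]")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------

MODEL_ROUTES = ("linear", "mri_morph")
METRICS_TABLE = (("peak_kam", "KAM", "peak"), ("kam_impulse", "KAM", "impulse"),
                 ("peak_mcf", "MCF", "peak"), ("mcf_impulse", "MCF", "impulse"))


class CohortStudy:
    """The full synthetic study: subjects, conditions, trials, both models."""

    def __init__(self, seed: int = 1, demographics=COHORT_DEMOGRAPHICS,
                 n_trials: int = 3, conditions: dict | None = None,
                 noise: MarkerNoise | None = None,
                 template: TemplateModel | None = None,
                 wedge_cop_shift: float | None = None,
                 routes=MODEL_ROUTES):
        self.seed = int(seed)
        self.demographics = list(demographics)
        self.n_trials = n_trials
        self.conditions = conditions or default_conditions()
        self.noise = noise if noise is not None else MarkerNoise()
        self.template = template or TemplateModel()
        self.wedge_cop_shift = wedge_cop_shift
        self.routes = routes

    def build_subjects(self) -> list:
        return [generate_subject(self.seed + 97 * i, demo, template=self.template)
                for i, demo in enumerate(self.demographics)]

    def personalize(self, subject: SyntheticSubject) -> dict:
        models = {}
        if "linear" in self.routes:
            standing = generate_standing_trial(subject,
                                               seed=subject.spec.rng_seed + 11)
            models["linear"], _ = optimize_linear_scaling(standing, self.template,
                                                          subject.spec)
        if "mri_morph" in self.routes:
            models["mri_morph"], _ = morph_model(self.template, subject.bones,
                                                 subject.spec)
        return models

    def fit(self, progress: bool = False) -> "CohortResults":
        rows = []
        subjects = self.build_subjects()
        extra = {}
        if self.wedge_cop_shift is not None:
            extra["wedge_cop_shift"] = self.wedge_cop_shift
        for si, subject in enumerate(subjects):
            models = self.personalize(subject)
            for ci, (cname, cond) in enumerate(self.conditions.items()):
                for ti in range(self.n_trials):
                    tseed = (self.seed + 1009 * si + 101 * ci + ti) % (2 ** 31)
                    trial = generate_trial(subject, cond, noise=self.noise,
                                           seed=tseed, **extra)
                    for route, model in models.items():
                        res = GaitTrialModel(trial, model).fit()
                        met = res.metrics()
                        row = {"patient": subject.spec.id, "condition": cname,
                               "trial": ti, "model": route}
                        for key, var, which in METRICS_TABLE:
                            row[key] = getattr(met[var], which)
                        row["peak_tcf"] = met["TCF"].peak
                        row["max_residual_force"] = float(
                            np.abs(res.dyn["residuals"][:, :3]).max())
                        rows.append(row)
            if progress:
                print(f"  analyzed subject {subject.spec.id}")
        return CohortResults(trials=pd.DataFrame(rows), study=self)


@dataclass
class CohortResults:
    trials: pd.DataFrame
    study: CohortStudy

    # -- aggregation ----------------------------------------------------
    def patient_means(self, metric: str, route: str) -> pd.DataFrame:
        """patients x conditions table of per-patient trial means."""
        sub = self.trials[self.trials["model"] == route]
        tbl = sub.pivot_table(index="patient", columns="condition",
                              values=metric, aggfunc="mean")
        return tbl[[c for c in oc.CONDITION_ORDER if c in tbl.columns]]

    def group_table(self, route: str) -> pd.DataFrame:
        """Group mean +/- SD per metric and condition (descriptive table)."""
        rows = {}
        for metric, *_ in [(m,) for m, _, _ in METRICS_TABLE]:
            pm = self.patient_means(metric, route)
            rows[metric] = {c: f"{pm[c].mean():.2f} ± {pm[c].std(ddof=1):.2f}"
                            for c in pm.columns}
        return pd.DataFrame(rows).T

    def selections(self, metric: str, route: str) -> dict:
        """Per-patient and group best-alteration choices."""
        pm = self.patient_means(metric, route)
        out = {pat: oc.select_best_alteration(pm.loc[pat].to_dict()).choice
               for pat in pm.index}
        out["group"] = oc.select_best_alteration(pm.mean(axis=0).to_dict()).choice
        return out

    def selection_table(self) -> pd.DataFrame:
        rows = []
        for metric in ("peak_mcf", "mcf_impulse"):
            for route in self.study.routes:
                sel = self.selections(metric, route)
                for pat, choice in sel.items():
                    rows.append({"metric": metric, "model": route,
                                 "patient": pat, "selection": choice})
        return pd.DataFrame(rows)

    # -- statistics -----------------------------------------------------
    def stats(self, metric: str, route: str, alpha: float = 0.05,
              n_comparisons: int | None = None) -> dict:
        pm = self.patient_means(metric, route)
        sel = self.selections(metric, route)
        anova = oc.rm_anova(pm.to_numpy())
        pairs = {}
        shapiro_rows = []
        for cond in [c for c in pm.columns if c != "shod"]:
            pairs[cond] = (pm["shod"].to_numpy(), pm[cond].to_numpy())
        chosen = np.array([pm.loc[p, sel[p]] if sel[p] != "none" else pm.loc[p, "shod"]
                           for p in pm.index])
        pairs["individual"] = (pm["shod"].to_numpy(), chosen)
        for name, (x, y) in pairs.items():
            d = np.asarray(x) - np.asarray(y)
            if np.ptp(d) > 0:
                w, p = oc.shapiro_wilk(d)
            else:
                w, p = np.nan, np.nan
            shapiro_rows.append({"contrast": name, "W": w, "p": p})
        posthoc = oc.bonferroni_posthoc(pairs, alpha=alpha,
                                        n_comparisons=n_comparisons)
        return {"anova": anova, "posthoc": posthoc,
                "shapiro": pd.DataFrame(shapiro_rows).set_index("contrast"),
                "selections": sel}

    def stats_report(self, alpha: float = 0.05) -> dict:
        """The four repeated-measures analyses (2 MCF metrics x 2 routes)."""
        out = {}
        for metric in ("peak_mcf", "mcf_impulse"):
            for route in self.study.routes:
                out[(metric, route)] = self.stats(metric, route, alpha=alpha)
        return out

    def summary(self) -> str:
        lines = ["Synthetic cohort study "
                 f"({self.trials['patient'].nunique()} patients, "
                 f"{self.study.n_trials} trials/condition)"]
        for route in self.study.routes:
            lines.append(f"\n[{route}] group means ± SD")
            lines.append(self.group_table(route).to_string())
        rep = self.stats_report()
        for (metric, route), r in rep.items():
            a = r["anova"]
            lines.append(f"\nRM-ANOVA {metric} ({route}): "
                         f"F({a['df'][0]},{a['df'][1]}) = {a['F']:.3f}, p = {a['p']:.3f}")
            ind = r["posthoc"].loc["individual"]
            lines.append(f"  shod - individual best: "
                         f"{ind['mean_difference']:.3f} (SE {ind['se']:.3f}, "
                         f"adj p = {ind['p_adj']:.3f})")
        return "\n".join(lines)
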