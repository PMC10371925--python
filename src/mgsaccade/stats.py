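"""Condition-level statistics for scored memory-guided saccade trials.

Implements the study's inferential layer: per-subject condition
summaries, one-way repeated-measures ANOVA with partial eta squared,
paired t tests with Cohen's dz, tangential endpoint precision, the
12-bin location-heuristic analysis with a group-level Fisher r-to-z
test, inclusion-rate contrasts, the paired-t power calculator, and a
sensitivity rerun that drops high-exclusion subjects.

Conventions: the rm-ANOVA uses the condition x subject interaction as
its error term, F = MS_cond / MS_(cond x subj), df = (k-1, (k-1)(n-1)),
partial eta squared = SS_cond / (SS_cond + SS_error), with no sphericity
correction (matching integer error dfs). Cohen's dz = mean(d) / sd(d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CONDITIONS

__all__ = [
    "AnovaResult",
    "PairedTResult",
    "BinAnalysisResult",
    "summarize",
    "condition_matrix",
    "rm_anova_oneway",
    "paired_t",
    "one_sample_t",
    "tangential_precision",
    "fisher_z",
    "bin_heuristic_analysis",
    "compare_inclusion_rates",
    "power_paired_t",
    "analyze",
    "sensitivity_rerun",
]

PAIRWISE_CONTRASTS = (
    ("R1", "R2-random"),
    ("R1", "R2-best"),
    ("R2-random", "R2-best"),
)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "F": self.F, "df_effect": self.df_effect, "df_error": self.df_error,
            "p": self.p, "partial_eta_sq": self.partial_eta_sq,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    dz: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p, "dz": self.dz,
                "degenerate": self.degenerate}


def summarize(scored: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition summary over *included* trials.

    Expects the scored-trial table (columns ``subject``, ``condition``,
    ``recall_error_deg``, ``rt_ms``, ``n_saccades``, ``excluded``,
    endpoint/target columns). Cells with zero included trials are kept
    with NaN means and ``missing=True`` so callers can drop subjects
    listwise.
    """
    rows = []
    for (subj, cond), g in scored.groupby(["subject", "condition"], sort=True):
        inc = g[~g["excluded"].astype(bool)]
        n_inc, n_tot = len(inc), len(g)
        if n_inc > 0:
            tang = (
                tangential_precision(
                    inc[["final_x", "final_y"]].to_numpy(float),
                    np.degrees(np.arctan2(inc["target_y"], inc["target_x"])),
                )
                if n_inc >= 2
                else np.nan
            )
            rows.append({
                "subject": subj, "condition": cond,
                "mean_error_deg": float(inc["recall_error_deg"].mean()),
                "mean_rt_ms": float(inc["rt_ms"].mean()),
                "tangential_sd_deg": tang,
                "mean_n_saccades": float(inc["n_saccades"].mean()),
                "n_included": n_inc, "n_total": n_tot,
                "prop_included": n_inc / n_tot,
                "missing": False,
            })
        else:
            rows.append({
                "subject": subj, "condition": cond,
                "mean_error_deg": np.nan, "mean_rt_ms": np.nan,
                "tangential_sd_deg": np.nan, "mean_n_saccades": np.nan,
                "n_included": 0, "n_total": n_tot, "prop_included": 0.0,
                "missing": True,
            })
    return pd.DataFrame(rows)


def condition_matrix(summary: pd.DataFrame, value: str) -> np.ndarray:
    """Complete n_subjects x 3 matrix of ``value``; drops subjects with any
    missing cell (listwise)."""
    wide = summary.pivot(index="subject", columns="condition", values=value)
    wide = wide.reindex(columns=list(CONDITIONS)).dropna()
    return wide.to_numpy(float)


def rm_anova_oneway(matrix: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on an n x k within-subject matrix.

    Explicit sums-of-squares decomposition: SS_total = SS_subject +
    SS_condition + SS_error, with the condition x subject interaction as
    the error term. Perfectly additive data (SS_error = 0) are returned
    with ``degenerate=True``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 subjects, k >= 2 conditions")
    if np.isnan(m).any():
        raise ValueError("matrix contains missing cells; drop subjects listwise first")
    n, k = m.shape
    grand = m.mean()
    ss_cond = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((m - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_e, df_r = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df_e
    ms_err = ss_err / df_r
    scale = max(ss_tot, 1.0)
    if ms_err <= 1e-12 * scale:
        if ss_cond <= 1e-12 * scale:
            return AnovaResult(0.0, df_e, df_r, 1.0, 0.0, degenerate=True)
        return AnovaResult(np.inf, df_e, df_r, 0.0, 1.0, degenerate=True)
    F = ms_cond / ms_err
    p = float(sps.f.sf(F, df_e, df_r))
    eta = ss_cond / (ss_cond + ss_err)
    return AnovaResult(float(F), df_e, df_r, p, float(eta))


def _t_from_diff(d: np.ndarray) -> PairedTResult:
    d = np.asarray(d, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return PairedTResult(0.0, n - 1, 1.0, 0.0, degenerate=True)
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedTResult(t, n - 1, 0.0, t, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return PairedTResult(float(t), n - 1, p, float(d.mean() / sd))


def paired_t(a: np.ndarray, b: np.ndarray) -> PairedTResult:
    """Two-tailed paired t test of a vs b with Cohen's dz = mean(d)/sd(d)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    res = _t_from_diff(a - b)
    if not res.degenerate:
        # cross-check t/p against scipy's paired test (same formula)
        t_sp, p_sp = sps.ttest_rel(a, b)
        res = PairedTResult(float(t_sp), res.df, float(p_sp), res.dz)
    return res


def one_sample_t(x: np.ndarray, popmean: float = 0.0) -> PairedTResult:
    """Two-tailed one-sample t test, reported with dz = mean/sd."""
    return _t_from_diff(np.asarray(x, dtype=float) - popmean)


def tangential_precision(
    endpoints_xy: np.ndarray, target_angles_deg: np.ndarray
) -> float:
    """SD of endpoint positions tangential to the fixation-target axis.

    Each endpoint is rotated about the origin so its reported target lies
    at polar angle 0 (i.e., at (ecc, 0)); the sample SD (ddof=1) of the
    rotated y coordinates is returned, in degrees.
    """
    pts = np.asarray(endpoints_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 endpoints of shape (n, 2)")
    a = -np.radians(np.asarray(target_angles_deg, dtype=float))
    y_rot = pts[:, 0] * np.sin(a) + pts[:, 1] * np.cos(a)
    return float(np.std(y_rot, ddof=1))


def fisher_z(r: float, cap: float = 1.0 - 1e-12) -> float:
    """Variance-stabilizing transform atanh(r), with |r| capped below 1."""
    return float(np.arctanh(np.clip(r, -cap, cap)))


@dataclass
class BinAnalysisResult:
    per_subject: pd.DataFrame  # subject, r, z, n_bins_used, flag
    group: PairedTResult | None
    n_bins: int
    error_source: str
    method: str

    def as_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "error_source": self.error_source,
            "method": self.method,
            "group": None if self.group is None else self.group.as_dict(),
            "per_subject": self.per_subject.to_dict(orient="records"),
        }


def bin_heuristic_analysis(
    scored: pd.DataFrame,
    n_bins: int = 12,
    error_source: str = "R1",
    method: str = "pearson",
    min_bins: int = 3,
) -> BinAnalysisResult:
    """Location-heuristic test: does R2-best choice track per-location recall?

    Polar angle is split into ``n_bins`` equal arcs anchored at 0 deg
    (rightward). Per subject, the mean recall error of included
    ``error_source`` trials and the proportion of included R2-best trials
    whose *reported* target falls in each bin are correlated across bins
    (Pearson by default, Spearman optional); bins lacking either an
    error-source trial or an available R2-best target are excluded
    pairwise. Correlations are Fisher-z transformed and tested against 0
    across subjects. A reliably negative group test indicates choices
    follow the subject's per-location accuracy map (the heuristic); a
    null result indicates location-agnostic choice.
    """
    if error_source not in ("R1", "R2-random"):
        raise ValueError("error_source must be 'R1' or 'R2-random'")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    inc = scored[~scored["excluded"].astype(bool)]
    rows = []
    for subj, g in inc.groupby("subject", sort=True):
        err_trials = g[g["condition"] == error_source]
        best = g[g["condition"] == "R2-best"]
        flag = None
        if len(err_trials) == 0 or len(best) == 0:
            rows.append({"subject": subj, "r": np.nan, "z": np.nan,
                         "n_bins_used": 0, "flag": "no_trials"})
            continue
        eb = np.digitize(np.mod(err_trials["reported_angle_deg"], 360.0), edges) - 1
        err_mean = np.full(n_bins, np.nan)
        for b in range(n_bins):
            m = eb == b
            if m.any():
                err_mean[b] = err_trials["recall_error_deg"].to_numpy()[m].mean()
        cb = np.digitize(np.mod(best["reported_angle_deg"], 360.0), edges) - 1
        choice_prop = np.bincount(cb, minlength=n_bins) / len(best)
        # a bin is available on the choice side if any R2-best trial *presented*
        # a target there; fall back to reported bins if presented angles absent
        if {"target_angle_0", "target_angle_1"}.issubset(best.columns):
            pres = np.concatenate([
                np.mod(best["target_angle_0"].dropna().to_numpy(float), 360.0),
                np.mod(best["target_angle_1"].dropna().to_numpy(float), 360.0),
            ])
        else:
            pres = np.mod(best["reported_angle_deg"].to_numpy(float), 360.0)
        avail = np.zeros(n_bins, dtype=bool)
        avail[np.unique(np.digitize(pres, edges) - 1)] = True
        use = ~np.isnan(err_mean) & avail
        if use.sum() < min_bins:
            rows.append({"subject": subj, "r": np.nan, "z": np.nan,
                         "n_bins_used": int(use.sum()), "flag": "too_few_bins"})
            continue
        ev, cv = err_mean[use], choice_prop[use]
        if np.std(ev) == 0.0 or np.std(cv) == 0.0:
            rows.append({"subject": subj, "r": np.nan, "z": np.nan,
                         "n_bins_used": int(use.sum()), "flag": "zero_variance"})
            continue
        if method == "pearson":
            r = float(np.corrcoef(ev, cv)[0, 1])
        else:
            r = float(sps.spearmanr(ev, cv).statistic)
        rows.append({"subject": subj, "r": r, "z": fisher_z(r),
                     "n_bins_used": int(use.sum()), "flag": flag})
    per_subject = pd.DataFrame(rows)
    zs = per_subject["z"].dropna().to_numpy()
    group = one_sample_t(zs) if len(zs) >= 2 else None
    return BinAnalysisResult(per_subject, group, n_bins, error_source, method)


def compare_inclusion_rates(summary: pd.DataFrame) -> dict[str, PairedTResult]:
    """Paired t tests of per-subject inclusion proportions between conditions."""
    wide = summary.pivot(index="subject", columns="condition",
                         values="prop_included").dropna()
    out = {}
    for a, b in PAIRWISE_CONTRASTS:
        out[f"{a}_vs_{b}"] = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
    return out


def power_paired_t(
    dz: float,
    power: float = 0.80,
    alpha: float = 0.05,
    two_tailed: bool = True,
    n_max: int = 100_000,
) -> int:
    """Smallest n giving the requested power for a paired (one-sample) t test.

    Uses the exact noncentral-t power function: with noncentrality
    dz * sqrt(n) and df = n - 1, power = P(|T'| > t_crit) (two-tailed)
    or P(T' > t_crit) (one-tailed).
    """
    if dz <= 0:
        raise ValueError("dz must be > 0")
    if not (0.0 < power < 1.0 and 0.0 < alpha < 1.0):
        raise ValueError("power and alpha must be in (0, 1)")
    for n in range(2, n_max + 1):
        df = n - 1
        ncp = dz * np.sqrt(n)
        if two_tailed:
            tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
            pw = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
        else:
            tcrit = sps.t.ppf(1.0 - alpha, df)
            pw = sps.nct.sf(tcrit, df, ncp)
        if pw >= power:
            return n
    raise ValueError("requested power not reached within n_max")


def _pairwise_block(wide: pd.DataFrame) -> dict:
    out = {}
    for a, b in PAIRWISE_CONTRASTS:
        out[f"{a}_vs_{b}"] = paired_t(wide[a].to_numpy(), wide[b].to_numpy()).as_dict()
    return out


def analyze(
    scored: pd.DataFrame,
    n_bins: int = 12,
    bin_error_source: str = "R1",
    bin_method: str = "pearson",
) -> dict:
    """Full condition-level statistics report (JSON-serializable dict)."""
    summary = summarize(scored)
    report: dict = {"n_subjects": int(summary["subject"].nunique())}
    for value, label in [
        ("mean_error_deg", "recall_error"),
        ("mean_rt_ms", "rt"),
        ("tangential_sd_deg", "tangential_sd"),
        ("mean_n_saccades", "n_saccades"),
    ]:
        wide = summary.pivot(index="subject", columns="condition", values=value)
        wide = wide.reindex(columns=list(CONDITIONS)).dropna()
        block: dict = {
            "condition_means": {c: float(wide[c].mean()) for c in CONDITIONS},
            "n_subjects_used": int(len(wide)),
        }
        if len(wide) >= 2:
            block["anova"] = rm_anova_oneway(wide.to_numpy(float)).as_dict()
            block["pairwise"] = _pairwise_block(wide)
        report[label] = block
    if summary["subject"].nunique() >= 2:
        report["inclusion"] = {
            k: v.as_dict() for k, v in compare_inclusion_rates(summary).items()
        }
    else:
        report["inclusion"] = None
    try:
        report["bin_heuristic"] = bin_heuristic_analysis(
            scored, n_bins=n_bins, error_source=bin_error_source, method=bin_method
        ).as_dict()
    except ValueError:
        report["bin_heuristic"] = None
    report["summary"] = summary.to_dict(orient="records")
    return report


def sensitivity_rerun(
    scored: pd.DataFrame, exclusion_rate_cutoff: float = 0.20, **analyze_kwargs
) -> dict:
    """Re-run the full report keeping only subjects at or below the
    excluded-trial-rate cutoff."""
    rate = scored.groupby("subject")["excluded"].mean()
    keep = rate[rate <= exclusion_rate_cutoff].index
    if len(keep) < 2:
        raise ValueError("fewer than 2 subjects retained at this cutoff")
    sub = scored[scored["subject"].isin(keep)]
    report = analyze(sub, **analyze_kwargs)
    report["dropped_subjects"] = sorted(set(scored["subject"]) - set(keep))
    report["exclusion_rate_cutoff"] = exclusion_rate_cutoff
    return report
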