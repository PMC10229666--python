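"""Survival layer: KM curves, log-rank, Cox PH, risk groups, C-index.

Molecular clusters (MCs) carry distinct overall-survival profiles; this
module estimates them (Kaplan–Meier with Greenwood/log-log intervals),
tests pairwise separation (log-rank), adjusts for clinical covariates
(Cox proportional hazards, Efron ties), aggregates MCs into risk groups
by similarity of their survival curves over the landmark window where
all curves stay above a survival floor (0.25 by default), and compares
risk scores by bootstrapped differences of Harrell's C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
import statsmodels.api as sm


@dataclass
class SurvivalCurve:
    times: np.ndarray        # ordered observed times (months)
    S: np.ndarray            # survival probability at each time
    at_risk: np.ndarray
    events: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float = np.nan

    def validate(self) -> None:
        if (np.diff(self.S) > 1e-12).any():
            raise AssertionError("S must be non-increasing")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise AssertionError("S outside [0,1]")

    def survival_at(self, t: np.ndarray | float) -> np.ndarray:
        """Step-function value S(t); S(t)=1 before the first observed time."""
        t = np.atleast_1d(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.S[np.clip(idx, 0, len(self.S) - 1)])
        return out


@dataclass(frozen=True)
class RiskGroupingConfig:
    survival_floor: float = 0.25
    n_groups_target: int | None = None
    linkage: str = "average"
    grid_points: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.survival_floor < 1.0):
            raise ValueError("survival_floor must be in (0,1)")


@dataclass
class RiskGrouping:
    assignment: dict[str, int]          # MC name -> group id (0 = best OS)
    n_groups: int
    group_medians: dict[int, float]     # pooled KM median OS per group
    group_median_ci: dict[int, tuple[float, float]]
    landmark_time: float = np.nan

    def validate(self) -> None:
        if set(self.assignment.values()) != set(range(self.n_groups)):
            raise AssertionError("group ids must be 0..n_groups-1")
        meds = [self.group_medians[g] for g in range(self.n_groups)]
        clean = [m for m in meds if np.isfinite(m)]
        if clean != sorted(clean, reverse=True):
            raise AssertionError("groups must be ordered by median OS descending")


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit estimator with Greenwood variance and log-log 95% CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    t = tab.index.to_numpy(dtype=float)
    keep = t > 0  # drop the t=0 anchor row; S(0)=1 is implicit
    ci = kmf.confidence_interval_survival_function_
    curve = SurvivalCurve(
        times=t[keep],
        S=kmf.survival_function_["KM_estimate"].to_numpy()[keep],
        at_risk=tab["at_risk"].to_numpy()[keep],
        events=tab["observed"].to_numpy()[keep],
        ci_lower=ci.iloc[:, 0].to_numpy()[keep],
        ci_upper=ci.iloc[:, 1].to_numpy()[keep],
        median=float(kmf.median_survival_time_),
    )
    curve.validate()
    return curve


def logrank_pairwise(times, events, labels) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group log-rank test for every pair of groups.

    Returns ``(statistic, p_value)`` square DataFrames (chi-squared on
    1 df); ``-log10(p)`` of the latter is the heatmap substrate.
    Groups with no subjects are excluded with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    groups = [g for g in np.unique(labels) if (labels == g).sum() > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    stat = pd.DataFrame(0.0, index=groups, columns=groups)
    pval = pd.DataFrame(1.0, index=groups, columns=groups)
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            mi, mj = labels == gi, labels == gj
            res = logrank_test(times[mi], times[mj], events[mi], events[mj])
            stat.loc[gi, gj] = stat.loc[gj, gi] = res.test_statistic
            pval.loc[gi, gj] = pval.loc[gj, gi] = res.p_value
    return stat, pval


def cox_ph(
    times, events, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) with Wald intervals.

    Returns a per-covariate table with ``coef``, ``se``, ``HR``,
    ``HR_lower``, ``HR_upper``, ``p`` plus the model concordance in
    ``.attrs['concordance']``.
    """
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    if (covariates.nunique() <= 1).any():
        bad = list(covariates.columns[covariates.nunique() <= 1])
        raise ValueError(f"constant covariates: {bad}")
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = events
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")  # lifelines: Efron ties
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "HR": s["exp(coef)"],
            "HR_lower": s["exp(coef) lower 95%"],
            "HR_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    out.attrs["concordance"] = float(cph.concordance_index_)
    return out


def _silhouette_cut(tree: np.ndarray, D_square: np.ndarray) -> int:
    """Group count maximizing the mean silhouette of the curve clustering
    (ties toward fewer groups)."""
    n = len(D_square)
    best_k, best_s = 2, -np.inf
    for k in range(2, n):
        labels = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        from sklearn.metrics import silhouette_score

        s = silhouette_score(D_square, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def aggregate_risk_groups(
    curves: dict[str, SurvivalCurve],
    cfg: RiskGroupingConfig | None = None,
    survival_data: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> RiskGrouping:
    """Aggregate MCs whose survival profiles are similar where all stay
    above the survival floor.

    The landmark t* is the largest time at which every MC's S(t) still
    exceeds ``survival_floor``; each MC is embedded by its S values on a
    uniform grid over [0, t*] and grouped by agglomerative clustering on
    L2 curve distance, cut at ``n_groups_target`` when given, else at
    the group count maximizing the silhouette of the curve clustering.  Group medians come from the
    pooled KM fit when raw ``survival_data`` is supplied, else from the
    mean of member medians.
    """
    cfg = cfg or RiskGroupingConfig()
    names = sorted(curves)
    if not names:
        raise ValueError("need at least one curve")

    last_above = []
    for nm in names:
        c = curves[nm]
        above = c.times[c.S > cfg.survival_floor]
        last_above.append(above.max() if above.size else 0.0)
    t_star = float(min(last_above))
    if t_star <= 0:
        warnings.warn(
            "some curve drops below the survival floor immediately; "
            "falling back to the shortest observed horizon"
        )
        t_star = float(min(c.times.max() for c in curves.values()))

    grid = np.linspace(0.0, t_star, cfg.grid_points)
    profile = np.vstack([curves[nm].survival_at(grid) for nm in names])

    if len(names) == 1:
        groups = np.zeros(1, dtype=int)
        n_groups = 1
    else:
        D_square = np.sqrt(
            ((profile[:, None, :] - profile[None, :, :]) ** 2).sum(axis=2)
        )
        D = squareform(D_square, checks=False)
        tree = linkage(D, method=cfg.linkage)
        if cfg.n_groups_target is not None:
            n_groups = min(cfg.n_groups_target, len(names))
        elif np.allclose(D, 0):
            n_groups = 1
        else:
            n_groups = _silhouette_cut(tree, D_square)
        groups = fcluster(tree, t=n_groups, criterion="maxclust") - 1
        n_groups = len(np.unique(groups))

    # order groups by pooled median OS, best first
    medians, cis = {}, {}
    for g in np.unique(groups):
        members = [names[i] for i in range(len(names)) if groups[i] == g]
        if survival_data is not None:
            t = np.concatenate([survival_data[m][0] for m in members])
            e = np.concatenate([survival_data[m][1] for m in members])
            kmf = KaplanMeierFitter().fit(t, e)
            from lifelines.utils import median_survival_times

            med = float(kmf.median_survival_time_)
            ci_df = median_survival_times(kmf.confidence_interval_)
            lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
        else:
            member_meds = [curves[m].median for m in members]
            med = float(np.nanmean(member_meds))
            lo = hi = np.nan
        medians[int(g)] = med
        cis[int(g)] = (lo, hi)

    order = sorted(medians, key=lambda g: -(medians[g] if np.isfinite(medians[g]) else np.inf))
    remap = {old: new for new, old in enumerate(order)}
    grouping = RiskGrouping(
        assignment={names[i]: remap[int(groups[i])] for i in range(len(names))},
        n_groups=int(len(order)),
        group_medians={remap[g]: medians[g] for g in medians},
        group_median_ci={remap[g]: cis[g] for g in cis},
        landmark_time=t_star,
    )
    grouping.validate()
    return grouping


def harrell_c(times, events, risk_scores) -> float:
    """Censoring-aware concordance between risk score and survival order.

    Higher risk score must pair with shorter survival; 0.5 is chance.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    scores = np.asarray(risk_scores, dtype=float)
    if not (len(times) == len(events) == len(scores)):
        raise ValueError("inputs must align")
    # lifelines' concordance_index expects higher prediction = longer survival
    return float(concordance_index(times, -scores, events))


def bootstrap_c_difference(
    times, events, scores_a, scores_b, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Paired bootstrap of C_A - C_B with a percentile 95% CI."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    delta = harrell_c(times, events, sa) - harrell_c(times, events, sb)
    rng = np.random.default_rng(seed)
    n = len(times)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if events[idx].sum() == 0:
            draws[b] = np.nan
            continue
        draws[b] = harrell_c(times[idx], events[idx], sa[idx]) - harrell_c(
            times[idx], events[idx], sb[idx]
        )
    lo, hi = np.nanpercentile(draws, [2.5, 97.5])
    return float(delta), (float(lo), float(hi))


def response_logistic(
    response, cluster_labels, covariates: pd.DataFrame | None = None,
    reference: object | None = None,
) -> pd.DataFrame:
    """Multivariate logistic regression of treatment response.

    Cluster labels enter as dummies against ``reference`` (largest
    cluster by default); returns per-term OR with Wald 95% CI and p.
    Perfect separation (e.g. all responses identical) raises.
    """
    y = np.asarray(response, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("response is degenerate: only one outcome level")
    labels = pd.Series(np.asarray(cluster_labels), name="cluster").astype(str)
    if reference is None:
        reference = labels.value_counts().idxmax()
    dummies = pd.get_dummies(labels, prefix="MC", dtype=float)
    ref_col = f"MC_{reference}"
    if ref_col not in dummies.columns:
        raise ValueError(f"reference cluster {reference!r} not present")
    Xd = dummies.drop(columns=[ref_col])
    if covariates is not None:
        Xd = pd.concat([Xd, pd.DataFrame(covariates).reset_index(drop=True)], axis=1)
    Xd = sm.add_constant(Xd.astype(float))
    try:
        fit = sm.Logit(y, Xd).fit(disp=0)
    except Exception as exc:  # separation / singular design
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    params = fit.params
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "OR": np.exp(params),
            "OR_lower": np.exp(ci[0]),
            "OR_upper": np.exp(ci[1]),
            "p": fit.pvalues,
        }
    )
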