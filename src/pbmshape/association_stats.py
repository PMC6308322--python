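"""Association statistics: ICP categories, clustered regression, RM-ANOVA, ROC.

The unit of observation for shape scores is the scan (or eye); subjects
contribute two eyes, so eye-level analyses must account for within-subject
correlation.  Intracranial pressure (ICP) is measured once per subject as
lumbar-puncture opening pressure in cm H2O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import ClassificationError, EstimationError, InputError

ICP_NORMAL_MAX = 20.0  # cm H2O, upper bound of the normal category
ICP_ELEVATED_MIN = 25.0  # cm H2O, lower bound of the elevated category

DICHOTOMIES = ("elevated_vs_rest", "rest_vs_normal")


def categorize_icp(pressure: float) -> str:
    """Map an opening pressure (cm H2O) to normal / borderline / elevated.

    Boundaries: normal iff p <= 20; borderline iff 20 < p < 25;
    elevated iff p >= 25.
    """
    p = float(pressure)
    if not np.isfinite(p) or p < 0:
        raise InputError(f"opening pressure must be finite and >= 0, got {pressure}")
    if p <= ICP_NORMAL_MAX:
        return "normal"
    if p < ICP_ELEVATED_MIN:
        return "borderline"
    return "elevated"


@dataclass(frozen=True)
class IcpRecord:
    subject_id: str
    opening_pressure: float  # cm H2O
    category: str = ""

    def __post_init__(self):
        cat = categorize_icp(self.opening_pressure)
        if self.category and self.category != cat:
            raise InputError(
                f"category {self.category!r} inconsistent with pressure "
                f"{self.opening_pressure} (expected {cat!r})"
            )
        object.__setattr__(self, "category", cat)


@dataclass
class GeeFit:
    slope: float  # change in score per cm H2O
    intercept: float
    slope_se: float  # robust (sandwich) SE
    intercept_se: float
    wald_z: float
    p_value: float
    working_corr: float  # exchangeable correlation parameter (0 under independence)
    n_clusters: int
    n_obs: int
    converged: bool


def fit_gee(
    scores,
    icp,
    clusters,
    working: str = "exchangeable",
) -> GeeFit:
    """Identity-link Gaussian GEE of shape score on ICP with clustered eyes.

    Robust (sandwich) standard errors use the Mancl-DeRouen bias-reduced
    estimator and the Wald statistic is referred to a t distribution with
    (n_clusters - 2) degrees of freedom, which keeps the test close to nominal
    size at cohort-scale cluster counts.
    """
    y = np.asarray(scores, dtype=float)
    x = np.asarray(icp, dtype=float)
    groups = np.asarray(clusters)
    if y.shape != x.shape or y.shape != groups.shape:
        raise InputError("scores, icp and clusters must have equal length")
    n_clusters = len(np.unique(groups))
    if n_clusters < 3:
        raise InputError(f"fit_gee requires >= 3 clusters, got {n_clusters}")
    if np.ptp(x) == 0:
        raise EstimationError("singular design: ICP is constant")
    if working not in ("exchangeable", "independence"):
        raise InputError(f"unknown working correlation {working!r}")

    X = sm.add_constant(x)
    # Perfect-fit and constant-response cases degenerate in the sandwich
    # estimator (zero residual variance); resolve them exactly.
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    scale = max(1.0, float(np.max(np.abs(y))))
    if np.max(np.abs(resid)) < 1e-10 * scale:
        exact_zero = abs(beta[1]) < 1e-12 * scale
        return GeeFit(
            slope=float(beta[1]),
            intercept=float(beta[0]),
            slope_se=0.0,
            intercept_se=0.0,
            wald_z=0.0 if exact_zero else np.inf,
            p_value=1.0 if exact_zero else 0.0,
            working_corr=0.0,
            n_clusters=n_clusters,
            n_obs=len(y),
            converged=True,
        )

    cov = (
        sm.cov_struct.Exchangeable()
        if working == "exchangeable"
        else sm.cov_struct.Independence()
    )
    model = sm.GEE(y, X, groups=groups, family=sm.families.Gaussian(), cov_struct=cov)
    res = model.fit(cov_type="bias_reduced", maxiter=100)
    converged = bool(getattr(res, "converged", True))
    slope, intercept = float(res.params[1]), float(res.params[0])
    se_slope, se_int = float(res.bse[1]), float(res.bse[0])
    if se_slope == 0:
        z = 0.0 if slope == 0 else np.inf
        p = 1.0 if slope == 0 else 0.0
    else:
        z = slope / se_slope
        p = 2.0 * sps.t.sf(abs(z), df=max(n_clusters - 2, 1))
    dep = cov.dep_params if working == "exchangeable" else 0.0
    return GeeFit(
        slope=slope,
        intercept=intercept,
        slope_se=se_slope,
        intercept_se=se_int,
        wald_z=float(z),
        p_value=float(p),
        working_corr=float(np.atleast_1d(dep)[0]) if dep is not None else 0.0,
        n_clusters=n_clusters,
        n_obs=len(y),
        converged=converged,
    )


def gee_slope_ci(fit: GeeFit, level: float = 0.95) -> tuple[float, float]:
    """Robust t-based confidence interval for the ICP slope."""
    tcrit = sps.t.ppf(0.5 + level / 2.0, df=max(fit.n_clusters - 2, 1))
    return (fit.slope - tcrit * fit.slope_se, fit.slope + tcrit * fit.slope_se)


@dataclass
class RmAnovaResult:
    angle_f: float
    angle_p: float
    angle_df: tuple[int, int]
    eye_f: float
    eye_p: float
    eye_df: tuple[int, int]
    icp_f: float
    icp_p: float
    icp_df: tuple[int, int]
    n_subjects: int
    n_dropped: int  # subjects removed by listwise handling
    gg_epsilon: float | None = None


def _ratio_f(ss_effect, df_effect, ss_error, df_error):
    if ss_effect <= 0 or df_effect <= 0:
        return 0.0, 1.0
    ms_err = ss_error / df_error if df_error > 0 else 0.0
    if ms_err <= 0:
        return np.inf, 0.0
    f = (ss_effect / df_effect) / ms_err
    return float(f), float(sps.f.sf(f, df_effect, df_error))


def rm_anova(
    table: pd.DataFrame,
    icp: dict | pd.Series,
    gg_correction: bool = False,
    expected_angles: tuple | None = None,
) -> RmAnovaResult:
    """Split-plot repeated-measures ANOVA of PC1_all with ICP as covariate.

    ``table`` must have columns ``subject_id``, ``eye``, ``angle_deg`` and
    ``score`` with one row per cell.  Within-subject effects (scan angle, eye)
    are tested against their subject-interaction error strata; the
    between-subject ICP covariate is tested against the residual
    between-subject variation.  Subjects with incomplete eye x angle tables
    are dropped (listwise handling); optionally a Greenhouse-Geisser epsilon
    correction is applied to the angle test.
    """
    req = {"subject_id", "eye", "angle_deg", "score"}
    if not req.issubset(table.columns):
        raise InputError(f"table missing columns {sorted(req - set(table.columns))}")
    icp = dict(icp) if not isinstance(icp, dict) else icp
    if expected_angles is not None:
        missing = sorted(set(expected_angles) - set(table["angle_deg"]))
        if missing:
            raise InputError(f"design error: no subject has data at angle(s) {missing}")
    angles = np.sort(table["angle_deg"].unique())
    eyes = np.sort(table["eye"].unique())
    a, e = len(angles), len(eyes)
    if a < 2:
        raise InputError("rm_anova needs >= 2 angle levels")
    cell = table.pivot_table(
        index="subject_id", columns=["eye", "angle_deg"], values="score", aggfunc="mean"
    )
    complete = cell.dropna(axis=0)
    n_dropped = len(cell) - len(complete)
    s = len(complete)
    if s < 3:
        raise InputError(f"rm_anova requires >= 3 complete subjects, got {s}")

    # y[s, e, a]
    y = np.empty((s, e, a))
    for ei, eye in enumerate(eyes):
        for ai, ang in enumerate(angles):
            y[:, ei, ai] = complete[(eye, ang)].to_numpy()

    grand = y.mean()
    subj_mean = y.mean(axis=(1, 2))
    angle_mean = y.mean(axis=(0, 1))
    eye_mean = y.mean(axis=(0, 2))
    sa_mean = y.mean(axis=1)  # (s, a)
    se_mean = y.mean(axis=2)  # (s, e)

    ss_angle = s * e * np.sum((angle_mean - grand) ** 2)
    ss_as = e * np.sum((sa_mean - subj_mean[:, None] - angle_mean[None, :] + grand) ** 2)
    df_angle, df_as = a - 1, (a - 1) * (s - 1)

    ss_eye = s * a * np.sum((eye_mean - grand) ** 2)
    ss_es = a * np.sum((se_mean - subj_mean[:, None] - eye_mean[None, :] + grand) ** 2)
    df_eye, df_es = e - 1, (e - 1) * (s - 1)

    gg_eps = None
    if gg_correction and a > 2:
        # epsilon from the eye-averaged subject x angle matrix
        resid = sa_mean - sa_mean.mean(axis=0, keepdims=True)
        S = resid.T @ resid / max(s - 1, 1)
        mean_diag = np.trace(S) / a
        mean_all = S.mean()
        num = (a * (mean_diag - mean_all)) ** 2
        den = (a - 1) * (np.sum(S**2) - 2 * a * np.sum(S.mean(axis=1) ** 2) + a**2 * mean_all**2)
        gg_eps = float(np.clip(num / den if den > 0 else 1.0, 1.0 / (a - 1), 1.0))

    if gg_eps is not None:
        f_angle, _ = _ratio_f(ss_angle, df_angle, ss_as, df_as)
        p_angle = float(sps.f.sf(f_angle, gg_eps * df_angle, gg_eps * df_as)) if np.isfinite(f_angle) and f_angle > 0 else (1.0 if f_angle == 0 else 0.0)
    else:
        f_angle, p_angle = _ratio_f(ss_angle, df_angle, ss_as, df_as)
    f_eye, p_eye = _ratio_f(ss_eye, df_eye, ss_es, df_es)

    # Between-subject stratum: subject means regressed on ICP.
    try:
        x = np.array([float(icp[sid]) for sid in complete.index])
    except KeyError as exc:
        raise InputError(f"missing ICP for subject {exc}") from exc
    if np.ptp(x) == 0:
        raise EstimationError("singular design: ICP is constant across subjects")
    xc = x - x.mean()
    yc = subj_mean - subj_mean.mean()
    slope = float(xc @ yc / (xc @ xc))
    ss_icp = a * e * slope**2 * float(xc @ xc)
    ss_b_resid = a * e * float(np.sum((yc - slope * xc) ** 2))
    df_icp, df_b = 1, s - 2
    f_icp, p_icp = _ratio_f(ss_icp, df_icp, ss_b_resid, df_b)

    return RmAnovaResult(
        angle_f=f_angle,
        angle_p=p_angle,
        angle_df=(df_angle, df_as),
        eye_f=f_eye,
        eye_p=p_eye,
        eye_df=(df_eye, df_es),
        icp_f=f_icp,
        icp_p=p_icp,
        icp_df=(df_icp, df_b),
        n_subjects=s,
        n_dropped=n_dropped,
        gg_epsilon=gg_eps,
    )


@dataclass
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    dichotomy: str
    n_positive: int
    n_negative: int
    operating_points: pd.DataFrame  # sensitivity, specificity, threshold


def select_one_eye(table: pd.DataFrame, eye_rule: str = "right", seed: int | None = None) -> pd.DataFrame:
    """Reduce an eye-level score table to one row per subject.

    ``eye_rule``: "right" prefers OD and falls back to OS, "left" the reverse,
    "random" picks a seeded random eye per subject.
    """
    if eye_rule not in ("right", "left", "random"):
        raise InputError(f"unknown eye_rule {eye_rule!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for sid, sub in table.groupby("subject_id", sort=True):
        eyes = list(sub["eye"].unique())
        if eye_rule == "random":
            pick = eyes[rng.integers(len(eyes))]
        else:
            pref = "OD" if eye_rule == "right" else "OS"
            pick = pref if pref in eyes else eyes[0]
        rows.append(sub[sub["eye"] == pick].iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    m, n = len(pos), len(neg)
    # placement values (structural components)
    v10 = np.empty(m)
    for i, xi in enumerate(pos):
        v10[i] = (np.sum(xi > neg) + 0.5 * np.sum(xi == neg)) / n
    v01 = np.empty(n)
    for j, yj in enumerate(neg):
        v01[j] = (np.sum(pos > yj) + 0.5 * np.sum(pos == yj)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Empirical AUC = normalized Mann-Whitney U with half credit for ties."""
    combined = np.concatenate([pos, neg])
    ranks = sps.rankdata(combined)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_auc(
    table: pd.DataFrame,
    dichotomy: str = "elevated_vs_rest",
    eye_rule: str = "right",
    seed: int | None = None,
) -> RocResult:
    """ROC analysis of per-subject shape scores against ICP categories.

    ``table`` needs columns ``subject_id``, ``eye``, ``score`` and
    ``category``.  One eye per subject is kept (``eye_rule``) so observations
    are independent.  Dichotomies: ``elevated_vs_rest`` (elevated, >= 25 cm
    H2O, versus normal or borderline) and ``rest_vs_normal`` (borderline or
    elevated, > 20 cm H2O, versus normal).  The 95% CI uses the DeLong
    variance of the empirical AUC.
    """
    req = {"subject_id", "eye", "score", "category"}
    if not req.issubset(table.columns):
        raise InputError(f"table missing columns {sorted(req - set(table.columns))}")
    if dichotomy not in DICHOTOMIES:
        raise InputError(f"unknown dichotomy {dichotomy!r}")
    one = select_one_eye(table, eye_rule=eye_rule, seed=seed)
    if dichotomy == "elevated_vs_rest":
        positive = one["category"] == "elevated"
    else:
        positive = one["category"].isin(["borderline", "elevated"])
    y = positive.to_numpy(dtype=bool)
    scores = one["score"].to_numpy(dtype=float)
    if y.all() or not y.any():
        raise ClassificationError(
            f"dichotomy {dichotomy!r} leaves a single class "
            f"({int(y.sum())} positive of {len(y)})"
        )
    pos, neg = scores[y], scores[~y]
    auc = mann_whitney_auc(pos, neg)
    var = _delong_variance(pos, neg)
    half = 1.959963984540054 * np.sqrt(var)
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    fpr, tpr, thr = roc_curve(y.astype(int), scores, drop_intermediate=False)
    ops = pd.DataFrame({"sensitivity": tpr, "specificity": 1 - fpr, "threshold": thr})
    return RocResult(
        auc=auc,
        ci_lower=float(lo),
        ci_upper=float(hi),
        dichotomy=dichotomy,
        n_positive=int(y.sum()),
        n_negative=int((~y).sum()),
        operating_points=ops,
    )
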