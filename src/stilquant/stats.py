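"""Survival and concordance statistics for biomarker evaluation.

Manual-score handling (two-block averaging, >10% cutpoint), Kaplan–Meier
estimation, two-sample log-rank, Cox proportional hazards with the
increment scalings (manual % / 10, density / 300), maximally selected rank
statistics for data-driven cutpoint selection, pairwise Spearman
correlation, and the sensitivity/specificity concordance report between
manual and automated dichotomizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats as sps

__all__ = [
    "combine_block_scores",
    "dichotomize",
    "Dichotomy",
    "km_estimate",
    "KMResult",
    "logrank_stat",
    "LogrankResult",
    "cox_fit",
    "SurvivalFit",
    "maxstat_cutpoint",
    "CutpointResult",
    "pairwise_spearman",
    "concordance_report",
    "ConcordanceReport",
    "prepare_cohort",
    "MANUAL_CUTPOINT_PCT",
    "DENSITY_SCALE",
    "MANUAL_SCALE",
]

MANUAL_CUTPOINT_PCT = 10.0  # manual sTIL dichotomized strictly-greater at 10%
MANUAL_SCALE = 10.0  # continuous manual score entered per +10%
DENSITY_SCALE = 300.0  # continuous density entered per +300 cells/mm²


# ---------------------------------------------------------------------------
# score handling
# ---------------------------------------------------------------------------


def combine_block_scores(scores) -> float:
    """Average the manual sTIL percent over the available tumor blocks
    (one or two); NaN when no block score exists."""
    vals = [s for s in scores if s is not None and np.isfinite(s)]
    if not vals:
        return float("nan")
    if len(vals) > 2:
        raise ValueError("at most two block scores expected")
    return float(np.mean(vals))


@dataclass(frozen=True)
class Dichotomy:
    """Binary grouping with the boundary rule recorded."""

    high: np.ndarray  # True = high group
    cutpoint: float
    rule: str  # "strictly_greater" or "geq"


def dichotomize(values, cutpoint: float, rule: str) -> Dichotomy:
    """Split into low/high groups.  Manual scores use ``strictly_greater``
    at 10%; densities use ``geq`` at the selected cutpoint."""
    v = np.asarray(values, dtype=float)
    if rule == "strictly_greater":
        high = v > cutpoint
    elif rule == "geq":
        high = v >= cutpoint
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return Dichotomy(high=high, cutpoint=float(cutpoint), rule=rule)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


@dataclass
class KMResult:
    """Product-limit estimate: right-continuous step function with
    Greenwood-based confidence band and median survival."""

    timeline: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    median: float
    median_ci: tuple[float, float]

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.timeline,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def km_estimate(times, events, alpha: float = 0.05) -> KMResult:
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if len(times) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    ci = kmf.confidence_interval_
    med_ci_df = median_survival_times(ci)
    med_ci = (float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1]))
    return KMResult(
        timeline=kmf.survival_function_.index.to_numpy(float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(float),
        ci_low=ci.iloc[:, 0].to_numpy(float),
        ci_high=ci.iloc[:, 1].to_numpy(float),
        median=float(kmf.median_survival_time_),
        median_ci=med_ci,
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def _logrank_z(times: np.ndarray, events: np.ndarray, group1: np.ndarray) -> float:
    """Signed standardized two-sample log-rank statistic.

    Positive when group1 has *more* events than expected (worse survival).
    Hypergeometric variance; tied events decrement risk sets simultaneously.
    """
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order].astype(float), group1[order].astype(float)
    _, idx = np.unique(t, return_index=True)
    d = np.add.reduceat(e, idx)
    d1 = np.add.reduceat(e * g, idx)
    leave = np.add.reduceat(np.ones_like(e), idx)
    leave1 = np.add.reduceat(g, idx)
    n = len(t) - np.concatenate([[0.0], np.cumsum(leave)[:-1]])
    n1 = g.sum() - np.concatenate([[0.0], np.cumsum(leave1)[:-1]])
    ev = d > 0
    d, d1, n, n1 = d[ev], d1[ev], n[ev], n1[ev]
    o_minus_e = float((d1 - d * n1 / n).sum())
    ok = n > 1
    var = float((d[ok] * (n1[ok] / n[ok]) * (1 - n1[ok] / n[ok]) * (n[ok] - d[ok]) / (n[ok] - 1)).sum())
    if var <= 0:
        return 0.0
    return o_minus_e / np.sqrt(var)


@dataclass(frozen=True)
class LogrankResult:
    z: float  # signed standardized statistic for the labeled group
    chi2: float
    p: float


def logrank_stat(times, events, groups) -> LogrankResult:
    """Two-sample log-rank test.  ``groups`` is boolean (or two-level);
    both groups must be non-empty."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g = np.asarray(groups)
    if g.dtype != bool:
        levels = np.unique(g)
        if len(levels) != 2:
            raise ValueError("exactly two groups required")
        g = g == levels[1]
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    z = _logrank_z(times, events, g)
    chi2 = z * z
    return LogrankResult(z=float(z), chi2=float(chi2), p=float(sps.chi2.sf(chi2, 1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


class CoxConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (e.g. monotone likelihood)."""


@dataclass
class SurvivalFit:
    """Per-term hazard ratios with Wald CIs, from an Efron-ties Cox fit on
    complete cases only."""

    terms: pd.DataFrame  # index=term; columns coef, hr, ci_low, ci_high, p
    log_likelihood: float
    n_used: int
    n_events: int

    def hr(self, term: str) -> float:
        return float(self.terms.loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.terms.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def summary(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.index.name = "term"
        return out.reset_index()


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    scaling: dict[str, float] | None = None,
) -> SurvivalFit:
    """Cox PH fit (Efron tie handling) of ``covariates`` on one endpoint.

    ``scaling`` divides a covariate before entry so its HR refers to a fixed
    increment (e.g. ``{"stil_density": 300}`` → HR per +300 cells/mm²); the
    scaled term is renamed ``<name>_per_<scale>``.  Incomplete cases are
    dropped; at least one event is required.
    """
    cols = [duration_col, event_col] + list(covariates)
    data = df[cols].dropna().copy()
    n_used = len(data)
    if n_used == 0:
        raise ValueError("no complete cases")
    n_events = int(data[event_col].sum())
    if n_events < 1:
        raise CoxConvergenceError("no events among complete cases")
    for name, scale in (scaling or {}).items():
        if name in data.columns:
            new = f"{name}_per_{scale:g}"
            data[new] = data[name] / scale
            data = data.drop(columns=[name])

    # a constant covariate carries no information: flat partial likelihood,
    # HR exactly 1 (reported as a degenerate term, not an optimizer failure)
    cov_cols = [c for c in data.columns if c not in (duration_col, event_col)]
    constant = [c for c in cov_cols if data[c].nunique() <= 1]
    active = [c for c in cov_cols if c not in constant]

    rows = {}
    loglik = float("nan")
    if active:
        fitter = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(
                    data[[duration_col, event_col] + active],
                    duration_col=duration_col,
                    event_col=event_col,
                )
        except Exception as exc:  # lifelines ConvergenceError etc.
            raise CoxConvergenceError(f"Cox fit failed: {exc}") from exc
        s = fitter.summary
        if (
            not np.isfinite(s["se(coef)"]).all()
            or (np.abs(s["coef"]) > 20).any()
            or (s["se(coef)"] > 20).any()
        ):
            raise CoxConvergenceError(
                "monotone partial likelihood (a coefficient diverged); "
                f"coefs={s['coef'].to_dict()}"
            )
        for term in s.index:
            rows[term] = {
                "coef": float(s.loc[term, "coef"]),
                "hr": float(s.loc[term, "exp(coef)"]),
                "ci_low": float(np.exp(s.loc[term, "coef lower 95%"])),
                "ci_high": float(np.exp(s.loc[term, "coef upper 95%"])),
                "p": float(s.loc[term, "p"]),
            }
        loglik = float(fitter.log_likelihood_)
    for term in constant:
        rows[term] = {"coef": 0.0, "hr": 1.0, "ci_low": 1.0, "ci_high": 1.0, "p": 1.0}
    terms = pd.DataFrame.from_dict(rows, orient="index").reindex(
        [c for c in cov_cols if c in rows]
    )
    return SurvivalFit(
        terms=terms,
        log_likelihood=loglik,
        n_used=n_used,
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# maximally selected rank statistics
# ---------------------------------------------------------------------------


@dataclass
class CutpointResult:
    """Outcome of the maximally-selected-rank-statistic search."""

    cutpoint: float
    statistic: float  # max |standardized log-rank statistic|
    p_adjusted: float
    p_method: str  # "miller-siegmund (approximate)" or "permutation"
    window: tuple[float, float]  # quantile window searched
    n_candidates: int
    candidates: np.ndarray = field(repr=False, default=None)
    statistics: np.ndarray = field(repr=False, default=None)


def _maxstat_scan(
    times: np.ndarray, events: np.ndarray, biomarker: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = np.quantile(biomarker, window)
    cands = np.unique(biomarker)
    cands = cands[(cands > lo) & (cands <= hi)]
    zs = np.array([_logrank_z(times, events, biomarker >= c) for c in cands])
    return cands, zs


def _miller_siegmund_p(b: float, eps1: float, eps2: float) -> float:
    """Approximate p-value bound for the maximum of the standardized
    log-rank process over a restricted proportion window (an improved
    Bonferroni-type bound; conservative for small candidate sets)."""
    if b <= 0:
        return 1.0
    phi = sps.norm.pdf(b)
    term = 4 * phi / b
    if b > 1:
        term += phi * (b - 1.0 / b) * np.log((eps2 * (1 - eps1)) / ((1 - eps2) * eps1))
    return float(np.clip(term, 0.0, 1.0))


def maxstat_cutpoint(
    times,
    events,
    biomarker,
    window: tuple[float, float] = (0.10, 0.90),
    p_method: str = "miller-siegmund",
    n_permutations: int = 1000,
    seed: int | None = None,
) -> CutpointResult:
    """Select the biomarker cutpoint maximizing the two-sample log-rank split.

    Every distinct biomarker value between the window quantiles is a
    candidate µ; the split is {biomarker ≥ µ} vs {< µ}.  The adjusted
    p-value uses the Miller–Siegmund bound (flagged approximate) or, with
    ``p_method="permutation"``, an exact Monte-Carlo permutation null.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    biomarker = np.asarray(biomarker, float)
    cands, zs = _maxstat_scan(times, events, biomarker, window)
    if len(cands) < 1 or len(np.unique(biomarker)) < 2:
        raise ValueError("fewer than one candidate cutpoint inside the window")
    best = int(np.argmax(np.abs(zs)))
    b = float(np.abs(zs[best]))
    # achieved low-group proportions at the window edges
    props = np.array([(biomarker < c).mean() for c in (cands[0], cands[-1])])
    eps1 = float(np.clip(props.min(), 1e-6, 0.5))
    eps2 = float(np.clip(props.max(), 0.5, 1 - 1e-6))
    if p_method == "miller-siegmund":
        p = _miller_siegmund_p(b, eps1, eps2)
        method = "miller-siegmund (approximate)"
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(biomarker)
            _, pz = _maxstat_scan(times, events, perm, window)
            if len(pz) and np.abs(pz).max() >= b:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        method = "permutation"
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return CutpointResult(
        cutpoint=float(cands[best]),
        statistic=b,
        p_adjusted=float(p),
        p_method=method,
        window=tuple(window),
        n_candidates=len(cands),
        candidates=cands,
        statistics=zs,
    )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def pairwise_spearman(count_matrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlation (average ranks for ties) between every pair
    of readers.  ``count_matrix``: readers × observations (DataFrame rows =
    readers, or 2-D array).  Constant vectors give NaN correlations."""
    if isinstance(count_matrix, pd.DataFrame):
        mat = count_matrix.to_numpy(float)
        names = list(count_matrix.index)
    else:
        mat = np.asarray(count_matrix, float)
        names = [f"reader{i}" for i in range(mat.shape[0])]
    k, m = mat.shape
    if m < 3:
        raise ValueError("at least 3 paired observations required")
    rho = np.eye(k)
    pvals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(mat[i]) == 0 or np.ptp(mat[j]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(mat[i], mat[j])
            rho[i, j] = rho[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    return (
        pd.DataFrame(rho, index=names, columns=names),
        pd.DataFrame(pvals, index=names, columns=names),
    )


@dataclass
class ConcordanceReport:
    """2×2 agreement between manual (reference) and automated grouping."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    discrepant: pd.DataFrame  # id, manual_high, auto_high, near-cutpoint flags


def concordance_report(
    manual_high,
    auto_high,
    ids=None,
    manual_scores=None,
    auto_scores=None,
    manual_cutpoint: float = MANUAL_CUTPOINT_PCT,
    auto_cutpoint: float = 470.0,
    manual_band: float = 10.0,
    auto_band: float = 250.0,
) -> ConcordanceReport:
    """Sensitivity/specificity of the automated grouping against the manual
    grouping (manual high = positive reference), with a list of discrepant
    cases flagged when both continuous scores sit within configurable bands
    of their cutpoints (the expected discrepancy zone)."""
    m = np.asarray(manual_high, bool)
    a = np.asarray(auto_high, bool)
    if len(m) != len(a):
        raise ValueError("group vectors differ in length")
    n = len(m)
    ids = np.asarray(ids if ids is not None else np.arange(n))
    tp = int((m & a).sum())
    fn = int((m & ~a).sum())
    tn = int((~m & ~a).sum())
    fp = int((~m & a).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    disc = m != a
    rows = {"id": ids[disc], "manual_high": m[disc], "auto_high": a[disc]}
    if manual_scores is not None and auto_scores is not None:
        ms = np.asarray(manual_scores, float)[disc]
        as_ = np.asarray(auto_scores, float)[disc]
        rows["manual_score"] = ms
        rows["auto_score"] = as_
        rows["near_cutpoints"] = (np.abs(ms - manual_cutpoint) <= manual_band) & (
            np.abs(as_ - auto_cutpoint) <= auto_band
        )
    return ConcordanceReport(
        tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec,
        discrepant=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

REQUIRED_COHORT_COLUMNS = [
    "id",
    "stil_density",
    "manual_stil_pct",
    "os_time",
    "os_event",
    "rfs_time",
    "rfs_event",
    "age_years",
    "tumor_size_cm",
    "n_positive_nodes",
    "tumor_type",
]

COVARIATE_CODINGS = ["age_ge50", "size_gt2cm", "nodes_1_3", "nodes_ge4", "type_lobular", "type_other"]


def prepare_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table and derive the standard covariate codings
    (age ≥50, size >2 cm, nodes 1–3 / ≥4, type lobular/other vs ductal).

    All schema violations are collected and reported together.
    """
    problems: list[str] = []
    for col in REQUIRED_COHORT_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing column: {col}")
    if problems:
        raise ValueError("cohort schema violations: " + "; ".join(problems))
    df = df.copy()
    if df["id"].duplicated().any():
        problems.append("duplicated ids: " + ", ".join(map(str, df.loc[df["id"].duplicated(), "id"].unique()[:5])))
    for col in ("os_time", "rfs_time"):
        if (df[col].dropna() < 0).any():
            problems.append(f"negative times in {col}")
    for col in ("os_event", "rfs_event"):
        bad = ~df[col].dropna().isin([0, 1])
        if bad.any():
            problems.append(f"non-binary events in {col}")
    known_types = {"ductal", "lobular", "other"}
    bad_types = set(df["tumor_type"].dropna().unique()) - known_types
    if bad_types:
        problems.append(f"unknown tumor_type values: {sorted(bad_types)}")
    if problems:
        raise ValueError("cohort schema violations: " + "; ".join(problems))
    df["age_ge50"] = (df["age_years"] >= 50).astype(float)
    df["size_gt2cm"] = (df["tumor_size_cm"] > 2).astype(float)
    df["nodes_1_3"] = df["n_positive_nodes"].between(1, 3).astype(float)
    df["nodes_ge4"] = (df["n_positive_nodes"] >= 4).astype(float)
    df["type_lobular"] = (df["tumor_type"] == "lobular").astype(float)
    df["type_other"] = (df["tumor_type"] == "other").astype(float)
    return df
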