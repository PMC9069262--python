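"""Associations between genetic variation and migratory passage date.

Three model families:

* OLS of capture day-of-year on a principal-component score, with sex as
  a covariate and optionally a PC x sex interaction, to ask whether
  multilocus genetic variation predicts passage date;
* weekly counted-allele frequency trajectories per locus (7-day bins,
  frequencies plotted at the midpoint day of each week), with linear and
  polynomial fits of frequency on midpoint day compared by a likelihood
  ratio test;
* OLS of capture day on sex alone, the differential-migration check.

For nested Gaussian OLS fits the likelihood-ratio statistic
2(ll_full - ll_reduced) = n log(RSS_r / RSS_f) is a monotone transform of
the exact F statistic, so :class:`LrtResult` carries two p-values: the
asymptotic chi-square p (``p_chisq``) and the exact finite-sample p from
the F distribution (``p_value``, the default used downstream).  At the
handful of weekly points these trajectories provide, the chi-square
approximation rejects well above its nominal level while the F-based p is
exactly calibrated; both are reported so either convention can be
inspected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class TimingFit:
    """An OLS fit summary: coefficients, tests and Gaussian log-likelihood."""

    response: str
    terms: list[str]
    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    df_resid: int
    loglik: float  # Gaussian, maximum-likelihood variance
    r_squared: float
    n_obs: int


@dataclass
class LrtResult:
    ll_reduced: float
    ll_full: float
    df_diff: int
    statistic: float  # 2 (ll_full - ll_reduced)
    p_chisq: float  # asymptotic chi-square p
    p_value: float  # exact F-based p for nested Gaussian OLS (default)


def _fit_summary(model: sm.OLS, response: str) -> TimingFit:
    res = model.fit()
    names = list(res.params.index)
    return TimingFit(
        response=response,
        terms=names,
        params=dict(res.params),
        bse=dict(res.bse),
        tvalues=dict(res.tvalues),
        pvalues=dict(res.pvalues),
        df_resid=int(res.df_resid),
        loglik=float(res.llf),
        r_squared=float(res.rsquared),
        n_obs=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# PC-score and sex regressions
# ---------------------------------------------------------------------------

def fit_pc_timing(
    scores: pd.Series,
    meta: pd.DataFrame,
    terms: tuple[str, ...] = ("pc", "sex"),
) -> TimingFit:
    """OLS of capture day on a PC score, with optional sex and interaction terms.

    ``scores`` is indexed by sample_id.  Only migrants with a recorded
    capture day enter; samples of unknown sex are dropped (with a
    warning) whenever a sex term is requested.  Sex is coded F=0, M=1.
    """
    allowed = {"pc", "sex", "interaction"}
    if not set(terms) <= allowed:
        raise ValueError(f"terms must be a subset of {allowed}")
    if "interaction" in terms and not {"pc", "sex"} <= set(terms):
        raise ValueError("interaction requires both pc and sex terms")

    m = meta[meta["capture_day"].notna()].copy()
    m = m[m["sample_id"].isin(scores.index)]
    use_sex = "sex" in terms or "interaction" in terms
    if use_sex:
        n_unknown = int((m["sex"] == "unknown").sum())
        if n_unknown:
            log.warning("dropping %d migrants of unknown sex", n_unknown)
        m = m[m["sex"] != "unknown"]

    y = m["capture_day"].astype(float).to_numpy()
    cols = {}
    if "pc" in terms:
        cols["pc"] = scores.loc[m["sample_id"]].to_numpy(dtype=float)
    if use_sex:
        cols["sex"] = (m["sex"] == "M").astype(float).to_numpy()
    if "interaction" in terms:
        cols["pc:sex"] = cols["pc"] * cols["sex"]

    X = pd.DataFrame(cols)
    for name, col in cols.items():
        if np.std(col) == 0:
            raise ValueError(f"predictor {name!r} is constant")
    X = sm.add_constant(X)
    if len(y) - X.shape[1] < 3:
        raise ValueError(f"only {len(y)} usable migrants; too few residual df")
    return _fit_summary(sm.OLS(y, X), "capture_day")


def sex_timing_test(meta: pd.DataFrame) -> TimingFit:
    """OLS of capture day on sex (F=0, M=1) among migrants of known sex."""
    m = meta[meta["capture_day"].notna() & meta["sex"].isin(["F", "M"])]
    if m["sex"].nunique() < 2:
        raise ValueError("need migrants of both sexes")
    y = m["capture_day"].astype(float).to_numpy()
    X = sm.add_constant(pd.DataFrame({"sex": (m["sex"] == "M").astype(float).to_numpy()}))
    return _fit_summary(sm.OLS(y, X), "capture_day")


# ---------------------------------------------------------------------------
# Weekly allele-frequency trajectories
# ---------------------------------------------------------------------------

def repolarize_major(gm: GenotypeMatrix, subset: list[str]) -> GenotypeMatrix:
    """Flip each locus so the counted allele is the major allele in ``subset``.

    Loci with counted-allele frequency below 0.5 in the subset have their
    codes mapped 0<->2 (and the counted-allele label annotated as
    flipped); frequency exactly 0.5 keeps the original polarity.  The
    operation is idempotent.  The major allele is defined once, over the
    whole subset, so weekly frequencies cannot flip polarity bin to bin.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    rows = gm.sample_index(subset)
    freqs = gm.allele_freq(rows)
    codes = gm.codes.copy()
    counted = list(gm.counted_allele)
    n_allmissing = int(np.isnan(freqs).sum())
    if n_allmissing:
        log.warning("%d loci all-missing in subset; polarity unchanged", n_allmissing)
    for j, f in enumerate(freqs):
        if not np.isnan(f) and f < 0.5:
            col = codes[:, j]
            codes[:, j] = np.where(col == MISSING, MISSING, 2 - col)
            counted[j] = f"~{counted[j]}" if not counted[j].startswith("~") else counted[j][1:]
    return GenotypeMatrix(list(gm.sample_ids), list(gm.locus_ids), codes, counted)


def weekly_frequencies(
    gm: GenotypeMatrix,
    meta: pd.DataFrame,
    locus: str,
    week_origin: str = "first_capture",
) -> pd.DataFrame:
    """Counted-allele frequency of one locus in 7-day capture bins.

    Bins are anchored at the earliest migrant capture day (the default
    ``week_origin`` policy; an integer day-of-year anchors explicitly).
    Each row gives week_index, midpoint_day (bin start + 3), the number
    of individuals and called alleles, the frequency and its binomial
    standard error sqrt(f(1-f)/n_alleles).  Empty bins are omitted.
    """
    m = meta[meta["capture_day"].notna()]
    if len(m) == 0:
        raise ValueError("no migrants with capture_day")
    days = m["capture_day"].astype(int).to_numpy()
    origin = int(days.min()) if week_origin == "first_capture" else int(week_origin)
    j = gm.locus_index([locus])[0]
    codes = gm.codes[gm.sample_index(m["sample_id"]), j]

    week = (days - origin) // 7
    rows = []
    for w in sorted(set(week.tolist())):
        sel = (week == w) & (codes != MISSING)
        n_ind = int(sel.sum())
        if n_ind == 0:
            continue
        n_alleles = 2 * n_ind
        f = codes[sel].sum() / n_alleles
        rows.append(
            {
                "week_index": int(w),
                "midpoint_day": origin + 7 * int(w) + 3,
                "n_individuals": n_ind,
                "n_called_alleles": n_alleles,
                "frequency": f,
                "se": float(np.sqrt(f * (1 - f) / n_alleles)),
            }
        )
    return pd.DataFrame(rows)


def _poly_design(day: np.ndarray, degree: int) -> np.ndarray:
    """Polynomial design on centred, scaled day (intercept first)."""
    x = (day - day.mean()) / (day.std() if day.std() > 0 else 1.0)
    return np.column_stack([x**k for k in range(degree + 1)])


def fit_trend_lrt(
    wf: pd.DataFrame,
    degree_full: int = 2,
    weighting: str = "none",
):
    """Linear vs polynomial trend in weekly frequency, with a nested LRT.

    Fits frequency on midpoint-day polynomials of degree 1 (reduced) and
    ``degree_full`` (full).  ``weighting``: ``"none"`` (OLS, default),
    ``"samplesize"`` (WLS with weights = called alleles) or
    ``"binomial"`` (logistic GLM on allele counts; LRT from its deviance).
    Requires at least ``degree_full + 2`` weekly points.
    """
    if degree_full < 1:
        raise ValueError("degree_full must be >= 1")
    if len(wf) < degree_full + 2:
        raise ValueError(f"need >= {degree_full + 2} weekly points, have {len(wf)}")
    day = wf["midpoint_day"].to_numpy(dtype=float)
    freq = wf["frequency"].to_numpy(dtype=float)
    n = len(wf)

    if weighting == "binomial":
        counts = np.column_stack(
            [
                np.round(wf["frequency"] * wf["n_called_alleles"]).astype(int),
                np.round((1 - wf["frequency"]) * wf["n_called_alleles"]).astype(int),
            ]
        )
        fits = []
        for degree in (1, degree_full):
            X = _poly_design(day, degree)
            res = sm.GLM(counts, X, family=sm.families.Binomial()).fit()
            fits.append(res)
        ll_r, ll_f = float(fits[0].llf), float(fits[1].llf)
        red = full = None
    else:
        weights = wf["n_called_alleles"].to_numpy(dtype=float) if weighting == "samplesize" else None
        results = []
        for degree in (1, degree_full):
            X = _poly_design(day, degree)
            model = sm.WLS(freq, X, weights=weights) if weights is not None else sm.OLS(freq, X)
            results.append(model.fit())
        ll_r, ll_f = float(results[0].llf), float(results[1].llf)
        red, full = results

    df_diff = degree_full - 1
    statistic = max(0.0, 2.0 * (ll_f - ll_r))
    if df_diff == 0:  # degenerate: identical models
        lrt = LrtResult(ll_r, ll_f, 0, statistic, 1.0, 1.0)
        return (
            _trend_summary(red, 1, n),
            _trend_summary(full, degree_full, n),
            lrt,
        )
    p_chisq = float(stats.chi2.sf(statistic, df_diff))
    if red is not None and df_diff >= 1:
        # exact nested-OLS p: LRT is monotone in F = ((RSS_r-RSS_f)/df) / (RSS_f/df_resid)
        rss_r, rss_f = float(red.ssr), float(full.ssr)
        df_resid = n - (degree_full + 1)
        if rss_f <= 0 or df_resid <= 0:
            p_exact = p_chisq
        else:
            fstat = ((rss_r - rss_f) / df_diff) / (rss_f / df_resid)
            p_exact = float(stats.f.sf(fstat, df_diff, df_resid))
    else:
        p_exact = p_chisq

    lrt = LrtResult(ll_r, ll_f, df_diff, statistic, p_chisq, p_exact)
    return _trend_summary(red, 1, n), _trend_summary(full, degree_full, n), lrt


def _trend_summary(res, degree: int, n: int) -> TimingFit | None:
    if res is None:
        return None
    names = ["intercept"] + [f"day^{k}" for k in range(1, degree + 1)]
    return TimingFit(
        response="frequency",
        terms=names,
        params=dict(zip(names, np.asarray(res.params, dtype=float))),
        bse=dict(zip(names, np.asarray(res.bse, dtype=float))),
        tvalues=dict(zip(names, np.asarray(res.tvalues, dtype=float))),
        pvalues=dict(zip(names, np.asarray(res.pvalues, dtype=float))),
        df_resid=int(res.df_resid),
        loglik=float(res.llf),
        r_squared=float(getattr(res, "rsquared", np.nan)),
        n_obs=n,
    )


def plot_weekly(wf: pd.DataFrame, lrt=None, ax=None, label: str | None = None):
    """Frequency vs midpoint day, point area proportional to n, +/-SE bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(wf["midpoint_day"], wf["frequency"], yerr=wf["se"], fmt="none", ecolor="grey", lw=1)
    ax.scatter(wf["midpoint_day"], wf["frequency"], s=8 * wf["n_individuals"], zorder=3)
    ax.set_xlabel("midpoint day of week (day of year)")
    ax.set_ylabel("major-allele frequency")
    if label:
        ax.set_title(label)
    return ax
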