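"""Negative-binomial differential abundance across depth and treatment.

A deliberately simple per-feature NB-GLM engine: median-of-ratios size
factors, per-feature dispersion by profile maximum likelihood, nested-model
likelihood-ratio tests for the depth effect, Wald contrasts of treatment
versus control within a depth stratum, and Benjamini-Hochberg FDR control.
Unlike shrinkage-based engines there is no dispersion trend, no outlier
handling and no independent filtering: count tables are accepted unfiltered
and zeros are handled by the NB likelihood itself.

Direction calls for the depth series come from per-feature ordinary least
squares of log normalized counts on numeric depth (stratum midpoints), run
only on features passing the LRT at the FDR gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 50.0
IRLS_MAXITER = 100
IRLS_TOL = 1e-8


def size_factors(
    counts: pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios sample size factors, scaled to geometric mean 1.

    For each feature positive in every sample, the geometric mean across
    samples forms a reference; a sample's factor is the median of its
    count/reference ratios.  With ``pseudo_reference`` the reference uses
    features positive in at least one sample, ignoring zero ratios per
    sample (fallback for sparse tables with no all-positive feature).
    """
    k = counts.to_numpy(dtype=float)
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        if not pseudo_reference:
            raise ValueError(
                "no feature is positive in all samples; re-run with "
                "pseudo_reference=True"
            )
        any_pos = (k > 0).any(axis=1)
        with np.errstate(divide="ignore"):
            logk = np.where(k > 0, np.log(np.where(k > 0, k, 1.0)), np.nan)
        ref = np.exp(np.nanmean(logk[any_pos], axis=1))
        ratios = k[any_pos] / ref[:, None]
        s = np.nanmedian(np.where(ratios > 0, ratios, np.nan), axis=0)
    else:
        sub = k[all_pos]
        ref = np.exp(np.log(sub).mean(axis=1))
        s = np.median(sub / ref[:, None], axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def bh_fdr(p: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through and
    are excluded from the effective number of tests."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    pv = arr[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.minimum(q, 1.0)
        out[mask] = qv
    return out


def design_matrix(
    design: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with intercept from categorical terms.

    Levels are sorted; the first level of each term is the reference.  A
    term named ``depth_cm`` (or any numeric column) enters as a numeric
    covariate instead.
    """
    cols = [np.ones(len(design))]
    names = ["Intercept"]
    for term in terms:
        col = design[term]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
            continue
        levels = sorted(col.astype(str).unique())
        for lev in levels[1:]:
            cols.append((col.astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{term}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix for terms {terms} is rank-deficient")
    return X, names


def _nb_llf(y, X, offset, alpha):
    fam = (
        sm.families.Poisson()
        if alpha < DISPERSION_FLOOR
        else sm.families.NegativeBinomial(alpha=alpha)
    )
    model = sm.GLM(y, X, family=fam, offset=offset)
    res = model.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL)
    return res


def estimate_dispersion(y: np.ndarray, X: np.ndarray, offset: np.ndarray) -> float:
    """Per-feature NB dispersion by Cox-Reid adjusted profile likelihood.

    Maximizes the GLM profile log-likelihood minus the Cox-Reid adjustment
    0.5 * logdet(X' W X) over log-dispersion within [floor, ceiling]; the
    adjustment compensates the downward bias of plug-in ML when the mean
    model uses up a non-trivial share of the degrees of freedom.  The
    Poisson limit applies at the floor.
    """
    def neg_apl(log_a):
        alpha = float(np.exp(log_a))
        try:
            res = _nb_llf(y, X, offset, alpha)
            mu = res.fittedvalues
            w = mu / (1.0 + alpha * mu)  # IRLS weights for NB log link
            _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
            return -(res.llf - 0.5 * logdet)
        except Exception:
            return np.inf

    res = minimize_scalar(
        neg_apl,
        bounds=(np.log(DISPERSION_FLOOR), np.log(DISPERSION_CEIL)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


@dataclass
class DiffAbundResult:
    table: pd.DataFrame
    design_full: list[str]
    design_reduced: list[str] | None = None


def nb_lrt(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    full_terms: list[str] = ("replicate", "time_point", "treat_control", "depth"),
    reduced_terms: list[str] = ("replicate", "time_point", "treat_control"),
    sf: pd.Series | None = None,
) -> DiffAbundResult:
    """Likelihood-ratio test of nested NB GLMs per feature.

    Dispersion is estimated once per feature on the full model and shared by
    both fits; the statistic 2 * (ll_full - ll_reduced) refers to a chi-square
    with df equal to the parameter difference.  All-zero or non-converging
    features get p = NaN and are excluded from the BH correction.
    """
    if not set(reduced_terms) <= set(full_terms):
        raise ValueError("reduced model terms must nest within the full model")
    design = design.set_index("sample_id").loc[counts.columns].reset_index()
    X_full, names_full = design_matrix(design, list(full_terms))
    X_red, names_red = design_matrix(design, list(reduced_terms))
    df_diff = X_full.shape[1] - X_red.shape[1]
    if df_diff <= 0:
        raise ValueError("full model adds no parameters over the reduced model")
    if sf is None:
        sf = size_factors(counts, pseudo_reference=True)
    offset = np.log(sf.loc[counts.columns].to_numpy())

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fid, row in counts.iterrows():
            y = row.to_numpy(dtype=float)
            if y.sum() == 0:
                rows.append((fid, np.nan, np.nan, np.nan, False))
                continue
            try:
                alpha = estimate_dispersion(y, X_full, offset)
                ll_full = _nb_llf(y, X_full, offset, alpha).llf
                ll_red = _nb_llf(y, X_red, offset, alpha).llf
                stat = max(2.0 * (ll_full - ll_red), 0.0)
                p = float(stats.chi2.sf(stat, df_diff))
                rows.append((fid, alpha, stat, p, True))
            except Exception:
                rows.append((fid, np.nan, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows, columns=["feature_id", "dispersion", "statistic", "p", "converged"]
    ).set_index("feature_id")
    table["fdr"] = bh_fdr(table["p"])
    return DiffAbundResult(table, names_full, names_red)


def depth_direction(
    norm_counts: pd.DataFrame,
    depths: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature OLS of log(normalized + pseudocount) on numeric depth.

    Returns slope, slope-t-test p, BH FDR and an Increase/Decrease/Neither
    direction at FDR <= 0.05.  Intended for features already passing the
    depth LRT gate.
    """
    x = depths.loc[norm_counts.columns].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct depths")
    logy = np.log(norm_counts.to_numpy(dtype=float) + pseudocount)
    n = len(x)
    xc = x - x.mean()
    sxx = (xc**2).sum()
    yc = logy - logy.mean(axis=1, keepdims=True)
    slopes = yc @ xc / sxx
    resid = yc - np.outer(slopes, xc)
    sigma2 = (resid**2).sum(axis=1) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slopes / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    fdr = bh_fdr(p)
    direction = np.where(
        (fdr <= 0.05) & (slopes > 0),
        "Increase",
        np.where((fdr <= 0.05) & (slopes < 0), "Decrease", "Neither"),
    )
    return pd.DataFrame(
        {"slope": slopes, "p": p, "fdr": fdr, "direction": direction},
        index=norm_counts.index,
    )


def treatment_contrast(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    depth_stratum: str,
    terms: list[str] = ("replicate", "time_point", "factor"),
    sf: pd.Series | None = None,
) -> DiffAbundResult:
    """Wald test of treatment vs control within one depth stratum.

    Fits the NB GLM with the combined treatment-depth factor on all samples
    and tests the contrast between the ``treatment`` and ``control`` levels
    of ``depth_stratum`` (e.g. ``"20cm"``).  Direction at FDR <= 0.05 follows
    the contrast sign (positive = higher under treatment).
    """
    design = design.set_index("sample_id").loc[counts.columns].reset_index()
    lev_t, lev_c = f"treatment{depth_stratum}", f"control{depth_stratum}"
    present = set(design["factor"].astype(str))
    if not {lev_t, lev_c} <= present:
        raise ValueError(f"factor levels {lev_t!r} / {lev_c!r} absent")
    X, names = design_matrix(design, list(terms))
    contrast = np.zeros(X.shape[1])
    for lev, sign in ((lev_t, 1.0), (lev_c, -1.0)):
        name = f"factor[{lev}]"
        if name in names:
            contrast[names.index(name)] = sign
        # reference level contributes zero
    if not contrast.any():
        raise ValueError("contrast is identically zero")
    if sf is None:
        sf = size_factors(counts, pseudo_reference=True)
    offset = np.log(sf.loc[counts.columns].to_numpy())

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fid, row in counts.iterrows():
            y = row.to_numpy(dtype=float)
            if y.sum() == 0:
                rows.append((fid, np.nan, np.nan, np.nan, np.nan, False))
                continue
            try:
                alpha = estimate_dispersion(y, X, offset)
                res = _nb_llf(y, X, offset, alpha)
                est = float(contrast @ res.params)
                se = float(np.sqrt(contrast @ res.cov_params() @ contrast))
                z = est / se
                p = 2.0 * float(stats.norm.sf(abs(z)))
                rows.append((fid, alpha, est, z, p, True))
            except Exception:
                rows.append((fid, np.nan, np.nan, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows,
        columns=["feature_id", "dispersion", "log_fc", "statistic", "p",
                 "converged"],
    ).set_index("feature_id")
    table["fdr"] = bh_fdr(table["p"])
    table["direction"] = np.where(
        (table["fdr"] <= 0.05) & (table["log_fc"] > 0),
        "Increase",
        np.where(
            (table["fdr"] <= 0.05) & (table["log_fc"] < 0),
            "Decrease",
            "Neither",
        ),
    )
    return DiffAbundResult(table, names)


def depth_response_groups(
    counts: pd.DataFrame,
    norm_counts: pd.DataFrame,
    design: pd.DataFrame,
    fdr_gate: float = 0.05,
) -> pd.DataFrame:
    """Two-stage depth response call: NB LRT gate, then OLS slope direction.

    Features failing the LRT at ``fdr_gate`` (or with NaN p) are Neither;
    survivors take the direction of their log-count-on-depth slope when that
    slope's BH FDR also passes the gate.
    """
    lrt = nb_lrt(counts, design)
    passed = lrt.table.index[(lrt.table["fdr"] <= fdr_gate).fillna(False)]
    out = pd.DataFrame(
        {"lrt_p": lrt.table["p"], "lrt_fdr": lrt.table["fdr"]},
        index=counts.index,
    )
    out["slope"] = np.nan
    out["direction"] = "Neither"
    if len(passed):
        depths = design.set_index("sample_id")["depth_cm"]
        dd = depth_direction(norm_counts.loc[passed], depths)
        out.loc[passed, "slope"] = dd["slope"]
        out.loc[passed, "direction"] = dd["direction"]
    return out
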