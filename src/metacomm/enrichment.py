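"""Category enrichment between genome response groups, and related statistics.

The central procedure is a two-stage cascade run per category (phylum or
metabolic function) against the Increase / Decrease / Neither response
groups of a condition:

1. categories absent from either the Increase or the Decrease group are
   dropped; the rest get an exact Fisher test on the 2 x 3 carrier /
   non-carrier by group table, BH-corrected;
2. categories at Fisher FDR <= 0.1 get a permutation post hoc: the observed
   statistic is |c_inc/n_inc - c_dec/n_dec| and the null redraws the two
   group-sized sets from all genomes without replacement (10,000 draws),
   counting strictly greater permuted statistics; permutation p-values are
   BH-corrected and FDR <= 0.05 is significant.

Also here: Kruskal-Wallis / Wilcoxon contrasts of per-genome diversity
metrics between response groups, Spearman co-occurrence correlation with FDR
masking, and proteomics rank / hypergeometric over-representation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .diffabund import bh_fdr

GROUPS = ("Increase", "Decrease", "Neither")


@dataclass
class PermutationSpec:
    n_perm: int = 10_000
    seed: int = 0
    #: "disjoint": the two pseudo-groups are drawn jointly without
    #: replacement (label permutation); "independent": each is drawn
    #: separately and may overlap
    draw_mode: str = "disjoint"


def prefilter_categories(
    presence: pd.DataFrame, groups: pd.Series
) -> list[str]:
    """Categories with at least one carrier in both Increase and Decrease."""
    inc = presence.loc[groups[groups == "Increase"].index]
    dec = presence.loc[groups[groups == "Decrease"].index]
    keep = inc.any(axis=0) & dec.any(axis=0)
    return list(presence.columns[keep])


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2xc(
    carriers: np.ndarray, group_sizes: np.ndarray, n_cap: int = 5000
) -> float:
    """Exact two-sided Fisher test p for a 2 x c carrier table.

    ``carriers[g]`` is the number of carrier genomes in group g out of
    ``group_sizes[g]``.  The two-sided p sums the multivariate
    hypergeometric probabilities (margins fixed) of every table at most as
    probable as the observed one (probability-mass criterion, with the usual
    1e-7 relative tolerance).
    """
    carriers = np.asarray(carriers, dtype=int)
    sizes = np.asarray(group_sizes, dtype=int)
    if (carriers < 0).any() or (carriers > sizes).any():
        raise ValueError("carrier counts must lie in [0, group size]")
    N = int(sizes.sum())
    if N > n_cap:
        raise ValueError(
            f"table total {N} exceeds cap {n_cap}; use a Monte-Carlo test"
        )
    K = int(carriers.sum())
    denom = _log_binom(N, K)

    nz = sizes > 0
    sizes_nz = sizes[nz]
    c = len(sizes_nz)
    logp_obs = sum(_log_binom(n, a) for n, a in zip(sizes_nz, carriers[nz])) - denom

    # enumerate all compositions of K over the c columns (a_g <= n_g)
    tables = [np.zeros((1, 0), dtype=int)]
    for g in range(c):
        prev = tables[-1]
        used = prev.sum(axis=1)
        new = []
        for row, u in zip(prev, used):
            remaining_cap = sizes_nz[g + 1:].sum()
            lo = max(0, K - u - remaining_cap)
            hi = min(sizes_nz[g], K - u)
            for a in range(lo, hi + 1):
                new.append(np.append(row, a))
        tables.append(np.array(new, dtype=int))
    grid = tables[-1]
    logp = (
        _log_binom(sizes_nz[None, :], grid).sum(axis=1) - denom
    )
    return float(np.exp(logp[logp <= logp_obs + 1e-7]).sum().clip(max=1.0))


def fisher_2x3(
    presence: pd.Series, groups: pd.Series, n_cap: int = 5000
) -> float:
    """Fisher exact test of a category's carriers across the three groups."""
    sizes, carriers = [], []
    for g in GROUPS:
        idx = groups[groups == g].index
        sizes.append(len(idx))
        carriers.append(int(presence.loc[idx].astype(bool).sum()))
    return fisher_exact_2xc(np.array(carriers), np.array(sizes), n_cap=n_cap)


def permutation_posthoc(
    presence: pd.Series,
    groups: pd.Series,
    spec: PermutationSpec = PermutationSpec(),
) -> float:
    """Permutation p for the Increase-vs-Decrease carrier-fraction gap.

    Observed statistic T = |c_inc/n_inc - c_dec/n_dec|.  Each permutation
    redraws sets of the two group sizes from *all* genomes (so the null
    reflects the category's overall frequency) and the p-value is the
    fraction of permuted T strictly exceeding the observed T.  A category
    carried by every genome or by none (zero-variance) returns p = 1.
    """
    x = presence.loc[groups.index].astype(bool).to_numpy()
    n_inc = int((groups == "Increase").sum())
    n_dec = int((groups == "Decrease").sum())
    if n_inc < 1 or n_dec < 1:
        raise ValueError("both Increase and Decrease groups must be non-empty")
    n_tot = len(groups)
    if n_inc + n_dec > n_tot:
        raise ValueError("group sizes exceed total genomes")
    if x.all() or not x.any():
        return 1.0

    c_inc = x[(groups == "Increase").to_numpy()].sum()
    c_dec = x[(groups == "Decrease").to_numpy()].sum()
    t_obs = abs(c_inc / n_inc - c_dec / n_dec)

    rng = np.random.default_rng(spec.seed)
    if spec.draw_mode == "disjoint":
        u = rng.random((spec.n_perm, n_tot))
        idx = np.argpartition(u, n_inc + n_dec - 1, axis=1)[:, : n_inc + n_dec]
        pick = x[idx]
        t_perm = np.abs(
            pick[:, :n_inc].sum(axis=1) / n_inc
            - pick[:, n_inc:].sum(axis=1) / n_dec
        )
    elif spec.draw_mode == "independent":
        t_perm = np.empty(spec.n_perm)
        for i in range(spec.n_perm):
            a = x[rng.choice(n_tot, n_inc, replace=False)].sum() / n_inc
            b = x[rng.choice(n_tot, n_dec, replace=False)].sum() / n_dec
            t_perm[i] = abs(a - b)
    else:
        raise ValueError("draw_mode must be 'disjoint' or 'independent'")
    return float((t_perm > t_obs + 1e-12).sum() / spec.n_perm)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame
    fisher_gate: float = 0.1
    significance: float = 0.05


def enrichment_cascade(
    presence: pd.DataFrame,
    groups: pd.Series,
    spec: PermutationSpec = PermutationSpec(),
    fisher_gate: float = 0.1,
    significance: float = 0.05,
) -> EnrichmentResult:
    """Fisher-then-permutation enrichment of categories between groups.

    ``presence`` is a genome x category boolean (or count) matrix aligned to
    ``groups``.  Stage order: carrier prefilter, 2 x 3 Fisher with BH, gate
    at ``fisher_gate``, permutation post hoc on gated categories with BH,
    significance at ``significance``.  ``enriched_group`` is the side with
    the larger carrier fraction.
    """
    presence = presence.loc[groups.index].astype(bool)
    cats = prefilter_categories(presence, groups)
    inc_idx = groups[groups == "Increase"].index
    dec_idx = groups[groups == "Decrease"].index

    rows = []
    for cat in cats:
        col = presence[cat]
        fp = fisher_2x3(col, groups)
        f_inc = col.loc[inc_idx].mean()
        f_dec = col.loc[dec_idx].mean()
        rows.append(
            {
                "category": cat,
                "carriers_increase": int(col.loc[inc_idx].sum()),
                "carriers_decrease": int(col.loc[dec_idx].sum()),
                "frac_increase": f_inc,
                "frac_decrease": f_dec,
                "fisher_p": fp,
                "enriched_group": "Increase" if f_inc >= f_dec else "Decrease",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "category", "carriers_increase", "carriers_decrease",
            "frac_increase", "frac_decrease", "fisher_p", "enriched_group",
        ],
    ).set_index("category")
    table["fisher_fdr"] = bh_fdr(table["fisher_p"]) if len(table) else []
    table["perm_p"] = np.nan
    gated = table.index[table["fisher_fdr"] <= fisher_gate]
    ss = np.random.SeedSequence(spec.seed)
    for cat, child in zip(gated, ss.spawn(len(gated))):
        sub = PermutationSpec(
            n_perm=spec.n_perm,
            seed=int(child.generate_state(1)[0] % (2**31)),
            draw_mode=spec.draw_mode,
        )
        table.loc[cat, "perm_p"] = permutation_posthoc(
            presence[cat], groups, sub
        )
    table["perm_fdr"] = bh_fdr(table["perm_p"])
    table["significant"] = (table["perm_fdr"] <= significance).fillna(False)
    return EnrichmentResult(table, fisher_gate, significance)


def diversity_contrast(
    metrics: pd.DataFrame,
    groups: pd.Series,
    kw_gate: float = 0.1,
    significance: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis then Wilcoxon contrast of per-genome metrics.

    Each metric column is first compared across the three response groups
    (Kruskal-Wallis with tie correction, BH across metrics); metrics at
    FDR <= ``kw_gate`` get a two-sided rank-sum test between Increase and
    Decrease, BH-corrected, significant at <= ``significance``.
    """
    metrics = metrics.loc[groups.index]
    samples = {g: groups[groups == g].index for g in GROUPS}
    if sum(len(idx) > 0 for idx in samples.values()) < 2:
        raise ValueError("need at least 2 non-empty groups")

    rows = []
    for col in metrics.columns:
        vals = [metrics.loc[idx, col].dropna() for idx in samples.values()]
        vals = [v.to_numpy() for v in vals if len(v)]
        if np.ptp(np.concatenate(vals)) == 0:
            h, p = 0.0, 1.0  # all values identical: no evidence of difference
        else:
            h, p = stats.kruskal(*vals)
        rows.append({"metric": col, "kw_H": h, "kw_p": p})
    out = pd.DataFrame(rows).set_index("metric")
    out["kw_fdr"] = bh_fdr(out["kw_p"])
    out["wilcoxon_p"] = np.nan
    for col in out.index[out["kw_fdr"] <= kw_gate]:
        a = metrics.loc[samples["Increase"], col].dropna()
        b = metrics.loc[samples["Decrease"], col].dropna()
        if len(a) and len(b):
            combined = np.concatenate([a, b])
            no_ties = len(np.unique(combined)) == len(combined)
            # exact null distribution when feasible (no ties, modest n)
            method = "exact" if no_ties and max(len(a), len(b)) < 50 \
                else "asymptotic"
            out.loc[col, "wilcoxon_p"] = stats.mannwhitneyu(
                a, b, alternative="two-sided", method=method
            ).pvalue
    out["wilcoxon_fdr"] = bh_fdr(out["wilcoxon_p"])
    out["significant"] = (out["wilcoxon_fdr"] <= significance).fillna(False)
    return out


def cooccurrence_spearman(
    fm: pd.DataFrame, significance: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of function count vectors across genomes.

    Returns (rho, fdr, mask): correlation and BH-FDR matrices over function
    pairs, and the boolean significance mask at ``significance``.
    Zero-variance functions get NaN correlations and are never significant.
    """
    if fm.shape[0] < 3:
        raise ValueError("need at least 3 genomes")
    cols = list(fm.columns)
    m = len(cols)
    rho = np.full((m, m), np.nan)
    pmat = np.full((m, m), np.nan)
    arr = fm.to_numpy(dtype=float)
    var = arr.std(axis=0) > 0
    np.fill_diagonal(rho, 1.0)
    iu = np.triu_indices(m, k=1)
    for i, j in zip(*iu):
        if var[i] and var[j]:
            r, p = stats.spearmanr(arr[:, i], arr[:, j])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    qv = bh_fdr(pmat[iu])
    fdr = np.full((m, m), np.nan)
    fdr[iu] = qv
    fdr.T[iu] = qv
    mask = np.nan_to_num(fdr, nan=1.0) <= significance
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(fdr, index=cols, columns=cols),
        pd.DataFrame(mask, index=cols, columns=cols),
    )


def proteomics_summary(
    spectra: pd.DataFrame, min_samples: int = 5
) -> pd.DataFrame:
    """Mean within-sample abundance rank of functional groups.

    ``spectra`` is a function x sample table of summed spectral counts.
    Functions detected (count > 0) in fewer than ``min_samples`` samples are
    removed; the rest are ranked within each sample (rank 1 = highest count,
    ties by average rank) and the mean rank is taken across the samples where
    the function was detected.
    """
    if (spectra.to_numpy() < 0).any():
        raise ValueError("spectral counts must be non-negative")
    detected = (spectra > 0).sum(axis=1)
    kept = spectra.loc[detected >= min_samples]
    ranks = kept.rank(axis=0, ascending=False, method="average")
    ranks = ranks.where(kept > 0)
    out = pd.DataFrame(
        {
            "n_samples_detected": (kept > 0).sum(axis=1),
            "mean_rank": ranks.mean(axis=1),
            "total_spectra": kept.sum(axis=1),
        }
    )
    return out.sort_values("mean_rank")


def ko_overrepresentation(
    hits_in_set: int, set_size: int, hits_in_db: int, db_size: int
) -> float:
    """Upper-tail hypergeometric P(X >= k) for category over-representation.

    ``set_size`` draws from a universe of ``db_size`` containing
    ``hits_in_db`` annotated members, observing ``hits_in_set`` annotated.
    """
    if set_size > db_size:
        raise ValueError("set_size cannot exceed db_size")
    if hits_in_set > min(set_size, hits_in_db):
        raise ValueError("observed hits exceed possible maximum")
    return float(stats.hypergeom.sf(hits_in_set - 1, db_size, hits_in_db,
                                    set_size))
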