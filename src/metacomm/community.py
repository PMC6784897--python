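"""Ordination and variable-importance analysis of SG abundance.

Standardization (Hellinger), variability/occupancy filtering, phylogenetic
beta diversity (normalized weighted UniFrac), non-metric multidimensional
scaling of the resulting distance matrix, and the multi-response permutation
procedure (MRPP) for the strength and significance of sample groupings.

By default the Hellinger-standardized, filtered table feeds UniFrac; pass the
library-normalized table instead to use unstandardized coverages (both
readings of the upstream protocol are supported).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode
from sklearn.manifold import MDS


@dataclass
class FilterSpec:
    """Row-filter thresholds: max CV of normalized coverage, and minimum
    number of samples whose raw coverage reaches ``occupancy_cov``."""

    cv_max: float = 3.0
    min_occupied: int = 5
    occupancy_cov: float = 0.25


def hellinger(x: pd.DataFrame) -> pd.DataFrame:
    """Hellinger standardization of a samples-as-rows abundance matrix.

    y_ij = sqrt(x_ij / row_total_i); each row's squares then sum to 1.
    """
    arr = x.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = arr.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("all-zero sample row")
    return pd.DataFrame(
        np.sqrt(arr / totals[:, None]), index=x.index, columns=x.columns
    )


def cv_occupancy_filter(
    normalized: pd.DataFrame,
    raw: pd.DataFrame,
    spec: FilterSpec = FilterSpec(),
) -> list[str]:
    """SG ids kept by the variability/occupancy filter (SGs as rows).

    An SG is kept iff the coefficient of variation (sample SD / mean) of its
    normalized coverage is <= ``cv_max`` *and* its raw coverage reaches
    ``occupancy_cov`` in at least ``min_occupied`` samples.  A zero-mean row
    (CV undefined) fails.
    """
    if not normalized.index.equals(raw.index):
        raise ValueError("normalized and raw tables must share SG rows")
    mean = normalized.mean(axis=1)
    sd = normalized.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    occupied = (raw >= spec.occupancy_cov).sum(axis=1)
    keep = (mean > 0) & (cv <= spec.cv_max) & (occupied >= spec.min_occupied)
    return list(normalized.index[keep])


def read_tree(newick: str, midpoint_if_unrooted: bool = True) -> TreeNode:
    """Parse a newick string; midpoint-root deterministically if unrooted."""
    tree = TreeNode.read(io.StringIO(newick))
    if midpoint_if_unrooted and len(tree.children) > 2:
        tree = tree.root_at_midpoint()
    return tree


def weighted_unifrac(
    tree: TreeNode | str,
    abundances: pd.DataFrame,
    normalized: bool = True,
) -> pd.DataFrame:
    """Pairwise (normalized) weighted UniFrac distances between samples.

    ``abundances`` has samples as rows and SGs (tree leaves) as columns.
    The raw statistic sums branch lengths weighted by the absolute difference
    in the proportion of each sample's total abundance descending the branch;
    the normalized form divides by the abundance-weighted root-to-leaf depth
    sum, bounding distances in [0, 1].
    """
    if isinstance(tree, str):
        tree = read_tree(tree)
    leaf_names = {t.name for t in tree.tips()}
    missing = [c for c in abundances.columns if c not in leaf_names]
    if missing:
        raise ValueError(f"SGs absent from tree: {missing[:5]}...")
    arr = abundances.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = arr.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("zero-total sample")
    props = arr / totals[:, None]
    n = arr.shape[0]
    col = {name: j for j, name in enumerate(abundances.columns)}

    # one postorder pass accumulates, per branch, the proportion of each
    # sample's abundance descending it; leaves absent from the table carry 0
    branch_lengths: list[float] = []
    branch_props: list[np.ndarray] = []
    desc: dict[int, np.ndarray] = {}
    leaf_depth = np.zeros((n, 0))
    depths: dict[int, float] = {}
    leaf_cols: list[int] = []
    leaf_path: list[float] = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            p = props[:, col[node.name]] if node.name in col else np.zeros(n)
        else:
            p = np.sum([desc.pop(id(ch)) for ch in node.children], axis=0)
        desc[id(node)] = p
        if node.parent is not None:
            length = node.length or 0.0
            branch_lengths.append(length)
            branch_props.append(p)
    # root-to-leaf path lengths for the normalization term
    for node in tree.preorder(include_self=True):
        depths[id(node)] = (
            0.0
            if node.parent is None
            else depths[id(node.parent)] + (node.length or 0.0)
        )
        if node.is_tip() and node.name in col:
            leaf_cols.append(col[node.name])
            leaf_path.append(depths[id(node)])
    lengths = np.asarray(branch_lengths)
    P = np.asarray(branch_props)  # branches x samples
    path = np.asarray(leaf_path)
    leaf_p = props[:, leaf_cols]  # samples x leaves

    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            u = float(lengths @ np.abs(P[:, i] - P[:, j]))
            if normalized:
                d_norm = float(path @ (leaf_p[i] + leaf_p[j]))
                u = u / d_norm if d_norm > 0 else 0.0
            out[i, j] = out[j, i] = u
    return pd.DataFrame(out, index=abundances.index, columns=abundances.index)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    restart_stresses: list[float]
    converged: bool
    degenerate: bool = False


def nmds(
    distances: pd.DataFrame,
    k: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1 with monotone regression.

    Runs ``restarts`` independent random starts and returns the lowest-stress
    solution, centered and rotated to its principal axes.  An all-equal
    (degenerate) distance matrix is flagged and returned with the trivial
    configuration.
    """
    d = distances.to_numpy(dtype=float)
    n = d.shape[0]
    if n < k + 2:
        raise ValueError("need at least k + 2 samples")
    off = d[~np.eye(n, dtype=bool)]
    if np.allclose(off, off[0]):
        coords = pd.DataFrame(
            np.zeros((n, k)), index=distances.index,
            columns=[f"NMDS{i + 1}" for i in range(k)],
        )
        return OrdinationResult(coords, np.nan, [], False, degenerate=True)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(restarts)]
    best_embed, stresses = None, []
    for cs in child_seeds:
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init="random",
            random_state=cs,
            normalized_stress=True,
            max_iter=max_iter,
            eps=tol,
        )
        embed = model.fit_transform(d)
        stresses.append(float(model.stress_))
        if best_embed is None or model.stress_ < min(stresses[:-1], default=np.inf):
            best_embed = embed
    best = float(min(stresses))

    centered = best_embed - best_embed.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    rotated = centered @ vt.T
    coords = pd.DataFrame(
        rotated, index=distances.index,
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return OrdinationResult(coords, best, stresses, converged=True)


@dataclass
class MRPPResult:
    A: float
    delta_obs: float
    delta_exp: float
    p: float
    n_perm: int


def _weighted_delta(d: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Group-size-weighted mean within-group pairwise distance (weight n_i)."""
    n = len(codes)
    delta = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ni = len(idx)
        sub = d[np.ix_(idx, idx)]
        mean_within = sub[np.triu_indices(ni, k=1)].mean()
        delta += ni / n * mean_within
    return delta


def mrpp(
    distances: pd.DataFrame,
    groups: pd.Series | list,
    n_perm: int = 10_000,
    seed: int = 0,
) -> MRPPResult:
    """Multi-response permutation procedure with group-size weights.

    The observed statistic is the weighted mean within-group distance
    delta; its permutation mean gives the chance-corrected agreement
    A = 1 - delta / E[delta].  The p-value uses the (1 + exceed) / (1 + N)
    Monte-Carlo convention on delta_perm <= delta_obs.
    """
    d = distances.to_numpy(dtype=float)
    labels = pd.Series(list(groups), index=distances.index)
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group must have size >= 2")

    delta_obs = _weighted_delta(d, codes, len(uniques))
    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_perm)
    work = codes.copy()
    for i in range(n_perm):
        rng.shuffle(work)
        perm_deltas[i] = _weighted_delta(d, work, len(uniques))
    delta_exp = float(perm_deltas.mean())
    p = (1 + int((perm_deltas <= delta_obs).sum())) / (1 + n_perm)
    return MRPPResult(
        A=1.0 - delta_obs / delta_exp,
        delta_obs=float(delta_obs),
        delta_exp=delta_exp,
        p=float(p),
        n_perm=n_perm,
    )
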