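"""Species-group census from marker-protein sequences.

Species groups (SGs) are clusters of single-copy marker proteins (rpS3) at
>= 99% identity, greedily built in descending length order the way
``usearch -cluster_fast`` does with exhaustive candidate comparison.  The
module also provides the detection rule (>= 2 mapped reads), sequencing-depth
normalization of per-contig coverage, incidence-based richness estimators
(Chao2 / iChao2) and a species-accumulation (collector's) curve with a
Lomolino model fit.

Identity between two sequences is matches / alignment columns of a global
alignment (computed with edlib); length-sort ties are broken lexicographically
by sequence id so clustering is fully deterministic.

The >= 99%-identity read-pair mapping filter applied before read counting is
a mapper's job and is upstream of this module: ``call_presence`` and the
abundance tables consume already-filtered counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class MarkerHit:
    """One HMM hit of the marker protein in one sample's assembly."""

    protein_id: str
    score: float
    length: int
    contig_id: str
    contig_length: int
    sample_id: str


@dataclass
class SpeciesGroup:
    sg_id: str
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)
    representative_contig: str | None = None


def filter_marker_hits(
    hits: list[MarkerHit] | pd.DataFrame,
    score_cut: float = 40.0,
    min_len: int = 200,
) -> list[MarkerHit] | pd.DataFrame:
    """Keep hits with score strictly above ``score_cut`` and length >= ``min_len``.

    The score threshold is exclusive (a hit *above* the cutoff is confident);
    the length threshold is inclusive (sequences shorter than ``min_len``
    residues are removed).
    """
    if isinstance(hits, pd.DataFrame):
        keep = (hits["score"] > score_cut) & (hits["length"] >= min_len)
        return hits.loc[keep].copy()
    return [h for h in hits if h.score > score_cut and h.length >= min_len]


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Uses edlib's Needleman-Wunsch edit-distance path; columns are all cigar
    positions (matches, mismatches, insertions, deletions).
    """
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    cols = sum(int(n) for n in re.findall(r"(\d+)[=XIDM]", res["cigar"]))
    return (cols - res["editDistance"]) / cols


def greedy_identity_cluster(
    seqs: dict[str, str] | list[tuple[str, str]],
    threshold: float = 0.99,
    identity_fn=pairwise_identity,
) -> list[SpeciesGroup]:
    """Greedy length-sorted centroid clustering at an identity threshold.

    Sequences are processed in descending length order (ties broken by id).
    Each sequence is compared against *every* existing centroid (the
    maxaccepts/maxrejects = 0 semantic); it joins the centroid of maximal
    identity if that identity >= ``threshold``, else founds a new cluster.
    ``identity_fn(a, b)`` may be swapped out (e.g. for a precomputed table).
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise ValueError("no sequences to cluster")
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))

    clusters: list[SpeciesGroup] = []
    centroid_seqs: list[str] = []
    for sid, seq in items:
        best_i, best_ident = -1, -1.0
        for i, cseq in enumerate(centroid_seqs):
            ident = identity_fn(seq, cseq)
            if ident > best_ident:
                best_i, best_ident = i, ident
        if best_i >= 0 and best_ident >= threshold:
            clusters[best_i].member_ids.append(sid)
        else:
            clusters.append(
                SpeciesGroup(
                    sg_id=f"SG{len(clusters):04d}",
                    centroid_id=sid,
                    member_ids=[sid],
                )
            )
            centroid_seqs.append(seq)
    return clusters


def assign_representative_contigs(
    clusters: list[SpeciesGroup], contig_of: dict[str, tuple[str, int]]
) -> None:
    """Set each cluster's representative to its longest member contig.

    ``contig_of`` maps protein id -> (contig_id, contig_length); ties broken
    by contig id.
    """
    for cl in clusters:
        contigs = [contig_of[m] for m in cl.member_ids if m in contig_of]
        if contigs:
            cl.representative_contig = max(contigs, key=lambda c: (c[1], c[0]))[0]


def call_presence(read_counts: pd.DataFrame, min_reads: int = 2) -> pd.DataFrame:
    """SG x sample incidence: present iff >= ``min_reads`` mapped reads."""
    if (read_counts.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    return read_counts >= min_reads


def normalize_coverage(
    raw: pd.DataFrame, library_sizes: pd.Series
) -> pd.DataFrame:
    """Per-10^8-reads coverage: raw / reads sequenced in sample * 1e8."""
    libs = library_sizes.reindex(raw.columns)
    if libs.isna().any():
        raise ValueError("library size missing for some samples")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return raw.div(libs, axis=1) * 1e8


@dataclass
class FrequencyCounts:
    """Incidence frequency counts across ``m`` sampling units."""

    m: int
    s_obs: int
    q1: int
    q2: int
    q3: int
    q4: int

    @classmethod
    def from_incidence(cls, incidence: pd.DataFrame) -> "FrequencyCounts":
        """Build from an SG x sample boolean incidence matrix."""
        freq = incidence.sum(axis=1)
        return cls(
            m=incidence.shape[1],
            s_obs=int((freq > 0).sum()),
            q1=int((freq == 1).sum()),
            q2=int((freq == 2).sum()),
            q3=int((freq == 3).sum()),
            q4=int((freq == 4).sum()),
        )


def chao2_ichao2(fc: FrequencyCounts) -> dict[str, float]:
    """Incidence-based richness estimators Chao2 and iChao2.

    Chao2 uses the classic singleton/doubleton form with the bias-corrected
    variant when no doubletons exist.  iChao2 adds the triple/quadruple
    improvement term; when q4 = 0 it is replaced by 1 (the convention of the
    estimator's source implementation).
    """
    m, s, q1, q2, q3, q4 = fc.m, fc.s_obs, fc.q1, fc.q2, fc.q3, fc.q4
    if m < 4:
        raise ValueError("iChao2 requires at least 4 sampling units")
    k = (m - 1) / m
    if q2 > 0:
        chao2 = s + k * q1 * q1 / (2.0 * q2)
    else:
        chao2 = s + k * q1 * (q1 - 1) / (2.0 * (q2 + 1))
    q4_eff = q4 if q4 > 0 else 1
    improve = ((m - 3) / (4.0 * m)) * (q3 / q4_eff) * max(
        q1 - ((m - 3) / (2.0 * (m - 1))) * q2 * q3 / q4_eff, 0.0
    )
    return {"chao2": chao2, "ichao2": chao2 + improve}


def lomolino(x: np.ndarray, smax: float, xmid: float, slope: float) -> np.ndarray:
    """Three-parameter Lomolino accumulation model S(x) = Smax / (1 + slope^ln(xmid/x))."""
    x = np.asarray(x, dtype=float)
    return smax / (1.0 + np.power(slope, np.log(xmid / x)))


def _lomolino_slope_at(x: float, smax: float, xmid: float, slope: float) -> float:
    u = np.power(slope, np.log(xmid / x))
    return smax * u * np.log(slope) / (x * (1.0 + u) ** 2)


@dataclass
class CollectorsCurveFit:
    smax: float
    xmid: float
    slope: float
    converged: bool
    residual_rms: float
    slope_at_max: float
    extrapolated_2x: float


def fit_lomolino(
    x: np.ndarray, s: np.ndarray, n_starts: int = 5, tol: float = 1e-8
) -> CollectorsCurveFit:
    """Multi-start nonlinear least squares fit of the Lomolino model."""
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    smax0 = float(s.max())
    starts = [
        (smax0 * f, xm, sl)
        for f, xm, sl in [
            (1.1, np.median(x), 2.0),
            (1.5, np.median(x), 5.0),
            (2.0, x.max(), 10.0),
            (1.2, x.max() / 2.0, 1.5),
            (3.0, x.max(), 3.0),
        ]
    ][:n_starts]

    def resid(p):
        return lomolino(x, *p) - s

    best, best_cost = None, np.inf
    for p0 in starts:
        try:
            sol = least_squares(
                resid,
                p0,
                bounds=([1e-6, 1e-6, 1.0 + 1e-9], [np.inf, np.inf, np.inf]),
                xtol=tol,
                ftol=tol,
                gtol=tol,
            )
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        return CollectorsCurveFit(np.nan, np.nan, np.nan, False, np.nan,
                                  np.nan, np.nan)
    smax, xmid, slope = best.x
    rms = float(np.sqrt(2 * best.cost / len(x)))
    return CollectorsCurveFit(
        smax=float(smax),
        xmid=float(xmid),
        slope=float(slope),
        converged=bool(best.success),
        residual_rms=rms,
        slope_at_max=float(_lomolino_slope_at(x.max(), smax, xmid, slope)),
        extrapolated_2x=float(lomolino(np.array([2 * x.max()]), smax, xmid,
                                       slope)[0]),
    )


def collectors_curve(
    sg_sets: dict[str, set[str]],
    iters: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, CollectorsCurveFit]:
    """Species-accumulation curve over random sample subsets plus model fit.

    For each subset size from 1 to the number of samples, draws ``iters``
    random subsets without replacement and counts unique SGs assembled in
    the union; fits the Lomolino model to the mean curve.
    """
    samples = sorted(sg_sets)
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    sizes = np.arange(1, n + 1)
    means = np.empty(n)
    for k in sizes:
        vals = []
        for _ in range(iters):
            chosen = rng.choice(samples, size=k, replace=False)
            union: set[str] = set()
            for s in chosen:
                union |= sg_sets[s]
            vals.append(len(union))
        means[k - 1] = np.mean(vals)
    curve = pd.DataFrame({"n_samples": sizes, "mean_sg": means})
    fit = fit_lomolino(sizes, means)
    return curve, fit
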