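"""Genome bin QC, dereplication and functional-annotation filtering.

Bins pass QC at >= 70% estimated completeness and < 10% contamination; one
bin per species group survives dereplication (highest completeness, then
lowest contamination, then lexicographic bin id).  Domain hits from a
CAZyme-style HMM search are filtered on e-value and HMM coverage, and
overlapping hits on the same protein are resolved to the lowest e-value.
Per-genome CAZy-family diversity uses Shannon, Simpson and inverse-Simpson
(1 / sum p^2) metrics.

The targeted carbon/nitrogen function catalog below is configuration, not a
fixed vocabulary: it defaults to 29 entries covering C1 compound turnover
(methanol, CO, formamide, formaldehyde), complex-carbohydrate side-group
esterases, acetate capture and the inorganic nitrogen cycle, and is fully
user-editable.  Type-I CO dehydrogenase (the CO-oxidizing coxL subtype) is
recognized by its active-site loop motif AYRCSFR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default 29-entry targeted C/N function catalog
TARGETED_FUNCTIONS = (
    "xoxF",          # lanthanide-dependent methanol dehydrogenase
    "coxL-TypeI",    # CO dehydrogenase large subunit, CO-oxidizing subtype
    "coxL-other",    # non-TypeI molybdoprotein dehydrogenase homologues
    "amiF",          # formamidase
    "FAL",           # formaldehyde oxidation
    "fdhA",          # formate dehydrogenase
    "NIT",           # nitrilase
    "URE",           # urease
    "ACL",           # acetyl-CoA synthetase
    "ackA",          # acetate kinase
    "pta",           # phosphotransacetylase
    "CE1",           # carbohydrate esterase family 1
    "CE4",           # carbohydrate esterase family 4
    "amoA",          # ammonia monooxygenase subunit A
    "hao",           # hydroxylamine oxidoreductase
    "nxrA",          # nitrite oxidoreductase
    "narG",          # respiratory nitrate reductase
    "napA",          # periplasmic nitrate reductase
    "nasA",          # assimilatory nitrate reductase
    "nirA",          # assimilatory nitrite reductase
    "nirB",          # NADH-dependent nitrite reductase
    "nrfA",          # cytochrome c nitrite reductase
    "nirK",          # Cu-containing NO-forming nitrite reductase
    "nirS",          # cd1-type NO-forming nitrite reductase
    "norB",          # nitric oxide reductase
    "nosZ",          # nitrous oxide reductase
    "nifH",          # nitrogenase iron protein
    "glnA",          # glutamine synthetase
    "gdhA",          # glutamate dehydrogenase
)

COXL_TYPE1_MOTIF = "AYRCSFR"
VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

#: composite capacities as (name, any-of list, all-of list)
DEFAULT_COMPOSITES = (
    ("acetate_capture", ("CE1", "CE4"), ("ACL",)),
)


def qc_filter(
    bins: pd.DataFrame,
    min_completeness: float = 70.0,
    max_contamination: float = 10.0,
) -> pd.DataFrame:
    """Bins with completeness >= 70% and contamination strictly < 10%."""
    keep = (bins["completeness"] >= min_completeness) & (
        bins["contamination"] < max_contamination
    )
    return bins.loc[keep].copy()


def dereplicate_by_sg(bins: pd.DataFrame) -> pd.DataFrame:
    """One best bin per species group.

    Ranking: highest completeness, then lowest contamination, then smallest
    bin id.  Bins without an SG link are dropped.
    """
    linked = bins.dropna(subset=["sg_id"])
    ordered = linked.sort_values(
        ["sg_id", "completeness", "contamination", "bin_id"],
        ascending=[True, False, True, True],
    )
    return ordered.groupby("sg_id", as_index=False).head(1).reset_index(drop=True)


@dataclass
class DomainHit:
    protein_id: str
    family: str
    e_value: float
    start: int
    end: int
    hmm_coverage: float


def filter_domain_hits(
    hits: pd.DataFrame,
    e_max: float = 1e-14,
    min_coverage: float = 0.35,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Quality- and overlap-filter domain hits.

    Keeps hits with e-value strictly below ``e_max`` and HMM coverage
    strictly above ``min_coverage``; then, among kept hits on the same
    protein whose residue intervals (1-based, inclusive) share at least
    ``min_overlap`` residues, only the lowest-e-value hit survives (ties by
    family name order).  Iterated until no overlaps remain.
    """
    if (hits["start"] > hits["end"]).any():
        raise ValueError("hit intervals must have start <= end")
    kept = hits.loc[
        (hits["e_value"] < e_max) & (hits["hmm_coverage"] > min_coverage)
    ].copy()
    out_idx: list = []
    for _, sub in kept.groupby("protein_id", sort=False):
        sub = sub.sort_values(["e_value", "family"], kind="mergesort")
        accepted: list[tuple[int, int]] = []
        for idx, row in sub.iterrows():
            s, e = int(row["start"]), int(row["end"])
            overlap = any(
                min(e, e2) - max(s, s2) + 1 >= min_overlap for s2, e2 in accepted
            )
            if not overlap:
                accepted.append((s, e))
                out_idx.append(idx)
    return kept.loc[sorted(out_idx, key=list(kept.index).index)]


def coxl_type1_motif(seq: str, motif: str = COXL_TYPE1_MOTIF) -> bool:
    """True iff the exact Type-I CO dehydrogenase motif occurs in ``seq``."""
    seq = seq.upper()
    bad = set(seq) - VALID_AA
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    return motif in seq


def cazy_diversity(cazy_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-genome diversity of CAZy-family counts.

    Returns shannon (-sum p ln p), simpson (1 - sum p^2), inv_simpson
    (1 / sum p^2) and richness (families with count > 0).  Genomes with no
    CAZy hits get zero shannon/richness, NaN inverse Simpson and are flagged.
    """
    arr = cazy_counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    totals = arr.sum(axis=1)
    out = pd.DataFrame(index=cazy_counts.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals[:, None] > 0, arr / totals[:, None], 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        sum_p2 = (p**2).sum(axis=1)
        out["shannon"] = -plogp.sum(axis=1)
        out["simpson"] = np.where(totals > 0, 1.0 - sum_p2, 0.0)
        out["inv_simpson"] = np.where(totals > 0, 1.0 / sum_p2, np.nan)
    out["richness"] = (arr > 0).sum(axis=1)
    out["empty"] = totals == 0
    return out


def targeted_function_table(
    hits: pd.DataFrame,
    catalog: tuple[str, ...] = TARGETED_FUNCTIONS,
    composites: tuple = DEFAULT_COMPOSITES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-genome hit counts over the targeted function catalog.

    ``hits`` needs columns ``genome_id`` and ``function``; identifiers not
    in the catalog are dropped with a warning column in the return.  Also
    evaluates composite capacities: boolean flags requiring at least one
    function from the any-of list and all functions of the all-of list.
    """
    known = hits["function"].isin(catalog)
    counts = (
        hits.loc[known]
        .groupby(["genome_id", "function"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(catalog), fill_value=0)
    )
    genomes = hits["genome_id"].unique()
    counts = counts.reindex(genomes, fill_value=0)
    counts.columns.name = None

    flags = pd.DataFrame(index=counts.index)
    for name, any_of, all_of in composites:
        present = counts > 0
        ok_any = (
            present[[f for f in any_of if f in counts.columns]].any(axis=1)
            if any_of
            else True
        )
        ok_all = (
            present[[f for f in all_of if f in counts.columns]].all(axis=1)
            if all_of
            else True
        )
        flags[name] = ok_any & ok_all
    return counts, flags


def composite_flags_from_matrix(
    fm: pd.DataFrame, composites: tuple = DEFAULT_COMPOSITES
) -> pd.DataFrame:
    """Composite capacity flags straight from a genome x function matrix."""
    present = fm > 0
    flags = pd.DataFrame(index=fm.index)
    for name, any_of, all_of in composites:
        ok_any = (
            present[[f for f in any_of if f in fm.columns]].any(axis=1)
            if any_of
            else pd.Series(True, index=fm.index)
        )
        ok_all = (
            present[[f for f in all_of if f in fm.columns]].all(axis=1)
            if all_of
            else pd.Series(True, index=fm.index)
        )
        flags[name] = ok_any & ok_all
    return flags
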