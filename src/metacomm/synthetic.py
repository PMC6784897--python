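"""Synthetic inputs for the full analysis pipeline.

The generator emulates a 60-sample soil sampling campaign: three replicate
pairs of plots (one plot of each pair under extended spring rainfall), three
depth strata (10-20, 20-30, 30-40 cm) and five sampling dates, with per-depth
sample counts of 24/16/20 so that the treatment contrasts at 10-20 cm and
30-40 cm see 24 and 20 samples respectively.  Species-group (SG) read counts
are negative-binomial draws around compositional means with planted depth
slopes, treatment effects and per-plot random effects; genome tables carry
planted category enrichments between response groups; marker-protein FASTA
files carry a controlled identity structure for clustering tests.

Every function is deterministic given its ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEPTH_LEVELS = ("10-20", "20-30", "30-40")
DEPTH_MIDPOINTS = {"10-20": 15.0, "20-30": 25.0, "30-40": 35.0}

#: plot -> replicate pair, mirroring the paired-plot layout of the field site
PLOT_REPLICATE = {2: "A", 5: "A", 9: "B", 12: "B", 13: "C", 16: "C"}
#: one plot of each pair receives the rainfall-extension treatment
TREATED_PLOTS = frozenset({5, 12, 16})

# (depth, plot, date) schedule yielding 60 samples: 24 at 10-20 cm,
# 16 at 20-30 cm and 20 at 30-40 cm, every plot x depth cell covered.
_SCHEDULE: list[tuple[str, int, int]] = (
    [("10-20", p, t) for p in PLOT_REPLICATE for t in (1, 2, 3, 4)]
    + [("20-30", p, t) for p in PLOT_REPLICATE for t in (2, 4)]
    + [("20-30", p, 5) for p in (2, 5, 9, 12)]
    + [("30-40", p, t) for p in PLOT_REPLICATE for t in (1, 3, 5)]
    + [("30-40", p, 2) for p in (13, 16)]
)

DEFAULT_PHYLA = (
    "Acidobacteria", "Verrucomicrobia", "Chloroflexi", "Proteobacteria",
    "Gemmatimonadetes", "Rokubacteria", "Bacteroidetes", "Actinobacteria",
    "Planctomycetes", "Nitrospirae", "Thaumarchaeota", "Bathyarchaeota",
    "Euryarchaeota", "Firmicutes", "Armatimonadetes", "Elusimicrobia",
    "Cyanobacteria", "Dormibacteraeota",
)


@dataclass
class CommunitySimParams:
    """Parameters of the SG count simulation.

    ``depth_log2fc`` is the log2 change in expected relative abundance per
    depth stratum for depth-responsive SGs; ``treat_log2fc`` likewise for
    treatment-responsive SGs under rainfall extension.  ``dispersion`` is the
    NB dispersion alpha in the mean-dispersion form Var = mu + alpha * mu^2.
    """

    n_sg: int = 300
    n_samples: int = 60
    frac_depth_responsive: float = 0.3
    frac_treat_responsive: float = 0.1
    depth_log2fc: float = 1.0
    treat_log2fc: float = 1.0
    plot_log2sd: float = 0.25
    dispersion: float = 0.05
    libsize_range: tuple[int, int] = (500_000, 2_000_000)
    read_length: int = 200
    contig_length_range: tuple[int, int] = (2_000, 500_000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sg < 1:
            raise ValueError("n_sg must be positive")
        if not (0 <= self.frac_depth_responsive <= 1):
            raise ValueError("frac_depth_responsive must be in [0, 1]")
        if not (0 <= self.frac_treat_responsive <= 1):
            raise ValueError("frac_treat_responsive must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.libsize_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("libsize_range must be positive and ordered")
        for v in (self.depth_log2fc, self.treat_log2fc, self.plot_log2sd):
            if not np.isfinite(v):
                raise ValueError("effect sizes must be finite")


@dataclass
class GenomeSimParams:
    """Parameters of the genome-table simulation (one response condition)."""

    n_genomes: int = 793
    phylum_labels: tuple[str, ...] = DEFAULT_PHYLA
    n_functions: int = 29
    n_cazy_families: int = 246
    #: (category, group, odds multiplier); category is a function name,
    #: a CAZy family name or a phylum; group is "Increase" or "Decrease"
    planted_enrichments: list[tuple[str, str, float]] = field(default_factory=list)
    #: fractions of genomes labelled Increase / Decrease (rest Neither);
    #: default mirrors 391 and 179 of 793 depth-responsive genomes
    frac_increase: float = 391 / 793
    frac_decrease: float = 179 / 793
    completeness_beta: tuple[float, float] = (7.0, 2.0)
    contamination_beta: tuple[float, float] = (1.0, 30.0)
    extra_bin_rate: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 3:
            raise ValueError("need at least 3 genomes")
        if self.frac_increase + self.frac_decrease > 1:
            raise ValueError("group fractions exceed 1")
        for _, group, mult in self.planted_enrichments:
            if group not in ("Increase", "Decrease"):
                raise ValueError("planted groups must be Increase or Decrease")
            if mult <= 0:
                raise ValueError("odds multipliers must be positive")


@dataclass
class SequenceSimParams:
    """Parameters of the marker-protein FASTA simulation."""

    n_clusters: int = 20
    members_per_cluster: int = 3
    seq_length: int = 300
    within_identity: float = 0.995
    between_identity: float = 0.90
    seed: int = 0

    def validate(self) -> None:
        if self.seq_length < 200:
            raise ValueError("seq_length must be >= 200 residues")
        if not (self.between_identity < self.within_identity <= 1):
            raise ValueError("need between_identity < within_identity <= 1")
        if self.n_clusters < 1 or self.members_per_cluster < 1:
            raise ValueError("cluster counts must be positive")


def sample_design(n_samples: int = 60) -> pd.DataFrame:
    """The sampling-campaign design table.

    Columns: sample_id, plot, replicate, treat_control, depth, depth_cm
    (stratum midpoint), time_point, factor (combined treatment-depth level).
    """
    if n_samples != len(_SCHEDULE):
        raise ValueError(
            f"the built-in campaign has {len(_SCHEDULE)} samples; "
            f"got n_samples={n_samples}"
        )
    rows = []
    for depth, plot, date in _SCHEDULE:
        treat = "treatment" if plot in TREATED_PLOTS else "control"
        depth_code = depth.split("-")[1] + "cm"
        rows.append(
            {
                "sample_id": f"P{plot:02d}_D{depth}_T{date}",
                "plot": plot,
                "replicate": PLOT_REPLICATE[plot],
                "treat_control": treat,
                "depth": depth,
                "depth_cm": DEPTH_MIDPOINTS[depth],
                "time_point": f"T{date}",
                "factor": f"{treat}{depth_code}",
            }
        )
    design = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
    return design


def simulate_coalescent_tree(labels: list[str], rng: np.random.Generator) -> str:
    """Random ultrametric coalescent tree over ``labels`` as a newick string."""
    nodes = [(lab, 0.0) for lab in labels]
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nwk_j, h_j) = nodes.pop(j)
        (nwk_i, h_i) = nodes.pop(i)
        merged = f"({nwk_i}:{height - h_i:.6f},{nwk_j}:{height - h_j:.6f})"
        nodes.append((merged, height))
    return nodes[0][0] + ";"


def simulate_community(
    params: CommunitySimParams,
) -> tuple[dict[str, pd.DataFrame | pd.Series], pd.DataFrame, str, dict]:
    """Simulate the SG x sample abundance tables, design, tree and truth.

    Returns ``(tables, design, newick, truth)`` where ``tables`` holds
    ``read_counts``, ``raw_coverage``, ``normalized_coverage`` (SG rows,
    sample columns) and ``library_sizes``; ``truth`` records the planted
    responsive SG sets and their effect directions.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    design = sample_design(params.n_samples)
    n_sg, n_samp = params.n_sg, len(design)
    sg_ids = [f"SG{i:04d}" for i in range(n_sg)]

    # heavy-tailed baseline relative abundances (rank-abundance-like)
    base = np.exp(rng.normal(0.0, 1.5, size=n_sg))

    # planted responders: half increase with depth, half decrease
    n_depth = int(round(params.frac_depth_responsive * n_sg))
    depth_idx = rng.choice(n_sg, size=n_depth, replace=False)
    depth_sign = np.zeros(n_sg)
    depth_sign[depth_idx[: n_depth // 2]] = 1.0
    depth_sign[depth_idx[n_depth // 2:]] = -1.0

    n_treat = int(round(params.frac_treat_responsive * n_sg))
    treat_idx = rng.choice(n_sg, size=n_treat, replace=False)
    treat_sign = np.zeros(n_sg)
    treat_sign[treat_idx[: n_treat // 2]] = 1.0
    treat_sign[treat_idx[n_treat // 2:]] = -1.0

    plots = sorted(PLOT_REPLICATE)
    plot_eff = rng.normal(0.0, params.plot_log2sd, size=(n_sg, len(plots)))
    plot_col = {p: k for k, p in enumerate(plots)}

    libsizes = rng.integers(
        params.libsize_range[0], params.libsize_range[1] + 1, size=n_samp
    ).astype(float)

    depth_step = design["depth"].map(
        {d: k for k, d in enumerate(DEPTH_LEVELS)}
    ).to_numpy()
    treated = (design["treat_control"] == "treatment").to_numpy().astype(float)
    pcols = design["plot"].map(plot_col).to_numpy()

    log2w = (
        np.log2(base)[:, None]
        + np.outer(depth_sign * params.depth_log2fc, depth_step)
        + np.outer(treat_sign * params.treat_log2fc, treated)
        + plot_eff[:, pcols]
    )
    w = np.exp2(log2w)
    mu = libsizes[None, :] * w / w.sum(axis=0, keepdims=True)

    alpha = params.dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    contig_len = rng.integers(
        params.contig_length_range[0], params.contig_length_range[1] + 1, size=n_sg
    ).astype(float)
    raw_cov = counts * params.read_length / contig_len[:, None]

    cols = design["sample_id"].tolist()
    read_counts = pd.DataFrame(counts, index=sg_ids, columns=cols)
    raw_coverage = pd.DataFrame(raw_cov, index=sg_ids, columns=cols)
    library_sizes = pd.Series(libsizes, index=cols, name="library_size")
    normalized = raw_coverage.div(library_sizes, axis=1) * 1e8

    newick = simulate_coalescent_tree(sg_ids, rng)

    truth = {
        "depth_increase": [sg_ids[i] for i in np.flatnonzero(depth_sign > 0)],
        "depth_decrease": [sg_ids[i] for i in np.flatnonzero(depth_sign < 0)],
        "treat_increase": [sg_ids[i] for i in np.flatnonzero(treat_sign > 0)],
        "treat_decrease": [sg_ids[i] for i in np.flatnonzero(treat_sign < 0)],
        "contig_length": dict(zip(sg_ids, contig_len)),
    }
    tables = {
        "read_counts": read_counts,
        "raw_coverage": raw_coverage,
        "normalized_coverage": normalized,
        "library_sizes": library_sizes,
    }
    return tables, design, newick, truth


def _planted_rates(base_rate: float, mult: float) -> float:
    odds = base_rate / (1.0 - base_rate) * mult
    return odds / (1.0 + odds)


def simulate_genomes(
    params: GenomeSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate genome bins, function/CAZy count matrices and response groups.

    Returns ``(bins, functions, cazy, groups)``: a bin table with QC metadata
    and SG linkage (including lower-quality duplicate bins per SG so that
    dereplication is exercised), genome x function and genome x CAZy-family
    count matrices, and the genome -> {Increase, Decrease, Neither} labels.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_genomes
    genome_ids = [f"G{i:04d}" for i in range(n)]

    n_inc = int(round(params.frac_increase * n))
    n_dec = int(round(params.frac_decrease * n))
    labels = np.array(
        ["Increase"] * n_inc
        + ["Decrease"] * n_dec
        + ["Neither"] * (n - n_inc - n_dec)
    )
    rng.shuffle(labels)
    if min(n_inc, n_dec, n - n_inc - n_dec) == 0:
        raise ValueError("a response group is empty under these fractions")
    groups = pd.Series(labels, index=genome_ids, name="response")

    phyla = list(params.phylum_labels)
    base_w = rng.dirichlet(np.full(len(phyla), 2.0))
    phylum_mult = {g: np.ones(len(phyla)) for g in ("Increase", "Decrease", "Neither")}
    for cat, grp, mult in params.planted_enrichments:
        if cat in phyla:
            phylum_mult[grp][phyla.index(cat)] *= mult
    phylum = np.empty(n, dtype=object)
    for grp, mults in phylum_mult.items():
        mask = labels == grp
        w = base_w * mults
        w = w / w.sum()
        phylum[mask] = rng.choice(phyla, size=mask.sum(), p=w)

    from .annotation import TARGETED_FUNCTIONS

    func_names = list(TARGETED_FUNCTIONS[: params.n_functions])
    if len(func_names) < params.n_functions:
        func_names += [
            f"fn{i}" for i in range(len(func_names), params.n_functions)
        ]
    cazy_names = [f"CAZy{i:03d}" for i in range(params.n_cazy_families)]
    # keep the two esterase families of the composite-capacity rule if room
    for known, pos in (("CE1", 0), ("CE4", 1), ("GH5", 2)):
        if params.n_cazy_families > pos:
            cazy_names[pos] = known

    def count_matrix(names: list[str], lo: float, hi: float) -> pd.DataFrame:
        base_rates = rng.uniform(lo, hi, size=len(names))
        mat = np.zeros((n, len(names)), dtype=np.int64)
        for j, name in enumerate(names):
            rates = {g: base_rates[j] for g in ("Increase", "Decrease", "Neither")}
            for cat, grp, mult in params.planted_enrichments:
                if cat == name:
                    rates[grp] = _planted_rates(base_rates[j], mult)
            for grp, rate in rates.items():
                mask = labels == grp
                present = rng.random(mask.sum()) < rate
                extra = rng.poisson(0.7, size=mask.sum())
                mat[mask, j] = present * (1 + extra)
        return pd.DataFrame(mat, index=genome_ids, columns=names)

    functions = count_matrix(func_names, 0.10, 0.45)
    cazy = count_matrix(cazy_names, 0.02, 0.30)

    a_c, b_c = params.completeness_beta
    a_x, b_x = params.contamination_beta
    completeness = 100.0 * rng.beta(a_c, b_c, size=n)
    contamination = 100.0 * rng.beta(a_x, b_x, size=n)

    rows = []
    for i, gid in enumerate(genome_ids):
        sg = f"SG{i:04d}"
        rows.append(
            {
                "bin_id": gid,
                "sg_id": sg,
                "completeness": completeness[i],
                "contamination": contamination[i],
                "phylum": phylum[i],
            }
        )
        # redundant sister bins from other samples: strictly worse QC
        for k in range(rng.poisson(params.extra_bin_rate)):
            rows.append(
                {
                    "bin_id": f"{gid}_dup{k}",
                    "sg_id": sg,
                    "completeness": completeness[i] * rng.uniform(0.5, 0.98),
                    "contamination": contamination[i] + rng.uniform(0.1, 5.0),
                    "phylum": phylum[i],
                }
            )
    bins = pd.DataFrame(rows)
    return bins, functions, cazy, groups


def _mutate(seq: np.ndarray, n_mut: int, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if n_mut == 0:
        return out
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = [a for a in AMINO_ACIDS if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return out


def simulate_marker_sequences(params: SequenceSimParams) -> list[tuple[str, str]]:
    """Simulate marker-protein records as ``(id, sequence)`` pairs.

    Cluster ``c`` has a random centroid; members are substitution-mutated
    copies at identity >= ``within_identity``.  Distinct centroids are
    independent random sequences, re-drawn if any pair exceeds
    ``between_identity`` (vanishingly rare at realistic lengths).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    L = params.seq_length
    max_mut = int(np.floor((1.0 - params.within_identity) * L))

    aas = np.array(list(AMINO_ACIDS))
    centroids = []
    for _ in range(params.n_clusters):
        for _attempt in range(100):
            cand = aas[rng.integers(len(aas), size=L)]
            if all(
                np.mean(cand == c) <= params.between_identity for c in centroids
            ):
                break
        else:
            raise ValueError(
                "could not draw centroids below between_identity; "
                "sequence length too short"
            )
        centroids.append(cand)

    records = []
    for c, centroid in enumerate(centroids):
        for m in range(params.members_per_cluster):
            if m == 0:
                seq = centroid
            else:
                seq = _mutate(centroid, int(rng.integers(0, max_mut + 1)), rng)
            records.append((f"SG{c:04d}_m{m}", "".join(seq)))
    return records


def write_community(
    out_dir: str | Path,
    tables: dict,
    design: pd.DataFrame,
    newick: str,
    truth: dict,
) -> None:
    """Write community outputs as TSV / newick / JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("read_counts", "raw_coverage", "normalized_coverage"):
        tables[name].to_csv(out / f"{name}.tsv", sep="\t", index_label="sg_id")
    tables["library_sizes"].to_frame().to_csv(
        out / "library_sizes.tsv", sep="\t", index_label="sample_id"
    )
    design.to_csv(out / "metadata.tsv", sep="\t", index=False)
    (out / "tree.nwk").write_text(newick + "\n")
    (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))


def write_genomes(
    out_dir: str | Path,
    bins: pd.DataFrame,
    functions: pd.DataFrame,
    cazy: pd.DataFrame,
    groups: pd.Series,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bins.to_csv(out / "bins.tsv", sep="\t", index=False)
    functions.to_csv(out / "functions.tsv", sep="\t", index_label="genome_id")
    cazy.to_csv(out / "cazy.tsv", sep="\t", index_label="genome_id")
    groups.to_frame().to_csv(out / "response_groups.tsv", sep="\t",
                             index_label="genome_id")


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k: k + 80] + "\n")
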