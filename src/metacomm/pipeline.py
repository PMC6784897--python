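"""End-to-end orchestration: census -> community structure -> differential
abundance -> genome annotation -> enrichment, with one config, per-stage
seeds and a reproducible run manifest.

All matrices travel as TSV (samples as columns), trees as newick, proteins
as FASTA.  In synthetic mode the generator stands in for raw-data inputs so
the whole analysis runs from a seed alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, census, community, diffabund, enrichment, synthetic


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with their standard defaults."""

    out_dir: str = "metacomm_out"
    # census
    cluster_identity: float = 0.99
    hit_score_cut: float = 40.0
    hit_min_len: int = 200
    presence_min_reads: int = 2
    # community structure
    cv_max: float = 3.0
    min_occupied: int = 5
    occupancy_cov: float = 0.25
    nmds_restarts: int = 20
    use_hellinger_for_unifrac: bool = True
    mrpp_permutations: int = 10_000
    # genome QC / annotation
    min_completeness: float = 70.0
    max_contamination: float = 10.0
    evalue_max: float = 1e-14
    hmm_coverage_min: float = 0.35
    # statistics
    fdr_gate: float = 0.1
    fdr_significant: float = 0.05
    n_perm: int = 10_000
    # per-stage seeds
    seed_community: int = 1
    seed_genomes: int = 2
    seed_sequences: int = 3
    seed_nmds: int = 4
    seed_mrpp: int = 5
    seed_enrichment: int = 6
    # synthetic-generator knobs (used in synthetic mode only)
    synthetic: dict = field(default_factory=dict)
    # input paths (ignored in synthetic mode)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_seed(cls, seed: int, **overrides) -> "PipelineConfig":
        """Derive all per-stage seeds from one master seed."""
        ss = np.random.SeedSequence(seed)
        seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)]
        return cls(
            seed_community=seeds[0],
            seed_genomes=seeds[1],
            seed_sequences=seeds[2],
            seed_nmds=seeds[3],
            seed_mrpp=seeds[4],
            seed_enrichment=seeds[5],
            **overrides,
        )


# ---------------------------------------------------------------------------
# bookkeeping identities used when summarizing published group counts

def fraction_of_total(*parts: int, total: int, percent: bool = True) -> float:
    """Share of ``total`` covered by the summed parts (as percent)."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = sum(parts) / total
    return 100.0 * frac if percent else frac


def per_sample_mean(total: int, n_samples: int) -> float:
    """Mean count per sample, e.g. marker sequences or bins per metagenome."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return total / n_samples


def condition_group_size(n_increase: int, n_decrease: int) -> int:
    """Genomes entering an enrichment condition: responders on either side."""
    return n_increase + n_decrease


# ---------------------------------------------------------------------------

def validate_inputs(
    tables: dict,
    design: pd.DataFrame,
    newick: str | None = None,
    bins: pd.DataFrame | None = None,
) -> list[str]:
    """Consistency report over pipeline inputs; empty list means clean."""
    report: list[str] = []
    counts = tables.get("read_counts")
    meta_samples = set(design["sample_id"])
    if counts is not None:
        extra = set(counts.columns) - meta_samples
        if extra:
            report.append(f"samples missing from metadata: {sorted(extra)[:5]}")
        for name in ("raw_coverage", "normalized_coverage"):
            other = tables.get(name)
            if other is not None and not other.columns.equals(counts.columns):
                report.append(f"{name} columns disagree with read_counts")
        libs = tables.get("library_sizes")
        if libs is not None and (libs.reindex(counts.columns).isna().any()
                                 or (libs <= 0).any()):
            report.append("library sizes missing or non-positive")
    if newick is not None and counts is not None:
        tree = community.read_tree(newick)
        leaves = {t.name for t in tree.tips()}
        missing = set(counts.index) - leaves
        if missing:
            report.append(f"SGs absent from tree: {sorted(missing)[:5]}")
    cells = design.groupby(["plot", "depth"]).size()
    n_expected = design["plot"].nunique() * design["depth"].nunique()
    if len(cells) < n_expected:
        report.append("some plot x depth cells have no samples")
    if bins is not None:
        bad = ~bins["completeness"].between(0, 100)
        if bad.any():
            report.append("completeness outside [0, 100]")
        if (bins["contamination"] < 0).any():
            report.append("negative contamination")
    return report


@dataclass
class RunManifest:
    stages: list[dict] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)

    def record(self, stage: str, t0: float, **counts) -> None:
        self.stages.append(
            {"stage": stage, "seconds": round(time.time() - t0, 3), **counts}
        )

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stages, "seeds": self.seeds,
             "input_hashes": self.input_hashes},
            indent=1,
        )


def _hash_frame(df: pd.DataFrame | pd.Series) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()[:16]


def load_inputs(in_dir: str | Path) -> dict:
    """Load pipeline inputs from a directory of TSV / newick / FASTA files.

    Expects the layout the synthetic writers emit: read_counts.tsv,
    raw_coverage.tsv, normalized_coverage.tsv, library_sizes.tsv,
    metadata.tsv, tree.nwk, bins.tsv, functions.tsv, cazy.tsv,
    response_groups.tsv and optionally markers.faa.  Missing optional files
    yield None entries; a missing required file raises with its name.
    """
    d = Path(in_dir)
    required = ["read_counts.tsv", "raw_coverage.tsv", "metadata.tsv"]
    for name in required:
        if not (d / name).exists():
            raise FileNotFoundError(f"required input {name} missing in {d}")
    tables = {
        "read_counts": pd.read_csv(d / "read_counts.tsv", sep="\t", index_col=0),
        "raw_coverage": pd.read_csv(d / "raw_coverage.tsv", sep="\t", index_col=0),
    }
    if (d / "library_sizes.tsv").exists():
        tables["library_sizes"] = pd.read_csv(
            d / "library_sizes.tsv", sep="\t", index_col=0
        ).iloc[:, 0]
    if (d / "normalized_coverage.tsv").exists():
        tables["normalized_coverage"] = pd.read_csv(
            d / "normalized_coverage.tsv", sep="\t", index_col=0
        )
    elif "library_sizes" in tables:
        tables["normalized_coverage"] = census.normalize_coverage(
            tables["raw_coverage"], tables["library_sizes"]
        )
    else:
        raise FileNotFoundError(
            "need normalized_coverage.tsv or library_sizes.tsv"
        )
    out = {
        "tables": tables,
        "design": pd.read_csv(d / "metadata.tsv", sep="\t"),
        "newick": (d / "tree.nwk").read_text() if (d / "tree.nwk").exists()
        else None,
        "bins": pd.read_csv(d / "bins.tsv", sep="\t")
        if (d / "bins.tsv").exists() else None,
        "functions": pd.read_csv(d / "functions.tsv", sep="\t", index_col=0)
        if (d / "functions.tsv").exists() else None,
        "cazy": pd.read_csv(d / "cazy.tsv", sep="\t", index_col=0)
        if (d / "cazy.tsv").exists() else None,
        "groups": pd.read_csv(
            d / "response_groups.tsv", sep="\t", index_col=0
        ).iloc[:, 0]
        if (d / "response_groups.tsv").exists() else None,
        "records": None,
    }
    if (d / "markers.faa").exists():
        from Bio import SeqIO

        out["records"] = [
            (r.id, str(r.seq)) for r in SeqIO.parse(d / "markers.faa", "fasta")
        ]
    return out


def run_all(
    config: PipelineConfig,
    synthetic_mode: bool = True,
    write: bool = False,
) -> dict:
    """Execute the full pipeline and return all stage outputs + manifest.

    In synthetic mode the community, genome and sequence generators supply
    every input.  Stage order: census, community structure, differential
    abundance, genome annotation, enrichment.  A failing stage raises with
    its name; previously computed outputs stay in the returned dict.
    """
    cfg = config
    manifest = RunManifest(
        seeds={
            k: getattr(cfg, k)
            for k in vars(cfg)
            if k.startswith("seed_")
        }
    )
    out: dict = {"manifest": manifest}
    stage = "inputs"
    try:
        t0 = time.time()
        if synthetic_mode:
            syn = dict(cfg.synthetic)
            comm_params = synthetic.CommunitySimParams(
                seed=cfg.seed_community, **syn.get("community", {})
            )
            tables, design, newick, truth = synthetic.simulate_community(
                comm_params
            )
            gen_params = synthetic.GenomeSimParams(
                seed=cfg.seed_genomes, **syn.get("genomes", {})
            )
            bins, functions, cazy, groups_truth = synthetic.simulate_genomes(
                gen_params
            )
            seq_params = synthetic.SequenceSimParams(
                seed=cfg.seed_sequences, **syn.get("sequences", {})
            )
            records = synthetic.simulate_marker_sequences(seq_params)
        else:
            in_dir = cfg.inputs.get("dir")
            if not in_dir:
                raise ValueError("config.inputs['dir'] required without "
                                 "synthetic mode")
            loaded = load_inputs(in_dir)
            tables, design, newick = (loaded["tables"], loaded["design"],
                                      loaded["newick"])
            bins, functions, cazy = (loaded["bins"], loaded["functions"],
                                     loaded["cazy"])
            groups_truth, records, truth = loaded["groups"], loaded["records"], {}
            if newick is None:
                raise ValueError(
                    "tree.nwk missing but weighted UniFrac is requested"
                )
        out.update(
            tables=tables, design=design, newick=newick, truth=truth,
            bins=bins, functions=functions, cazy=cazy,
            groups_truth=groups_truth, records=records,
        )
        manifest.input_hashes = {
            "read_counts": _hash_frame(tables["read_counts"]),
            "design": _hash_frame(design.astype(str)),
            "bins": _hash_frame(bins.astype(str)),
        }
        manifest.record(stage, t0, n_samples=len(design),
                        n_sg=len(tables["read_counts"]))

        stage = "census"
        t0 = time.time()
        report = validate_inputs(tables, design, newick, bins)
        if report:
            raise ValueError(f"input validation failed: {report}")
        clusters = (
            census.greedy_identity_cluster(dict(records),
                                           threshold=cfg.cluster_identity)
            if records else []
        )
        incidence = census.call_presence(
            tables["read_counts"], cfg.presence_min_reads
        )
        fc = census.FrequencyCounts.from_incidence(incidence)
        richness = census.chao2_ichao2(fc)
        out.update(clusters=clusters, incidence=incidence, richness=richness)
        manifest.record(stage, t0, n_clusters=len(clusters),
                        s_obs=fc.s_obs)

        stage = "community_structure"
        t0 = time.time()
        norm_samples = tables["normalized_coverage"].T  # samples as rows
        hel = community.hellinger(norm_samples)
        kept = community.cv_occupancy_filter(
            tables["normalized_coverage"],
            tables["raw_coverage"],
            community.FilterSpec(cfg.cv_max, cfg.min_occupied,
                                 cfg.occupancy_cov),
        )
        table_for_unifrac = (hel if cfg.use_hellinger_for_unifrac
                             else norm_samples)[kept]
        dm = community.weighted_unifrac(newick, table_for_unifrac)
        ord_res = community.nmds(dm, restarts=cfg.nmds_restarts,
                                 seed=cfg.seed_nmds)
        meta = design.set_index("sample_id").loc[dm.index]
        mrpp_results = {
            var: community.mrpp(dm, meta[var], n_perm=cfg.mrpp_permutations,
                                seed=cfg.seed_mrpp)
            for var in ("depth", "replicate", "treat_control", "time_point")
        }
        out.update(kept_sgs=kept, distances=dm, ordination=ord_res,
                   mrpp=mrpp_results)
        manifest.record(stage, t0, n_kept=len(kept),
                        nmds_stress=round(float(ord_res.stress), 4))

        stage = "differential_abundance"
        t0 = time.time()
        depth_groups = diffabund.depth_response_groups(
            tables["read_counts"], tables["normalized_coverage"], design,
            fdr_gate=cfg.fdr_significant,
        )
        treat = {}
        for stratum in ("20cm", "40cm"):
            res = diffabund.treatment_contrast(
                tables["read_counts"], design, stratum
            )
            treat[stratum] = res.table
        out.update(depth_groups=depth_groups, treatment=treat)
        manifest.record(
            stage, t0,
            n_increase=int((depth_groups["direction"] == "Increase").sum()),
            n_decrease=int((depth_groups["direction"] == "Decrease").sum()),
        )

        stage = "genome_annotation"
        t0 = time.time()
        if bins is None or functions is None or cazy is None or \
                groups_truth is None:
            manifest.record(stage, t0, skipped=1)
            manifest.record("enrichment", t0, skipped=1)
            return out
        passing = annotation.qc_filter(bins, cfg.min_completeness,
                                       cfg.max_contamination)
        derep = annotation.dereplicate_by_sg(passing)
        genome_ids = [g for g in derep["bin_id"] if g in functions.index]
        diversity = annotation.cazy_diversity(cazy.loc[genome_ids])
        out.update(passing_bins=passing, derep_bins=derep,
                   cazy_div=diversity)
        manifest.record(stage, t0, n_pass=len(passing), n_derep=len(derep))

        stage = "enrichment"
        t0 = time.time()
        groups = groups_truth.loc[genome_ids]
        spec = enrichment.PermutationSpec(
            n_perm=cfg.n_perm, seed=cfg.seed_enrichment
        )
        phylum_presence = pd.get_dummies(
            bins.set_index("bin_id").loc[genome_ids, "phylum"]
        ).astype(bool)
        func_res = enrichment.enrichment_cascade(
            functions.loc[genome_ids] > 0, groups, spec,
            cfg.fdr_gate, cfg.fdr_significant,
        )
        phy_res = enrichment.enrichment_cascade(
            phylum_presence, groups, spec, cfg.fdr_gate, cfg.fdr_significant
        )
        div_res = enrichment.diversity_contrast(
            diversity[["shannon", "inv_simpson", "richness"]], groups,
            cfg.fdr_gate, cfg.fdr_significant,
        )
        out.update(enrich_functions=func_res, enrich_phyla=phy_res,
                   diversity_contrast=div_res)
        manifest.record(
            stage, t0,
            n_sig_functions=int(func_res.table["significant"].sum()),
            n_sig_phyla=int(phy_res.table["significant"].sum()),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if write:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        synthetic.write_community(out_dir / "inputs", tables, design, newick,
                                  truth)
        synthetic.write_genomes(out_dir / "inputs", bins, functions, cazy,
                                groups_truth)
        synthetic.write_fasta(out_dir / "inputs" / "markers.faa", records)
        dm.to_csv(out_dir / "unifrac_distances.tsv", sep="\t")
        ord_res.coordinates.to_csv(out_dir / "nmds_coordinates.tsv", sep="\t")
        depth_groups.to_csv(out_dir / "depth_response.tsv", sep="\t")
        for stratum, tab in treat.items():
            tab.to_csv(out_dir / f"treatment_{stratum}.tsv", sep="\t")
        func_res.table.to_csv(out_dir / "enrichment_functions.tsv", sep="\t")
        phy_res.table.to_csv(out_dir / "enrichment_phyla.tsv", sep="\t")
        div_res.to_csv(out_dir / "cazy_diversity_contrast.tsv", sep="\t")
        (out_dir / "mrpp.json").write_text(
            json.dumps({k: asdict(v) for k, v in mrpp_results.items()},
                       indent=1)
        )
        (out_dir / "manifest.json").write_text(manifest.to_json())
    return out
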