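"""End-to-end orchestration: simulate/load -> coverage -> counts ->
differential -> clusters -> enrichment, with a run report.

A run is declared by a single config mapping (YAML on disk). Either a
``simulate`` section generates the dataset, or an ``inputs`` section
points at BED read files, a refFlat-style annotation, chromosome sizes
and an optional GMT. All stages write TSVs into a fixed directory layout
under the output directory:

    coverage/   bedGraph per sample+mark, TSS meta-profile per mark
    counts/     promoter count matrix per mark + sample sheet
    diff/       per-mark differential tables + significance calls
    clusters/   assignments, per-cluster summaries, merge list, heatmap matrix
    enrichment/ per-cluster gene-set enrichment, group comparison
    report/     run report (text + TSV)

Reruns with the same config and seed reproduce the tables byte for byte.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .clustering import (
    cluster_meta_profiles,
    cluster_summary,
    cut_clusters,
    group_average,
    hier_cluster,
    zscale_counts,
)
from .coverage import (
    build_coverage,
    deduplicate_reads,
    extend_reads,
    meta_profile,
    normalize_per_million,
    quantile_normalize,
    smooth,
)
from .differential import differential_table, select_significant, size_factors
from .io_formats import (
    read_annotation,
    read_bed_reads,
    read_chrom_sizes,
    read_gmt,
    write_bedgraph,
)
from .promoters import assemble_count_matrix, count_reads_in_windows, promoter_windows
from .setstats import hypergeom_enrichment, mannwhitney_compare
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("promdiff")

DEFAULT_PARAMS: dict[str, Any] = {
    "fragment_length": 200,
    "smooth_window": 1000,
    "flank": 2000,
    "bin": 50,
    "upstream": 1000,
    "downstream": 1000,
    "lfc_threshold": 1.0,
    "p_threshold": 0.05,
    "k": 4,
    "phenotype_threshold": 0.5,
    "counting_mode": "read_5prime",
    "pseudocount": 1.0,
    "deduplicate": True,
    "quantile_ties": "average",
    "write_coverage": True,
    "comparison_set": None,
}


@dataclass(slots=True)
class RunConfig:
    marks: list[str]
    samples: dict[str, str]  # sample id -> group
    params: dict[str, Any]
    seed: int = 0
    simulate: dict[str, Any] | None = None
    inputs: dict[str, Any] | None = None

    def group_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.samples.values():
            out[g] = out.get(g, 0) + 1
        return out


def validate_config(raw: Mapping[str, Any]) -> tuple[RunConfig | None, list[str]]:
    """Check a raw config mapping; returns (config, errors) with all
    violations aggregated rather than failing on the first."""
    errors: list[str] = []
    params = dict(DEFAULT_PARAMS)
    params.update(raw.get("params", {}) or {})
    for key in ("lfc_threshold", "phenotype_threshold", "pseudocount"):
        if params[key] <= 0:
            errors.append(f"params.{key} must be positive")
    if not 0 < params["p_threshold"] <= 1:
        errors.append("params.p_threshold must lie in (0, 1]")
    if params["counting_mode"] not in ("read_5prime", "fragment_overlap"):
        errors.append(f"unknown counting mode {params['counting_mode']!r}")
    if params["k"] < 1:
        errors.append("params.k must be >= 1")

    sim = raw.get("simulate")
    inputs = raw.get("inputs")
    if sim is None and inputs is None:
        errors.append("config needs a 'simulate' or an 'inputs' section")

    marks: list[str] = list(raw.get("marks", []) or [])
    samples: dict[str, str] = dict(raw.get("samples", {}) or {})
    if sim is not None:
        try:
            sim_cfg = SimulationConfig(**{**sim, "seed": raw.get("seed", 0)})
            marks = marks or list(sim_cfg.marks)
            samples = samples or {
                s: sim_cfg.group_of(s) for s in sim_cfg.sample_ids()
            }
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate section invalid: {exc}")
    if inputs is not None:
        for key in ("annotation", "chrom_sizes", "reads"):
            if key not in inputs:
                errors.append(f"inputs.{key} missing")
        for key in ("annotation", "chrom_sizes", "gene_sets"):
            p = inputs.get(key)
            if p is not None and not Path(p).exists():
                errors.append(f"inputs.{key}: no such file {p}")
        reads = inputs.get("reads", {}) or {}
        marks = marks or sorted(reads)
        for mark, per_sample in reads.items():
            for sid, path in (per_sample or {}).items():
                if not Path(path).exists():
                    errors.append(f"reads file missing for sample {sid}/{mark}: {path}")
        if not samples:
            errors.append("'samples' (sample -> group) is required with explicit inputs")
    if samples:
        groups = set(samples.values())
        if not {"patient", "control"} <= groups:
            errors.append("both 'patient' and 'control' groups need >= 1 sample")
    if not marks:
        errors.append("no marks defined")
    if errors:
        return None, errors
    return (
        RunConfig(
            marks=marks,
            samples=samples,
            params=params,
            seed=int(raw.get("seed", 0)),
            simulate=dict(sim) if sim is not None else None,
            inputs=dict(inputs) if inputs is not None else None,
        ),
        [],
    )


def load_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


@dataclass(slots=True)
class RunReport:
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    version: str = __version__
    seed: int = 0
    config_echo: dict[str, Any] = field(default_factory=dict)

    def record(self, stage: str, **info: Any) -> None:
        self.stages.setdefault(stage, {}).update(info)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": stage, "key": k, "value": v}
            for stage, info in self.stages.items()
            for k, v in info.items()
        ]
        return pd.DataFrame(rows, columns=["stage", "key", "value"])

    def write(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / "report.tsv", sep="\t", index=False)
        with open(out_dir / "report.txt", "w") as fh:
            fh.write(f"promdiff {self.version}, seed {self.seed}\n\n")
            for stage, info in self.stages.items():
                fh.write(f"[{stage}]\n")
                for k, v in info.items():
                    fh.write(f"  {k}: {v}\n")
                fh.write("\n")
            fh.write("[config]\n")
            for k, v in self.config_echo.items():
                fh.write(f"  {k}: {v}\n")


def _setup_logging(verbose: bool = False) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def run_pipeline(config: RunConfig, out_dir: str | Path, verbose: bool = False) -> RunReport:
    """Execute every stage; returns the run report (also written to disk)."""
    _setup_logging(verbose)
    out = Path(out_dir)
    for sub in ("coverage", "counts", "diff", "clusters", "enrichment", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    params = config.params
    report = RunReport(seed=config.seed, config_echo={**params, "marks": config.marks})

    # ---- stage 1: inputs -------------------------------------------------
    gene_sets = None
    if config.simulate is not None:
        logger.info("simulating dataset (seed %d)", config.seed)
        sim_cfg = SimulationConfig(**{**config.simulate, "seed": config.seed})
        data = simulate_dataset(sim_cfg, include_input=False)
        chrom_sizes, genes = data["chrom_sizes"], data["genes"]
        reads_by = {
            (m, s): data["reads"][(m, s)] for m in config.marks for s in config.samples
        }
        truth = data["truth"]
        truth.to_csv(out / "report" / "truth.tsv", sep="\t")
    else:
        assert config.inputs is not None
        chrom_sizes = read_chrom_sizes(config.inputs["chrom_sizes"])
        genes = read_annotation(config.inputs["annotation"])
        reads_by = {
            (m, s): read_bed_reads(config.inputs["reads"][m][s])
            for m in config.marks
            for s in config.samples
        }
        if config.inputs.get("gene_sets"):
            gene_sets = read_gmt(config.inputs["gene_sets"])
    report.record(
        "inputs",
        genes=len(genes),
        chromosomes=len(chrom_sizes),
        samples=len(config.samples),
        marks=len(config.marks),
    )

    # ---- stage 2: deduplication + coverage -------------------------------
    dedup_by: dict[tuple[str, str], list] = {}
    n_in = n_kept = 0
    for key, reads in reads_by.items():
        n_in += len(reads)
        dedup_by[key] = deduplicate_reads(reads) if params["deduplicate"] else list(reads)
        n_kept += len(dedup_by[key])
    report.record("deduplicate", reads_in=n_in, reads_kept=n_kept)

    tss_sites = [(g.txn.chrom, g.tss, g.txn.strand) for g in genes]
    tss_by_gene = {g.gene_id: (g.txn.chrom, g.tss, g.txn.strand) for g in genes}
    tracks_by_mark: dict[str, dict[str, Any]] = {}
    for mark in config.marks:
        per_sample = {}
        for sid in config.samples:
            frags = extend_reads(dedup_by[(mark, sid)], params["fragment_length"], chrom_sizes)
            track = build_coverage(frags, chrom_sizes)
            track = smooth(normalize_per_million(track), params["smooth_window"])
            per_sample[sid] = track
        sids = list(per_sample)
        normed = quantile_normalize(
            [per_sample[s] for s in sids], ties=params["quantile_ties"]
        )
        tracks_by_mark[mark] = dict(zip(sids, normed))
        if params["write_coverage"]:
            for sid, track in tracks_by_mark[mark].items():
                write_bedgraph(track, out / "coverage" / f"{mark}_{sid}.bedgraph")
        prof = meta_profile(tracks_by_mark[mark], tss_sites, params["flank"], params["bin"])
        df = prof.to_frame()
        for g in ("patient", "control"):
            cols = [s for s in config.samples if config.samples[s] == g]
            df[f"mean_{g}"] = df[cols].mean(axis=1)
        df.to_csv(out / "coverage" / f"profile_{mark}.tsv", sep="\t", index=False)
        logger.info("coverage: %s done (%d samples)", mark, len(sids))
    report.record("coverage", profiles=len(config.marks))

    # ---- stage 3: promoter counts ---------------------------------------
    windows = promoter_windows(
        genes, chrom_sizes, params["upstream"], params["downstream"]
    )
    gene_ids = [w.gene_id for w in windows]
    matrices = {}
    for mark in config.marks:
        per_sample_counts = {}
        for sid in config.samples:
            source = dedup_by[(mark, sid)]
            if params["counting_mode"] == "fragment_overlap":
                source = extend_reads(source, params["fragment_length"], chrom_sizes)
            per_sample_counts[sid] = count_reads_in_windows(
                source, windows, params["counting_mode"]
            )
        mat = assemble_count_matrix(per_sample_counts, gene_ids, mark, config.samples)
        mat.to_tsv(
            out / "counts" / f"counts_{mark}.tsv", out / "counts" / "samples.tsv"
        )
        matrices[mark] = mat
    report.record("counts", promoters=len(windows))

    # ---- stage 4: differential ------------------------------------------
    tables = {}
    factors_by_mark = {}
    for mark in config.marks:
        factors_by_mark[mark] = size_factors(matrices[mark].counts)
        tables[mark] = differential_table(
            matrices[mark], pseudocount=params["pseudocount"], factors=factors_by_mark[mark]
        )
        tables[mark].to_csv(out / "diff" / f"diff_{mark}.tsv", sep="\t")
    call = select_significant(
        tables, params["lfc_threshold"], params["p_threshold"]
    )
    call.table.to_csv(out / "diff" / "significance.tsv", sep="\t")
    selected = call.selected_genes
    report.record("differential", genes_selected=len(selected))
    logger.info("differential: %d genes selected", len(selected))

    # ---- stage 5: clustering --------------------------------------------
    if len(selected) >= 2:
        fc = pd.DataFrame(
            {m: tables[m].loc[selected, "log2FC"] for m in config.marks}
        )
        dendro = hier_cluster(fc.to_numpy())
        k = min(params["k"], len(selected))
        assignment = cut_clusters(dendro, k, index=fc.index)
        summary = cluster_summary(
            fc, assignment, magnitude_threshold=params["phenotype_threshold"]
        )
        dendro.to_frame().to_csv(out / "clusters" / "merges.tsv", sep="\t", index=False)
        assigned = assignment.labels.to_frame()
        assigned["phenotype"] = summary.loc[assignment.labels, "phenotype"].to_numpy()
        assigned.to_csv(out / "clusters" / "assignments.tsv", sep="\t")
        summary.to_csv(out / "clusters" / "summary.tsv", sep="\t")
        heat = {}
        for mark in config.marks:
            z = zscale_counts(matrices[mark], factors_by_mark[mark]).loc[selected]
            ga = group_average(z, config.samples)
            heat[f"{mark}_patient"] = ga["patient"]
            heat[f"{mark}_control"] = ga["control"]
        pd.DataFrame(heat).to_csv(out / "clusters" / "heatmap_zscores.tsv", sep="\t")
        for cid in range(1, k + 1):
            members = assignment.members(cid)
            for mark in config.marks:
                prof = cluster_meta_profiles(
                    members, tracks_by_mark[mark], tss_by_gene, config.samples,
                    params["flank"], params["bin"],
                )
                prof.to_frame().to_csv(
                    out / "clusters" / f"profile_cluster{cid}_{mark}.tsv",
                    sep="\t", index=False,
                )
        report.record(
            "clustering",
            k=k,
            sizes=assignment.sizes().to_dict(),
            phenotypes=summary["phenotype"].to_dict(),
        )
    else:
        assignment = None
        summary = None
        report.record("clustering", skipped=f"only {len(selected)} genes selected")

    # ---- stage 6: enrichment + group comparison --------------------------
    if gene_sets and assignment is not None:
        universe = gene_ids
        top = {}
        for cid in range(1, assignment.k + 1):
            enr = hypergeom_enrichment(assignment.members(cid), gene_sets, universe)
            enr.to_csv(out / "enrichment" / f"enrichment_cluster{cid}.tsv", sep="\t")
            if len(enr):
                top[cid] = f"{enr.index[0]} (p={enr['pval'].iloc[0]:.3g})"
        report.record("enrichment", top_per_cluster=top)
    if gene_sets and params["comparison_set"]:
        gs = gene_sets[params["comparison_set"]]
        rows = []
        for mark in config.marks:
            lfc = tables[mark]["log2FC"]
            in_group = lfc.index.isin(gs.genes)
            res = mannwhitney_compare(lfc[in_group], lfc)
            rows.append({"mark": mark, "test": res.test, "U": res.statistic,
                         "pval": res.pvalue, "n_group": res.n_group,
                         "median_group": res.median_group,
                         "median_background": res.median_background})
        pd.DataFrame(rows).to_csv(
            out / "enrichment" / "group_comparison.tsv", sep="\t", index=False
        )
        report.record("group_comparison", set=params["comparison_set"])

    report.write(out / "report")
    logger.info("pipeline complete: %s", out)
    return report
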