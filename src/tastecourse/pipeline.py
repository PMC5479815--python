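"""End-to-end pipeline: simulate/load -> RPKM -> trim -> cluster -> consensus
-> differential testing -> enrichment, with a reproducibility manifest.

A single root seed expands to per-stage seeds through a named derivation
(:func:`derive_seed`), so one integer reproduces the whole run.  The manifest
records the config hash, derived seeds, and the gene-count funnel
(n_input -> n_trimmed -> cluster sizes -> consensus sizes -> n_significant);
re-running with the same config produces a byte-identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cluster import cluster_stages, kmeans_cluster, label_archetypes, two_branch_split
from .consensus import intersect_clusters, match_clusters
from .containers import StageMatrix
from .diffexp import de_test
from .enrich import GeneSetCollection, enrich
from .errors import ConfigError
from .quantify import compute_rpkm, log_normalize, log_transform, trim_genes
from .simulate import SimConfig, default_archetypes, generate_dataset


def derive_seed(root_seed: int, stage: str) -> int:
    """Stage seed = sha256("<root>:<stage>") reduced below 2**31."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    """All parameters of a pipeline run.

    Either ``sim`` is set (synthetic inputs are generated with the stage seed
    derived from ``seed``) or ``counts_a``/``counts_b`` point at TSV count
    matrices.  ``gmt`` optionally names a gene-set file for enrichment; a
    simulated run uses its planted categories when ``gmt`` is absent.
    """

    outdir: str = "run"
    seed: int = 0
    sim: SimConfig | None = field(default_factory=SimConfig)
    counts_a: str | None = None
    counts_b: str | None = None
    gmt: str | None = None
    day14_min: float = 0.2
    sum_min: float = 0.2
    day14_on: str = "A"
    sum_on: str = "B"
    normalize_mode: str = "subtract_log_mean"
    k: int = 4
    n_starts: int = 30
    max_iter: int = 30000
    linkage_metric: str = "euclidean"
    linkage_method: str = "complete"
    alpha: float = 0.05
    dispersion_mode: str = "shrunk"
    prior_weight: float = 10.0
    min_category: int = 2
    ease: bool = False

    def __post_init__(self) -> None:
        if self.sim is None and (self.counts_a is None or self.counts_b is None):
            raise ConfigError("provide either a sim config or two count paths")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", "default")
        if sim_raw is None:
            sim = None
        elif sim_raw == "default":
            sim = SimConfig()
        else:
            from .simulate import ArchetypeSpec, PlantedCategory

            arch = sim_raw.pop("archetypes", None)
            if arch is not None:
                sim_raw["archetypes"] = tuple(
                    ArchetypeSpec(a["name"], tuple(a["template"]), a["fraction"])
                    for a in arch
                )
            pc = sim_raw.pop("planted_category", "default")
            if pc is None:
                sim_raw["planted_category"] = None
            elif pc != "default":
                sim_raw["planted_category"] = PlantedCategory(**pc)
            for key in ("library_sizes", "gene_length_range", "decoy_size_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = SimConfig(**sim_raw)
        return cls(sim=sim, **raw)


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    filter_report: object
    models: tuple
    consensus: object
    de: object
    charts: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages in order, persisting artifacts under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "tastecourse",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {},
    }

    # --- inputs ------------------------------------------------------------
    collection = None
    if config.sim is not None:
        sim = dataclasses.replace(config.sim,
                                  seed=derive_seed(config.seed, "simulate"))
        manifest["stage_seeds"]["simulate"] = sim.seed
        counts_a, counts_b, truth, collection = generate_dataset(sim)
        truth.to_tsv(outdir / "truth.tsv")
    else:
        counts_a = StageMatrix.from_tsv(config.counts_a)
        counts_b = StageMatrix.from_tsv(config.counts_b)
    if config.gmt is not None:
        collection = GeneSetCollection.from_gmt(config.gmt)
    manifest["n_input"] = counts_a.n_genes

    # --- quantify + trim ----------------------------------------------------
    rpkm_a, rpkm_b = compute_rpkm(counts_a), compute_rpkm(counts_b)
    report = trim_genes(rpkm_a, rpkm_b, config.day14_min, config.sum_min,
                        config.day14_on, config.sum_on)
    report.to_json(outdir / "filter_report.json")
    report.to_tsv(outdir / "kept_genes.tsv")
    manifest["n_trimmed"] = report.n_kept
    rpkm_a, rpkm_b = report.apply(rpkm_a), report.apply(rpkm_b)
    counts_a, counts_b = report.apply(counts_a), report.apply(counts_b)

    # --- temporal clustering -------------------------------------------------
    templates = default_archetypes()
    models = []
    for name, rpkm in (("A", rpkm_a), ("B", rpkm_b)):
        seed = derive_seed(config.seed, f"kmeans_{name}")
        manifest["stage_seeds"][f"kmeans_{name}"] = seed
        norm = log_normalize(rpkm, mode=config.normalize_mode)
        model = kmeans_cluster(norm, k=config.k, n_starts=config.n_starts,
                               max_iter=config.max_iter, seed=seed)
        if config.k == len(templates):
            label_archetypes(model, templates)
        model.to_tsv(outdir / f"clusters_{name}.tsv")
        model.to_json(outdir / f"clusters_{name}.json")
        models.append(model)

        dend = cluster_stages(log_transform(rpkm),
                              metric=config.linkage_metric,
                              method=config.linkage_method)
        (outdir / f"stages_{name}.nwk").write_text(dend.to_newick() + "\n")
        early, late = two_branch_split(dend)
        manifest[f"stage_two_branch_{name}"] = [sorted(early), sorted(late)]
    model_a, model_b = models
    manifest["cluster_sizes_A"] = {str(c): v for c, v in model_a.sizes().items()}
    manifest["cluster_sizes_B"] = {str(c): v for c, v in model_b.sizes().items()}

    # --- consensus ------------------------------------------------------------
    mapping = match_clusters(model_a, model_b)
    cons = intersect_clusters(model_a, model_b, mapping)
    cons.to_json(outdir / "consensus.json")
    cons.write_gene_lists(outdir / "consensus")
    manifest["consensus_sizes"] = cons.sizes

    # --- differential expression ----------------------------------------------
    de = de_test(counts_a, counts_b, dispersion_mode=config.dispersion_mode,
                 alpha=config.alpha, prior_weight=config.prior_weight)
    de.to_tsv(outdir / "de_table.tsv")
    manifest["n_significant"] = de.n_significant
    manifest["n_nonconverged"] = de.n_nonconverged

    # --- enrichment -------------------------------------------------------------
    charts = {}
    if collection is not None:
        background = collection.restricted(set(report.kept_ids))
        queries = {"combined_up": cons.combined_up_set}
        if model_a.archetype_labels:
            c1 = model_a.cluster_of_archetype("late_rise")
            queries["cluster1"] = cons.shared_sets[c1]
        for name, query in queries.items():
            if not query:
                continue
            chart = enrich(query, background, min_category=config.min_category,
                           ease=config.ease)
            chart.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
            charts[name] = chart
            manifest[f"enrichment_top_{name}"] = str(chart.iloc[0]["term"])

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(outdir=outdir, manifest=manifest, filter_report=report,
                     models=(model_a, model_b), consensus=cons, de=de,
                     charts=charts)
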