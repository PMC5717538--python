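"""End-to-end orchestration: one config drives preprocessing, DGA scoring,
similarity clustering, network-module and functional-module activity,
association statistics, and drug integration, with deterministic seeding
and a content-hash manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import drugs as drug_mod
from . import functional as fm_mod
from . import network as net_mod
from . import preprocessing as prep
from . import similarity as sim
from . import stats as assoc
from .dga import DGAMatrix, RegTParams, dga_matrix
from .synthetic import (
    SyntheticConfig,
    generate_annotations,
    generate_compendium,
    generate_network,
    write_edge_list,
)

log = logging.getLogger("myonet")

#: Stage order used for child-seed derivation: child = (seed * 1000 + index) % 2**31
STAGES = ("simulate", "permutation", "mcl")


def stage_seed(seed: int, stage: str) -> int:
    return (int(seed) * 1000 + STAGES.index(stage)) % 2**31


@dataclass
class PipelineConfig:
    """Single source of truth for a run: data location + parameters.

    Exactly one of ``synthetic`` (a :class:`SyntheticConfig` or its dict)
    and ``paths`` (expression/sample-sheet/edge-list/GMT/disease-gene/drug
    files) must be given.
    """

    synthetic: SyntheticConfig | None = None
    paths: dict | None = None
    alpha: float = 0.05
    n_perm: int = 100
    seed: int = 0
    reg_t: RegTParams = field(default_factory=RegTParams)
    mcl: net_mod.MCLParams = field(default_factory=net_mod.MCLParams)
    score_threshold: float = 0.85
    min_module_size: int = 3

    def __post_init__(self):
        if (self.synthetic is None) == (self.paths is None):
            raise ValueError("exactly one of {synthetic, paths} must be configured")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        if isinstance(self.reg_t, dict):
            self.reg_t = RegTParams(**self.reg_t)
        if isinstance(self.mcl, dict):
            self.mcl = net_mod.MCLParams(**self.mcl)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class PipelineResult:
    """Bundle of every stage's output plus the run manifest."""

    universe: list
    dga: DGAMatrix
    similarity: sim.SimilarityResult
    modules: net_mod.ModuleSet
    pma: net_mod.ActivityMatrix
    stage1_modules: list
    signature_modules: list
    expression_threshold: float
    fma: net_mod.ActivityMatrix | None
    shared_fm_reports: dict
    overlap_table: object | None
    concordance: assoc.ConcordanceTable | None
    fisher_p: float | None
    druggable: tuple | None
    cluster_modules: dict
    unique_modules: dict
    shared_all_modules: set
    cluster_drugs: dict
    truth: object | None
    manifest: dict


def _fmt(x: float) -> str:
    return f"{float(x):.12g}"


def _hash_matrix(m: np.ndarray) -> str:
    payload = ";".join(_fmt(v) for v in np.asarray(m, dtype=float).ravel())
    return hashlib.sha256(payload.encode()).hexdigest()


def _load_real_inputs(paths: dict, tmpdir=None):
    studies = []
    for entry in paths["studies"]:
        s = prep.load_study(entry["expression"], entry["samples"], entry.get("disease"))
        studies.append(s)
    return studies


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute all stages in order and return the result bundle.

    Stage order: preprocessing -> DGA -> similarity -> protein modules ->
    functional modules -> association statistics -> drugs.  A single run
    seed fans out to per-stage child seeds (documented counter scheme), so
    identical configs produce identical manifests.
    """
    t0 = time.time()
    truth = None
    if config.synthetic is not None:
        import dataclasses

        syn = dataclasses.replace(config.synthetic, seed=stage_seed(config.seed, "simulate"))
        log.info("simulate: %d diseases, %d genes", syn.n_diseases, syn.n_genes)
        studies, truth = generate_compendium(syn)
        edges = generate_network(syn, truth)
        disease_lists, fm_sets, drug_rows = generate_annotations(syn, truth)
        fms = fm_mod.FunctionalModuleSet(
            modules=fm_sets, families={k: "synthetic" for k in fm_sets}
        )
        drug_map = drug_mod.DrugGeneMap(
            targets={d: t for d, t, _ in drug_rows},
            approved={d: a for d, _, a in drug_rows},
        )
        network = _network_from_edges(edges, config.score_threshold)
    else:
        studies = _load_real_inputs(config.paths)
        network = net_mod.load_edges(config.paths["edges"], config.score_threshold)
        fms = fm_mod.load_gene_sets(config.paths["gmt"]) if "gmt" in config.paths else None
        disease_lists = _read_disease_lists(config.paths.get("disease_genes"))
        drug_map = (
            drug_mod.read_drug_table(config.paths["drugs"]) if "drugs" in config.paths else None
        )

    # preprocessing: per-disease batch merge, z-transform, common universe
    merged = []
    by_disease: dict = {}
    for s in studies:
        by_disease.setdefault(s.disease_id, []).append(s)
    for did in sorted(by_disease):
        merged.append(prep.ztransform(prep.merge_batches(by_disease[did])))
    universe, merged = prep.intersect_genes(merged)
    log.info("preprocessing: %d diseases on %d genes", len(merged), len(universe))

    # DGA + permutation sweep (one pass feeds pcor, PMA and FMA nulls)
    dga = dga_matrix(merged, config.reg_t)
    modules = net_mod.mcl_cluster(network, config.mcl)
    modules = net_mod.filter_modules(modules, config.min_module_size, universe)
    log.info(
        "modules: %d -> %d after min-size filter", modules.report["original"],
        modules.report["surviving"],
    )
    perm_seed = stage_seed(config.seed, "permutation")
    pcor_null = sim.permutation_null(
        merged, config.reg_t, config.n_perm, perm_seed, sim.STAT_PCOR
    )
    pma_null = sim.permutation_null(
        merged, config.reg_t, config.n_perm, perm_seed, sim.STAT_MODULE, modules=modules
    )
    similarity = sim.similarity_analysis(
        merged, config.reg_t, config.n_perm, perm_seed, config.alpha,
        dga=dga, null_store=pcor_null,
    )
    log.info("similarity: cut height %.4f", similarity.cut_height)

    pma = net_mod.module_activity(modules, dga, pma_null)
    stage1, signature, threshold = net_mod.signature_modules(pma, config.alpha)

    fma = None
    shared_reports: dict = {}
    if fms is not None and len(fms):
        fm_universe = {
            k: v & set(universe) for k, v in fms.modules.items() if v & set(universe)
        }
        fm_set = net_mod.ModuleSet(modules=fm_universe, provenance="gmt")
        fma_null = sim.permutation_null(
            merged, config.reg_t, config.n_perm, perm_seed, sim.STAT_MODULE, modules=fm_set
        )
        fma = net_mod.module_activity(fm_set, dga, fma_null)
        for a, b, _, _ in similarity.significant_pairs():
            shared_reports[(a, b)] = fm_mod.shared_fms((a, b), fma, config.alpha)

    overlap_table = concordance = fisher_p = None
    if disease_lists:
        listed = set().union(*disease_lists.values())
        gl_universe = listed | set(universe)
        lists = assoc.DiseaseGeneLists(lists=disease_lists, universe=gl_universe)
        overlap_table, gene_sig = assoc.pairwise_overlap_table(lists, config.alpha)
        from itertools import combinations

        all_pairs = set(combinations(sorted(disease_lists), 2))
        expr_sig = {
            tuple(sorted((a, b))) for a, b, _, _ in similarity.significant_pairs()
        } & all_pairs
        concordance = assoc.concordance_from_pairs(all_pairs, gene_sig, expr_sig)
        fisher_p = assoc.fisher_concordance(concordance)
        log.info("association: fisher p = %.4g", fisher_p)

    druggable = None
    cluster_drugs: dict = {}
    unique_mods: dict = {}
    shared_all: set = set()
    cluster_mods: dict = {}
    if drug_map is not None:
        sig_genes = set()
        for m in signature:
            sig_genes |= modules.modules[m]
        if sig_genes:
            druggable = drug_mod.druggable_overrep(
                sig_genes, drug_map.druggable_genes & set(universe), set(universe)
            )
        members: dict = {}
        for d, c in similarity.clusters.items():
            if c != 0:
                members.setdefault(c, []).append(d)
        if len(members) >= 2:
            cluster_mods = drug_mod.cluster_associated_modules(pma, members, config.alpha)
            unique_mods, shared_all = drug_mod.cluster_unique_modules(cluster_mods)
            for c, mods in unique_mods.items():
                subset = net_mod.ModuleSet(
                    modules={m: modules.modules[m] for m in mods}, provenance="mcl"
                )
                cluster_drugs[c] = drug_mod.drugs_for_modules(subset, drug_map)

    manifest = {
        "seed": config.seed,
        "alpha": config.alpha,
        "n_perm": config.n_perm,
        "elapsed_s": round(time.time() - t0, 2),
        "n_diseases": len(merged),
        "n_genes": len(universe),
        "hashes": {
            "dga": _hash_matrix(dga.scores),
            "pcor": _hash_matrix(similarity.pcor),
            "pvals": _hash_matrix(similarity.pvals),
            "pma": _hash_matrix(pma.activity),
        },
        "clusters": {d: c for d, c in sorted(similarity.clusters.items())},
        "signature_modules": signature,
    }
    result = PipelineResult(
        universe=universe,
        dga=dga,
        similarity=similarity,
        modules=modules,
        pma=pma,
        stage1_modules=stage1,
        signature_modules=signature,
        expression_threshold=threshold,
        fma=fma,
        shared_fm_reports=shared_reports,
        overlap_table=overlap_table,
        concordance=concordance,
        fisher_p=fisher_p,
        druggable=druggable,
        cluster_modules=cluster_mods,
        unique_modules=unique_mods,
        shared_all_modules=shared_all,
        cluster_drugs=cluster_drugs,
        truth=truth,
        manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _network_from_edges(edges: list, threshold: float) -> net_mod.ProteinNetwork:
    best: dict = {}
    for a, b, s in edges:
        if a == b or s <= threshold:
            continue
        key = (a, b) if a < b else (b, a)
        best[key] = max(best.get(key, -1.0), s)
    if not best:
        raise ValueError("no synthetic edge passes the score threshold")
    kept = [(a, b, s) for (a, b), s in sorted(best.items())]
    nodes = sorted({n for a, b, _ in kept for n in (a, b)})
    return net_mod.ProteinNetwork(nodes=nodes, edges=kept)


def _read_disease_lists(path):
    if path is None:
        return None
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict = {}
    for row in df.itertuples():
        out.setdefault(row.disease, set()).add(row.gene)
    return out


def write_outputs(result: PipelineResult, outdir) -> dict:
    """Write all tabular outputs (TSV/JSON) and return path -> sha256."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = result.similarity.disease_ids
    written = {}

    def save_frame(frame, name):
        p = outdir / name
        frame.to_csv(p, sep="\t", float_format="%.12g")
        written[name] = hashlib.sha256(p.read_bytes()).hexdigest()

    save_frame(result.dga.to_frame(), "dga.tsv")
    save_frame(pd.DataFrame(result.similarity.pcor, index=d, columns=d), "pcor.tsv")
    save_frame(pd.DataFrame(result.similarity.pvals, index=d, columns=d), "pair_pvals.tsv")
    save_frame(result.pma.to_frame("activity"), "pma.tsv")
    save_frame(result.pma.to_frame("pvals"), "pma_pvals.tsv")
    if result.fma is not None:
        save_frame(result.fma.to_frame("activity"), "fma.tsv")
        save_frame(result.fma.to_frame("pvals"), "fma_pvals.tsv")
    if result.overlap_table is not None:
        p = outdir / "disease_gene_overlap.tsv"
        result.overlap_table.to_csv(p, sep="\t", index=False, float_format="%.12g")
        written[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    linkage_payload = {
        "diseases": d,
        "merges": [
            {"left": int(a), "right": int(b), "height": float(_fmt(h)), "size": int(s)}
            for a, b, h, s in result.similarity.linkage
        ],
        "cut_height": float(_fmt(result.similarity.cut_height)),
        "clusters": result.similarity.clusters,
    }
    (outdir / "linkage.json").write_text(json.dumps(linkage_payload, indent=1))
    net_mod.write_gmt(result.modules, outdir / "modules.gmt")
    (outdir / "signature.json").write_text(
        json.dumps(
            {
                "stage1": result.stage1_modules,
                "signature": result.signature_modules,
                "expression_threshold": None
                if np.isnan(result.expression_threshold)
                else float(_fmt(result.expression_threshold)),
            },
            indent=1,
        )
    )
    export_networks(result, outdir, fmt="sif")
    export_networks(result, outdir, fmt="graphml")
    for extra in ("linkage.json", "signature.json", "modules.gmt"):
        written[extra] = hashlib.sha256((outdir / extra).read_bytes()).hexdigest()
    manifest = dict(result.manifest)
    manifest["files"] = written
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return written


def export_networks(result: PipelineResult, outdir, fmt: str = "sif") -> list:
    """Export the disease-similarity graph for network viewers.

    Nodes are diseases; edges are the significant pairs with the partial
    correlation as attribute.  SIF is one edge per line
    (``a similar_to b``); GraphML goes through networkx and round-trips to
    the identical edge set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = result.similarity.significant_pairs()
    paths = []
    if fmt == "sif":
        p = outdir / "disease_similarity.sif"
        with open(p, "w") as fh:
            for a, b, _, _ in pairs:
                fh.write(f"{a}\tsimilar_to\t{b}\n")
        paths.append(p)
    elif fmt == "graphml":
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(result.similarity.disease_ids)
        for a, b, pc, pv in pairs:
            g.add_edge(a, b, pcor=pc, pval=pv)
        p = outdir / "disease_similarity.graphml"
        nx.write_graphml(g, p)
        paths.append(p)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return paths
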