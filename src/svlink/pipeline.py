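"""End-to-end orchestration: simulate -> merge -> filter -> FST ->
annotate -> bulk DE -> single-cell -> integration, with a JSON run
report.  All stage outputs land under one run directory with fixed
names; a run is reproducible from its echoed config and seed alone."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import replace

import numpy as np
import pandas as pd

from . import __version__, annotate as ann, bulk_de, integrate, popgen, sc, simulate, sv_io
from .config import PipelineConfig

logger = logging.getLogger(__name__)

SPECIES_A = "speciesA"
SPECIES_B = "speciesB"


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def _add_ratio_tests(enrich: pd.DataFrame, markers: pd.DataFrame,
                     gene_lists: dict[str, set]) -> pd.DataFrame:
    """Append one-vs-rest Welch t columns to an enrichment table."""
    t_vals, p_vals = [], []
    for _, row in enrich.iterrows():
        try:
            res = integrate.one_vs_rest_ratio_test(
                markers, gene_lists[row["list"]], row["cluster_id"]
            )
            t_vals.append(res.t)
            p_vals.append(res.p)
        except ValueError:
            t_vals.append(np.nan)
            p_vals.append(np.nan)
    out = enrich.copy()
    out["ovr_t"] = t_vals
    out["ovr_p"] = p_vals
    return out


def simulate_inputs(config: PipelineConfig, outdir: str) -> dict:
    """Generate and serialize every synthetic input; returns artifacts."""
    simdir = os.path.join(outdir, "inputs")
    os.makedirs(simdir, exist_ok=True)
    models_a = simulate.make_gene_models(config.sim, prefix="GA")
    models_b = simulate.make_gene_models(config.sim, prefix="GB")
    ortho = simulate.make_ortholog_map(
        models_a, models_b, config.ortholog_fraction_shared, seed=config.seed
    )
    sc_a = simulate.simulate_sc_counts(
        models_a, config.sim, SPECIES_A,
        add_specific_cluster=config.sim.species_specific_cluster,
    )
    sc_b = simulate.simulate_sc_counts(
        models_b, config.sim, SPECIES_B, add_specific_cluster=False,
    )
    favored = sc_a.marker_assignment.get(0, [])
    cohort = simulate.simulate_sv_cohort(models_a, config.sim, favored_gene_ids=favored)
    bulk = simulate.simulate_bulk_counts(models_a, config.sim)

    ann.write_gff3(models_a, os.path.join(simdir, "genes_a.gff3"))
    ann.write_gff3(models_b, os.path.join(simdir, "genes_b.gff3"))
    sv_io.write_population_map(cohort.popmap, os.path.join(simdir, "popmap.tsv"))
    vcf_paths = []
    for sample, records in cohort.callsets.items():
        path = os.path.join(simdir, f"{sample}.vcf")
        sv_io.write_sv_vcf(records, path, sample_ids=[sample])
        vcf_paths.append(path)
    simulate.write_counts_tsv(bulk.counts, os.path.join(simdir, "bulk_counts.tsv"))
    simulate.write_group_map(bulk.groups, os.path.join(simdir, "bulk_groups.tsv"))
    sc_a.matrix.to_mtx_dir(os.path.join(simdir, "sc_a"))
    sc_b.matrix.to_mtx_dir(os.path.join(simdir, "sc_b"))
    simulate.write_ortholog_tsv(ortho, os.path.join(simdir, "orthologs.tsv"))

    truth = cohort.truth
    truth.de_gene_ids = bulk.truth_de
    truth.marker_assignment = {str(k): v for k, v in sc_a.marker_assignment.items()}
    if sc_a.species_specific_cluster_id is not None:
        truth.species_specific_cluster_id = str(sc_a.species_specific_cluster_id)
    truth.to_json(os.path.join(simdir, "truth.json"))
    return {
        "models_a": models_a, "models_b": models_b, "ortho": ortho,
        "sc_a": sc_a, "sc_b": sc_b, "cohort": cohort, "bulk": bulk,
        "vcf_paths": sorted(vcf_paths), "truth": truth,
    }


def run_pipeline(config: PipelineConfig, outdir: str, synthetic: bool = True,
                 inputs: dict | None = None) -> dict:
    """Execute every stage and write the report bundle.

    With ``synthetic=True`` all inputs are generated under
    ``outdir/inputs`` first.  Otherwise ``inputs`` must supply paths:
    ``sample_vcfs``, ``popmap``, ``gff3``, ``bulk_counts``,
    ``bulk_groups``, ``sc_a_dir``, ``sc_b_dir``, ``orthologs``.
    Returns the run report dictionary (also written as report.json).
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    counts: dict[str, int] = {}

    if synthetic:
        art = simulate_inputs(config, outdir)
        models = art["models_a"]
        ortho = art["ortho"]
        callsets = [sv_io.read_sv_vcf(p) for p in art["vcf_paths"]]
        popmap = art["cohort"].popmap
        bulk_counts, bulk_groups = art["bulk"].counts, art["bulk"].groups
        cm_a, cm_b = art["sc_a"].matrix, art["sc_b"].matrix
    else:
        if inputs is None:
            raise ValueError("inputs required when synthetic=False")
        models = ann.read_gff3(inputs["gff3"], config.annotate.promoter_bp,
                               config.annotate.flank_bp)
        ortho = simulate.read_ortholog_tsv(inputs["orthologs"])
        callsets = [sv_io.read_sv_vcf(p) for p in sorted(inputs["sample_vcfs"])]
        popmap = sv_io.read_population_map(inputs["popmap"])
        bulk_counts = pd.read_csv(inputs["bulk_counts"], sep="\t", index_col=0)
        bulk_groups = sv_io.read_population_map(inputs["bulk_groups"])
        cm_a = sc.CellMatrix.from_mtx_dir(inputs["sc_a_dir"], SPECIES_A)
        cm_b = sc.CellMatrix.from_mtx_dir(inputs["sc_b_dir"], SPECIES_B)

    # --- SV merge + filter -------------------------------------------------
    samples = sorted({s for cs in callsets for s in cs.sample_ids})
    merged = sv_io.merge_callsets(
        callsets, config.merge.max_dist_bp,
        config.merge.require_type_match, config.merge.min_support,
    )
    sv_io.write_sv_vcf(merged, os.path.join(outdir, "merged.vcf"), sample_ids=samples)
    matrix = sv_io.to_genotype_matrix(merged, samples)
    filtered = sv_io.filter_callset(
        matrix, config.filter.max_missing, config.filter.mac, config.filter.min_qual
    )
    assert filtered.records is not None
    sv_io.write_sv_vcf(filtered.records, os.path.join(outdir, "filtered.vcf"), sample_ids=samples)
    counts["sv_merged"] = matrix.n_sv
    counts["sv_filtered"] = filtered.n_sv

    # --- FST + candidate selection ----------------------------------------
    fst_results = popgen.fst_per_sv(filtered, popmap, config.fst.estimator)
    selected = popgen.select_top_fraction(fst_results, config.fst.top_fraction)
    popgen.fst_table(filtered, fst_results, selected).to_csv(
        os.path.join(outdir, "fst.tsv"), sep="\t", index=False
    )
    counts["sv_high_fst"] = len(selected)

    # --- region annotation + gene lists -----------------------------------
    annotations = ann.classify_all(
        filtered.records, models, config.annotate.promoter_bp, config.annotate.flank_bp
    )
    ann.annotations_to_frame(annotations).to_csv(
        os.path.join(outdir, "annotation.tsv"), sep="\t", index=False
    )
    lists = ann.gene_category_lists(annotations, selected)
    _write_json({k: sorted(v) for k, v in lists.items()},
                os.path.join(outdir, "gene_lists.json"))
    counts["genes_list1"] = len(lists["list1"])
    counts["genes_list2"] = len(lists["list2"])

    # --- bulk DE -----------------------------------------------------------
    de_res = bulk_de.de_test(bulk_counts, bulk_groups, config.de.alpha, config.de.min_abs_lfc)
    de_res.to_csv(os.path.join(outdir, "de_results.tsv"), sep="\t", index_label="gene_id")
    degs = set(de_res.index[de_res["is_deg"]])
    counts["degs"] = len(degs)

    universe = set(ortho["gene_a"])
    assoc_payload: dict = {}
    try:
        assoc = integrate.chi_square_association(
            universe, degs & universe, lists["list1"] & universe
        )
        assoc_payload = {
            "chi2": assoc.chi2, "df": assoc.df, "p": assoc.p,
            "table": assoc.table.tolist(),
        }
    except ValueError as exc:
        assoc_payload = {"error": str(exc)}
    _write_json(assoc_payload, os.path.join(outdir, "association.json"))
    _write_json(
        integrate.venn_counts(lists["list1"], lists["list2"], degs),
        os.path.join(outdir, "venn.json"),
    )

    # --- single-cell -------------------------------------------------------
    qc_a = sc.qc_filter(cm_a, config.sc.min_genes_a, config.sc.max_mito)
    qc_b = sc.qc_filter(cm_b, config.sc.min_genes_b, config.sc.max_mito)
    counts["cells_a"], counts["cells_b"] = qc_a.n_cells, qc_b.n_cells
    norm_a, norm_b = sc.lognormalize(qc_a), sc.lognormalize(qc_b)
    labels_a = sc.cluster_cells(norm_a, config.sc.n_pcs, config.sc.resolution,
                                config.seed, config.sc.k_neighbors)
    labels_b = sc.cluster_cells(norm_b, config.sc.n_pcs, config.sc.resolution,
                                config.seed, config.sc.k_neighbors)
    for name, norm, labels in (("a", norm_a, labels_a), ("b", norm_b, labels_b)):
        pd.DataFrame({"cell_id": norm.cell_ids, "cluster": labels}).to_csv(
            os.path.join(outdir, f"sc_labels_{name}.tsv"), sep="\t", index=False
        )
    markers_a = sc.find_markers(norm_a, labels_a)
    markers_b = sc.find_markers(norm_b, labels_b)
    markers_a.to_csv(os.path.join(outdir, "markers_a.tsv"), sep="\t", index=False)
    markers_b.to_csv(os.path.join(outdir, "markers_b.tsv"), sep="\t", index=False)
    counts["clusters_a"] = int(len(np.unique(labels_a)))
    counts["clusters_b"] = int(len(np.unique(labels_b)))

    prof_a = sc.cluster_profiles(norm_a, labels_a)
    prof_b = sc.cluster_profiles(norm_b, labels_b)
    rmat, novelty = sc.cross_species_correlation(
        prof_a, prof_b, ortho, config.sc.novel_r_threshold
    )
    rmat.to_csv(os.path.join(outdir, "correlation.tsv"), sep="\t", index_label="cluster_a")
    novelty.to_csv(os.path.join(outdir, "novelty.tsv"), sep="\t", index=False)
    counts["novel_clusters_a"] = int(novelty["novel"].sum())

    joint = sc.joint_cluster(
        qc_a, qc_b, ortho, config.sc.joint_n_pcs, config.sc.joint_resolution,
        config.seed, config.sc.k_neighbors,
    )
    pd.DataFrame({"cell_id": joint.labels.index, "cluster": joint.labels.to_numpy(),
                  "species": joint.species.to_numpy()}).to_csv(
        os.path.join(outdir, "joint_labels.tsv"), sep="\t", index=False
    )
    joint.composition.to_csv(os.path.join(outdir, "composition.tsv"), sep="\t",
                             index_label="cluster")
    counts["clusters_joint"] = int(joint.composition.shape[0])

    # --- integration (per-cluster enrichment) ------------------------------
    gene_lists_a = {
        "SVgene": lists["list1"] & universe,
        "DEG": degs & universe,
        "SVDEG": (lists["list1"] & degs) & universe,
    }
    a2b = dict(zip(ortho["gene_a"], ortho["gene_b"]))
    universe_b = set(ortho["gene_b"])
    gene_lists_b = {
        name: {a2b[g] for g in genes if g in a2b} for name, genes in gene_lists_a.items()
    }
    enrich_a = _add_ratio_tests(
        integrate.marker_enrichment(markers_a, gene_lists_a, universe),
        markers_a, gene_lists_a,
    )
    enrich_b = _add_ratio_tests(
        integrate.marker_enrichment(markers_b, gene_lists_b, universe_b),
        markers_b, gene_lists_b,
    )
    enrich_a.to_csv(os.path.join(outdir, "enrichment_a.tsv"), sep="\t", index=False)
    enrich_b.to_csv(os.path.join(outdir, "enrichment_b.tsv"), sep="\t", index=False)

    # --- report ------------------------------------------------------------
    import scipy
    import sklearn

    report = {
        "svlink_version": __version__,
        "versions": {
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "sklearn": sklearn.__version__,
        },
        "seed": config.seed,
        "synthetic": synthetic,
        "config": config.to_dict(),
        "row_counts": counts,
    }
    _write_json(report, os.path.join(outdir, "report.json"))
    return report
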