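import hashlib
import json

import numpy as np
import pytest

from svlink import sv_io
from svlink.annotate import write_gff3
from svlink.simulate import (
    SimConfig,
    make_gene_models,
    make_ortholog_map,
    simulate_bulk_counts,
    simulate_sc_counts,
    simulate_sv_cohort,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_sv=-1).validate()
    with pytest.raises(ValueError):
        SimConfig(divergence_delta=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(n_divergent_sv=10, n_sv=5).validate()
    with pytest.raises(ValueError):
        SimConfig(mito_gene_fraction=1.0).validate()
    SimConfig().validate()


# gene models --------------------------------------------------------------

def test_zero_genes_empty_set():
    assert len(make_gene_models(SimConfig(n_genes=0))) == 0


def test_models_nonoverlapping_and_in_bounds():
    cfg = SimConfig(seed=3, n_chroms=1, chrom_length_bp=1_000_000, n_genes=100)
    models = make_gene_models(cfg)
    assert len(models) == 100
    genes = sorted(models, key=lambda g: (g.chrom, g.tx_start))
    # exhaustive pairwise interval scan
    for a, b in zip(genes, genes[1:]):
        if a.chrom == b.chrom:
            assert b.tx_start - a.tx_end - 1 >= 300, (a.gene_id, b.gene_id)
    for g in genes:
        assert 1 <= g.tx_start <= g.tx_end <= cfg.chrom_length_bp


def test_models_structure_invariants(small_models):
    for g in small_models:
        assert g.cds and g.utr5 and g.utr3 and g.exons
        exonic = {p for s, e in g.exons for p in range(s, e + 1)}
        coding = {p for s, e in g.cds for p in range(s, e + 1)}
        utr = {p for s, e in g.utr5 + g.utr3 for p in range(s, e + 1)}
        assert coding <= exonic and utr <= exonic
        assert not (coding & utr)
        assert min(exonic) == g.tx_start and max(exonic) == g.tx_end


def test_models_deterministic(tmp_path):
    cfg = SimConfig(seed=8, n_genes=30, n_chroms=1)
    p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
    write_gff3(make_gene_models(cfg), p1)
    write_gff3(make_gene_models(cfg), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_models_infeasible_packing_error():
    with pytest.raises(ValueError, match="cannot place"):
        make_gene_models(SimConfig(n_genes=500, n_chroms=1, chrom_length_bp=100_000))


def test_mito_prefix_fraction():
    cfg = SimConfig(seed=1, n_genes=100, mito_gene_fraction=0.05, n_chroms=1)
    models = make_gene_models(cfg)
    n_mito = sum(g.startswith("MT-") for g in models.gene_ids)
    assert n_mito == 5


# SV cohort ----------------------------------------------------------------

def test_cohort_no_divergent(small_models):
    cfg = SimConfig(seed=2, n_sv=50, n_divergent_sv=0, n_genes=60, n_chroms=1)
    cohort = simulate_sv_cohort(small_models, cfg)
    assert cohort.truth.divergent_sv_ids == set()


def test_cohort_fixed_divergence_exact(small_models):
    cfg = SimConfig(seed=4, n_sv=400, n_divergent_sv=25, divergence_delta=1.0,
                    n_genes=60, n_chroms=1)
    cohort = simulate_sv_cohort(small_models, cfg)
    codes = cohort.matrix.codes
    idx = {sv: i for i, sv in enumerate(cohort.matrix.sv_ids)}
    n_a = cfg.n_samples_pop_a
    for sv in cohort.truth.divergent_sv_ids:
        row = codes[idx[sv]]
        p_a = row[:n_a].sum() / (2 * n_a)
        p_b = row[n_a:].sum() / (2 * (len(row) - n_a))
        assert abs(p_a - p_b) == 1.0


def test_cohort_intermediate_divergence(small_models):
    cfg = SimConfig(seed=4, n_sv=100, n_divergent_sv=100, divergence_delta=0.6,
                    n_genes=60, n_chroms=1, n_samples_pop_a=500, n_samples_pop_b=500)
    cohort = simulate_sv_cohort(small_models, cfg, missing_rate=0)
    codes = cohort.matrix.codes
    gaps = []
    for row in codes:
        p_a = row[:500].sum() / 1000
        p_b = row[500:].sum() / 1000
        gaps.append(abs(p_a - p_b))
    assert np.mean(gaps) == pytest.approx(0.6, abs=0.03)


def test_cohort_truth_closure(small_cohort, small_models):
    sv_ids = set(small_cohort.matrix.sv_ids)
    assert small_cohort.truth.divergent_sv_ids <= sv_ids
    assert set(small_cohort.truth.sv_placement) == sv_ids
    gene_ids = {g for _, g in small_cohort.truth.sv_placement.values() if g}
    assert gene_ids and gene_ids <= set(small_models.gene_ids)


def test_cohort_placement_matches_classifier(small_cohort, small_models):
    from svlink.annotate import classify_sv

    for rec in small_cohort.sites[:100]:
        category, _ = small_cohort.truth.sv_placement[rec.id]
        assert classify_sv(rec, small_models).category == category


def test_cohort_hardy_weinberg():
    cfg = SimConfig(seed=6, n_sv=40, n_divergent_sv=0, n_genes=30, n_chroms=1,
                    n_samples_pop_a=5000, n_samples_pop_b=5000)
    models = make_gene_models(cfg)
    cohort = simulate_sv_cohort(models, cfg, missing_rate=0)
    for row in cohort.matrix.codes:
        n = len(row)
        p = row.sum() / (2 * n)
        if p < 0.05 or p > 0.95:
            continue
        exp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
        obs = np.bincount(row.astype(int), minlength=3)
        # within ~4 binomial standard errors
        for o, e in zip(obs, exp):
            se = np.sqrt(max(e * (1 - e / n), 1))
            assert abs(o - e) < 5 * se


def test_cohort_determinism(small_config, small_models, tmp_path):
    c1 = simulate_sv_cohort(small_models, small_config)
    c2 = simulate_sv_cohort(small_models, small_config)
    assert c1.matrix.sv_ids == c2.matrix.sv_ids
    assert np.array_equal(c1.matrix.codes, c2.matrix.codes)
    p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
    sample = c1.matrix.sample_ids[0]
    sv_io.write_sv_vcf(c1.callsets[sample], p1, [sample])
    sv_io.write_sv_vcf(c2.callsets[sample], p2, [sample])
    assert hashlib.sha256(p1.read_bytes()).digest() == hashlib.sha256(p2.read_bytes()).digest()


def test_cohort_delta_above_one_rejected(small_models):
    cfg = SimConfig(divergence_delta=2.0)
    with pytest.raises(ValueError):
        simulate_sv_cohort(small_models, cfg)


def test_truth_json_round_trip(small_cohort, tmp_path):
    path = tmp_path / "truth.json"
    small_cohort.truth.to_json(path)
    data = json.loads(path.read_text())
    assert set(data["divergent_sv_ids"]) == small_cohort.truth.divergent_sv_ids


# bulk ---------------------------------------------------------------------

def test_bulk_seeded_lfc_recovered(small_models):
    cfg = SimConfig(seed=9, n_genes=60, n_de_genes=10, de_log2fc=3.0, n_chroms=1)
    bulk = simulate_bulk_counts(small_models, cfg, n_a=10, n_b=10, dispersion=0.02)
    from svlink.bulk_de import size_factors

    norm = bulk.counts / size_factors(bulk.counts)
    cols_a = [c for c in norm if bulk.groups[c] == "groupA"]
    cols_b = [c for c in norm if bulk.groups[c] == "groupB"]
    checked = 0
    for gene, lfc in bulk.truth_de.items():
        mean_a = norm.loc[gene, cols_a].mean()
        mean_b = norm.loc[gene, cols_b].mean()
        if min(mean_a, mean_b) < 5:  # pseudocount-free ratio needs signal
            continue
        obs = np.log2(mean_b) - np.log2(mean_a)
        assert obs == pytest.approx(lfc, abs=0.3)
        checked += 1
    assert checked >= 5


def test_bulk_too_many_de_genes(small_models):
    cfg = SimConfig(n_genes=60, n_de_genes=61)
    with pytest.raises(ValueError):
        simulate_bulk_counts(small_models, cfg)


def test_bulk_min_samples(small_models):
    with pytest.raises(ValueError):
        simulate_bulk_counts(small_models, SimConfig(n_genes=60), n_a=1, n_b=5)


# single cell --------------------------------------------------------------

def test_sc_marker_elevated_in_home_cluster(small_models):
    cfg = SimConfig(seed=10, n_genes=60, n_clusters=3, cells_per_cluster=80,
                    markers_per_cluster=5, n_chroms=1, species_specific_cluster=False)
    sim = simulate_sc_counts(small_models, cfg, "speciesA")
    counts = sim.matrix.counts
    gene_index = {g: i for i, g in enumerate(sim.matrix.gene_ids)}
    for cl, markers in sim.marker_assignment.items():
        home = sim.labels == cl
        for g in markers:
            i = gene_index[g]
            assert counts[i, home].mean() > counts[i, ~home].mean()


def test_sc_species_specific_flag_semantics(small_models):
    cfg = SimConfig(seed=10, n_genes=60, n_clusters=2, cells_per_cluster=30,
                    n_chroms=1, species_specific_cluster=False)
    sim = simulate_sc_counts(small_models, cfg, "speciesA")
    assert sim.species_specific_cluster_id is None
    cfg2 = SimConfig(seed=10, n_genes=60, n_clusters=2, cells_per_cluster=30,
                     n_chroms=1, species_specific_cluster=True)
    sim2 = simulate_sc_counts(small_models, cfg2, "speciesA")
    assert sim2.species_specific_cluster_id == 2
    assert set(sim2.marker_assignment) == {0, 1, 2}


def test_sc_marker_sets_disjoint(small_models):
    cfg = SimConfig(seed=10, n_genes=60, n_clusters=4, cells_per_cluster=10,
                    markers_per_cluster=5, n_chroms=1)
    sim = simulate_sc_counts(small_models, cfg, "speciesA")
    all_markers = [g for ms in sim.marker_assignment.values() for g in ms]
    assert len(all_markers) == len(set(all_markers))


def test_sc_mito_fraction(small_models):
    cfg = SimConfig(seed=10, n_genes=60, n_clusters=2, cells_per_cluster=200,
                    mito_gene_fraction=0.05, n_chroms=1, species_specific_cluster=False)
    sim = simulate_sc_counts(small_models, cfg, "speciesA", mito_fail_rate=0.0)
    mito = sim.matrix.mito_flags
    frac = sim.matrix.counts[mito].sum() / sim.matrix.counts.sum()
    assert frac == pytest.approx(0.05, abs=0.01)


def test_sc_too_many_markers_error(small_models):
    cfg = SimConfig(n_genes=60, n_clusters=10, markers_per_cluster=10, n_chroms=1)
    with pytest.raises(ValueError):
        simulate_sc_counts(small_models, cfg, "speciesA")


# orthologs ----------------------------------------------------------------

def test_ortholog_identity_map(small_models):
    table = make_ortholog_map(small_models, small_models, 1.0, seed=1)
    assert list(table["gene_a"]) == list(table["gene_b"]) == small_models.gene_ids


def test_ortholog_empty(small_models):
    assert len(make_ortholog_map(small_models, small_models, 0.0, seed=1)) == 0


def test_ortholog_partial_counts():
    cfg_a = SimConfig(seed=1, n_genes=100, n_chroms=1)
    cfg_b = SimConfig(seed=1, n_genes=120, n_chroms=1)
    ma = make_gene_models(cfg_a, prefix="GA")
    mb = make_gene_models(cfg_b, prefix="GB")
    table = make_ortholog_map(ma, mb, 0.8, seed=2)
    assert len(table) == 80
    assert table["gene_a"].is_unique and table["gene_b"].is_unique
    assert set(table["gene_a"]) <= set(ma.gene_ids)
    assert set(table["gene_b"]) <= set(mb.gene_ids)


def test_ortholog_fraction_bounds(small_models):
    with pytest.raises(ValueError):
        make_ortholog_map(small_models, small_models, 1.2, seed=0)
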