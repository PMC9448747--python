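import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from svlink import sc
from svlink.sc import (
    CellMatrix,
    cluster_cells,
    cluster_profiles,
    cross_species_correlation,
    find_markers,
    joint_cluster,
    lognormalize,
    qc_filter,
)
from svlink.simulate import (
    SimConfig,
    make_gene_models,
    make_ortholog_map,
    simulate_sc_counts,
)


def _cell_matrix(counts, mito=None, species="speciesA"):
    counts = np.asarray(counts, dtype=np.int64)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    cells = [f"c{j}" for j in range(counts.shape[1])]
    if mito is None:
        mito = np.zeros(counts.shape[0], dtype=bool)
    return CellMatrix(counts, genes, cells, np.asarray(mito, bool), species)


@pytest.fixture(scope="module")
def sc_pair():
    cfg = SimConfig(seed=30)
    ma = make_gene_models(cfg, prefix="GA")
    mb = make_gene_models(cfg, prefix="GB")
    sim_a = simulate_sc_counts(ma, cfg, "speciesA", add_specific_cluster=True)
    sim_b = simulate_sc_counts(mb, cfg, "speciesB", add_specific_cluster=False)
    ortho = make_ortholog_map(ma, mb, 0.9, seed=30)
    return cfg, sim_a, sim_b, ortho


# QC -----------------------------------------------------------------------

def test_qc_removes_low_gene_cells():
    counts = np.zeros((400, 2), dtype=np.int64)
    counts[:250, 0] = 1  # 250 detected genes
    counts[:350, 1] = 1
    out = qc_filter(_cell_matrix(counts), min_genes=300)
    assert out.cell_ids == ["c1"]


def test_qc_removes_high_mito_cells():
    mito = np.zeros(10, dtype=bool)
    mito[0] = True
    counts = np.ones((10, 2), dtype=np.int64)
    counts[0, 0] = 3   # mito fraction 3/12 = 0.25
    counts[0, 1] = 1   # 1/10 = 0.1
    out = qc_filter(_cell_matrix(counts, mito), min_genes=1, max_mito=0.20)
    assert out.cell_ids == ["c1"]


def test_qc_boundaries_kept():
    # one mito gene at 74 counts + 296 unit counts: 297 detected genes,
    # total 370, mito fraction 74/370 = 0.2 exactly — both boundaries hit
    mito = np.zeros(300, dtype=bool)
    mito[0] = True
    counts = np.zeros((300, 1), dtype=np.int64)
    counts[0, 0] = 74
    counts[1:297, 0] = 1
    out = qc_filter(_cell_matrix(counts, mito), min_genes=297, max_mito=0.20)
    assert out.n_cells == 1  # both boundaries inclusive


def test_qc_identity_and_idempotent():
    counts = np.ones((50, 5), dtype=np.int64) * 3
    m = _cell_matrix(counts)
    out = qc_filter(m, min_genes=10)
    assert out.cell_ids == m.cell_ids
    again = qc_filter(out, min_genes=10)
    assert again.cell_ids == out.cell_ids
    assert np.array_equal(again.counts, out.counts)


def test_qc_all_removed_error():
    counts = np.zeros((10, 3), dtype=np.int64)
    counts[0] = 1
    with pytest.raises(ValueError, match="removed all"):
        qc_filter(_cell_matrix(counts), min_genes=5)


# lognormalize -------------------------------------------------------------

def test_lognormalize_zero_is_zero():
    counts = np.array([[0, 5], [10, 5]])
    out = lognormalize(_cell_matrix(counts))
    assert out.values[0, 0] == 0.0


def test_lognormalize_total_equals_scale():
    counts = np.zeros((3, 1), dtype=np.int64)
    counts[:, 0] = [3, 7, 9990]
    out = lognormalize(_cell_matrix(counts), scale=10000.0)
    assert out.values[0, 0] == pytest.approx(np.log(1 + 3))
    assert out.values[1, 0] == pytest.approx(np.log(1 + 7))


def test_lognormalize_formula_oracle():
    rng = np.random.default_rng(31)
    counts = rng.poisson(5, size=(40, 30)).astype(np.int64)
    counts[0, :] += 1  # avoid empty cells
    out = lognormalize(_cell_matrix(counts), scale=10000.0)
    totals = counts.sum(axis=0)
    expected = np.log1p(counts / totals * 10000.0)
    assert np.allclose(out.values, expected, atol=1e-12)


def test_lognormalize_zero_cell_error():
    counts = np.zeros((5, 2), dtype=np.int64)
    counts[:, 0] = 1
    with pytest.raises(ValueError):
        lognormalize(_cell_matrix(counts))


# clustering ---------------------------------------------------------------

def test_cluster_two_separated_groups(sc_pair):
    cfg, sim_a, _, _ = sc_pair
    cfg2 = SimConfig(seed=32, n_clusters=2, cells_per_cluster=120,
                     species_specific_cluster=False)
    models = make_gene_models(cfg2)
    sim = simulate_sc_counts(models, cfg2, "speciesA")
    norm = lognormalize(qc_filter(sim.matrix, min_genes=100))
    labels = cluster_cells(norm, seed=0)
    truth = {c: l for c, l in zip(sim.matrix.cell_ids, sim.labels)}
    t = [truth[c] for c in norm.cell_ids]
    assert adjusted_rand_score(t, labels) == 1.0


def test_cluster_homogeneous_single_cluster():
    cfg = SimConfig(seed=33, n_clusters=1, cells_per_cluster=200,
                    species_specific_cluster=False)
    models = make_gene_models(cfg)
    sim = simulate_sc_counts(models, cfg, "speciesA")
    norm = lognormalize(qc_filter(sim.matrix, min_genes=100))
    labels = cluster_cells(norm, resolution=0.5, seed=0)
    assert len(np.unique(labels)) == 1


def test_cluster_determinism(sc_pair):
    _, sim_a, _, _ = sc_pair
    norm = lognormalize(qc_filter(sim_a.matrix, min_genes=100))
    l1 = cluster_cells(norm, seed=7)
    l2 = cluster_cells(norm, seed=7)
    assert np.array_equal(l1, l2)


def test_cluster_too_few_cells_error():
    counts = np.random.default_rng(0).poisson(5, size=(50, 10)).astype(np.int64) + 1
    norm = lognormalize(_cell_matrix(counts))
    with pytest.raises(ValueError):
        cluster_cells(norm, n_pcs=5, k_neighbors=20)


def test_cluster_needs_nonconstant_genes():
    counts = np.ones((30, 40), dtype=np.int64)
    norm = lognormalize(_cell_matrix(counts))
    with pytest.raises(ValueError, match="non-constant"):
        cluster_cells(norm, n_pcs=20)


# markers ------------------------------------------------------------------

def test_markers_recover_seeded(sc_pair):
    _, sim_a, _, _ = sc_pair
    qc = qc_filter(sim_a.matrix, min_genes=100)
    norm = lognormalize(qc)
    labels = cluster_cells(norm, seed=0)
    truth = {c: l for c, l in zip(sim_a.matrix.cell_ids, sim_a.labels)}
    t = np.array([truth[c] for c in norm.cell_ids])
    markers = find_markers(norm, labels)
    # map detected clusters to truth clusters by majority
    for cl in np.unique(labels):
        truth_cl = np.bincount(t[labels == cl]).argmax()
        seeded = set(sim_a.marker_assignment[int(truth_cl)])
        found = set(markers.loc[markers["cluster_id"] == cl, "gene_id"])
        recall = len(seeded & found) / len(seeded)
        assert recall >= 0.8, (cl, truth_cl, recall)
        precision = len(seeded & found) / max(1, len(found))
        if int(truth_cl) != sim_a.species_specific_cluster_id:
            assert precision >= 0.8


def test_markers_label_shuffle_near_zero(sc_pair):
    _, sim_a, _, _ = sc_pair
    norm = lognormalize(qc_filter(sim_a.matrix, min_genes=100))
    labels = cluster_cells(norm, seed=0)
    rng = np.random.default_rng(34)
    shuffled = rng.permutation(labels)
    markers = find_markers(norm, shuffled)
    n_tests = len(norm.gene_ids) * len(np.unique(labels))
    assert len(markers) <= 0.01 * n_tests


def test_markers_constant_gene_absent():
    rng = np.random.default_rng(35)
    counts = rng.poisson(5, size=(30, 60)).astype(np.int64)
    counts[0, :] = 7  # constant gene
    counts[1, :30] = 40  # marker of cluster 0
    norm = lognormalize(_cell_matrix(counts + 1))
    labels = np.array([0] * 30 + [1] * 30)
    markers = find_markers(norm, labels)
    assert "g0" not in set(markers["gene_id"])


def test_markers_singleton_cluster_skipped():
    rng = np.random.default_rng(36)
    counts = rng.poisson(5, size=(30, 31)).astype(np.int64) + 1
    norm = lognormalize(_cell_matrix(counts))
    labels = np.array([0] * 30 + [1])
    with pytest.warns(UserWarning, match="fewer than 2 cells"):
        markers = find_markers(norm, labels)
    assert set(markers["cluster_id"]) <= {0}


def test_markers_require_two_clusters():
    counts = np.ones((10, 5), dtype=np.int64)
    norm = lognormalize(_cell_matrix(counts))
    with pytest.raises(ValueError):
        find_markers(norm, np.zeros(5, dtype=int))


def test_markers_invariant_under_label_permutation(sc_pair):
    _, sim_a, _, _ = sc_pair
    norm = lognormalize(qc_filter(sim_a.matrix, min_genes=100))
    labels = cluster_cells(norm, seed=0)
    remap = {l: 10 - l for l in np.unique(labels)}
    relabeled = np.array([remap[l] for l in labels])
    m1 = find_markers(norm, labels)
    m2 = find_markers(norm, relabeled)
    m1["cluster_id"] = m1["cluster_id"].map(remap)
    key = ["cluster_id", "gene_id"]
    pd.testing.assert_frame_equal(
        m1.sort_values(key).reset_index(drop=True),
        m2.sort_values(key).reset_index(drop=True),
    )


# cross-species correlation ------------------------------------------------

def test_correlation_identical_profiles():
    rng = np.random.default_rng(37)
    prof = pd.DataFrame(rng.random((50, 3)), index=[f"g{i}" for i in range(50)])
    ortho = pd.DataFrame({"gene_a": prof.index, "gene_b": prof.index})
    rmat, report = cross_species_correlation(prof, prof, ortho)
    assert np.allclose(np.diag(rmat), 1.0)
    assert not report["novel"].any()


def test_correlation_novel_cluster_flagged(sc_pair):
    _, sim_a, sim_b, ortho = sc_pair
    norm_a = lognormalize(qc_filter(sim_a.matrix, min_genes=100))
    norm_b = lognormalize(qc_filter(sim_b.matrix, min_genes=100))
    la, lb = cluster_cells(norm_a, seed=0), cluster_cells(norm_b, seed=0)
    rmat, report = cross_species_correlation(
        cluster_profiles(norm_a, la), cluster_profiles(norm_b, lb), ortho
    )
    truth = {c: l for c, l in zip(sim_a.matrix.cell_ids, sim_a.labels)}
    t = np.array([truth[c] for c in norm_a.cell_ids])
    spec_label = None
    for cl in np.unique(la):
        if np.bincount(t[la == cl]).argmax() == sim_a.species_specific_cluster_id:
            spec_label = cl
    assert spec_label is not None
    rep = report.set_index("cluster")
    assert bool(rep.loc[spec_label, "novel"])
    assert rep.loc[spec_label, "max_r"] < 0.31
    assert not rep.drop(index=spec_label)["novel"].any()


def test_correlation_boundary_not_flagged():
    """max r exactly at the threshold is not novel (strict <)."""
    rng = np.random.default_rng(38)
    u = rng.standard_normal(200)
    v = rng.standard_normal(200)
    u -= u.mean()
    v -= v.mean()
    v -= u * (u @ v) / (u @ u)  # orthogonalize
    r_target = 0.31
    y = r_target * u / np.linalg.norm(u) + np.sqrt(1 - r_target**2) * v / np.linalg.norm(v)
    genes = [f"g{i}" for i in range(200)]
    pa = pd.DataFrame({"a0": u}, index=genes)
    pb = pd.DataFrame({"b0": y}, index=genes)
    ortho = pd.DataFrame({"gene_a": genes, "gene_b": genes})
    rmat, _ = cross_species_correlation(pa, pb, ortho)
    r_exact = float(rmat.iloc[0, 0])
    _, report = cross_species_correlation(pa, pb, ortho, novel_r_threshold=r_exact)
    assert not report["novel"].iloc[0]
    _, report2 = cross_species_correlation(pa, pb, ortho, novel_r_threshold=np.nextafter(r_exact, 1))
    assert report2["novel"].iloc[0]


def test_correlation_too_few_orthologs():
    prof = pd.DataFrame({"a": [1.0]}, index=["g0"])
    ortho = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g0"]})
    with pytest.raises(ValueError):
        cross_species_correlation(prof, prof, ortho)


# joint clustering ---------------------------------------------------------

def test_joint_cluster_composition(sc_pair):
    _, sim_a, sim_b, ortho = sc_pair
    qa = qc_filter(sim_a.matrix, min_genes=100)
    qb = qc_filter(sim_b.matrix, min_genes=100)
    joint = joint_cluster(qa, qb, ortho, seed=0)
    comp = joint.composition
    assert np.allclose(comp.sum(axis=1), 1.0)
    # shared clusters contain both species; the specific cluster is >= 95% A
    spec_cells = {
        c for c, l in zip(sim_a.matrix.cell_ids, sim_a.labels)
        if l == sim_a.species_specific_cluster_id
    }
    frac_a = joint.labels[joint.labels.index.isin(spec_cells)].mode()
    spec_joint = int(frac_a.iloc[0])
    assert comp.loc[spec_joint, "speciesA"] >= 0.95
    for cl in comp.index:
        if cl != spec_joint:
            assert 0 < comp.loc[cl, "speciesA"] < 1


def test_joint_cluster_empty_ortholog_error(sc_pair):
    _, sim_a, sim_b, _ = sc_pair
    empty = pd.DataFrame({"gene_a": [], "gene_b": []})
    with pytest.raises(ValueError):
        joint_cluster(sim_a.matrix, sim_b.matrix, empty)


# I/O ----------------------------------------------------------------------

def test_mtx_round_trip(tmp_path, sc_pair):
    _, sim_a, _, _ = sc_pair
    sim_a.matrix.to_mtx_dir(tmp_path / "mtx")
    back = CellMatrix.from_mtx_dir(tmp_path / "mtx", "speciesA")
    assert back.gene_ids == sim_a.matrix.gene_ids
    assert back.cell_ids == sim_a.matrix.cell_ids
    assert np.array_equal(back.counts, sim_a.matrix.counts)
    assert np.array_equal(back.mito_flags, sim_a.matrix.mito_flags)


def test_cell_matrix_validation():
    with pytest.raises(ValueError):
        CellMatrix(np.ones((2, 2)), ["g0", "g1"], ["c0", "c1"],
                   np.zeros(2, bool))  # non-integer
    with pytest.raises(ValueError):
        CellMatrix(-np.ones((2, 2), dtype=np.int64), ["g0", "g1"], ["c0", "c1"],
                   np.zeros(2, bool))
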