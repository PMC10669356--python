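import numpy as np
import pytest

from periofem.geometry import ToothParams, build_tooth, reduce_attachment
from periofem.meshing import (FEMesh, box_mesh, convergence_study,
                              generate_mesh, mesh_quality_report,
                              split_prisms)

REFERENCE_PRISM = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                            [0, 0, 1.0], [1, 0, 1], [0, 1, 1]])


def test_prism_split_partitions_volume():
    """Minimal-index splitting yields three positive tets that exactly
    tile any affinely mapped prism, for every global-id labelling."""
    rng = np.random.default_rng(0)
    for _ in range(300):
        ids = rng.permutation(100000)[:6]
        a = rng.normal(0, 1, (3, 3))
        if np.linalg.det(a) < 0:
            a[0] *= -1
        pts = REFERENCE_PRISM @ a.T
        pos = {i: p for i, p in zip(ids, pts)}
        tets = split_prisms(ids[None, :])
        vols = []
        for t in tets:
            x = np.array([pos[i] for i in t])
            vols.append(np.dot(x[1] - x[0],
                               np.cross(x[2] - x[0], x[3] - x[0])) / 6.0)
        assert min(vols) > 0
        assert sum(vols) == pytest.approx(0.5 * np.linalg.det(a), rel=1e-9)


def test_prism_split_conforming_across_shared_faces():
    # two prisms sharing a vertical quad face must cut it along the same
    # diagonal regardless of processing order
    rng = np.random.default_rng(1)
    for _ in range(100):
        ids = rng.permutation(1000)[:8]
        p1 = ids[[0, 1, 2, 4, 5, 6]]
        p2 = ids[[1, 3, 2, 5, 7, 6]]   # shares face (1, 2, 5, 6)
        faces = set()
        for tets in (split_prisms(p1[None]), split_prisms(p2[None])):
            for t in tets:
                for tri in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
                    faces.add(tuple(sorted(t[list(tri)])))
        quad = {ids[1], ids[2], ids[5], ids[6]}
        cut = [f for f in faces if set(f) < quad]
        # the shared quad appears as exactly two triangles (one diagonal)
        assert len(set(cut)) == 2


def test_box_mesh_volume_and_tags():
    mesh = box_mesh((1.0, 1.0, 1.0), size=0.25, order=1)
    vols = mesh.volumes()
    assert np.all(vols > 0)
    assert vols.sum() == pytest.approx(1.0, abs=1e-9)
    for name in ("xmin", "xmax", "ymin", "ymax", "zmin", "zmax"):
        assert mesh.facet_sets[name].areas(mesh.nodes).sum() == \
            pytest.approx(1.0, abs=1e-9)


def test_bimaterial_interface_conformity():
    def classify(x, y, z):
        return np.where(z < 0.5, "lower", "upper")
    mesh = box_mesh((1, 1, 1), size=0.25, order=1, classify=classify)
    fs = mesh.facet_sets["interface"]
    assert fs.areas(mesh.nodes).sum() == pytest.approx(1.0, abs=1e-9)
    # each interface facet is shared by exactly one element of each region
    own = mesh.region_id[fs.owners]
    opp = mesh.region_id[fs.opposite]
    assert np.all(own != opp)


def test_no_duplicate_coincident_nodes(coarse_single_mesh):
    key = np.round(coarse_single_mesh.nodes, 8)
    unique = np.unique(key, axis=0)
    assert len(unique) == coarse_single_mesh.n_nodes


def test_tooth_mesh_structure(coarse_single_mesh):
    mesh = coarse_single_mesh
    assert np.all(mesh.volumes() > 0)
    regions = set(np.asarray(mesh.region_names)[np.unique(mesh.region_id)])
    assert {"enamel", "dentin", "pulp", "cementum", "pdl",
            "cortical_bone", "cancellous_bone"} <= regions
    for name in ("pdl_bone_interface", "pdl_root_interface",
                 "occlusal_patch", "outer_bone_boundary", "symmetry_plane"):
        assert len(mesh.facet_sets[name]) > 0, name


def test_pdl_two_elements_through_thickness(coarse_single_mesh):
    mesh = coarse_single_mesh
    pdl = np.where(mesh.region_mask("pdl"))[0]
    bone_nodes = set(np.unique(mesh.facet_sets["pdl_bone_interface"].corners))
    root_nodes = set(np.unique(mesh.facet_sets["pdl_root_interface"].corners))
    touches_bone = np.array([bool(set(mesh.elems[e, :4]) & bone_nodes)
                             for e in pdl])
    touches_root = np.array([bool(set(mesh.elems[e, :4]) & root_nodes)
                             for e in pdl])
    # two radial element layers: inner-layer tets miss the bone interface,
    # outer-layer tets miss the root interface
    assert np.any(~touches_bone)
    assert np.any(~touches_root)


def test_volume_conservation_against_parametric(single_model):
    mesh = generate_mesh(single_model, size=1.6, order=1, symmetric=False)
    assert mesh.volumes().sum() == pytest.approx(single_model.total_volume(),
                                                 rel=5e-3)


def test_half_mesh_volume_is_half(single_model):
    half = generate_mesh(single_model, size=1.8, order=1, symmetric=True)
    assert half.symmetry_factor == 2.0
    assert half.volumes().sum() * 2 == pytest.approx(
        single_model.total_volume(), rel=7e-3)


def test_volume_invariant_under_refinement(single_model):
    coarse = generate_mesh(single_model, size=1.8, order=1)
    fine = generate_mesh(single_model, size=1.3, order=1)
    assert coarse.volumes().sum() == pytest.approx(fine.volumes().sum(),
                                                   rel=5e-3)


def test_exposed_root_tagged_after_reduction(single_model):
    reduced = reduce_attachment(single_model, 4.0)
    mesh = generate_mesh(reduced, size=1.8, order=1)
    fs = mesh.facet_sets["exposed_root"]
    assert len(fs) > 0
    cent = fs.centroids(mesh.nodes)
    assert cent[:, 2].max() < reduced.support_start_z
    assert cent[:, 2].min() > 0.0


def test_mesh_determinism(single_model):
    a = generate_mesh(single_model, size=1.8, order=2)
    b = generate_mesh(single_model, size=1.8, order=2)
    assert a.content_hash() == b.content_hash()


def test_quality_report_counts(coarse_single_mesh):
    report = mesh_quality_report(coarse_single_mesh)
    total = report[report["region"] == "TOTAL"].iloc[0]
    assert total["n_elements"] == coarse_single_mesh.n_elements
    by_region = report[report["region"] != "TOTAL"]
    assert by_region["n_elements"].sum() == coarse_single_mesh.n_elements
    assert total["min_volume_mm3"] > 0


def test_quality_report_flags_degenerate_tet():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [1, 1, 1e-9]], dtype=float)
    elems = np.array([[0, 1, 2, 3], [0, 1, 2, 4]])  # second tet ~flat
    mesh = FEMesh(nodes=nodes, elems=elems,
                  region_id=np.zeros(2, dtype=np.int16),
                  region_names=["block"])
    report = mesh_quality_report(mesh)
    assert report[report["region"] == "TOTAL"]["n_degenerate"].iloc[0] >= 1


def test_mesh_vtu_round_trip(tmp_path, coarse_single_mesh):
    from periofem.meshing import load_mesh_vtu, save_mesh_vtu
    path = save_mesh_vtu(coarse_single_mesh, tmp_path / "mesh.vtu")
    back = load_mesh_vtu(path, coarse_single_mesh.region_names,
                         symmetry_factor=2.0)
    assert back.n_elements == coarse_single_mesh.n_elements
    assert np.allclose(np.sort(back.volumes()),
                       np.sort(coarse_single_mesh.volumes()), atol=1e-12)
    assert np.array_equal(np.bincount(back.region_id),
                          np.bincount(coarse_single_mesh.region_id))
    a = back.facet_sets["pdl_bone_interface"].areas(back.nodes).sum()
    b = coarse_single_mesh.facet_sets["pdl_bone_interface"].areas(
        coarse_single_mesh.nodes).sum()
    assert a == pytest.approx(b, rel=1e-12)


def test_convergence_study_input_validation(single_model):
    with pytest.raises(ValueError, match="three"):
        convergence_study(single_model, [1.0, 0.5])
    with pytest.raises(ValueError, match="decreasing"):
        convergence_study(single_model, [1.0, 1.2, 0.8])


def test_convergence_study_constant_observable(single_model):
    table = convergence_study(single_model, [2.6, 2.2, 1.9],
                              observable=lambda mesh, fld: 42.0, order=1)
    assert np.allclose(table["observable"], 42.0)
    assert table["converged"].iloc[-1]
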