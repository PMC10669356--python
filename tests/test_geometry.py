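import numpy as np
import pytest
import trimesh

from periofem.geometry import (GeometryError, ToothParamError, ToothParams,
                               build_tooth, create_cementum_layer,
                               create_pdl_layer, graded_cementum_thickness,
                               import_surfaces, offset_closed_curve,
                               points_in_mesh, reduce_attachment)


def open_cylinder(r=3.0, h=10.0, n=96, rows=40):
    """Lateral wall of a cylinder (open tube), outward-oriented."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    zs = np.linspace(0, h, rows + 1)
    verts = np.array([[r * np.cos(t), r * np.sin(t), z]
                      for z in zs for t in th])
    faces = []
    for k in range(rows):
        for j in range(n):
            a, b = k * n + j, k * n + (j + 1) % n
            faces += [(a, b, b + n), (a, b + n, a + n)]
    return trimesh.Trimesh(verts, np.array(faces), process=False)


# ---------------------------------------------------------------------------
# parameters

def test_parameter_validation_messages():
    with pytest.raises(ToothParamError, match="furcation"):
        ToothParams(tooth_class="multi_rooted").validate()
    with pytest.raises(ToothParamError, match="pulp_scale"):
        ToothParams(pulp_scale=0.95).validate()
    with pytest.raises(ToothParamError, match="cortical shell"):
        ToothParams(cortical_shell_thickness=4.0,
                    bone_block_dims=(9.0, 9.0, 17.0)).validate()
    with pytest.raises(ToothParamError, match="bone block depth"):
        ToothParams(bone_block_dims=(14.0, 14.0, 12.0)).validate()


def test_reduction_bounds(single_model):
    with pytest.raises(GeometryError, match="reduction"):
        reduce_attachment(single_model, -1.0)
    with pytest.raises(GeometryError, match="reduction"):
        reduce_attachment(single_model, 14.5)


# ---------------------------------------------------------------------------
# layering rules

def test_cementum_three_step_grading():
    # thickness measured from the CEJ: 50 um cervical, 100 um middle,
    # 150 um apical third
    assert graded_cementum_thickness(0.1) == pytest.approx(0.05)
    assert graded_cementum_thickness(0.5) == pytest.approx(0.10)
    assert graded_cementum_thickness(0.9) == pytest.approx(0.15)


def test_offset_circle_exact():
    r = np.full(512, 3.0)
    out = offset_closed_curve(r, 0.1, np.linspace(0, 2 * np.pi, 7))
    assert np.allclose(out, 3.1, atol=1e-9)


def test_offset_self_intersection_detected():
    th = np.arange(512) * (2 * np.pi / 512)
    r = 1.0 - 0.45 * np.sin(th) ** 8  # deep narrow concave grooves
    with pytest.raises(GeometryError, match="self-intersect"):
        offset_closed_curve(r, 0.5, np.array([0.0]))


def test_pdl_shell_cylinder_annulus_oracle():
    shell = create_pdl_layer(open_cylinder(), 0.1)
    assert shell.is_watertight
    expected = np.pi * (3.1 ** 2 - 3.0 ** 2) * 10.0  # 19.16 mm^3
    assert shell.volume == pytest.approx(expected, rel=0.01)


def test_pdl_shell_hemisphere_oracle():
    ico = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    keep = np.where(ico.triangles_center[:, 2] > 0)[0]
    hemi = ico.submesh([keep], append=True)
    shell = create_pdl_layer(hemi, 0.1)
    expected = 2.0 / 3.0 * np.pi * (5.1 ** 3 - 5.0 ** 3)  # ~16.0 mm^3
    assert shell.volume == pytest.approx(expected, rel=0.02)


def test_pdl_shell_degenerate_thickness():
    with pytest.raises(GeometryError, match="thickness"):
        create_pdl_layer(open_cylinder(), 0.0)


def test_cementum_shell_graded_cylinder_oracle():
    cem = create_cementum_layer(open_cylinder(h=12.0, rows=48),
                                cej_point=(0, 0, 0), apex_point=(0, 0, 12))
    expected = sum(np.pi * ((3.0 + t) ** 2 - 9.0) * 4.0
                   for t in (0.05, 0.10, 0.15))
    assert cem.volume == pytest.approx(expected, rel=0.01)


def test_cementum_shell_degenerate_inputs():
    cyl = open_cylinder()
    with pytest.raises(GeometryError, match="zero"):
        create_cementum_layer(cyl, (0, 0, 0), (0, 0, 0))
    short = open_cylinder(h=0.5, rows=2)
    with pytest.raises(GeometryError, match="three cementum steps"):
        create_cementum_layer(short, (0, 0, 0), (0, 0, 0.5))


# ---------------------------------------------------------------------------
# built models

def test_pdl_thickness_uniform_on_built_models(single_model, multi_model):
    # 0.1 mm +- 20% at >= 95% of sampled surface points
    for model in (single_model, multi_model):
        d = model.sample_pdl_thickness(200, np.random.default_rng(7))
        frac = np.mean((d > 0.08) & (d < 0.12))
        assert frac >= 0.95


def test_furcation_landmarks(multi_model):
    assert multi_model.furcation_start_z == pytest.approx(3.0)
    roof = multi_model.furcation_roof_point
    # roof point sits on the inter-root septum side (x = 0) below the
    # furcation depth, inside the waist
    assert roof[0] == pytest.approx(0.0, abs=1e-12)
    assert roof[2] > multi_model.furcation_start_z
    trunk = multi_model.params._base_radius(roof[2])
    assert roof[1] < trunk  # waist narrower than the trunk envelope


def test_reduction_identity(single_model):
    same = reduce_attachment(single_model, 0.0)
    th = np.linspace(0, 2 * np.pi, 33)
    for z in (0.5, 4.0, 9.0):
        assert np.array_equal(same.level_radii(z, th),
                              single_model.level_radii(z, th))


def test_cylinder_root_reduction_linear_area():
    # taper-free root: lateral PDL area decreases exactly linearly in the
    # cervical third where the cementum thickness is constant
    params = ToothParams(root_cervical_radius=3.0, root_apical_radius=3.0,
                         root_length=12.0, crest_offset=0.0,
                         bone_block_dims=(14.0, 14.0, 16.0))
    model = build_tooth(params)
    areas = [reduce_attachment(model, r).pdl_lateral_area(n_z=300)
             for r in (0.0, 1.0, 2.0, 3.0)]
    diffs = np.diff(areas)
    assert np.all(diffs < 0)
    perimeter = 2 * np.pi * (3.0 + 0.05 + 0.1)
    assert np.allclose(-diffs, perimeter, rtol=2e-3)


def test_reduction_area_strictly_decreasing(multi_model):
    areas = [reduce_attachment(multi_model, r).pdl_lateral_area(n_z=150)
             for r in (0.0, 2.0, 4.0, 6.0, 8.0)]
    assert np.all(np.diff(areas) < 0)


def test_furcation_exposed_after_deep_reduction(multi_model):
    roof_z = multi_model.furcation_roof_point[2]
    deep = reduce_attachment(multi_model, 6.0)
    # support starts apical to the roof: the furcation is exposed
    assert deep.support_start_z > roof_z
    from periofem.meshing import generate_mesh
    mesh = generate_mesh(deep, size=2.0, order=1)
    fs = mesh.facet_sets["pdl_bone_interface"]
    cent = fs.centroids(mesh.nodes)
    assert cent[:, 2].min() > roof_z  # no PDL support coronal to the roof


def test_mirror_symmetry(single_model, multi_model):
    th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    for model in (single_model, multi_model):
        for z in (-2.0, 1.0, 5.0, 10.0):
            r = model.level_radii(z, th)
            r_mirror = model.level_radii(z, -th)
            assert np.allclose(r, r_mirror, atol=1e-9)


def test_solid_extraction_watertight_and_volume(single_model):
    solids = single_model.solids(mesh_size=1.8)
    assert set(solids) == {"enamel", "dentin", "pulp", "cementum", "pdl",
                           "cortical_bone", "cancellous_bone"}
    for tissue, mesh in solids.items():
        assert mesh.is_watertight, tissue
        assert mesh.volume > 0, tissue
    # PDL shell volume ~ interface area x 0.1 mm thickness
    ratio = solids["pdl"].volume / single_model.pdl_lateral_area()
    assert 0.08 < ratio < 0.13


# ---------------------------------------------------------------------------
# import / export

def test_surface_round_trip(tmp_path, single_model):
    paths = single_model.export_surfaces(tmp_path, file_format="stl",
                                         mesh_size=1.8)
    imported = import_surfaces(paths)
    for tissue, solid in single_model.solids(1.8).items():
        a = np.unique(np.round(np.asarray(solid.vertices), 4), axis=0)
        b = np.unique(np.round(np.asarray(imported.solids[tissue].vertices),
                               4), axis=0)
        assert a.shape == b.shape
        assert np.allclose(a, b, atol=1e-4)


def test_import_rejects_overlapping_solids(tmp_path):
    s1 = trimesh.creation.icosphere(2, 3.0)
    s2 = trimesh.creation.icosphere(2, 3.0)
    s2.apply_translation([1.0, 0, 0])
    p1, p2 = tmp_path / "a.stl", tmp_path / "b.stl"
    s1.export(p1)
    s2.export(p2)
    with pytest.raises(GeometryError, match="overlap"):
        import_surfaces({"dentin": p1, "pulp": p2})


def test_import_rejects_suspicious_units(tmp_path):
    big = trimesh.creation.icosphere(1, 800.0)
    p = tmp_path / "big.stl"
    big.export(p)
    with pytest.raises(GeometryError, match="unit"):
        import_surfaces({"dentin": p})


def test_import_rejects_open_surface(tmp_path):
    p = tmp_path / "open.stl"
    open_cylinder().export(p)
    with pytest.raises(GeometryError, match="watertight"):
        import_surfaces({"dentin": p})


def test_import_generates_missing_pdl(tmp_path):
    cyl = trimesh.creation.cylinder(radius=3.0, height=16.0, sections=64)
    cyl.apply_translation([0, 0, 5.0])  # crown above z=0, root below... root is +z
    p = tmp_path / "dentin.stl"
    cyl.export(p)
    model = import_surfaces({"dentin": p}, config={"cej_z": 0.0},
                            generate_pdl=True)
    assert "pdl" in model.solids
    assert model.solids["pdl"].volume > 0


def test_points_in_mesh_agrees_with_geometry():
    sphere = trimesh.creation.icosphere(3, 2.0)
    rng = np.random.default_rng(3)
    pts = rng.uniform(-3, 3, size=(300, 3))
    inside = points_in_mesh(sphere, pts)
    truth = np.linalg.norm(pts, axis=1) < 2.0
    # boundary-adjacent points may disagree within facet tolerance
    clear = np.abs(np.linalg.norm(pts, axis=1) - 2.0) > 0.05
    assert np.array_equal(inside[clear], truth[clear])
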