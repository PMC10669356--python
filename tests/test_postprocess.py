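import numpy as np
import pytest

from periofem.materials import MaterialSpec
from periofem.meshing import box_mesh
from periofem.postprocess import (ContactPressureMap, PostprocessError,
                                  contact_pressure, detect_failure,
                                  export_fields, regional_summary,
                                  stress_invariants, voigt_to_tensor)
from periofem.solver import (LoadProtocol, SolutionField, apply_supports,
                             assemble, compute_stress, solve_terminal,
                             traction_load)
from periofem.vtu import read_vtu


def solved_bimaterial(traction, split_axis="z", steel_only=True):
    """Roller-supported block with an internal interface, uniaxial load."""
    def classify(x, y, z):
        coord = {"x": x, "y": y, "z": z}[split_axis]
        return np.where(coord < 0.5, "lower", "upper")
    mesh = box_mesh((1.0, 1.0, 1.0), size=0.25, order=2, classify=classify)
    spec = MaterialSpec("steel", 200e3, 0.3)
    mats = {"lower": spec, "upper": spec}
    system = apply_supports(assemble(mesh, mats), mesh,
                            [("zmin", (2,)), ("xmin", (0,)), ("ymin", (1,))],
                            use_symmetry=False)
    f = traction_load(mesh, "zmax", np.asarray(traction, float))
    u = system.solve(f)
    stress = compute_stress(mesh, u.reshape(-1, 3), mats)
    fld = SolutionField(u.reshape(-1, 3), stress, 1.0,
                        np.asarray(traction, float), materials=mats)
    return mesh, fld


def test_pressure_on_interface_perpendicular_to_load():
    mesh, fld = solved_bimaterial((0, 0, -1.0), split_axis="z")
    pm = contact_pressure(fld, mesh, "interface")
    assert np.allclose(pm.pressure, 1.0, atol=1e-8)
    assert pm.peak_raw == pytest.approx(1.0, abs=1e-8)
    # the facet owner here is the supported lower block, so the traction
    # integral is the force the upper block exerts on it: the full
    # applied load crosses the section
    assert np.allclose(pm.traction_integral, [0, 0, -1.0], atol=1e-8)


def test_pressure_on_interface_parallel_to_load():
    mesh, fld = solved_bimaterial((0, 0, -1.0), split_axis="x")
    pm = contact_pressure(fld, mesh, "interface")
    # free lateral faces: no transverse normal stress on a vertical cut
    assert np.allclose(pm.pressure, 0.0, atol=1e-8)


def test_zero_load_zero_pressure():
    mesh, fld = solved_bimaterial((0, 0, -1.0), split_axis="z")
    zero = fld.scaled(1e-30)
    zero.load_fraction = 1.0
    pm = contact_pressure(zero, mesh, "interface")
    assert np.allclose(pm.pressure, 0.0, atol=1e-20)


def test_sign_convention_flips_with_load():
    mesh, fld_c = solved_bimaterial((0, 0, -1.0), split_axis="z")
    # same block pulled instead of pressed: tension = negative pressure
    system = apply_supports(
        assemble(mesh, fld_c.materials), mesh,
        [("zmin", (2,)), ("xmin", (0,)), ("ymin", (1,))], use_symmetry=False)
    f = traction_load(mesh, "zmax", np.array([0, 0, 1.0]))
    u = system.solve(f)
    stress = compute_stress(mesh, u.reshape(-1, 3), fld_c.materials)
    fld_t = SolutionField(u.reshape(-1, 3), stress, 1.0,
                          np.array([0, 0, 1.0]), materials=fld_c.materials)
    pc = contact_pressure(fld_c, mesh, "interface")
    pt = contact_pressure(fld_t, mesh, "interface")
    assert np.allclose(pc.pressure, -pt.pressure, atol=1e-10)


def test_empty_interface_raises():
    mesh, fld = solved_bimaterial((0, 0, -1.0))
    with pytest.raises(PostprocessError, match="empty"):
        contact_pressure(fld, mesh, "no_such_interface")


# ---------------------------------------------------------------------------
# stress invariants

def test_invariants_closed_forms():
    hydro = np.array([[2.0, 2.0, 2.0, 0, 0, 0]])
    uni = np.array([[3.0, 0, 0, 0, 0, 0]])
    fld = SolutionField(np.zeros((1, 3)), np.vstack([hydro, uni]), 1.0,
                        np.zeros(3))
    inv = stress_invariants(fld)
    assert inv["von_mises"][0] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(inv.iloc[0][["sigma_1", "sigma_2", "sigma_3"]], 2.0)
    assert inv["von_mises"][1] == pytest.approx(3.0)
    assert inv["sigma_1"][1] == pytest.approx(3.0)


def test_principals_match_tensor_invariants():
    rng = np.random.default_rng(2)
    voigt = rng.normal(0, 5, (50, 6))
    fld = SolutionField(np.zeros((1, 3)), voigt, 1.0, np.zeros(3))
    inv = stress_invariants(fld)
    t = voigt_to_tensor(voigt)
    p = inv[["sigma_1", "sigma_2", "sigma_3"]].to_numpy()
    assert np.allclose(p.sum(axis=1), np.trace(t, axis1=1, axis2=2),
                       atol=1e-10)
    assert np.allclose(p.prod(axis=1), np.linalg.det(t), rtol=1e-8,
                       atol=1e-8)
    assert np.all(np.diff(p, axis=1) <= 1e-12)  # descending order


# ---------------------------------------------------------------------------
# zones

def synthetic_map(mesh, model, value=1.0):
    fs = mesh.facet_sets["pdl_bone_interface"]
    areas = fs.areas(mesh.nodes)
    return ContactPressureMap(
        interface="pdl_bone_interface", centroids=fs.centroids(mesh.nodes),
        areas=areas, normals=fs.normals(mesh.nodes),
        pressure=np.full(len(fs), value), traction_integral=np.zeros(3))


def test_zone_partition_and_uniform_means(single_model, coarse_single_mesh):
    pm = synthetic_map(coarse_single_mesh, single_model)
    summary = regional_summary(pm, single_model)
    t = summary.table
    assert "furcation_roof" not in t.index  # single-rooted tooth
    assert t["area_mm2"].sum() == pytest.approx(pm.areas.sum(), rel=1e-6)
    assert np.allclose(t["mean_MPa"], 1.0)
    assert np.allclose(t["peak_MPa"], 1.0)


def test_zones_track_remaining_interface(single_model, multi_model):
    from periofem.geometry import reduce_attachment
    from periofem.meshing import generate_mesh
    reduced = reduce_attachment(single_model, 5.0)
    mesh = generate_mesh(reduced, size=2.0, order=1)
    pm = synthetic_map(mesh, reduced)
    summary = regional_summary(pm, reduced)
    cerv = pm.centroids[summary.zone_of_facet == "cervical"]
    assert cerv[:, 2].min() >= reduced.support_start_z - 1e-6


def test_failure_detection_threshold_crossing():
    v = detect_failure([1, 2, 3], [0.4, 0.5, 0.95], threshold=0.9)
    assert v.failed and v.criterion == "pressure_threshold"
    assert v.triggering_reduction == 3


def test_failure_detection_none():
    v = detect_failure([1, 2, 3], [0.4, 0.5, 0.6], threshold=0.9)
    assert not v.failed and v.criterion is None


def test_failure_detection_solver_failure_first():
    v = detect_failure([1, 2], [None, 0.95], threshold=0.9,
                       solver_failed=[True, False])
    assert v.failed and v.criterion == "solver_failure"
    assert v.triggering_reduction == 1


# ---------------------------------------------------------------------------
# export

def test_export_fields_round_trip(tmp_path, single_model, coarse_single_mesh,
                                  coarse_single_solution):
    pm = contact_pressure(coarse_single_solution, coarse_single_mesh)
    paths = export_fields(coarse_single_solution, pm, coarse_single_mesh,
                          tmp_path, model=single_model)
    nodes, elems, pdata, cdata = read_vtu(paths["vtu"])
    assert np.allclose(nodes, coarse_single_mesh.nodes, atol=1e-12)
    assert np.allclose(pdata["displacement"],
                       coarse_single_solution.displacements, atol=1e-12)
    assert np.allclose(cdata["stress_voigt"],
                       coarse_single_solution.stress, atol=1e-12)
    zones = paths["zones_csv"].read_text().strip().split("\n")
    assert len(zones) == 4  # header + cervical/mid_root/apical
    assert paths["pressure_png"].exists()


def test_peak_measures_ordering(coarse_single_mesh, coarse_single_solution):
    pm = contact_pressure(coarse_single_solution, coarse_single_mesh)
    assert pm.peak <= pm.peak_raw
    assert pm.area_weighted_mean <= pm.peak
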