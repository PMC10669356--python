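"""Study orchestration: baseline characterization and attachment-loss sweeps.

The core experiment mirrors the clinical question: how does the load on
the remaining periodontal ligament escalate as horizontal attachment
loss progresses in 1 mm steps, and at what reduction does a tooth become
mechanically hopeless?  A sweep builds one reduced model per step,
re-meshes, solves the occlusal load case, extracts the PDL-bone contact
pressure and its regional distribution, and applies the failure
criterion.  After the first confirmed failure one extra step is run to
confirm, then the sweep stops; later rows are marked not evaluated.

Absolute pressures depend on how much of the masticatory muscle force an
individual tooth receives, which is anatomy-specific; the calibration
mode scales the load so the full-support peak pressure matches a chosen
anchor (e.g. 0.48 MPa for a single-rooted tooth), making cross-class
trend comparisons meaningful.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import LayeredToothModel, ToothParams, build_tooth, reduce_attachment
from .materials import material_table
from .meshing import generate_mesh
from .postprocess import (FailureVerdict, RegionalSummary, contact_pressure,
                          detect_failure, regional_summary)
from .solver import (LoadProtocol, SolverError, apply_supports, assemble,
                     solve_terminal)

__all__ = [
    "AttachmentSweepResult",
    "ClassComparison",
    "run_sweep",
    "compare_tooth_classes",
    "plot_pressure_surface",
]

_ROW_COLUMNS = [
    "reduction_mm", "applied_resultant_N", "peak_pdl_pressure_MPa",
    "p99_pdl_pressure_MPa", "mean_pdl_pressure_MPa", "interface_area_mm2",
    "cervical_peak_MPa", "mid_root_peak_MPa", "apical_peak_MPa",
    "furcation_roof_peak_MPa", "apical_load_share", "transmitted_load_error",
    "equilibrium_rel_error", "linearity_rel_error",
    "solver_failed", "evaluated",
]


@dataclass
class AttachmentSweepResult:
    """Table of per-reduction readouts plus provenance metadata."""

    table: pd.DataFrame
    verdict: FailureVerdict
    summaries: dict[float, RegionalSummary]
    metadata: dict

    @property
    def evaluated(self) -> pd.DataFrame:
        return self.table[self.table["evaluated"]]

    @property
    def failure_reduction(self) -> float:
        """Triggering reduction in mm, or +inf if the sweep never failed."""
        if self.verdict.failed and self.verdict.triggering_reduction is not None:
            return float(self.verdict.triggering_reduction)
        return float("inf")

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "metadata": self.metadata,
            "verdict": dataclasses.asdict(self.verdict),
            "rows": self.table.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2, default=float))
        return path


def run_sweep(tooth: ToothParams | LayeredToothModel,
              protocol: LoadProtocol | None = None,
              reductions=None,
              mesh_size: float | None = None,
              order: int = 2,
              calibrate_to: float | None = None,
              failure_threshold: float = 0.90,
              seed: int = 0) -> AttachmentSweepResult:
    """Run the attachment-loss sweep for one tooth.

    Parameters
    ----------
    tooth : tooth parameters (or a pre-built full-support model)
    protocol : occlusal load ramp; default :class:`LoadProtocol`
    reductions : strictly increasing attachment reductions in mm starting
        at 0; default 0..9 in 1 mm steps (clipped below root length)
    mesh_size : target element size in mm; the default (0.95 mm for
        single-rooted, 1.15 mm for the larger multi-rooted domain) gives
        both classes a comparable element budget (~35-40k full-model
        equivalent quadratic tets)
    calibrate_to : if given, scale the load so the full-support peak PDL
        pressure equals this anchor (MPa) before sweeping
    failure_threshold : peak-pressure failure criterion in MPa
    seed : recorded in the metadata; the pipeline itself is deterministic
    """
    model0 = tooth if isinstance(tooth, LayeredToothModel) else build_tooth(tooth)
    params = model0.params
    if mesh_size is None:
        mesh_size = 1.15 if params.tooth_class == "multi_rooted" else 0.95
    protocol = protocol or LoadProtocol()
    if reductions is None:
        reductions = [float(r) for r in range(0, 10)
                      if r < params.root_length - 1.0]
    reductions = [float(r) for r in reductions]
    if reductions[0] != 0.0 or np.any(np.diff(reductions) <= 0):
        raise ValueError("reductions must increase strictly from 0")

    def solve_reduction(red: float):
        model = reduce_attachment(model0, red)
        mesh = generate_mesh(model, size=mesh_size, order=order)
        system = apply_supports(assemble(mesh), mesh, "outer_bone_boundary")
        fld = solve_terminal(system, protocol)
        return model, mesh, fld

    # calibration against the full-support baseline (linear model: a pure
    # load scaling, no re-solve needed)
    scale = 1.0
    base = solve_reduction(0.0)
    if calibrate_to is not None:
        p0 = contact_pressure(base[2], base[1]).peak
        scale = calibrate_to / p0
        protocol = protocol.scaled(scale)
        base = (base[0], base[1], base[2].scaled(scale))
        base[2].load_fraction = 1.0

    rows, summaries, mesh_hashes = [], {}, {}
    peaks, solver_failed_flags, seen_reductions = [], [], []
    failures = 0
    for red in reductions:
        if failures >= 2:
            rows.append(dict.fromkeys(_ROW_COLUMNS, np.nan)
                        | {"reduction_mm": red, "evaluated": False,
                           "solver_failed": False})
            continue
        unsupported = (params.crest_offset + red
                       > params.root_length - max(mesh_size, 1.0))
        row = {"reduction_mm": red,
               "applied_resultant_N": float(np.hypot(*protocol.terminal_force)),
               "evaluated": True, "solver_failed": False}
        if unsupported:
            row |= {"solver_failed": True}
            peaks.append(None)
            solver_failed_flags.append(True)
            seen_reductions.append(red)
            failures += 1
            rows.append({c: row.get(c, np.nan) for c in _ROW_COLUMNS})
            continue
        try:
            model, mesh, fld = base if red == 0.0 else solve_reduction(red)
            pmap = contact_pressure(fld, mesh)
            summary = regional_summary(pmap, model)
            t = summary.table
            row |= {
                "peak_pdl_pressure_MPa": pmap.peak,
                "p99_pdl_pressure_MPa": pmap.p99,
                "mean_pdl_pressure_MPa": pmap.area_weighted_mean,
                "interface_area_mm2": float(pmap.areas.sum()
                                            * mesh.symmetry_factor),
                "cervical_peak_MPa": summary.peak("cervical"),
                "mid_root_peak_MPa": summary.peak("mid_root"),
                "apical_peak_MPa": summary.peak("apical"),
                "furcation_roof_peak_MPa": (
                    summary.peak("furcation_roof")
                    if "furcation_roof" in t.index else np.nan),
                "apical_load_share": summary.load_share("apical"),
                "transmitted_load_error":
                    pmap.transmitted_load_error(fld.applied_force),
                "equilibrium_rel_error": fld.equilibrium_rel_error,
                "linearity_rel_error": fld.linearity_rel_error,
            }
            summaries[red] = summary
            mesh_hashes[red] = mesh.content_hash()
            peaks.append(pmap.peak)
            solver_failed_flags.append(False)
            if pmap.peak > failure_threshold:
                failures += 1
        except SolverError:
            row |= {"solver_failed": True}
            peaks.append(None)
            solver_failed_flags.append(True)
            failures += 1
        seen_reductions.append(red)
        rows.append({c: row.get(c, np.nan) for c in _ROW_COLUMNS})

    table = pd.DataFrame(rows, columns=_ROW_COLUMNS)
    verdict = detect_failure(seen_reductions, peaks,
                             threshold=failure_threshold,
                             solver_failed=solver_failed_flags)
    metadata = {
        "tooth_params": dataclasses.asdict(params),
        "attachment_step_mm": float(np.diff(reductions).min())
        if len(reductions) > 1 else None,
        "protocol": dataclasses.asdict(protocol),
        "calibrate_to_MPa": calibrate_to,
        "calibration_scale": scale,
        "failure_threshold_MPa": failure_threshold,
        "mesh_size_mm": mesh_size,
        "element_order": order,
        "mesh_hashes": {str(k): v for k, v in mesh_hashes.items()},
        "materials": material_table().to_dict(orient="records"),
        "seed": seed,
        "software_version": __version__,
    }
    return AttachmentSweepResult(table=table, verdict=verdict,
                                 summaries=summaries, metadata=metadata)


# ---------------------------------------------------------------------------
# class comparison

@dataclass
class ClassComparison:
    """Side-by-side view of two sweeps (conventionally single vs multi)."""

    table: pd.DataFrame
    failure_first: float
    failure_second: float
    ordering_margin: float       # failure_second - failure_first
    normalized_curves: pd.DataFrame

    @property
    def second_fails_no_earlier(self) -> bool:
        return self.ordering_margin >= 0.0


def compare_tooth_classes(single: AttachmentSweepResult,
                          multi: AttachmentSweepResult) -> ClassComparison:
    """Compare failure thresholds and normalized escalation curves.

    Both sweeps must share the load calibration mode; the expected
    clinical ordering is that the multi-rooted tooth fails no earlier
    than the single-rooted one.
    """
    cal_a = single.metadata.get("calibrate_to_MPa")
    cal_b = multi.metadata.get("calibrate_to_MPa")
    if (cal_a is None) != (cal_b is None):
        raise ValueError("incompatible calibrations: one sweep is "
                         "pressure-anchored, the other is not")
    curves = []
    for label, res in (("first", single), ("second", multi)):
        ev = res.evaluated.dropna(subset=["peak_pdl_pressure_MPa"])
        base = ev["peak_pdl_pressure_MPa"].iloc[0]
        curves.append(pd.DataFrame({
            "class": label,
            "reduction_mm": ev["reduction_mm"],
            "peak_MPa": ev["peak_pdl_pressure_MPa"],
            "normalized_peak": ev["peak_pdl_pressure_MPa"] / base,
        }))
    f1, f2 = single.failure_reduction, multi.failure_reduction
    margin = 0.0 if f1 == f2 else f2 - f1
    table = pd.DataFrame({
        "class": ["first", "second"],
        "failure_reduction_mm": [f1, f2],
        "baseline_peak_MPa": [c["peak_MPa"].iloc[0] for c in curves],
    })
    return ClassComparison(table=table, failure_first=f1, failure_second=f2,
                           ordering_margin=margin,
                           normalized_curves=pd.concat(curves,
                                                       ignore_index=True))


# ---------------------------------------------------------------------------
# plots

def plot_pressure_surface(result: AttachmentSweepResult, outdir,
                          n_force_steps: int | None = None
                          ) -> dict[str, Path]:
    """Peak PDL pressure versus (applied force, attachment reduction).

    Writes a line/surface figure and a CSV twin of the plotted data.
    The per-reduction force dependence is the exact linear ramp of the
    solve, sampled at the protocol's step count.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ev = result.evaluated.dropna(subset=["peak_pdl_pressure_MPa"])
    if len(ev) < 2:
        raise ValueError("need at least two evaluated reductions to plot")
    n_steps = n_force_steps or result.metadata["protocol"]["n_steps"]
    fractions = np.arange(1, n_steps + 1) / n_steps

    records = []
    for _, row in ev.iterrows():
        for fr in fractions:
            records.append({
                "reduction_mm": row["reduction_mm"],
                "applied_resultant_N": row["applied_resultant_N"] * fr,
                "peak_pdl_pressure_MPa": row["peak_pdl_pressure_MPa"] * fr,
            })
    data = pd.DataFrame(records)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "pressure_surface.csv"
    data.to_csv(csv_path, index=False)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
    for red, grp in data.groupby("reduction_mm"):
        ax1.plot(grp["applied_resultant_N"], grp["peak_pdl_pressure_MPa"],
                 label=f"{red:g} mm")
    ax1.set_xlabel("applied resultant force (N)")
    ax1.set_ylabel("peak PDL pressure (MPa)")
    ax1.legend(title="attachment loss", fontsize=7)
    ax2.plot(ev["reduction_mm"], ev["peak_pdl_pressure_MPa"], "o-")
    ax2.axhline(result.verdict.threshold_MPa, ls="--", c="r",
                label=f"failure {result.verdict.threshold_MPa:g} MPa")
    ax2.set_xlabel("attachment reduction (mm)")
    ax2.set_ylabel("peak PDL pressure at terminal load (MPa)")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    png_path = outdir / "pressure_surface.png"
    fig.savefig(png_path, dpi=110)
    plt.close(fig)
    return {"csv": csv_path, "png": png_path}
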