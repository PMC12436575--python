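"""End-to-end campaign orchestration.

One campaign runs, for every pore band and seed:

    generate porosity -> mesh -> constrained swelling (interface load)
    -> gated ingrowth -> compression stiffness pre/post
    -> push-out pre/post

and collects per-run metrics in tidy tables.  All randomness flows from the
config seeds, so two runs of the same config produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .fem_core import MaterialState
from .ingrowth import IngrowthHistory, density_to_modulus, run_ingrowth
from .mechanics import compression_stiffness, pushout
from .porous_geometry import (VOID, extract_anchor_submesh,
                              generate_porous_domain, mesh_domain)
from .swelling import (average_radial_stress, default_material,
                       simulate_constrained_swelling)
from .vtkio import write_vtk

__all__ = ["StageResult", "CampaignReport", "run_single", "run_campaign"]


@dataclass
class StageResult:
    """All artefacts of one generate->swell->ingrow->characterize pipeline."""

    band_um: tuple
    seed: int
    domain: object
    mesh: object
    submesh: object
    sigma_rr: float            # mean radial interface stress, MPa (signed)
    interface_area: float
    history: IngrowthHistory
    stiffness_pre: float
    stiffness_post: float
    pushout_pre: float
    pushout_post: float

    def metrics_row(self) -> dict:
        h = self.history
        last = h.iterations[-1] if len(h.iterations) else 0
        return {
            "pore_mean_um": self.band_um[0],
            "seed": self.seed,
            "porosity": self.domain.achieved_porosity,
            "sigma_rr_MPa": self.sigma_rr,
            "iterations": int(last),
            "grown_count": int(h.grown_count[-1]) if len(h.iterations) else 0,
            "depth_mm": float(h.depth_mm[-1]) if len(h.iterations) else 0.0,
            "filled_volume_ratio": float(h.filled_volume_ratio[-1]) if len(h.iterations) else 0.0,
            "added_mass_g": float(h.added_mass_g[-1]) if len(h.iterations) else 0.0,
            "stiffness_pre_MPa": self.stiffness_pre,
            "stiffness_post_MPa": self.stiffness_post,
            "pushout_pre_N": self.pushout_pre,
            "pushout_post_N": self.pushout_post,
        }


def _post_density_on_full_mesh(mesh, submesh, history) -> np.ndarray:
    rho_full = np.where(mesh.region == VOID, 0.01, 0.8)
    rho_full[mesh.region == 0] = 1.2  # anchor co-polymer
    rho_full[submesh.parent_elems] = history.rho_final
    return rho_full


def run_single(cfg: RunConfig, band: tuple[float, float], seed: int,
               alpha: float | None = None,
               iterations: int | None = None) -> StageResult:
    """Run the full pipeline for one pore band and seed."""
    spec = cfg.pore_spec(band, seed)
    domain = generate_porous_domain(
        spec, cfg.anchor_radius, cfg.slice_thickness, cfg.bone_layer, dim=cfg.dim)
    mesh = mesh_domain(domain, cfg.element_size)

    swell_sol = simulate_constrained_swelling(mesh, cfg.swelling)
    iface = average_radial_stress(swell_sol)
    sigma = iface.mean_radial_stress
    load = cfg.load_pressure if cfg.load_pressure is not None else abs(sigma)

    sub = extract_anchor_submesh(mesh)
    params = cfg.remodeling
    over = {}
    if alpha is not None:
        over["alpha_gate"] = alpha
    if iterations is not None:
        over["max_iterations"] = iterations
    if over:
        params = dataclasses.replace(params, **over)
    history = run_ingrowth(sub, load, params)

    mat_pre = default_material(sub, cfg.swelling)
    E_post = mat_pre.elastic_modulus.copy()
    void = sub.region == VOID
    E_post[void] = density_to_modulus(history.rho_final[void])
    mat_post = MaterialState(history.rho_final, E_post, mat_pre.poisson_ratio)
    k_pre = compression_stiffness(sub, mat_pre)
    k_post = compression_stiffness(sub, mat_post)

    rho_pre_full = _post_density_on_full_mesh(
        mesh, sub, IngrowthHistory(rho_final=history.rho_initial))
    rho_post_full = _post_density_on_full_mesh(mesh, sub, history)
    rho_init_full = rho_pre_full.copy()
    po_pre = pushout(mesh, rho_pre_full, load, cfg.friction_mu, cfg.jc,
                     cfg.pushout_displacement, mode="pre",
                     rho_initial=rho_init_full)
    po_post = pushout(mesh, rho_post_full, load, cfg.friction_mu, cfg.jc,
                      cfg.pushout_displacement, mode="post",
                      rho_initial=rho_init_full)

    return StageResult(
        band_um=band, seed=seed, domain=domain, mesh=mesh, submesh=sub,
        sigma_rr=sigma, interface_area=iface.interface_area,
        history=history, stiffness_pre=k_pre, stiffness_post=k_post,
        pushout_pre=po_pre.peak_force, pushout_post=po_post.peak_force,
    )


@dataclass
class CampaignReport:
    """Tabular summary of a campaign: one row per (pore band, seed)."""

    metrics: pd.DataFrame
    per_iteration: pd.DataFrame
    config: RunConfig

    def summary(self) -> str:
        lines = ["osteogrow campaign summary", "=" * 40]
        for _, row in self.metrics.iterrows():
            lines.append(
                f"pore {row.pore_mean_um:.0f} um seed {int(row.seed)}: "
                f"porosity {row.porosity:.3f}, sigma_rr {row.sigma_rr_MPa:+.2f} MPa, "
                f"depth {row.depth_mm:.2f} mm, fill {100 * row.filled_volume_ratio:.1f}%, "
                f"added mass {row.added_mass_g * 1e3:.2f} mg, "
                f"stiffness {row.stiffness_pre_MPa:.0f}->{row.stiffness_post_MPa:.0f} MPa, "
                f"push-out {row.pushout_pre_N:.0f}->{row.pushout_post_N:.0f} N"
            )
        return "\n".join(lines)


def run_campaign(cfg: RunConfig, outdir=None, dry_run: bool = False) -> CampaignReport | None:
    """Execute the campaign; write CSV/JSON (and optional VTK) artefacts."""
    cfg.to_dict()  # validates serializability
    if dry_run:
        return None
    rows, iter_rows = [], []
    out = Path(outdir if outdir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for band in cfg.pore_bands_um:
        for seed in cfg.seeds:
            res = run_single(cfg, tuple(band), int(seed),
                             iterations=cfg.ingrowth_iterations)
            rows.append(res.metrics_row())
            h = res.history
            for j, it in enumerate(h.iterations):
                iter_rows.append({
                    "pore_mean_um": band[0], "seed": seed, "iteration": int(it),
                    "grown_count": int(h.grown_count[j]),
                    "depth_mm": float(h.depth_mm[j]),
                    "filled_volume_ratio": float(h.filled_volume_ratio[j]),
                    "added_mass_g": float(h.added_mass_g[j]),
                    "eligible_count": int(h.eligible_count[j]),
                    "max_rel_change": float(h.max_rel_change[j]),
                })
            if cfg.write_vtk:
                write_vtk(out / f"density_p{band[0]:.0f}_s{seed}.vtk",
                          res.submesh,
                          cell_data={"region": res.submesh.region,
                                     "density": h.rho_final})
            np.savetxt(out / f"pores_p{band[0]:.0f}_s{seed}.csv",
                       res.domain.pores, delimiter=",",
                       header="x_mm,y_mm,diameter_mm", comments="")
    metrics = pd.DataFrame(rows)
    per_iter = pd.DataFrame(iter_rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    per_iter.to_csv(out / "per_iteration.csv", index=False)
    report = CampaignReport(metrics=metrics, per_iteration=per_iter, config=cfg)
    with open(out / "summary.json", "w") as f:
        json.dump({"config": cfg.to_dict(),
                   "metrics": metrics.to_dict(orient="records")}, f, indent=2)
    (out / "summary.txt").write_text(report.summary() + "\n")
    return report
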