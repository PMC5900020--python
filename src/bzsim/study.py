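"""The border-zone representation study: 12 configurations, maps, summaries.

The border zone (BZ) is represented by combining three cellular APD variants
(normal, longer = g_Ks x0.5, shorter = g_Ks x2.0) with four conductivity /
fiber columns:

    normal_anisotropic + horizontal fibers
    decreased_transverse + horizontal fibers
    decreased_transverse + random fibers
    decreased_isotropic + horizontal fibers

Healthy tissue always has normal anisotropic conductivity, control cell
parameters and fibers along x.  Each configuration is paced five beats at a
500 ms cycle length from the pre-paced single-cell state; activation,
repolarization and repolarization-gradient maps are extracted from the final
beat.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CONDUCTIVITY_SETS
from .cell import make_variant, pace_to_steady_state
from .fem import ConductivityField
from .geometry import (BORDER_ZONE, GeometryConfig, TissueMesh, assign_fibers,
                       build_mesh, place_stimulus)
from .maps import (activation_times, gradient_summary, max_near_interface,
                   repolarization_gradient, repolarization_times)
from .solver import TissueParams, find_tissue_threshold, run_simulation

APD_VARIANTS = {"normal": "control", "longer": "longer_apd",
                "shorter": "shorter_apd"}

# Figure layout: columns are conductivity/fiber combinations, rows APD
_COLUMNS = (
    ("normal_anisotropic", "horizontal"),
    ("decreased_transverse", "horizontal"),
    ("decreased_transverse", "random"),
    ("decreased_isotropic", "horizontal"),
)


@dataclass(frozen=True)
class BZConfiguration:
    """One computational representation of the border zone."""

    apd_variant: str = "normal"
    conductivity_mode: str = "normal_anisotropic"
    bz_fiber_mode: str = "horizontal"
    smooth_transition: float = 0.0   # conductivity ramp width, mm (0 = abrupt)
    random_seed: int = 0

    def __post_init__(self):
        if self.apd_variant not in APD_VARIANTS:
            raise ValueError(f"unknown APD variant {self.apd_variant!r}")
        if self.conductivity_mode not in CONDUCTIVITY_SETS:
            raise ValueError(
                f"unknown conductivity mode {self.conductivity_mode!r}")
        if self.bz_fiber_mode not in ("horizontal", "random"):
            raise ValueError(f"unknown fiber mode {self.bz_fiber_mode!r}")
        if (self.bz_fiber_mode == "random"
                and self.conductivity_mode != "decreased_transverse"):
            raise ValueError(
                "random fibers pair only with decreased_transverse")

    @property
    def name(self) -> str:
        n = f"{self.apd_variant}__{self.conductivity_mode}__{self.bz_fiber_mode}"
        if self.smooth_transition:
            n += f"__ramp{self.smooth_transition:g}"
        return n


def enumerate_configurations(random_seed: int = 0) -> list[BZConfiguration]:
    """The 12 BZ representations in figure order (rows: normal, longer,
    shorter APD; columns: the four conductivity/fiber combinations)."""
    return [BZConfiguration(apd_variant=apd, conductivity_mode=cond,
                            bz_fiber_mode=fib, random_seed=random_seed)
            for apd in ("normal", "longer", "shorter")
            for cond, fib in _COLUMNS]


def apply_bz_properties(mesh: TissueMesh, config: BZConfiguration):
    """Per-element conductivities and per-node g_Ks scaling for a
    configuration.

    Healthy elements get normal anisotropic conductivity and control cell
    parameters; BZ elements get the configured conductivity set, and
    BZ nodes (majority of incident elements) the variant g_Ks scale.
    """
    sl_n, st_n = CONDUCTIVITY_SETS["normal_anisotropic"]
    sl_bz, st_bz = CONDUCTIVITY_SETS[config.conductivity_mode]
    bz = mesh.region == BORDER_ZONE
    sigma_l = np.where(bz, sl_bz, sl_n)
    sigma_t = np.where(bz, st_bz, st_n)
    cond = ConductivityField(sigma_l, sigma_t)
    if config.smooth_transition:
        cond = apply_smooth_transition(cond, mesh, config.smooth_transition)

    gks_bz = make_variant(APD_VARIANTS[config.apd_variant]).gKs_scale
    node_gks = np.where(mesh.node_region() == BORDER_ZONE, gks_bz, 1.0)
    return cond, node_gks


def apply_smooth_transition(conductivity: ConductivityField, mesh: TissueMesh,
                            width: float) -> ConductivityField:
    """Ramp sigma_t linearly from the healthy value at the BZ/healthy
    interface down to the BZ value over ``width`` mm (radially inward)."""
    bz_thick = mesh.bz_outer_radius - mesh.scar_radius
    if width > bz_thick + 1e-9:
        raise ValueError(
            f"ramp width {width} mm exceeds BZ thickness {bz_thick} mm")
    if width <= 0:
        return conductivity
    _, st_healthy = CONDUCTIVITY_SETS["normal_anisotropic"]
    r = np.linalg.norm(mesh.element_centroids() - mesh.center, axis=1)
    inner = mesh.bz_outer_radius - width
    frac = np.clip((r - inner) / width, 0.0, 1.0)
    in_bz = mesh.region == BORDER_ZONE
    st = conductivity.sigma_t.copy()
    ramp = in_bz & (r >= inner)
    st[ramp] = st[ramp] + frac[ramp] * (st_healthy - st[ramp])
    return ConductivityField(conductivity.sigma_l.copy(), st)


@dataclass
class StudyResult:
    summary: pd.DataFrame
    maps: dict              # config name -> dict(at, rt, grad, record meta)
    failures: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def run_study(configs=None, geometry_config: GeometryConfig | None = None,
              tissue_params: TissueParams | None = None,
              output_dir=None, stimulus_radius: float = 0.5,
              prepace_beats: int = 100, keep_records: bool = False,
              thresholds=(3.2, 5.0)) -> StudyResult:
    """Run the configuration sweep and collect maps and gradient summaries.

    Cell pre-pacing is cached per APD variant.  The tissue stimulus
    amplitude is twice the diastolic threshold found once on the
    normal-conductivity sheet and held identical across configurations.
    Failures are recorded per configuration and do not stop the sweep.
    """
    configs = configs if configs is not None else enumerate_configurations()
    geo = geometry_config or GeometryConfig(resolution=0.15)
    tp = tissue_params or TissueParams(dt=0.1, n_ionic_substeps=2)

    base_mesh = place_stimulus(build_mesh(geo), stimulus_radius)

    states = {}
    for apd, variant in APD_VARIANTS.items():
        states[apd] = pace_to_steady_state(make_variant(variant),
                                           tp.cycle_length, prepace_beats)

    # stimulus: 2x tissue diastolic threshold on the normal sheet
    cond0, gks0 = apply_bz_properties(
        base_mesh, BZConfiguration())
    thr = find_tissue_threshold(base_mesh, cond0, tp, states["normal"], gks0)
    tp = replace(tp, stimulus_amplitude=2.0 * thr)

    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    rows = []
    maps = {}
    failures = {}
    for config in configs:
        t0 = time.time()
        try:
            mesh = assign_fibers(base_mesh, config.bz_fiber_mode,
                                 config.random_seed)
            cond, node_gks = apply_bz_properties(mesh, config)
            rec = run_simulation(mesh, cond, tp, states[config.apd_variant],
                                 gks_scale=node_gks)
            at = activation_times(rec)
            rt = repolarization_times(rec, activation=at)
            grad = repolarization_gradient(mesh, rt)
            summ = gradient_summary(grad, mesh, thresholds)
            summ.insert(0, "configuration", config.name)
            summ["max_grad_bz_edge"] = max_near_interface(grad, mesh)
            summ["max_activation_time"] = float(np.nanmax(at.values))
            summ["conduction_failure"] = rec.conduction_failure
            summ["elapsed_s"] = time.time() - t0
            rows.append(summ)
            entry = {"at": at, "rt": rt, "grad": grad, "mesh": mesh,
                     "config": config}
            if keep_records:
                entry["record"] = rec
            maps[config.name] = entry
            if out is not None:
                from .io import write_node_map, write_vtk
                write_node_map(out / f"{config.name}_at.txt", at)
                write_node_map(out / f"{config.name}_rt.txt", rt)
                write_node_map(out / f"{config.name}_grad.txt", grad)
                write_vtk(out / f"{config.name}.vtk", mesh,
                          point_data={"activation_ms": at.values,
                                      "repolarization_ms": rt.values,
                                      "gradient_ms_per_mm": grad.values})
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            failures[config.name] = repr(exc)

    summary = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame())
    meta = {"resolution": geo.resolution, "dt": tp.dt,
            "n_ionic_substeps": tp.n_ionic_substeps,
            "stimulus_amplitude": tp.stimulus_amplitude,
            "n_beats": tp.n_beats, "prepace_beats": prepace_beats,
            "n_nodes": base_mesh.n_nodes}
    if out is not None and len(summary):
        summary.to_csv(out / "summary.csv", index=False)
    return StudyResult(summary=summary, maps=maps, failures=failures,
                       meta=meta)
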