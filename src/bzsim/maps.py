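"""Activation/repolarization maps and repolarization-gradient statistics.

Activation time is the first upward crossing of -20 mV after the analysed
beat's stimulus onset; repolarization time is the first downward crossing of
-70 mV after that node's activation.  Crossings are refined by linear
interpolation between output samples.  The repolarization gradient is the
magnitude of the spatial gradient of repolarization time: constant per
linear triangle, averaged to nodes with area weights (exact for linear
fields).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import _shape_gradients
from .geometry import BORDER_ZONE, HEALTHY, TissueMesh
from .solver import VoltageRecord

ACTIVATION_THRESHOLD = -20.0   # mV
REPOLARIZATION_THRESHOLD = -70.0  # mV


@dataclass
class ScalarNodeMap:
    """Per-node scalar field with a validity mask (True = defined)."""

    values: np.ndarray
    mask: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)
    element_values: np.ndarray | None = None
    element_mask: np.ndarray | None = None

    def defined(self) -> np.ndarray:
        return self.values[self.mask]


def _beat_window(record: VoltageRecord, beat: int):
    onset = record.beat_onsets[beat]
    if beat in (-1, len(record.beat_onsets) - 1):
        sel = record.time >= onset - 1e-9
    else:
        nxt = record.beat_onsets[beat + 1]
        sel = (record.time >= onset - 1e-9) & (record.time < nxt)
    return record.time[sel] - onset, record.V[sel]


def activation_times(record: VoltageRecord,
                     threshold: float = ACTIVATION_THRESHOLD,
                     beat: int = -1) -> ScalarNodeMap:
    """First upward threshold crossing per node, in ms from the analysed
    beat's stimulus onset; nodes that never cross are masked."""
    t, V = _beat_window(record, beat)
    above = V >= threshold
    cross = ~above[:-1] & above[1:]
    has = cross.any(axis=0)
    k = np.argmax(cross, axis=0)
    idx = np.arange(V.shape[1])
    v0 = V[k, idx].astype(float)
    v1 = V[k + 1, idx].astype(float)
    frac = np.where(v1 > v0, (threshold - v0) / np.where(v1 > v0, v1 - v0, 1.0),
                    0.0)
    at = t[k] + frac * (t[k + 1] - t[k])
    at = np.where(above[0], 0.0, at)
    mask = has | above[0]
    at = np.where(mask, at, np.nan)
    return ScalarNodeMap(values=at, mask=mask, units="ms",
                         meta={"threshold": threshold, "beat": beat})


def repolarization_times(record: VoltageRecord,
                         threshold: float = REPOLARIZATION_THRESHOLD,
                         beat: int = -1,
                         activation: ScalarNodeMap | None = None
                         ) -> ScalarNodeMap:
    """First downward threshold crossing after each node's activation."""
    if activation is None:
        activation = activation_times(record, beat=beat)
    t, V = _beat_window(record, beat)
    at = np.where(activation.mask, activation.values, np.inf)
    above = V > threshold
    down = above[:-1] & ~above[1:]
    allowed = down & (t[:-1, None] >= at[None, :] - 1e-9)
    has = allowed.any(axis=0)
    k = np.argmax(allowed, axis=0)
    idx = np.arange(V.shape[1])
    v0 = V[k, idx].astype(float)
    v1 = V[k + 1, idx].astype(float)
    denom = np.where(v0 > v1, v0 - v1, 1.0)
    rt = t[k] + (v0 - threshold) / denom * (t[k + 1] - t[k])
    mask = has & activation.mask
    rt = np.where(mask, rt, np.nan)
    return ScalarNodeMap(values=rt, mask=mask, units="ms",
                         meta={"threshold": threshold, "beat": beat})


def repolarization_gradient(mesh: TissueMesh,
                            rt: ScalarNodeMap) -> ScalarNodeMap:
    """Magnitude of the spatial gradient of repolarization time (ms/mm).

    The gradient is constant on each linear triangle; node values are the
    area-weighted average over incident elements.  Elements touching a
    masked node are masked, and masking propagates to nodes all of whose
    incident elements are masked.
    """
    b, c, area = _shape_gradients(mesh)
    vals = np.where(rt.mask, rt.values, 0.0)
    ue = vals[mesh.triangles]
    gx = (ue * b).sum(axis=1)
    gy = (ue * c).sum(axis=1)
    gmag = np.hypot(gx, gy)
    e_ok = rt.mask[mesh.triangles].all(axis=1)
    gmag = np.where(e_ok, gmag, np.nan)

    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    w = np.where(e_ok, area, 0.0)
    for k in range(3):
        np.add.at(num, mesh.triangles[:, k], w * np.nan_to_num(gmag))
        np.add.at(den, mesh.triangles[:, k], w)
    mask = den > 0
    node_vals = np.where(mask, num / np.where(mask, den, 1.0), np.nan)
    return ScalarNodeMap(values=node_vals, mask=mask, units="ms/mm",
                         meta=dict(rt.meta), element_values=gmag,
                         element_mask=e_ok)


def gradient_summary(grad: ScalarNodeMap, mesh: TissueMesh,
                     thresholds=(3.2, 5.0)) -> pd.DataFrame:
    """Per-region maximum gradient and threshold-exceedance areas.

    Areas (mm^2) are accumulated from elements whose (constant) gradient
    magnitude exceeds each threshold; maxima are over node values.  Regions
    are healthy, border_zone and all surviving tissue.
    """
    if grad.element_values is None or grad.element_mask is None:
        raise ValueError("gradient map lacks element-level values")
    areas = mesh.element_areas()
    node_region = mesh.node_region()
    rows = []
    regions = [("healthy", mesh.region == HEALTHY, node_region == HEALTHY),
               ("border_zone", mesh.region == BORDER_ZONE,
                node_region == BORDER_ZONE),
               ("all", np.ones(mesh.n_elems, bool),
                np.ones(mesh.n_nodes, bool))]
    for name, esel, nsel in regions:
        esel = esel & grad.element_mask
        nsel = nsel & grad.mask
        row = {"region": name, "area_mm2": float(areas[esel].sum())}
        if not nsel.any():
            warnings.warn(f"region {name!r} has no defined nodes")
            row["max_gradient"] = 0.0
        else:
            row["max_gradient"] = float(np.nanmax(grad.values[nsel]))
        for thr in thresholds:
            if esel.any():
                exceed = esel & (grad.element_values > thr)
                a = float(areas[exceed].sum())
                frac = a / row["area_mm2"] if row["area_mm2"] > 0 else 0.0
            else:
                a, frac = 0.0, 0.0
            row[f"area_gt_{thr:g}"] = a
            row[f"frac_gt_{thr:g}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)


def max_near_interface(grad: ScalarNodeMap, mesh: TissueMesh,
                       band: float | None = None) -> float:
    """Maximum node gradient within ``band`` mm of the BZ/healthy interface
    (default: one BZ thickness)."""
    if band is None:
        band = mesh.bz_outer_radius - mesh.scar_radius
    r = np.linalg.norm(mesh.nodes - mesh.center, axis=1)
    sel = (np.abs(r - mesh.bz_outer_radius) <= band) & grad.mask
    if not sel.any():
        raise ValueError("no defined nodes near the BZ interface")
    return float(np.nanmax(grad.values[sel]))
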