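"""Plain-text exporters: legacy-ASCII VTK unstructured grids and node tables."""

from __future__ import annotations

import numpy as np

from .geometry import TissueMesh


def write_vtk(path, mesh: TissueMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid with region/fiber cell data."""
    cell_data = {"region": mesh.region.astype(float),
                 "fiber_angle": mesh.fiber_angle, **(cell_data or {})}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n"
                 "bzsim tissue\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.6g} {y:.6g} 0\n")
        fh.write(f"CELLS {mesh.n_elems} {4 * mesh.n_elems}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {mesh.n_elems}\n")
        fh.write("5\n" * mesh.n_elems)
        fh.write(f"CELL_DATA {mesh.n_elems}\n")
        for name, vals in cell_data.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.6g}" for v in vals) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, vals in point_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(
                    f"{v:.6g}" if np.isfinite(v) else "nan"
                    for v in vals) + "\n")


def write_mesh_text(node_path, elem_path, mesh: TissueMesh) -> None:
    """Plain-text mesh: one node per line 'x y'; one element per line
    'n1 n2 n3 region angle'."""
    with open(node_path, "w") as fh:
        for x, y in mesh.nodes:
            fh.write(f"{x:.9g} {y:.9g}\n")
    with open(elem_path, "w") as fh:
        for (a, b, c), reg, ang in zip(mesh.triangles, mesh.region,
                                       mesh.fiber_angle):
            fh.write(f"{a} {b} {c} {reg} {ang:.9g}\n")


def write_node_map(path, node_map) -> None:
    """Plain-text 'node_index value' table; masked nodes write 'nan'."""
    with open(path, "w") as fh:
        fh.write(f"# units {node_map.units} meta {node_map.meta}\n")
        for i, (v, ok) in enumerate(zip(node_map.values, node_map.mask)):
            fh.write(f"{i} {v:.6g}\n" if ok else f"{i} nan\n")


def load_config(path=None) -> dict:
    """Load a structured study configuration (YAML).

    With no path, returns the shipped defaults
    (``bzsim/data/default_config.yaml``), which hold the study's geometry,
    membrane, tissue and conductivity settings.
    """
    import yaml

    if path is None:
        from importlib.resources import files
        text = (files("bzsim") / "data" / "default_config.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)
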