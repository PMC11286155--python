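"""Minimal ASCII VTK unstructured-grid (.vtu) export.

Writes tetrahedral meshes with cell data (region labels, von Mises
fields) and point data (node-set masks, displacements) for inspection in
ParaView.  Plain-text XML only; kept deliberately small since no VTK
binding is assumed at run time.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from .mesh import LabelledTetMesh


def _array_block(name: str, data: np.ndarray, indent: str) -> str:
    data = np.asarray(data)
    comps = 1 if data.ndim == 1 else data.shape[1]
    dtype = "Int64" if np.issubdtype(data.dtype, np.integer) else "Float64"
    body = " ".join(map(str, data.ravel()))
    return (
        f'{indent}<DataArray type="{dtype}" Name="{escape(name)}" '
        f'NumberOfComponents="{comps}" format="ascii">\n'
        f"{indent}  {body}\n{indent}</DataArray>\n"
    )


def write_vtu(
    mesh: LabelledTetMesh,
    path: str | Path,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    include_node_sets: bool = True,
) -> Path:
    """Write the mesh (plus optional fields) as an ASCII .vtu file.

    Region labels always go out as cell data (``region``); node sets are
    written as 0/1 point-data masks unless disabled.
    """
    path = Path(path)
    cell_data = dict(cell_data or {})
    point_data = dict(point_data or {})
    cell_data.setdefault("region", mesh.region.astype(np.int64))
    if include_node_sets:
        for name, idx in mesh.node_sets.items():
            mask = np.zeros(mesh.n_nodes, dtype=np.int64)
            mask[np.asarray(idx, dtype=int)] = 1
            point_data.setdefault(f"nodeset_{name}", mask)

    n, m = mesh.n_nodes, mesh.n_elements
    parts = [
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        "  <UnstructuredGrid>\n"
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n'
    ]
    parts.append("      <Points>\n")
    parts.append(_array_block("coordinates", mesh.nodes.astype(float), "        "))
    parts.append("      </Points>\n      <Cells>\n")
    parts.append(_array_block("connectivity", mesh.tets.astype(np.int64), "        "))
    parts.append(_array_block("offsets", 4 * np.arange(1, m + 1), "        "))
    parts.append(_array_block("types", np.full(m, 10, dtype=np.int64), "        "))
    parts.append("      </Cells>\n      <CellData>\n")
    for name, arr in cell_data.items():
        parts.append(_array_block(name, arr, "        "))
    parts.append("      </CellData>\n      <PointData>\n")
    for name, arr in point_data.items():
        parts.append(_array_block(name, arr, "        "))
    parts.append("      </PointData>\n    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")
    path.write_text("".join(parts))
    return path


def write_node_sets_json(mesh: LabelledTetMesh, path: str | Path) -> Path:
    """Plain JSON sidecar listing node-set indices."""
    path = Path(path)
    payload = {k: np.asarray(v, dtype=int).tolist() for k, v in mesh.node_sets.items()}
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_fields_vtu(mesh, fields, solution=None, path="fields.vtu"):
    """Export a solved run: von Mises cell data plus displacement point data."""
    cell = {
        "von_mises_stress_MPa": fields.vm_stress,
        "von_mises_strain_microstrain": fields.vm_strain,
    }
    point = {}
    if solution is not None:
        point["displacement_mm"] = solution.u
        point["reaction_N"] = solution.reactions
    return write_vtu(mesh, path, cell_data=cell, point_data=point,
                     include_node_sets=False)
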