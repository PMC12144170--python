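"""File export/import: VTK XML unstructured grids, volumes, surface meshes,
and an Abaqus-style .inp text subset.

The VTU writer/reader is a small, self-contained implementation of the VTK
XML unstructured-grid format (ASCII appended-free flavour): enough for
tetrahedral meshes with per-node / per-element fields, node-set masks and
the region legend, and it round-trips bitwise for integers and to full
double precision for floats.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .grids import LabelMap, VoxelVolume
from .meshing import TetMesh

_VTK_TET4 = 10
_VTK_TET10 = 24


def _fmt_floats(a: np.ndarray) -> str:
    return " ".join(np.format_float_scientific(v, precision=17) for v in a.ravel())


def _fmt_ints(a: np.ndarray) -> str:
    return " ".join(str(int(v)) for v in a.ravel())


def write_vtu(path, mesh: TetMesh, cell_fields: dict[str, np.ndarray] | None = None,
              point_fields: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh plus named per-element / per-node arrays as .vtu.

    Region ids go into the cell array ``region_id`` with the legend stored
    as a JSON field-data array; node sets become 0/1 point masks named
    ``nset:NAME``.
    """
    cell_fields = dict(cell_fields or {})
    point_fields = dict(point_fields or {})
    for name, arr in cell_fields.items():
        if np.asarray(arr).shape[0] != mesh.n_elements:
            raise ValueError(f"cell field {name!r} length does not match elements")
    for name, arr in point_fields.items():
        if np.asarray(arr).shape[0] != mesh.n_nodes:
            raise ValueError(f"point field {name!r} length does not match nodes")

    cell_fields.setdefault("region_id", mesh.element_label)
    for sname, ids in mesh.node_sets.items():
        mask = np.zeros(mesh.n_nodes, dtype=np.int64)
        mask[ids] = 1
        point_fields.setdefault(f"nset:{sname}", mask)

    npe = mesh.elements.shape[1]
    ctype = _VTK_TET4 if npe == 4 else _VTK_TET10

    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    ug = ET.SubElement(root, "UnstructuredGrid")
    fd = ET.SubElement(ug, "FieldData")
    legend_json = json.dumps({str(k): v for k, v in mesh.legend.items()},
                             sort_keys=True)
    legend_bytes = np.frombuffer(legend_json.encode(), dtype=np.uint8)
    arr = ET.SubElement(
        fd, "DataArray", type="UInt8", Name="legend_json", format="ascii",
        NumberOfTuples=str(legend_bytes.size),
    )
    arr.text = _fmt_ints(legend_bytes)
    meta = ET.SubElement(
        fd, "DataArray", type="Int64", Name="element_order", format="ascii",
        NumberOfTuples="1",
    )
    meta.text = str(mesh.element_order)

    piece = ET.SubElement(
        ug, "Piece", NumberOfPoints=str(mesh.n_nodes), NumberOfCells=str(mesh.n_elements)
    )
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64", NumberOfComponents="3",
                       format="ascii")
    da.text = _fmt_floats(mesh.nodes)

    cells = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(cells, "DataArray", type="Int64", Name="connectivity",
                         format="ascii")
    conn.text = _fmt_ints(mesh.elements)
    offs = ET.SubElement(cells, "DataArray", type="Int64", Name="offsets",
                         format="ascii")
    offs.text = _fmt_ints(np.arange(1, mesh.n_elements + 1) * npe)
    types = ET.SubElement(cells, "DataArray", type="UInt8", Name="types",
                          format="ascii")
    types.text = _fmt_ints(np.full(mesh.n_elements, ctype))

    pdata = ET.SubElement(piece, "PointData")
    for name, arrv in point_fields.items():
        _field_array(pdata, name, np.asarray(arrv))
    cdata = ET.SubElement(piece, "CellData")
    for name, arrv in cell_fields.items():
        _field_array(cdata, name, np.asarray(arrv))

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="unicode")


def _field_array(parent, name: str, arr: np.ndarray) -> None:
    ncomp = 1 if arr.ndim == 1 else int(np.prod(arr.shape[1:]))
    if np.issubdtype(arr.dtype, np.integer):
        el = ET.SubElement(parent, "DataArray", type="Int64", Name=name,
                           NumberOfComponents=str(ncomp), format="ascii")
        el.text = _fmt_ints(arr)
    else:
        el = ET.SubElement(parent, "DataArray", type="Float64", Name=name,
                           NumberOfComponents=str(ncomp), format="ascii")
        el.text = _fmt_floats(arr)


def read_vtu(path) -> tuple[TetMesh, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Read a .vtu written by :func:`write_vtu`.

    Returns ``(mesh, cell_fields, point_fields)``; node sets and the region
    legend are restored onto the mesh.
    """
    root = ET.parse(str(path)).getroot()
    ug = root.find("UnstructuredGrid")
    legend = {}
    element_order = 1
    fd = ug.find("FieldData")
    if fd is not None:
        for da in fd.findall("DataArray"):
            if da.get("Name") == "legend_json":
                raw = bytes(int(t) for t in da.text.split())
                legend = {int(k): v for k, v in json.loads(raw.decode()).items()}
            if da.get("Name") == "element_order":
                element_order = int(da.text.strip())
    piece = ug.find("Piece")
    nn = int(piece.get("NumberOfPoints"))
    ne = int(piece.get("NumberOfCells"))
    pts_text = piece.find("Points/DataArray").text
    nodes = np.array(pts_text.split(), dtype=float).reshape(nn, 3)

    arrays = {da.get("Name"): da for da in piece.find("Cells").findall("DataArray")}
    conn = np.array(arrays["connectivity"].text.split(), dtype=np.int64)
    offsets = np.array(arrays["offsets"].text.split(), dtype=np.int64)
    npe = int(offsets[0])
    elements = conn.reshape(ne, npe)

    def read_fields(tag):
        out = {}
        sec = piece.find(tag)
        if sec is None:
            return out
        for da in sec.findall("DataArray"):
            ncomp = int(da.get("NumberOfComponents", "1"))
            if da.get("type").startswith("Int") or da.get("type").startswith("UInt"):
                arr = np.array(da.text.split(), dtype=np.int64)
            else:
                arr = np.array(da.text.split(), dtype=float)
            if ncomp > 1:
                arr = arr.reshape(-1, ncomp)
            out[da.get("Name")] = arr
        return out

    point_fields = read_fields("PointData")
    cell_fields = read_fields("CellData")
    element_label = cell_fields.pop("region_id").astype(np.int32)
    node_sets = {}
    for name in list(point_fields):
        if name.startswith("nset:"):
            node_sets[name[5:]] = np.flatnonzero(point_fields.pop(name))
    mesh = TetMesh(
        nodes=nodes,
        elements=elements,
        element_label=element_label,
        legend=legend or {int(k): str(k) for k in np.unique(element_label)},
        element_order=element_order,
        node_sets=node_sets,
    )
    return mesh, cell_fields, point_fields


# ---------------------------------------------------------------------------
# Volumes: NIfTI and MetaImage
# ---------------------------------------------------------------------------


def write_nifti(path, volume: VoxelVolume | LabelMap) -> None:
    import nibabel as nib

    data = volume.values if isinstance(volume, VoxelVolume) else volume.labels
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_nifti(path) -> VoxelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = np.abs(np.diag(img.affine)[:3])
    origin = img.affine[:3, 3]
    return VoxelVolume(values=np.asarray(img.dataobj, dtype=float),
                       spacing=spacing, origin=origin)


def write_mhd(path, volume: VoxelVolume | LabelMap) -> None:
    """MetaImage header + raw little-endian data file."""
    path = Path(path)
    data = volume.values if isinstance(volume, VoxelVolume) else volume.labels
    arr = np.asarray(data)
    elt = "MET_DOUBLE" if np.issubdtype(arr.dtype, np.floating) else "MET_INT"
    raw_name = path.with_suffix(".raw").name
    dims = arr.shape
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 3",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            f"DimSize = {dims[0]} {dims[1]} {dims[2]}",
            f"ElementSpacing = {volume.spacing[0]} {volume.spacing[1]} {volume.spacing[2]}",
            f"Offset = {volume.origin[0]} {volume.origin[1]} {volume.origin[2]}",
            f"ElementType = {elt}",
            f"ElementDataFile = {raw_name}",
            "",
        ]
    )
    path.write_text(header)
    out = arr.astype("<f8" if elt == "MET_DOUBLE" else "<i4")
    # MetaImage stores x fastest; our arrays are (x, y, z) C-order (z fastest)
    out.T.tofile(path.with_suffix(".raw"))


# ---------------------------------------------------------------------------
# Abaqus-style .inp subset (NODE / ELEMENT / NSET / ELSET cards)
# ---------------------------------------------------------------------------


def write_inp(path, mesh: TetMesh) -> None:
    lines = ["*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {float(x)!r}, {float(y)!r}, {float(z)!r}")
    etype = "C3D4" if mesh.element_order == 1 else "C3D10"
    lines.append(f"*ELEMENT, TYPE={etype}")
    for e, conn in enumerate(mesh.elements, start=1):
        lines.append(f"{e}, " + ", ".join(str(int(c) + 1) for c in conn))
    for rid in np.unique(mesh.element_label):
        region = mesh.legend[int(rid)]
        ids = np.flatnonzero(mesh.element_label == rid) + 1
        lines.append(f"*ELSET, ELSET={region.upper()}")
        lines.extend(_card_rows(ids))
    for sname, ids in mesh.node_sets.items():
        lines.append(f"*NSET, NSET={sname}")
        lines.extend(_card_rows(np.asarray(ids) + 1))
    Path(path).write_text("\n".join(lines) + "\n")


def _card_rows(ids: np.ndarray, per_row: int = 12) -> list[str]:
    rows = []
    for start in range(0, len(ids), per_row):
        rows.append(", ".join(str(int(i)) for i in ids[start:start + per_row]))
    return rows


def read_inp(path) -> TetMesh:
    """Read the .inp subset written by :func:`write_inp`."""
    nodes: list[list[float]] = []
    elements: list[list[int]] = []
    elsets: dict[str, list[int]] = {}
    nsets: dict[str, list[int]] = {}
    mode = None
    current = None
    order = 1
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            card = line.upper()
            if card.startswith("*NODE"):
                mode = "node"
            elif card.startswith("*ELEMENT"):
                mode = "element"
                order = 2 if "C3D10" in card else 1
            elif card.startswith("*ELSET"):
                mode = "elset"
                current = line.split("=", 1)[1].strip()
                elsets[current] = []
            elif card.startswith("*NSET"):
                mode = "nset"
                current = line.split("=", 1)[1].strip()
                nsets[current] = []
            else:
                mode = None
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if mode == "node":
            nodes.append([float(p) for p in parts[1:4]])
        elif mode == "element":
            elements.append([int(p) - 1 for p in parts[1:]])
        elif mode == "elset":
            elsets[current].extend(int(p) - 1 for p in parts)
        elif mode == "nset":
            nsets[current].extend(int(p) - 1 for p in parts)
    elements_arr = np.asarray(elements, dtype=np.int64)
    label = np.zeros(elements_arr.shape[0], dtype=np.int32)
    legend = {}
    for rid, (name, ids) in enumerate(sorted(elsets.items())):
        legend[rid] = name.lower()
        label[np.asarray(ids, dtype=np.int64)] = rid
    if not legend:
        legend = {0: "solid"}
    return TetMesh(
        nodes=np.asarray(nodes, dtype=float),
        elements=elements_arr,
        element_label=label,
        legend=legend,
        element_order=order,
        node_sets={k: np.asarray(v, dtype=np.int64) for k, v in nsets.items()},
    )
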