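"""Surface and field readers/writers plus the 4D-sequence manifest.

Surfaces round-trip through STL (via trimesh, geometry only — named data
arrays are dropped with a warning) and through ASCII VTK XML polydata
(.vtp) written by a minimal in-repo serializer, since no VTK binding is a
dependency of this package.  Cartesian field frames go to VTK XML image
data (.vti).  A 4D sequence is one file per frame plus a JSON manifest
recording times, the grid spec and a connectivity checksum.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import trimesh

from .lv import Mesh4D
from .overset import CartesianGrid

__version__ = "0.1.0"


def _ascii(arr) -> str:
    return " ".join(f"{v:.17g}" for v in np.asarray(arr).ravel())


def write_surface(path, vertices: np.ndarray, faces: np.ndarray,
                  point_data: dict | None = None) -> None:
    """Write a triangulated surface as .stl (geometry only) or .vtp (with data)."""
    path = Path(path)
    if path.suffix.lower() == ".stl":
        if point_data:
            warnings.warn("STL carries no data arrays; dropping "
                          + ", ".join(point_data))
        trimesh.Trimesh(vertices, faces, process=False).export(path)
        return
    if path.suffix.lower() != ".vtp":
        raise ValueError(f"unsupported surface format: {path.suffix}")
    root = ET.Element("VTKFile", type="PolyData", version="0.1", byte_order="LittleEndian")
    pd = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(pd, "Piece", NumberOfPoints=str(len(vertices)),
                          NumberOfPolys=str(len(faces)))
    pts = ET.SubElement(piece, "Points")
    ET.SubElement(pts, "DataArray", type="Float64", NumberOfComponents="3",
                  format="ascii").text = _ascii(vertices)
    if point_data:
        pdata = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            ET.SubElement(pdata, "DataArray", type="Float64", Name=name,
                          NumberOfComponents=str(ncomp), format="ascii").text = _ascii(arr)
    polys = ET.SubElement(piece, "Polys")
    ET.SubElement(polys, "DataArray", type="Int64", Name="connectivity",
                  format="ascii").text = _ascii(faces)
    ET.SubElement(polys, "DataArray", type="Int64", Name="offsets",
                  format="ascii").text = _ascii(3 * (np.arange(len(faces)) + 1))
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_surface(path):
    """Read .stl or .vtp; returns (vertices, faces, point_data_dict)."""
    path = Path(path)
    if path.suffix.lower() == ".stl":
        # STL stores a triangle soup; merging duplicate vertices restores
        # shared connectivity
        m = trimesh.load(path, process=True)
        return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64), {}
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise ValueError(f"malformed VTK XML in {path}: {e}") from e
    piece = tree.find(".//Piece")
    if piece is None:
        raise ValueError(f"malformed VTK XML in {path}: no Piece element")

    def parse(el, dtype):
        return np.fromstring(el.text, sep=" ", dtype=dtype)

    pts_el = piece.find("Points/DataArray")
    verts = parse(pts_el, float).reshape(-1, 3)
    conn = None
    for da in piece.findall("Polys/DataArray"):
        if da.get("Name") == "connectivity":
            conn = parse(da, np.int64).reshape(-1, 3)
    if conn is None:
        raise ValueError(f"malformed VTK XML in {path}: element path Polys/DataArray"
                         "[Name=connectivity] missing")
    data = {}
    for da in piece.findall("PointData/DataArray"):
        arr = parse(da, float)
        nc = int(da.get("NumberOfComponents", "1"))
        data[da.get("Name")] = arr.reshape(-1, nc) if nc > 1 else arr
    return verts, conn, data


def write_image_data(path, grid: CartesianGrid, cell_data: dict) -> None:
    """ASCII VTK XML image data (.vti) with named cell arrays."""
    path = Path(path)
    nx, ny, nz = grid.dims
    root = ET.Element("VTKFile", type="ImageData", version="0.1", byte_order="LittleEndian")
    img = ET.SubElement(root, "ImageData",
                        WholeExtent=f"0 {nx} 0 {ny} 0 {nz}",
                        Origin=_ascii(grid.origin),
                        Spacing=f"{grid.spacing:.17g} {grid.spacing:.17g} {grid.spacing:.17g}")
    piece = ET.SubElement(img, "Piece", Extent=f"0 {nx} 0 {ny} 0 {nz}")
    cd = ET.SubElement(piece, "CellData")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 3 else arr.shape[-1]
        # VTK cell ordering is x-fastest
        flat = np.moveaxis(arr, (0, 1, 2), (2, 1, 0)).ravel() if arr.ndim == 3 else \
            np.moveaxis(arr, (0, 1, 2), (2, 1, 0)).reshape(-1, ncomp)
        ET.SubElement(cd, "DataArray", type="Float64", Name=name,
                      NumberOfComponents=str(ncomp), format="ascii").text = _ascii(flat)
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_image_data(path):
    """Read a .vti written by :func:`write_image_data`; returns (grid, cell_data)."""
    tree = ET.parse(path)
    img = tree.find(".//ImageData")
    ext = [int(v) for v in img.find("Piece").get("Extent").split()]
    dims = (ext[1] - ext[0], ext[3] - ext[2], ext[5] - ext[4])
    origin = tuple(float(v) for v in img.get("Origin").split())
    spacing = float(img.get("Spacing").split()[0])
    grid = CartesianGrid(origin, spacing, dims)
    data = {}
    for da in img.findall(".//CellData/DataArray"):
        arr = np.fromstring(da.text, sep=" ")
        nc = int(da.get("NumberOfComponents", "1"))
        if nc == 1:
            data[da.get("Name")] = np.moveaxis(arr.reshape(dims[::-1]), (0, 1, 2), (2, 1, 0))
        else:
            data[da.get("Name")] = np.moveaxis(
                arr.reshape(*dims[::-1], nc), (0, 1, 2), (2, 1, 0))
    return grid, data


def connectivity_checksum(faces: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(faces, dtype=np.int64).tobytes()).hexdigest()[:16]


def write_mesh4d(directory, mesh: Mesh4D, *, fmt: str = "vtp",
                 config_hash: str = "") -> Path:
    """One surface file per frame plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for k in range(mesh.n_frames):
        name = f"frame_{k:04d}.{fmt}"
        write_surface(directory / name, mesh.frames[k], mesh.connectivity)
        files.append(name)
    manifest = {
        "files": files,
        "times_s": mesh.times.tolist(),
        "connectivity_sha256_16": connectivity_checksum(mesh.connectivity),
        "software_version": __version__,
        "config_hash": config_hash,
        "cycle_duration_s": mesh.metadata.get("cycle_duration"),
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_mesh4d(manifest_path) -> Mesh4D:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    frames = []
    conn = None
    for name in manifest["files"]:
        fp = manifest_path.parent / name
        if not fp.exists():
            raise FileNotFoundError(f"manifest refers to a missing frame file: {name}")
        v, f, _ = read_surface(fp)
        frames.append(v)
        conn = f
    if connectivity_checksum(conn) != manifest["connectivity_sha256_16"]:
        raise ValueError("connectivity checksum mismatch against the manifest")
    md = {}
    if manifest.get("cycle_duration_s"):
        md["cycle_duration"] = manifest["cycle_duration_s"]
    return Mesh4D(np.stack(frames), conn, np.asarray(manifest["times_s"]), md)


def write_field_series(directory, field, *, config_hash: str = "") -> Path:
    """Velocity/mask frames as .vti files plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for k in range(field.n_frames):
        name = f"field_{k:04d}.vti"
        write_image_data(directory / name, field.grid,
                         {"velocity": field.velocity[k],
                          "in_domain": field.mask[k].astype(float)})
        files.append(name)
    manifest = {
        "files": files,
        "times_s": field.times.tolist(),
        "grid": {"origin_mm": list(field.grid.origin),
                 "spacing_mm": field.grid.spacing,
                 "dims": list(field.grid.dims)},
        "software_version": __version__,
        "config_hash": config_hash,
        "cycle_duration_s": field.metadata.get("cycle_duration"),
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_field_series(manifest_path):
    from .flow import FlowField
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    vels, masks = [], []
    grid = None
    for name in manifest["files"]:
        fp = manifest_path.parent / name
        if not fp.exists():
            raise FileNotFoundError(f"manifest refers to a missing frame file: {name}")
        grid, data = read_image_data(fp)
        vels.append(data["velocity"])
        masks.append(data["in_domain"] > 0.5)
    md = {}
    if manifest.get("cycle_duration_s"):
        md["cycle_duration"] = manifest["cycle_duration_s"]
    return FlowField(grid, np.asarray(manifest["times_s"]), np.stack(vels),
                     np.stack(masks), metadata=md)


def write_field_csv(path, field, frame: int = 0) -> None:
    """Compact CSV export (cell index, u, v, w) for small grids."""
    import pandas as pd
    v = field.velocity[frame].reshape(-1, 3)
    df = pd.DataFrame({"cell": np.arange(len(v)), "u": v[:, 0], "v": v[:, 1], "w": v[:, 2]})
    df.to_csv(path, index=False)


def write_stencils_csv(path, interface) -> None:
    """Interface stencils as CSV: receptor index triple, 8 donor triples, 8 weights."""
    import pandas as pd
    rows = {}
    for ax, name in enumerate("ijk"):
        rows[f"receptor_{name}"] = interface.receptor_indices[:, ax]
    for d in range(8):
        for ax, name in enumerate("ijk"):
            rows[f"donor{d}_{name}"] = interface.donor_indices[:, d, ax]
    for d in range(8):
        rows[f"w{d}"] = interface.weights[:, d]
    pd.DataFrame(rows).to_csv(path, index=False)
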