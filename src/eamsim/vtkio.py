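"""Minimal legacy-VTK ASCII writers for visual inspection of models and maps."""

from __future__ import annotations

import numpy as np


def write_point_cloud(path, points: np.ndarray, point_data: dict = None):
    """Voxel nodes (or any point set) with per-point scalar arrays."""
    points = np.asarray(points, dtype=float)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\neamsim point cloud\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(points)} float\n")
        np.savetxt(f, points, fmt="%.4f")
        f.write(f"VERTICES {len(points)} {2 * len(points)}\n")
        np.savetxt(f, np.column_stack([np.ones(len(points), dtype=int),
                                       np.arange(len(points))]), fmt="%d")
        _write_point_data(f, len(points), point_data)


def write_surface(path, points: np.ndarray, triangles: np.ndarray,
                  point_data: dict = None):
    """Triangulated surface with optional per-point scalars."""
    points = np.asarray(points, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\neamsim surface\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(points)} float\n")
        np.savetxt(f, points, fmt="%.4f")
        f.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
        np.savetxt(f, np.column_stack([np.full(len(triangles), 3),
                                       triangles]), fmt="%d")
        _write_point_data(f, len(points), point_data)


def _write_point_data(f, n, point_data):
    if not point_data:
        return
    f.write(f"POINT_DATA {n}\n")
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, np.nan_to_num(arr.astype(float), nan=-1.0), fmt="%.6g")
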