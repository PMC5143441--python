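"""Persistence for models, fields, banks, solutions and analysis maps.

Formats: NIfTI (nibabel, affine in mm per NIfTI convention) and MHD/RAW
(SimpleITK) for property/HU volumes; HDF5 (h5py) for complex pressure
volumes and element banks; CSV/JSON for phase solutions and analysis maps;
CSV grid + STL (trimesh) for the 3D-printable aberrator height map; YAML
for configs.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np

from .analysis import CorrelationResult, RatioMap
from .correction import ElementFieldBank, PhaseSolution, Region
from .errors import ContractError
from .grid import VoxelGrid
from .models import AcousticModel, HeightMap, HUVolume
from .solver import PressureVolume

_M_TO_MM = 1e3

# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag([grid.dx * _M_TO_MM, grid.dy * _M_TO_MM, grid.dz * _M_TO_MM, 1.0])
    aff[:3, 3] = np.asarray(grid.origin) * _M_TO_MM
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> VoxelGrid:
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) / _M_TO_MM for i in range(3))
    origin = tuple(float(v) / _M_TO_MM for v in aff[:3, 3])
    return VoxelGrid(dims=tuple(shape), spacing=spacing, origin=origin)


def save_volume_nifti(path, data: np.ndarray, grid: VoxelGrid) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _nifti_affine(grid))
    nib.save(img, str(path))


def load_volume_nifti(path) -> tuple[np.ndarray, VoxelGrid]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return data, _grid_from_affine(img.affine, data.shape)


def save_model_nifti(model: AcousticModel, basepath) -> dict:
    """Write speed/attenuation/density as three NIfTI files; returns paths."""
    base = str(basepath)
    paths = {}
    for name in ("speed", "attenuation", "density"):
        p = f"{base}_{name}.nii.gz"
        save_volume_nifti(p, getattr(model, name), model.grid)
        paths[name] = p
    return paths


def load_model_nifti(basepath) -> AcousticModel:
    base = str(basepath)
    vols = {}
    grid = None
    for name in ("speed", "attenuation", "density"):
        data, g = load_volume_nifti(f"{base}_{name}.nii.gz")
        vols[name] = data
        grid = g
    return AcousticModel(grid=grid, **vols)


def save_hu_nifti(volume: HUVolume, path) -> None:
    save_volume_nifti(path, volume.hu, volume.grid)


def load_hu_nifti(path) -> HUVolume:
    hu, grid = load_volume_nifti(path)
    return HUVolume(grid=grid, hu=hu)


# ---------------------------------------------------------------------------
# MHD/RAW via SimpleITK
# ---------------------------------------------------------------------------

def save_volume_mhd(path, data: np.ndarray, grid: VoxelGrid) -> None:
    import SimpleITK as sitk

    # SimpleITK arrays are indexed [z, y, x]
    img = sitk.GetImageFromArray(np.asarray(data, dtype=np.float32).transpose(2, 1, 0))
    img.SetSpacing(tuple(s * _M_TO_MM for s in grid.spacing))
    img.SetOrigin(tuple(o * _M_TO_MM for o in grid.origin))
    sitk.WriteImage(img, str(path))


def load_volume_mhd(path) -> tuple[np.ndarray, VoxelGrid]:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    spacing = tuple(s / _M_TO_MM for s in img.GetSpacing())
    origin = tuple(o / _M_TO_MM for o in img.GetOrigin())
    return data, VoxelGrid(dims=data.shape, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def _write_grid_attrs(obj, grid: VoxelGrid) -> None:
    obj.attrs["dims"] = grid.dims
    obj.attrs["spacing"] = grid.spacing
    obj.attrs["origin"] = grid.origin


def _read_grid_attrs(obj) -> VoxelGrid:
    return VoxelGrid(
        dims=tuple(int(d) for d in obj.attrs["dims"]),
        spacing=tuple(float(s) for s in obj.attrs["spacing"]),
        origin=tuple(float(o) for o in obj.attrs["origin"]),
    )


def save_model_h5(model: AcousticModel, path) -> None:
    with h5py.File(path, "w") as f:
        _write_grid_attrs(f, model.grid)
        for name in ("speed", "attenuation", "density"):
            f.create_dataset(name, data=getattr(model, name))


def load_model_h5(path) -> AcousticModel:
    with h5py.File(path, "r") as f:
        grid = _read_grid_attrs(f)
        return AcousticModel(
            grid=grid,
            speed=f["speed"][...],
            attenuation=f["attenuation"][...],
            density=f["density"][...],
        )


def save_pressure_h5(volume: PressureVolume, path) -> None:
    with h5py.File(path, "w") as f:
        _write_grid_attrs(f, volume.grid)
        f.attrs["frequency"] = volume.frequency
        f.create_dataset("pressure", data=volume.pressure.astype(np.complex64))


def load_pressure_h5(path) -> PressureVolume:
    with h5py.File(path, "r") as f:
        return PressureVolume(
            pressure=f["pressure"][...].astype(complex),
            grid=_read_grid_attrs(f),
            frequency=float(f.attrs["frequency"]),
        )


def save_pressure_magnitude_nifti(volume: PressureVolume, path) -> None:
    save_volume_nifti(path, volume.magnitude, volume.grid)


def save_source_plane_h5(plane, path, element_index: int | None = None) -> None:
    from .arrays import SourcePlane  # noqa: F401  (type documented here)

    with h5py.File(path, "w") as f:
        f.attrs["z"] = plane.z
        f.attrs["frequency"] = plane.frequency
        if element_index is not None:
            f.attrs["element_index"] = int(element_index)
        f.create_dataset("pressure", data=plane.values.astype(np.complex64))


def load_source_plane_h5(path):
    from .arrays import SourcePlane

    with h5py.File(path, "r") as f:
        return SourcePlane(
            values=f["pressure"][...].astype(complex),
            z=float(f.attrs["z"]),
            frequency=float(f.attrs["frequency"]),
        )


def save_bank_h5(bank: ElementFieldBank, path) -> None:
    with h5py.File(path, "w") as f:
        _write_grid_attrs(f, bank.grid)
        f.attrs["frequency"] = bank.frequency
        f.attrs["n_elements"] = bank.n_elements
        r = bank.region
        f.attrs["region"] = [r.x0, r.x1, r.y0, r.y1, r.z0, r.z1]
        for i in range(bank.n_elements):
            f.create_dataset(f"element_{i:03d}", data=bank.fields[i].astype(np.complex64))


def load_bank_h5(path) -> ElementFieldBank:
    with h5py.File(path, "r") as f:
        grid = _read_grid_attrs(f)
        region = Region(*(int(v) for v in f.attrs["region"]))
        n = int(f.attrs["n_elements"])
        fields = np.empty((n, *region.shape), dtype=complex)
        for i in range(n):
            fields[i] = f[f"element_{i:03d}"][...]
        return ElementFieldBank(
            fields=fields, grid=grid, frequency=float(f.attrs["frequency"]), region=region
        )


# ---------------------------------------------------------------------------
# phase solutions
# ---------------------------------------------------------------------------

def save_solution_csv(solution: PhaseSolution, path) -> None:
    with open(path, "w") as f:
        f.write("element_index,phase_rad\n")
        for i, phi in enumerate(solution.phases):
            f.write(f"{i},{phi:.12g}\n")


def load_solution_csv(path) -> np.ndarray:
    data = np.genfromtxt(path, delimiter=",", names=True)
    return np.atleast_1d(data["phase_rad"]).astype(float)


def save_solution_json(solution: PhaseSolution, path) -> None:
    payload = {
        "target_m": [float(v) for v in solution.target],
        "target_index": [float(v) for v in solution.target_index],
        "phases_rad": [float(v) for v in solution.phases],
        "provenance": {k: _jsonable(v) for k, v in solution.provenance.items()},
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


# ---------------------------------------------------------------------------
# height map: CSV grid and printable STL
# ---------------------------------------------------------------------------

def save_heightmap_csv(hmap: HeightMap, path) -> None:
    np.savetxt(path, hmap.relief, delimiter=",")


def load_heightmap_csv(path, base_thickness: float, spacing) -> HeightMap:
    relief = np.atleast_2d(np.loadtxt(path, delimiter=","))
    return HeightMap(relief=relief, base_thickness=base_thickness, spacing=tuple(spacing))


def heightmap_to_mesh(hmap: HeightMap):
    """Closed surface mesh of the plate (flat base + relief top + walls)."""
    import trimesh

    nx, ny = hmap.relief.shape
    dx, dy = hmap.spacing
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    top_z = hmap.total_thickness

    def vid(i, j, layer):  # layer 0 = base, 1 = top
        return layer * nx * ny + i * ny + j

    verts = np.empty((2 * nx * ny, 3))
    for i in range(nx):
        for j in range(ny):
            verts[vid(i, j, 0)] = (xs[i], ys[j], 0.0)
            verts[vid(i, j, 1)] = (xs[i], ys[j], top_z[i, j])

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = vid(i, j, 1), vid(i + 1, j, 1), vid(i + 1, j + 1, 1), vid(i, j + 1, 1)
            faces += [[a, b, c], [a, c, d]]                  # top (outward +z)
            a, b, c, d = vid(i, j, 0), vid(i + 1, j, 0), vid(i + 1, j + 1, 0), vid(i, j + 1, 0)
            faces += [[a, c, b], [a, d, c]]                  # base (outward -z)
    for i in range(nx - 1):                                   # y walls
        for j in (0, ny - 1):
            a, b = vid(i, j, 0), vid(i + 1, j, 0)
            c, d = vid(i + 1, j, 1), vid(i, j, 1)
            tri = [[a, b, c], [a, c, d]] if j == 0 else [[a, c, b], [a, d, c]]
            faces += tri
    for j in range(ny - 1):                                   # x walls
        for i in (0, nx - 1):
            a, b = vid(i, j, 0), vid(i, j + 1, 0)
            c, d = vid(i, j + 1, 1), vid(i, j, 1)
            tri = [[a, c, b], [a, d, c]] if i == 0 else [[a, b, c], [a, c, d]]
            faces += tri
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=True)
    return mesh


def save_heightmap_stl(hmap: HeightMap, path) -> None:
    heightmap_to_mesh(hmap).export(str(path))


# ---------------------------------------------------------------------------
# analysis maps
# ---------------------------------------------------------------------------

def save_ratio_map(rmap: RatioMap, csv_path, json_path=None) -> None:
    nx, ny = rmap.values.shape
    with open(csv_path, "w") as f:
        f.write("x_m,y_m,ratio\n")
        for i in range(nx):
            for j in range(ny):
                f.write(f"{rmap.x[i]:.9g},{rmap.y[j]:.9g},{rmap.values[i, j]:.9g}\n")
    if json_path is not None:
        with open(json_path, "w") as f:
            json.dump(
                {
                    "reference": rmap.reference,
                    "min": float(rmap.values.min()),
                    "max": float(rmap.values.max()),
                    "mean": float(rmap.values.mean()),
                },
                f,
                indent=2,
            )


def save_correlation_result(result: CorrelationResult, csv_path, json_path=None, png_path=None) -> None:
    np.savetxt(csv_path, result.correlation, delimiter=",")
    if json_path is not None:
        with open(json_path, "w") as f:
            json.dump(
                {
                    "peak": float(result.correlation.max()),
                    "contour_areas_mm2": {str(k): v for k, v in result.contour_areas_mm2.items()},
                },
                f,
                indent=2,
            )
    if png_path is not None:
        render_correlation_png(result, png_path)


def render_correlation_png(result: CorrelationResult, path) -> None:
    """Correlation map with 25/50/75 % contour overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nx, ny = result.correlation.shape
    extent = [0, ny * result.spacing[1] * 1e3, 0, nx * result.spacing[0] * 1e3]
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(result.correlation, origin="lower", extent=extent, cmap="viridis")
    levels = sorted(result.contour_areas_mm2)
    colors = {0.25: "white", 0.5: "red", 0.75: "black"}
    ax.contour(
        result.correlation, levels=levels, origin="lower", extent=extent,
        colors=[colors.get(l, "gray") for l in levels],
    )
    ax.set_xlabel("y (mm)")
    ax.set_ylabel("x (mm)")
    fig.colorbar(im, ax=ax, label="normalized correlation")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
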