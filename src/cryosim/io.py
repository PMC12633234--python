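"""File formats and configuration: PDB/mmCIF atoms, MRC volumes and stacks,
CSV metadata tables, and flat key-value config files.

MRC files are written through gemmi in mode-2 (32-bit float) with the voxel
size carried in the unit-cell header; the slowest axis is z (sections), so a
volume array is indexed ``[z, y, x]`` and a stack ``[image, y, x]``.  The
metadata table is a CSV with one row per image and a fixed, documented
column set (angles in degrees, lengths in Å, voltage in kV, Cs in mm).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .imaging import ImageStack
from .optics import CTFParams
from .pose import EulerPose
from .volumes import RealVoxelVolume

__all__ = [
    "AtomRecord",
    "read_atoms",
    "write_volume_mrc",
    "read_volume_mrc",
    "write_stack_mrc",
    "read_stack_mrc",
    "METADATA_COLUMNS",
    "write_metadata",
    "read_metadata",
    "stack_metadata_frame",
    "read_config",
]

METADATA_COLUMNS = [
    "image",
    "phi",
    "theta",
    "psi",
    "tx",
    "ty",
    "defocus_u",
    "defocus_v",
    "astig_angle",
    "voltage",
    "cs",
    "amplitude_contrast",
    "phase_shift",
    "pixel_size",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, atomic number, position (Å), optional identifiers."""

    element: str
    atomic_number: int
    position: tuple[float, float, float]
    chain: str = ""
    residue: str = ""
    residue_number: int = 0
    is_ca: bool = False

    def __post_init__(self):
        if self.atomic_number < 1:
            raise ValueError("atomic number must be >= 1")
        if not all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


def read_atoms(path: str | os.PathLike, ca_only: bool = False) -> list[AtomRecord]:
    """Read atoms from a PDB or mmCIF file; optionally keep only C-alphas."""
    try:
        structure = gemmi.read_structure(os.fspath(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc
    records: list[AtomRecord] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    is_ca = atom.name == "CA" and atom.element.name == "C"
                    if ca_only and not is_ca:
                        continue
                    records.append(
                        AtomRecord(
                            element=atom.element.name,
                            atomic_number=atom.element.atomic_number,
                            position=(atom.pos.x, atom.pos.y, atom.pos.z),
                            chain=chain.name,
                            residue=residue.name,
                            residue_number=residue.seqid.num,
                            is_ca=is_ca,
                        )
                    )
        break  # first model only
    if not records:
        raise ValueError(f"no atoms selected from {path} (ca_only={ca_only})")
    return records


def atom_positions(records: list[AtomRecord]) -> np.ndarray:
    return np.array([r.position for r in records], dtype=float)


def _write_mrc(data: np.ndarray, cell_lengths, path) -> None:
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(data, dtype=np.float32))
    a, b, c = cell_lengths
    m.grid.unit_cell = gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(os.fspath(path))


def write_volume_mrc(vol: RealVoxelVolume, path: str | os.PathLike) -> None:
    n = vol.side
    _write_mrc(vol.grid, (n * vol.voxel_size,) * 3, path)


def read_volume_mrc(path: str | os.PathLike) -> RealVoxelVolume:
    try:
        m = gemmi.read_ccp4_map(os.fspath(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not read MRC file {path}: {exc}") from exc
    grid = np.array(m.grid, copy=True)
    voxel = m.grid.unit_cell.a / m.grid.nu
    return RealVoxelVolume(grid.astype(float), float(voxel))


def write_stack_mrc(stack: ImageStack, path: str | os.PathLike) -> None:
    n, ny, nx = stack.images.shape
    _write_mrc(
        stack.images, (float(n), ny * stack.pixel_size, nx * stack.pixel_size), path
    )


def read_stack_mrc(path: str | os.PathLike) -> ImageStack:
    try:
        m = gemmi.read_ccp4_map(os.fspath(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not read MRC file {path}: {exc}") from exc
    images = np.array(m.grid, copy=True).astype(float)
    pixel = m.grid.unit_cell.b / m.grid.nv
    return ImageStack(images, float(pixel))


def stack_metadata_frame(stack: ImageStack) -> pd.DataFrame:
    """Tabulate per-image pose and CTF metadata with the documented columns."""
    from .pose import euler_from_rotation

    rows = []
    for i in range(len(stack)):
        pose = stack.poses[i]
        ctf = stack.ctfs[i]
        phi, theta, psi = euler_from_rotation(pose.rotation)
        tx, ty = pose.translation
        rows.append(
            dict(
                image=i,
                phi=phi,
                theta=theta,
                psi=psi,
                tx=tx,
                ty=ty,
                defocus_u=ctf.defocus_u,
                defocus_v=ctf.defocus_v,
                astig_angle=ctf.astig_angle,
                voltage=ctf.voltage,
                cs=ctf.cs,
                amplitude_contrast=ctf.amplitude_contrast,
                phase_shift=ctf.phase_shift,
                pixel_size=stack.pixel_size,
            )
        )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def write_metadata(stack: ImageStack, path: str | os.PathLike) -> None:
    stack_metadata_frame(stack).to_csv(path, index=False)


def read_metadata(path: str | os.PathLike) -> tuple[list[EulerPose], list[CTFParams], float]:
    """Read a metadata CSV back into poses, CTFs, and the shared pixel size."""
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table is missing columns: {sorted(missing)}")
    poses = [
        EulerPose(r.phi, r.theta, r.psi, r.tx, r.ty) for r in df.itertuples()
    ]
    ctfs = [
        CTFParams(
            defocus_u=r.defocus_u,
            defocus_v=r.defocus_v,
            astig_angle=r.astig_angle,
            cs=r.cs,
            voltage=r.voltage,
            amplitude_contrast=r.amplitude_contrast,
            phase_shift=r.phase_shift,
        )
        for r in df.itertuples()
    ]
    return poses, ctfs, float(df["pixel_size"].iloc[0])


def read_config(path: str | os.PathLike) -> dict[str, str]:
    """Parse a flat ``key = value`` text config; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
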