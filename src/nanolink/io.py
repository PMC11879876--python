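"""Readers and writers for LAMMPS dump, LAMMPS data and extended-XYZ files.

The supported dump dialect is the plain-text ``atom`` style with columns
``id mol type x y z [ix iy iz]``; extra columns are ignored with a warning.
Molecules are nanostars: 7 core beads followed by 3 patch sites, consecutive
atom ids. Poses (centre + quaternion) are recovered on read by rigid-body
superposition against the body-frame geometry, which is exact for rigid
nanostars.

Atom-type convention: 1 = core bead of an A nanostar, 2 = patch of A,
3 = core of B, 4 = patch of B.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .core import (
    N_CORE_BEADS,
    VALENCE,
    Configuration,
    NanostarGeometry,
    PeriodicBox,
    Trajectory,
    TrajectoryError,
    quat_to_matrix,
)

logger = logging.getLogger(__name__)

SITES_PER_MOL = N_CORE_BEADS + VALENCE

_CORE_TYPE = {0: 1, 1: 3}
_PATCH_TYPE = {0: 2, 1: 4}


class ParseError(TrajectoryError):
    """Malformed trajectory file; message names frame and line."""


# ---------------------------------------------------------------------------
# pose recovery

def _batched_kabsch(body: np.ndarray, world: np.ndarray) -> np.ndarray:
    """Optimal rotations mapping body-frame sites onto centred world sites.

    body : (m, 3); world : (N, m, 3), already centred on the reference site.
    Returns rotation matrices (N, 3, 3).
    """
    h = np.einsum("nmi,mj->nij", world, body)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("nij,njk->nik", u, vt))
    fix = np.repeat(np.eye(3)[None], len(h), axis=0)
    fix[:, 2, 2] = det
    return np.einsum("nij,njk,nkl->nil", u, fix, vt)


def _matrix_to_quat(m: np.ndarray) -> np.ndarray:
    """Rotation matrices -> unit quaternions (w, x, y, z), batched."""
    from scipy.spatial.transform import Rotation

    q = Rotation.from_matrix(m).as_quat()  # (x, y, z, w)
    return np.concatenate([q[:, 3:4], q[:, :3]], axis=1)


def configuration_from_sites(
    site_coords: np.ndarray,
    box: PeriodicBox,
    geometry: NanostarGeometry,
    types: np.ndarray,
) -> Configuration:
    """Rebuild poses from unwrapped world site coordinates (N, 10, 3)."""
    centers = site_coords[:, 0, :]  # central bead defines the pose origin
    body = geometry.all_sites()
    rel = site_coords - centers[:, None, :]
    rot = _batched_kabsch(body, rel)
    quats = _matrix_to_quat(rot)
    return Configuration(
        positions=box.wrap(centers),
        quaternions=quats,
        box=box,
        geometry=geometry,
        types=types,
    )


# ---------------------------------------------------------------------------
# LAMMPS dump

def _frame_atom_table(config: Configuration) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(coords_unwrapped (M,3), types (M,), mols (M,)) for all sites in order."""
    sites = config.all_site_coords(wrap=False)  # contiguous rigid bodies
    n = config.n_nanostars
    types = np.empty(n * SITES_PER_MOL, dtype=np.int64)
    mols = np.repeat(np.arange(1, n + 1), SITES_PER_MOL)
    for i in range(n):
        t = int(config.types[i])
        base = i * SITES_PER_MOL
        types[base : base + N_CORE_BEADS] = _CORE_TYPE[t]
        types[base + N_CORE_BEADS : base + SITES_PER_MOL] = _PATCH_TYPE[t]
    return sites.reshape(-1, 3), types, mols


def write_dump(traj: Trajectory, path: str | Path) -> None:
    """Write a LAMMPS text dump with columns id mol type x y z ix iy iz."""
    if len(traj) == 0:
        raise TrajectoryError("cannot write an empty trajectory")
    path = Path(path)
    box = traj.box
    with open(path, "w") as fh:
        for frame_idx, config in enumerate(traj.frames):
            coords, types, mols = _frame_atom_table(config)
            images = np.floor(coords / box.lengths).astype(np.int64)
            wrapped = coords - images * box.lengths
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{int(round(traj.times[frame_idx] * 100))}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{len(coords)}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for L in box.lengths:
                fh.write(f"0.0 {L:.10g}\n")
            fh.write("ITEM: ATOMS id mol type x y z ix iy iz\n")
            for k in range(len(coords)):
                x, y, z = wrapped[k]
                ix, iy, iz = images[k]
                fh.write(
                    f"{k + 1} {mols[k]} {types[k]} "
                    f"{x:.10g} {y:.10g} {z:.10g} {ix} {iy} {iz}\n"
                )
    logger.info("wrote %d frames to %s", len(traj), path)


def _parse_dump_frames(lines: list[str], path: Path):
    i = 0
    n_lines = len(lines)
    frame_idx = 0
    expected_atoms = None
    while i < n_lines:
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ParseError(
                f"{path}: frame {frame_idx}, line {i + 1}: expected 'ITEM: TIMESTEP'"
            )
        try:
            timestep = int(lines[i + 1])
            if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
                raise ValueError
            n_atoms = int(lines[i + 3])
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}: frame {frame_idx}, line {i + 1}: malformed header"
            ) from None
        if expected_atoms is None:
            expected_atoms = n_atoms
        elif n_atoms != expected_atoms:
            raise ParseError(
                f"{path}: frame {frame_idx}, line {i + 4}: atom count {n_atoms} "
                f"differs from first frame's {expected_atoms}"
            )
        bounds_header = lines[i + 4]
        if not bounds_header.startswith("ITEM: BOX BOUNDS"):
            raise ParseError(
                f"{path}: frame {frame_idx}, line {i + 5}: expected box bounds"
            )
        if "xy" in bounds_header:
            raise ParseError(
                f"{path}: frame {frame_idx}: triclinic boxes are not supported"
            )
        lo_hi = [lines[i + 5 + k].split() for k in range(3)]
        lengths = np.array([float(b[1]) - float(b[0]) for b in lo_hi])
        origin = np.array([float(b[0]) for b in lo_hi])
        atoms_header = lines[i + 8]
        if not atoms_header.startswith("ITEM: ATOMS"):
            raise ParseError(
                f"{path}: frame {frame_idx}, line {i + 9}: expected 'ITEM: ATOMS'"
            )
        columns = atoms_header.split()[2:]
        required = ["id", "mol", "type", "x", "y", "z"]
        for col in required:
            if col not in columns:
                raise ParseError(
                    f"{path}: frame {frame_idx}: dump is missing column '{col}' "
                    f"(have {columns})"
                )
        has_images = all(c in columns for c in ("ix", "iy", "iz"))
        extra = set(columns) - set(required) - {"ix", "iy", "iz"}
        if extra and frame_idx == 0:
            warnings.warn(f"ignoring extra dump columns {sorted(extra)}", stacklevel=3)
        col_idx = {c: k for k, c in enumerate(columns)}
        start = i + 9
        raw = []
        for k in range(n_atoms):
            if start + k >= n_lines or lines[start + k].startswith("ITEM:"):
                raise ParseError(
                    f"{path}: frame {frame_idx}, line {start + k + 1}: "
                    f"expected {n_atoms} atom lines, file ended early"
                )
            raw.append(lines[start + k].split())
        table = np.array(raw, dtype=float)
        order = np.argsort(table[:, col_idx["id"]].astype(int))
        table = table[order]
        coords = table[:, [col_idx["x"], col_idx["y"], col_idx["z"]]] - origin
        if has_images:
            imgs = table[:, [col_idx["ix"], col_idx["iy"], col_idx["iz"]]]
            coords = coords + imgs * lengths
        wrapped_only = not has_images
        mols = table[:, col_idx["mol"]].astype(int)
        atypes = table[:, col_idx["type"]].astype(int)
        yield timestep, lengths, coords, mols, atypes, wrapped_only
        i = start + n_atoms
        frame_idx += 1


def _sites_to_config(
    lengths: np.ndarray,
    coords: np.ndarray,
    mols: np.ndarray,
    atypes: np.ndarray,
    geometry: NanostarGeometry,
    wrapped_only: bool,
    path: Path,
    frame_idx: int,
) -> Configuration:
    box = PeriodicBox(lengths)
    mol_ids = np.unique(mols)
    n = len(mol_ids)
    if len(coords) != n * SITES_PER_MOL:
        raise ParseError(
            f"{path}: frame {frame_idx}: {len(coords)} atoms is not "
            f"{SITES_PER_MOL} sites x {n} molecules"
        )
    sites = coords.reshape(n, SITES_PER_MOL, 3)
    if wrapped_only:
        # make each molecule contiguous by minimum-image steps from its centre
        center = sites[:, 0:1, :]
        sites = center + box.minimum_image(sites - center)
    types = np.where(atypes.reshape(n, SITES_PER_MOL)[:, 0] <= 2, 0, 1)
    return configuration_from_sites(sites, box, geometry, types)


def read_dump(path: str | Path, geometry: NanostarGeometry | None = None) -> Trajectory:
    """Read a LAMMPS text dump into a Trajectory.

    Coordinates are unwrapped with image flags when present; otherwise
    molecules are made contiguous by minimum-image reconstruction and a
    warning is logged.
    """
    path = Path(path)
    geometry = geometry or NanostarGeometry.default()
    lines = path.read_text().splitlines()
    frames, times = [], []
    warned = False
    for timestep, lengths, coords, mols, atypes, wrapped_only in _parse_dump_frames(
        lines, path
    ):
        if wrapped_only and not warned:
            logger.warning(
                "%s: no image flags; molecules re-unwrapped by minimum image", path
            )
            warned = True
        frames.append(
            _sites_to_config(
                lengths, coords, mols, atypes, geometry, wrapped_only, path, len(frames)
            )
        )
        times.append(timestep / 100.0)
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(frames=frames, times=np.array(times))


# ---------------------------------------------------------------------------
# LAMMPS data (atom style molecular), single configuration

def write_data(config: Configuration, path: str | Path) -> None:
    """Write a single configuration as a LAMMPS data file (style molecular)."""
    path = Path(path)
    coords, types, mols = _frame_atom_table(config)
    box = config.box
    n_types = int(types.max())
    with open(path, "w") as fh:
        fh.write("LAMMPS data file: nanostar configuration\n\n")
        fh.write(f"{len(coords)} atoms\n")
        fh.write(f"{n_types} atom types\n\n")
        for axis, L in zip("xyz", box.lengths):
            fh.write(f"0.0 {L:.10g} {axis}lo {axis}hi\n")
        fh.write("\nMasses\n\n")
        for t in range(1, n_types + 1):
            mass = 1.0 if t in (1, 3) else 1e-9  # patches are massless sites
            fh.write(f"{t} {mass}\n")
        fh.write("\nAtoms # molecular\n\n")
        images = np.floor(coords / box.lengths).astype(np.int64)
        wrapped = coords - images * box.lengths
        for k in range(len(coords)):
            x, y, z = wrapped[k]
            ix, iy, iz = images[k]
            fh.write(
                f"{k + 1} {mols[k]} {types[k]} "
                f"{x:.10g} {y:.10g} {z:.10g} {ix} {iy} {iz}\n"
            )


def read_data(path: str | Path, geometry: NanostarGeometry | None = None) -> Trajectory:
    """Read a LAMMPS data file (atom style molecular) as a 1-frame Trajectory."""
    path = Path(path)
    geometry = geometry or NanostarGeometry.default()
    lines = path.read_text().splitlines()
    n_atoms = None
    lengths = np.zeros(3)
    atoms_start = None
    for i, line in enumerate(lines):
        stripped = line.split("#")[0].strip()
        if stripped.endswith(" atoms"):
            n_atoms = int(stripped.split()[0])
        for k, axis in enumerate("xyz"):
            if stripped.endswith(f"{axis}lo {axis}hi"):
                lo, hi = map(float, stripped.split()[:2])
                lengths[k] = hi - lo
        if line.startswith("Atoms"):
            atoms_start = i + 2
    if n_atoms is None or atoms_start is None or np.any(lengths <= 0):
        raise ParseError(f"{path}: malformed data file header")
    raw = []
    for k in range(n_atoms):
        parts = lines[atoms_start + k].split()
        if len(parts) < 6:
            raise ParseError(f"{path}: line {atoms_start + k + 1}: short atom line")
        raw.append(parts[:9] if len(parts) >= 9 else parts[:6] + ["0", "0", "0"])
    table = np.array(raw, dtype=float)
    table = table[np.argsort(table[:, 0].astype(int))]
    coords = table[:, 3:6] + table[:, 6:9] * lengths
    config = _sites_to_config(
        lengths, coords, table[:, 1].astype(int), table[:, 2].astype(int),
        geometry, False, path, 0,
    )
    return Trajectory(frames=[config], times=np.array([0.0]))


# ---------------------------------------------------------------------------
# extended XYZ

def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write an extended-XYZ file; the comment line carries box and time.

    XYZ is positions-only: velocities and forces are never round-tripped
    through this format.
    """
    if len(traj) == 0:
        raise TrajectoryError("cannot write an empty trajectory")
    path = Path(path)
    box = traj.box
    L = box.lengths
    lattice = f"{L[0]:.10g} 0 0 0 {L[1]:.10g} 0 0 0 {L[2]:.10g}"
    with open(path, "w") as fh:
        for frame_idx, config in enumerate(traj.frames):
            coords, types, mols = _frame_atom_table(config)
            fh.write(f"{len(coords)}\n")
            fh.write(
                f'Lattice="{lattice}" Properties=type:I:1:pos:R:3:mol:I:1 '
                f"Time={traj.times[frame_idx]:.10g}\n"
            )
            for k in range(len(coords)):
                x, y, z = coords[k]
                fh.write(f"{types[k]} {x:.10g} {y:.10g} {z:.10g} {mols[k]}\n")


def read_xyz(path: str | Path, geometry: NanostarGeometry | None = None) -> Trajectory:
    """Read an extended-XYZ file written by :func:`write_xyz`."""
    path = Path(path)
    geometry = geometry or NanostarGeometry.default()
    lines = path.read_text().splitlines()
    frames, times = [], []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i])
        except ValueError:
            raise ParseError(
                f"{path}: frame {len(frames)}, line {i + 1}: expected atom count"
            ) from None
        comment = lines[i + 1]
        if 'Lattice="' not in comment:
            raise ParseError(
                f"{path}: frame {len(frames)}, line {i + 2}: missing Lattice"
            )
        cell = np.fromstring(comment.split('Lattice="')[1].split('"')[0], sep=" ")
        cell = cell.reshape(3, 3)
        if np.abs(cell - np.diag(np.diag(cell))).max() > 1e-12:
            raise ParseError(f"{path}: frame {len(frames)}: non-orthorhombic lattice")
        lengths = np.diag(cell).copy()
        t = 0.0
        for token in comment.split():
            if token.startswith("Time="):
                t = float(token[5:])
        raw = [lines[i + 2 + k].split() for k in range(n_atoms)]
        table = np.array(raw, dtype=float)
        coords = table[:, 1:4]
        frames.append(
            _sites_to_config(
                lengths, coords, table[:, 4].astype(int), table[:, 0].astype(int),
                geometry, False, path, len(frames),
            )
        )
        times.append(t)
        i += 2 + n_atoms
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(frames=frames, times=np.array(times))


# ---------------------------------------------------------------------------
# format dispatch

_READERS = {"lammps-dump": read_dump, "lammps-data": read_data, "xyz": read_xyz}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".dump", ".lammpstrj"):
        return "lammps-dump"
    if suffix == ".data":
        return "lammps-data"
    if suffix in (".xyz", ".extxyz"):
        return "xyz"
    raise ValueError(f"cannot infer trajectory format from '{path.name}'")


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    geometry: NanostarGeometry | None = None,
) -> Trajectory:
    """Read a trajectory, dispatching on format (inferred from suffix if None)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _READERS:
        raise ValueError(f"unknown format '{fmt}' (choose from {sorted(_READERS)})")
    return _READERS[fmt](path, geometry=geometry)


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    """Write a trajectory, dispatching on format (inferred from suffix if None)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "lammps-dump":
        write_dump(traj, path)
    elif fmt == "lammps-data":
        if len(traj) != 1:
            raise TrajectoryError("LAMMPS data files hold a single configuration")
        write_data(traj.frames[0], path)
    elif fmt == "xyz":
        write_xyz(traj, path)
    else:
        raise ValueError(f"unknown format '{fmt}'")
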