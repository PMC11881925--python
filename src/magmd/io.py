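"""Text formats: GRO structures (with optional velocities), minimal PDB
reading, multi-frame trajectories (extended XYZ or concatenated GRO), and
#-commented TSV observable tables.

Parsers reject malformed input with line-numbered errors rather than
silently repairing it; writers embed provenance (seed, config hash) in
comment/header lines when given.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .model import SystemState, Trajectory


class ParseError(ValueError):
    """Malformed structure/trajectory file."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path, self.line_no = path, line_no


@dataclass
class AtomRecords:
    """Naming metadata parallel to a SystemState's particle arrays."""

    residue_numbers: list[int] = dc_field(default_factory=list)
    residue_names: list[str] = dc_field(default_factory=list)
    atom_names: list[str] = dc_field(default_factory=list)

    @classmethod
    def generic(cls, n, atom_name="X", residue_name="MOL"):
        return cls(
            residue_numbers=list(range(1, n + 1)),
            residue_names=[residue_name] * n,
            atom_names=[atom_name] * n,
        )


def _parse_gro_frame(lines, start, path):
    """Parse one GRO frame starting at ``lines[start]``; returns
    (title, positions, velocities|None, box, next_index)."""
    if start >= len(lines):
        raise ParseError(path, start + 1, "unexpected end of file")
    title = lines[start].rstrip("\n")
    try:
        n_atoms = int(lines[start + 1].strip())
    except (IndexError, ValueError):
        raise ParseError(path, start + 2, "expected the atom count") from None
    end = start + 2 + n_atoms
    if len(lines) < end + 1:
        raise ParseError(
            path, len(lines), f"truncated frame: expected {n_atoms} atoms + box line"
        )
    res_num, res_name, at_name = [], [], []
    pos = np.empty((n_atoms, 3))
    vel = np.empty((n_atoms, 3))
    have_vel = True
    for k in range(n_atoms):
        line = lines[start + 2 + k].rstrip("\n")
        if len(line) < 44:
            raise ParseError(path, start + 3 + k, "atom record too short")
        try:
            res_num.append(int(line[0:5]))
            res_name.append(line[5:10].strip())
            at_name.append(line[10:15].strip())
            pos[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except ValueError as exc:
            raise ParseError(path, start + 3 + k, f"bad atom record: {exc}") from None
        if len(line) >= 68:
            try:
                vel[k] = [
                    float(line[44:52]),
                    float(line[52:60]),
                    float(line[60:68]),
                ]
            except ValueError as exc:
                raise ParseError(
                    path, start + 3 + k, f"bad velocity columns: {exc}"
                ) from None
        else:
            have_vel = False
    box_fields = lines[end].split()
    if len(box_fields) < 3:
        raise ParseError(path, end + 1, "expected a box line with >= 3 numbers")
    try:
        box = np.array([float(v) for v in box_fields[:3]])
    except ValueError as exc:
        raise ParseError(path, end + 1, f"bad box line: {exc}") from None
    records = AtomRecords(
        residue_numbers=res_num, residue_names=res_name, atom_names=at_name
    )
    return title, pos, (vel if have_vel else None), box, end + 1, records


def read_gro(path):
    """Read a GRO structure.

    Returns (SystemState skeleton, AtomRecords, title).  Masses and charges
    are filled with placeholders (1 u, 0 e) — the caller assigns them from a
    topology.  A box line of zeros yields an open (non-periodic) state.
    Missing velocity columns yield zero velocities; check
    ``state._velocities_present`` to decide whether to thermalize.
    """
    with open(path) as fh:
        lines = fh.readlines()
    title, pos, vel, box, _, rec = _parse_gro_frame(lines, 0, path)
    n = pos.shape[0]
    state = SystemState(
        positions=pos,
        velocities=vel if vel is not None else np.zeros((n, 3)),
        masses=np.ones(n),
        charges=np.zeros(n),
        box=box if np.all(box > 0) else None,
    )
    state._velocities_present = vel is not None
    return state, rec, title


def _format_gro_frame(state, records, title, with_velocities=True):
    n = state.n_particles
    out = [title, f"{n:5d}"]
    vel = state.velocities
    for k in range(n):
        base = (
            f"{records.residue_numbers[k] % 100000:5d}"
            f"{records.residue_names[k]:<5.5s}"
            f"{records.atom_names[k]:>5.5s}"
            f"{(k + 1) % 100000:5d}"
            f"{state.positions[k, 0]:8.3f}"
            f"{state.positions[k, 1]:8.3f}"
            f"{state.positions[k, 2]:8.3f}"
        )
        if with_velocities:
            base += f"{vel[k, 0]:8.4f}{vel[k, 1]:8.4f}{vel[k, 2]:8.4f}"
        out.append(base)
    box = state.box if state.box is not None else np.zeros(3)
    out.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    return "\n".join(out) + "\n"


def write_gro(state, records, path, title="magmd structure", with_velocities=True):
    """Write a fixed-width GRO file (positions %8.3f, velocities %8.4f)."""
    if records is None:
        records = AtomRecords.generic(state.n_particles)
    with open(path, "w") as fh:
        fh.write(_format_gro_frame(state, records, title, with_velocities))


def read_pdb_minimal(path):
    """Minimal PDB reader: ATOM/HETATM coordinates (Å → nm) + metadata.

    Keeps the first altLoc of duplicated atoms (the number dropped is
    reported in the returned metadata); parses CRYST1 into a box when
    present.  Raises on a file without ATOM records.
    """
    coords, atom_names, res_names, res_ids, chains, elements = [], [], [], [], [], []
    box = None
    seen_alt = set()
    n_altloc_dropped = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = np.array(
                        [
                            float(line[6:15]) / 10.0,
                            float(line[15:24]) / 10.0,
                            float(line[24:33]) / 10.0,
                        ]
                    )
                except ValueError as exc:
                    raise ParseError(path, line_no, f"bad CRYST1: {exc}") from None
            if rec not in ("ATOM  ", "HETATM"):
                continue
            altloc = line[16]
            key = (line[12:16], line[17:20], line[21], line[22:26])
            if altloc not in (" ", ""):
                if key in seen_alt:
                    n_altloc_dropped += 1
                    continue
                seen_alt.add(key)
            try:
                coords.append(
                    [
                        float(line[30:38]) / 10.0,
                        float(line[38:46]) / 10.0,
                        float(line[46:54]) / 10.0,
                    ]
                )
            except ValueError as exc:
                raise ParseError(path, line_no, f"bad coordinates: {exc}") from None
            atom_names.append(line[12:16].strip())
            res_names.append(line[17:20].strip())
            res_ids.append(int(line[22:26]))
            chains.append(line[21].strip())
            elements.append(line[76:78].strip() if len(line) > 76 else "")
    if not coords:
        raise ParseError(path, 0, "no ATOM/HETATM records found")
    return {
        "coordinates_nm": np.array(coords),
        "atom_names": atom_names,
        "residue_names": res_names,
        "residue_ids": res_ids,
        "chains": chains,
        "elements": elements,
        "box_nm": box,
        "n_altloc_dropped": n_altloc_dropped,
    }


def write_trajectory_frames(
    traj: Trajectory,
    path,
    fmt: str = "xyz",
    atom_names=None,
    comment_extra: str = "",
):
    """Write sampled frames as extended XYZ or concatenated (multi) GRO.

    The comment/title line of every frame carries ``time=<ps>`` (and the box
    for XYZ); velocities are written when the trajectory stores them.
    """
    n = traj.n_particles
    if atom_names is None:
        atom_names = ["X"] * n
    box = traj.box if traj.box is not None else np.zeros(3)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            if fmt == "xyz":
                fh.write(f"{n}\n")
                fh.write(
                    f"time={traj.times[f]:.6f} ps "
                    f"box={box[0]:.5f},{box[1]:.5f},{box[2]:.5f} nm "
                    f"{comment_extra}".rstrip()
                    + "\n"
                )
                for k in range(n):
                    line = (
                        f"{atom_names[k]:<4s} "
                        f"{traj.positions[f, k, 0]:12.6f} "
                        f"{traj.positions[f, k, 1]:12.6f} "
                        f"{traj.positions[f, k, 2]:12.6f}"
                    )
                    if traj.velocities is not None:
                        line += (
                            f" {traj.velocities[f, k, 0]:12.6f}"
                            f" {traj.velocities[f, k, 1]:12.6f}"
                            f" {traj.velocities[f, k, 2]:12.6f}"
                        )
                    fh.write(line + "\n")
            elif fmt == "gro-multi":
                state = SystemState(
                    positions=traj.positions[f],
                    velocities=(
                        traj.velocities[f]
                        if traj.velocities is not None
                        else np.zeros((n, 3))
                    ),
                    masses=np.ones(n),
                    charges=np.zeros(n),
                    box=traj.box,
                    time=float(traj.times[f]),
                )
                records = AtomRecords.generic(n)
                records.atom_names = list(atom_names)
                fh.write(
                    _format_gro_frame(
                        state,
                        records,
                        f"frame time={traj.times[f]:.6f} ps {comment_extra}".rstrip(),
                        with_velocities=traj.velocities is not None,
                    )
                )
            else:
                raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory_frames(path, fmt: str = "xyz") -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory_frames`.

    Enforces strictly increasing time stamps and rejects truncated frames
    (naming the frame index).
    """
    times, frames, vels = [], [], []
    box = None
    with open(path) as fh:
        lines = fh.readlines()
    if fmt == "xyz":
        i, frame_idx = 0, 0
        while i < len(lines):
            if lines[i].strip() == "":
                i += 1
                continue
            try:
                n = int(lines[i].strip())
            except ValueError:
                raise ParseError(path, i + 1, "expected an atom count") from None
            if len(lines) < i + 2 + n:
                raise ParseError(path, len(lines), f"truncated frame {frame_idx}")
            comment = lines[i + 1]
            t = _parse_comment_time(comment, path, i + 2)
            box = _parse_comment_box(comment)
            pos = np.empty((n, 3))
            vel = np.empty((n, 3))
            have_vel = True
            for k in range(n):
                parts = lines[i + 2 + k].split()
                if len(parts) < 4:
                    raise ParseError(
                        path, i + 3 + k, f"truncated frame {frame_idx}"
                    )
                pos[k] = [float(v) for v in parts[1:4]]
                if len(parts) >= 7:
                    vel[k] = [float(v) for v in parts[4:7]]
                else:
                    have_vel = False
            times.append(t)
            frames.append(pos)
            vels.append(vel if have_vel else None)
            i += 2 + n
            frame_idx += 1
    elif fmt == "gro-multi":
        i, frame_idx = 0, 0
        while i < len(lines):
            if lines[i].strip() == "":
                i += 1
                continue
            title, pos, vel, fbox, i, _rec = _parse_gro_frame(lines, i, path)
            times.append(_parse_comment_time(title, path, i))
            frames.append(pos)
            vels.append(vel)
            box = fbox if np.all(fbox > 0) else None
            frame_idx += 1
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    if not frames:
        raise ParseError(path, 0, "no frames found")
    t = np.array(times)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ParseError(path, 0, f"time stamps not strictly increasing at frame {bad}")
    have_all_vel = all(v is not None for v in vels)
    return Trajectory(
        times=t,
        positions=np.array(frames),
        velocities=np.array(vels) if have_all_vel else None,
        box=box,
    )


def _parse_comment_time(comment, path, line_no):
    for token in comment.split():
        if token.startswith("time="):
            try:
                return float(token[5:])
            except ValueError:
                break
    raise ParseError(path, line_no, "frame comment lacks a parsable 'time=' token")


def _parse_comment_box(comment):
    for token in comment.split():
        if token.startswith("box="):
            vals = np.array([float(v) for v in token[4:].split(",")])
            if np.all(vals > 0):
                return vals
    return None


def write_observable_table(df: pd.DataFrame, path, metadata: dict | None = None):
    """TSV with #-prefixed header metadata lines (provenance: seed, config)."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_observable_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
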