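"""Extended-XYZ trajectory reading/writing and observable CSV streams.

Frame format (extended XYZ): the comment line carries the orthorhombic box
as ``Lattice="Lx 0 0 0 Ly 0 0 0 Lz"``, a ``Properties`` descriptor, and any
per-frame scalar observables as ``key=value`` entries.  Coordinates are
serialised with 10 significant digits.  Reading is streaming: frames are
yielded one at a time without loading the file into memory.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

import numpy as np


class TrajectoryParseError(ValueError):
    def __init__(self, message, line=None, last_good_frame=None):
        self.line = line
        self.last_good_frame = last_good_frame
        detail = message
        if line is not None:
            detail += f" (line {line})"
        if last_good_frame is not None:
            detail += f"; last complete frame was #{last_good_frame}"
        super().__init__(detail)


@dataclass
class TrajectoryFrame:
    """One snapshot: species labels, coordinates, box, scalar observables."""

    species: list
    positions: np.ndarray
    box: np.ndarray
    observables: dict = field(default_factory=dict)


_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _format_comment(box, observables):
    lat = f'Lattice="{box[0]:.10g} 0 0 0 {box[1]:.10g} 0 0 0 {box[2]:.10g}"'
    props = "Properties=species:S:1:pos:R:3"
    extra = " ".join(f"{k}={v:.10g}" if isinstance(v, float) else f"{k}={v}"
                     for k, v in observables.items())
    return " ".join(x for x in (lat, props, extra) if x)


def write_frames(frames, path, mode="w"):
    """Write an iterable of TrajectoryFrame to an extended-XYZ file."""
    count = 0
    with open(path, mode) as fh:
        for fr in frames:
            n = len(fr.positions)
            if n != len(fr.species):
                raise ValueError("species/positions length mismatch")
            fh.write(f"{n}\n")
            fh.write(_format_comment(fr.box, fr.observables) + "\n")
            for sp, (x, y, z) in zip(fr.species, fr.positions):
                fh.write(f"{sp} {x:.10g} {y:.10g} {z:.10g}\n")
            count += 1
    return count


def write_trajectory(frames, path):
    return write_frames(frames, path, mode="w")


def _parse_comment(comment, lineno):
    obs = {}
    box = None
    for key, quoted, bare in _KV_RE.findall(comment):
        val = quoted if quoted != "" else bare
        if key == "Lattice":
            cells = [float(v) for v in val.split()]
            if len(cells) != 9:
                raise TrajectoryParseError("Lattice needs 9 numbers", line=lineno)
            box = np.array([cells[0], cells[4], cells[8]])
        elif key == "Properties":
            continue
        else:
            try:
                obs[key] = float(val)
            except ValueError:
                obs[key] = val
    if box is None:
        raise TrajectoryParseError("missing Lattice in comment line", line=lineno)
    return box, obs


def read_frames(path):
    """Yield TrajectoryFrame objects one at a time (streaming)."""
    frame_no = 0
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if header == "":
                return
            header = header.strip()
            if header == "":
                continue
            try:
                n = int(header)
            except ValueError:
                raise TrajectoryParseError(
                    f"expected atom count, got {header!r}", line=lineno,
                    last_good_frame=frame_no - 1 if frame_no else None)
            comment = fh.readline()
            lineno += 1
            if comment == "":
                raise TrajectoryParseError("truncated frame header", line=lineno,
                                           last_good_frame=frame_no - 1 if frame_no else None)
            box, obs = _parse_comment(comment.strip(), lineno)
            species = []
            pos = np.empty((n, 3))
            for i in range(n):
                line = fh.readline()
                lineno += 1
                if line == "":
                    raise TrajectoryParseError(
                        f"truncated frame (expected {n} sites, got {i})",
                        line=lineno, last_good_frame=frame_no - 1 if frame_no else None)
                parts = line.split()
                if len(parts) < 4:
                    raise TrajectoryParseError(f"bad site line {line!r}", line=lineno,
                                               last_good_frame=frame_no - 1 if frame_no else None)
                species.append(parts[0])
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            yield TrajectoryFrame(species, pos, box, obs)
            frame_no += 1


def read_trajectory(path):
    """Read a whole file into a list of frames (small files only)."""
    return list(read_frames(path))


# --- observables CSV ----------------------------------------------------------

OBS_COLUMNS = ["step", "time", "T", "P", "V", "mie", "coulomb_real",
               "coulomb_recip", "coulomb_self", "bond", "bend", "dihedral",
               "kinetic", "potential", "total", "conserved"]


class ObservableWriter:
    """Streams per-step observables to CSV."""

    def __init__(self, path):
        self._fh = open(path, "w", newline="")
        self._writer = csv.writer(self._fh)
        self._writer.writerow(OBS_COLUMNS)

    def write(self, step, obs):
        terms = obs.energy_terms
        row = [step, obs.time, obs.temperature, obs.pressure_atm, obs.volume]
        row += [terms.get(k, 0.0) for k in ("mie", "coulomb_real", "coulomb_recip",
                                            "coulomb_self", "bond", "bend", "dihedral")]
        row += [obs.kinetic, obs.potential, obs.total_energy, obs.conserved]
        self._writer.writerow([f"{v:.10g}" if isinstance(v, float) else v for v in row])

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def frames_from_trajectory(traj, topology):
    """Adapt an in-memory engine Trajectory to TrajectoryFrame objects."""
    labels = topology.site_type_labels().tolist()
    for (pos, box), rec in zip(traj.frames, traj.records):
        obs = {"time": rec.time, "T": rec.temperature, "P": rec.pressure_atm,
               "V": rec.volume, "E": rec.total_energy}
        yield TrajectoryFrame(labels, pos, box, obs)
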