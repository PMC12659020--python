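"""Extended-XYZ reading and writing.

Speaks the common dialect: per-frame comment line with `Lattice="..."`,
`Properties=species:S:1:pos:R:3[:forces:R:3]`, and scalar key=value
entries such as `energy=` or `delta_energy=`.  Floats are written with
10 significant digits in a fixed column order so fixture files are
byte-for-byte reproducible.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .structures import AtomicConfiguration, Trajectory


class ExtXYZError(ValueError):
    """Raised on malformed extended-XYZ input."""


_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')

_FLOAT_FMT = "%.10g"


def _parse_comment(line: str) -> dict:
    out = {}
    for m in _KV_RE.finditer(line):
        key = m.group(1)
        val = m.group(2) if m.group(2) is not None else m.group(3)
        out[key] = val
    return out


def _parse_properties(prop: str) -> list[tuple[str, str, int]]:
    toks = prop.split(":")
    if len(toks) % 3 != 0:
        raise ExtXYZError(f"malformed Properties string: {prop!r}")
    return [(toks[i], toks[i + 1], int(toks[i + 2])) for i in range(0, len(toks), 3)]


def read_extxyz(path: Union[str, Path]) -> Trajectory:
    """Read all frames of an extended-XYZ file into a Trajectory."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[AtomicConfiguration] = []
    i = 0
    n_frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ExtXYZError(f"frame {n_frame}: bad atom-count header {lines[i]!r}") from exc
        if i + 1 + natoms > len(lines):
            raise ExtXYZError(f"frame {n_frame}: truncated ({natoms} atoms declared)")
        meta = _parse_comment(lines[i + 1])

        cell = None
        if "Lattice" in meta:
            vals = [float(x) for x in meta["Lattice"].split()]
            if len(vals) != 9:
                raise ExtXYZError(f"frame {n_frame}: Lattice needs 9 numbers")
            cell = np.array(vals).reshape(3, 3)

        props = _parse_properties(meta.get("Properties", "species:S:1:pos:R:3"))
        elements: list[str] = []
        cols: dict[str, list] = {name: [] for name, _, _ in props}
        for k in range(natoms):
            toks = lines[i + 2 + k].split()
            pos = 0
            for name, kind, ncol in props:
                chunk = toks[pos:pos + ncol]
                if len(chunk) != ncol:
                    raise ExtXYZError(f"frame {n_frame}, atom {k}: too few columns")
                if kind == "S":
                    cols[name].extend(chunk)
                else:
                    cols[name].extend(float(x) for x in chunk)
                pos += ncol
        elements = list(cols["species"])
        positions = np.array(cols["pos"], dtype=float).reshape(natoms, 3)
        forces = None
        if "forces" in cols:
            forces = np.array(cols["forces"], dtype=float).reshape(natoms, 3)

        energy = float(meta["energy"]) if "energy" in meta else None
        info = {}
        for key, val in meta.items():
            if key in ("Lattice", "Properties", "energy"):
                continue
            try:
                info[key] = float(val)
            except ValueError:
                info[key] = val

        frames.append(AtomicConfiguration(elements=elements, positions=positions,
                                          cell=cell, energy=energy, forces=forces, info=info))
        i += 2 + natoms
        n_frame += 1
    if not frames:
        raise ExtXYZError(f"{path}: no frames found")
    return Trajectory(frames)


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_extxyz(traj_or_frames: Union[Trajectory, Iterable[AtomicConfiguration]],
                 path: Union[str, Path]) -> None:
    """Write frames to extended-XYZ with reproducible float formatting."""
    frames = list(traj_or_frames.frames if isinstance(traj_or_frames, Trajectory) else traj_or_frames)
    if not frames:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    out: list[str] = []
    for cfg in frames:
        out.append(str(cfg.n_atoms))
        parts = []
        if cfg.cell is not None:
            flat = " ".join(_fmt(v) for v in cfg.cell.ravel())
            parts.append(f'Lattice="{flat}"')
        prop = "species:S:1:pos:R:3"
        if cfg.forces is not None:
            prop += ":forces:R:3"
        parts.append(f"Properties={prop}")
        if cfg.energy is not None:
            parts.append(f"energy={_fmt(cfg.energy)}")
        for key in sorted(cfg.info):
            val = cfg.info[key]
            sval = _fmt(val) if isinstance(val, float) else str(val)
            parts.append(f"{key}={sval}")
        out.append(" ".join(parts))
        for k in range(cfg.n_atoms):
            row = [f"{cfg.elements[k]:2s}"] + [_fmt(v) for v in cfg.positions[k]]
            if cfg.forces is not None:
                row += [_fmt(v) for v in cfg.forces[k]]
            out.append(" ".join(row))
    path.write_text("\n".join(out) + "\n")
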