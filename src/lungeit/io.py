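"""Plain-text readers and writers.

Measurement frames travel as delimited text with columns
``frame_id  injection  measurement  value_real  value_imag`` so that
external acquisitions (frame x channel tables) can be imported without a
proprietary container. Meshes use the Gmsh MSH 2.2 ASCII layout; electrode
sets, patterns and solver reports serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import VoltageFrame
from .mesh import ElectrodeSet, StimPattern, TriMesh

__all__ = [
    "write_frames",
    "read_frames",
    "write_msh",
    "read_msh",
    "electrodes_to_dict",
    "electrodes_from_dict",
    "pattern_to_dict",
    "pattern_from_dict",
    "write_fom_csv",
]

_FRAME_COLS = ["frame_id", "injection", "measurement", "value_real", "value_imag"]


def write_frames(path, frames: list[VoltageFrame]) -> None:
    rows = []
    for f in frames:
        k = 0
        for inj, meas in enumerate(f.pattern.measurements):
            for m, _pair in enumerate(meas):
                v = complex(f.values[k])
                rows.append((f.label, inj, m, v.real, v.imag))
                k += 1
    pd.DataFrame(rows, columns=_FRAME_COLS).to_csv(path, sep="\t", index=False,
                                                   float_format="%.17g")


def read_frames(path, pattern: StimPattern) -> list[VoltageFrame]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_FRAME_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"frame table missing columns {sorted(missing)}")
    frames = []
    for label, grp in df.groupby("frame_id", sort=False):
        grp = grp.sort_values(["injection", "measurement"], kind="stable")
        vals = grp["value_real"].to_numpy()
        if np.any(grp["value_imag"].to_numpy() != 0):
            vals = vals + 1j * grp["value_imag"].to_numpy()
        frames.append(VoltageFrame(vals, pattern, label=str(label)))
    return frames


def write_msh(path, mesh: TriMesh) -> None:
    """Gmsh MSH 2.2 ASCII: node table + 2D triangle elements."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y) in enumerate(mesh.nodes, 1):
            fh.write(f"{i} {x:.16g} {y:.16g} 0\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_elements}\n")
        for i, (a, b, c) in enumerate(mesh.triangles + 1, 1):
            fh.write(f"{i} 2 2 0 0 {a} {b} {c}\n")
        fh.write("$EndElements\n")


def read_msh(path) -> TriMesh:
    lines = Path(path).read_text().splitlines()
    nodes, tris = [], []
    i = 0
    while i < len(lines):
        if lines[i].strip() == "$Nodes":
            n = int(lines[i + 1])
            for j in range(n):
                parts = lines[i + 2 + j].split()
                nodes.append((float(parts[1]), float(parts[2])))
            i += n + 2
        elif lines[i].strip() == "$Elements":
            n = int(lines[i + 1])
            for j in range(n):
                parts = lines[i + 2 + j].split()
                if int(parts[1]) == 2:           # 3-node triangle
                    ntags = int(parts[2])
                    tris.append(tuple(int(v) - 1 for v in parts[3 + ntags:6 + ntags]))
            i += n + 2
        else:
            i += 1
    if not nodes or not tris:
        raise ValueError("no nodes/triangles found in MSH file")
    return TriMesh(np.array(nodes), np.array(tris))


def electrodes_to_dict(el: ElectrodeSet) -> dict:
    return {"angles": el.angles.tolist(),
            "positions": el.positions.tolist(),
            "width": float(el.width),
            "contact_impedance": np.asarray(el.contact_impedance).tolist()}


def electrodes_from_dict(d: dict) -> ElectrodeSet:
    return ElectrodeSet(np.array(d["angles"]), np.array(d["positions"]),
                        width=d.get("width", 0.0),
                        contact_impedance=np.array(d.get("contact_impedance", 1e-3)))


def pattern_to_dict(p: StimPattern) -> dict:
    return {"injections": [list(x) for x in p.injections],
            "measurements": [[list(x) for x in m] for m in p.measurements],
            "amplitude": p.amplitude}


def pattern_from_dict(d: dict) -> StimPattern:
    return StimPattern([tuple(x) for x in d["injections"]],
                       [[tuple(x) for x in m] for m in d["measurements"]],
                       amplitude=d.get("amplitude", 1.0))


def write_fom_csv(path, rows: list[dict]) -> None:
    """One row per (case, state, method) with the full FoM battery."""
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
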