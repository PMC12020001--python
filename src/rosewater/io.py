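"""File formats: extended XYZ snapshots, CSV tables, TOML configs.

The snapshot dialect is extended XYZ with one 2D molecule per line
(columns x, y, theta) and the rectangular box in the comment line;
writing uses 17 significant digits so read/write round-trips are exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .md import Configuration

__all__ = ["write_xyz", "read_xyz", "write_toml"]


def write_xyz(frames, path: str | Path) -> None:
    """Write one or more configurations as extended XYZ frames."""
    if isinstance(frames, Configuration):
        frames = [frames]
    with open(path, "w") as fh:
        for conf in frames:
            fh.write(f"{conf.n_molecules}\n")
            fh.write(f'box="{conf.box[0]:.17g} {conf.box[1]:.17g}" '
                     'properties=species:S:1:pos:R:2:theta:R:1\n')
            for (x, y), th in zip(conf.positions, conf.orientations):
                fh.write(f"W {x:.17g} {y:.17g} {th:.17g}\n")


def read_xyz(path: str | Path) -> list[Configuration]:
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        comment = lines[i + 1]
        box_str = comment.split('box="')[1].split('"')[0]
        box = np.array([float(v) for v in box_str.split()])
        pos = np.empty((n, 2))
        phi = np.empty(n)
        for j in range(n):
            parts = lines[i + 2 + j].split()
            pos[j] = [float(parts[1]), float(parts[2])]
            phi[j] = float(parts[3])
        frames.append(Configuration(pos, phi, box))
        i += 2 + n
    return frames


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def write_toml(data: dict, path: str | Path) -> None:
    """Minimal TOML writer for flat dicts of scalars/arrays and one
    level of sub-tables."""
    lines = []
    tables = {}
    for k, v in data.items():
        if isinstance(v, dict):
            tables[k] = v
        else:
            lines.append(f"{k} = {_toml_value(v)}")
    for name, tab in tables.items():
        lines.append(f"\n[{name}]")
        for k, v in tab.items():
            lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")
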