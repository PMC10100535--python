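"""Minimal extended-XYZ reader/writer.

Dialect: per frame an atom-count line, a comment line holding ``key=value``
pairs (energies, time stamps), then one ``symbol x y z`` line per atom.
Coordinates are written with 12 decimal places so a write/read round trip is
the identity to 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["XYZFrame", "read_xyz", "write_xyz"]


@dataclass
class XYZFrame:
    symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3), A
    comment: dict[str, float | str] = field(default_factory=dict)


def _format_comment(comment: dict) -> str:
    parts = []
    for k, v in comment.items():
        if isinstance(v, float):
            parts.append(f"{k}={v:.12g}")
        else:
            parts.append(f"{k}={v}")
    return " ".join(parts)


def _parse_comment(line: str) -> dict[str, float | str]:
    out: dict[str, float | str] = {}
    for token in line.split():
        if "=" not in token:
            continue
        k, _, v = token.partition("=")
        try:
            out[k] = float(v)
        except ValueError:
            out[k] = v
    return out


def write_xyz(path: str | Path, frames: list[XYZFrame]) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            n = len(frame.symbols)
            if frame.coords.shape != (n, 3):
                raise ValueError(
                    f"frame has {n} symbols but coordinate shape {frame.coords.shape}"
                )
            fh.write(f"{n}\n{_format_comment(frame.comment)}\n")
            for sym, (x, y, z) in zip(frame.symbols, frame.coords):
                fh.write(f"{sym} {x:.12f} {y:.12f} {z:.12f}\n")


def read_xyz(path: str | Path) -> list[XYZFrame]:
    """Parse an extended-XYZ file; malformed content errors with the line number."""
    lines = Path(path).read_text().splitlines()
    frames: list[XYZFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        k = len(frames)
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise ValueError(f"line {i + 1}: expected an atom count, got {lines[i]!r}") from err
        if i + 1 >= len(lines):
            raise ValueError(f"frame {k}: missing comment line at line {i + 2}")
        comment = _parse_comment(lines[i + 1])
        symbols: list[str] = []
        coords = np.zeros((n, 3))
        for j in range(n):
            ln = i + 2 + j
            if ln >= len(lines):
                raise ValueError(
                    f"frame {k}: header promises {n} atoms but the file ends at line {ln}"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ValueError(
                    f"frame {k}, line {ln + 1}: expected 'symbol x y z', got {lines[ln]!r}"
                )
            symbols.append(parts[0])
            try:
                coords[j] = [float(p) for p in parts[1:4]]
            except ValueError as err:
                raise ValueError(f"line {ln + 1}: bad coordinate in {lines[ln]!r}") from err
        frames.append(XYZFrame(symbols=symbols, coords=coords, comment=comment))
        i += 2 + n
    return frames
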