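"""Readers and writers for (extended) XYZ geometry files and text Hessians.

The extended-XYZ dialect understood here is the common key=value comment
line with a ``Properties=`` descriptor, e.g.::

    3
    Properties=species:S:1:pos:R:3:forces:R:3 energy=-1.234 source=nms
    O  0.0 0.0 0.0  0.01 0.00 0.00
    ...

Plain XYZ (symbol + three coordinates per atom line) is accepted for
unlabeled input.  Hessian matrices travel as whitespace-delimited square
text matrices in eV/Å².
"""

from __future__ import annotations

import re
import shlex
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import CandidateSet, Geometry, Provenance


class GeometryParseError(ValueError):
    """Malformed XYZ/extXYZ content; message names the offending line."""


_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eEdD][+-]?\d+)?$")


def _parse_comment(comment: str) -> dict:
    """Parse an extXYZ ``key=value`` comment line into a dict."""
    out: dict = {}
    try:
        tokens = shlex.split(comment)
    except ValueError:
        return {}
    for tok in tokens:
        if "=" not in tok:
            continue
        key, _, val = tok.partition("=")
        if _NUMERIC_RE.match(val):
            fval = float(val.replace("D", "e").replace("d", "e"))
            out[key] = int(fval) if fval == int(fval) and "." not in val and "e" not in val.lower() else fval
        else:
            out[key] = val
    return out


def _parse_properties(spec: str) -> list[tuple[str, str, int]]:
    fields = spec.split(":")
    if len(fields) % 3 != 0:
        raise GeometryParseError(f"malformed Properties descriptor {spec!r}")
    return [
        (fields[i], fields[i + 1], int(fields[i + 2]))
        for i in range(0, len(fields), 3)
    ]


def read_geometries(path, format: str | None = None) -> list[Geometry]:
    """Read all frames of an XYZ / extended-XYZ file.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"xyz"``, ``"extxyz"`` or ``None`` to auto-detect per frame (a
        frame with a ``Properties=`` comment is treated as extended XYZ).

    Returns
    -------
    list of Geometry
        Energies/forces populated when the extended-XYZ header declares
        them; masses filled from the built-in element table.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    geoms: list[Geometry] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        lineno = i + 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise GeometryParseError(
                f"{path}:{lineno}: expected atom count, got {lines[i]!r}"
            ) from None
        if n_atoms <= 0:
            raise GeometryParseError(
                f"{path}:{lineno}: frame must contain at least one atom"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta = _parse_comment(comment)
        is_ext = "Properties" in meta and format != "xyz"
        if format == "extxyz" and "Properties" not in meta:
            raise GeometryParseError(
                f"{path}:{lineno + 1}: extxyz frame lacks Properties descriptor"
            )
        if is_ext:
            props = _parse_properties(str(meta.pop("Properties")))
        else:
            props = [("species", "S", 1), ("pos", "R", 3)]
        energy = meta.pop("energy", None)
        atom_lines = lines[i + 2 : i + 2 + n_atoms]
        if len(atom_lines) < n_atoms:
            raise GeometryParseError(f"{path}:{lineno}: truncated frame")
        symbols: list[str] = []
        columns: dict[str, list[list[float]]] = {
            name: [] for name, kind, _ in props if kind == "R"
        }
        for j, line in enumerate(atom_lines):
            parts = line.split()
            expected = sum(w for _, _, w in props)
            if len(parts) < expected:
                raise GeometryParseError(
                    f"{path}:{lineno + 2 + j}: expected {expected} columns, "
                    f"got {len(parts)}"
                )
            k = 0
            for name, kind, width in props:
                vals = parts[k : k + width]
                k += width
                if kind == "S":
                    symbols.append(vals[0])
                else:
                    try:
                        columns[name].append([float(v) for v in vals])
                    except ValueError:
                        raise GeometryParseError(
                            f"{path}:{lineno + 2 + j}: non-numeric value in "
                            f"column {name!r}"
                        ) from None
        coords = np.array(columns.get("pos", []), dtype=float)
        forces = columns.get("forces")
        geoms.append(
            Geometry(
                symbols=symbols,
                coords=coords,
                energy=energy,
                forces=None if forces is None else np.array(forces),
                metadata=meta,
            )
        )
        i += 2 + n_atoms
    return geoms


def _format_value(v) -> str:
    if isinstance(v, float):
        return f"{v:.12g}"
    s = str(v)
    return f'"{s}"' if (" " in s or not s) else s


def write_geometries(
    geoms: Sequence[Geometry], path, format: str = "extxyz"
) -> None:
    """Write geometries as (extended) XYZ; round-trips with ``read_geometries``.

    With ``format="xyz"`` only symbols and coordinates are written; with
    the default extended-XYZ dialect, energies, forces and metadata tags
    are serialized in the comment line / per-atom columns when present.
    """
    if len(geoms) == 0:
        raise ValueError("refusing to write an empty geometry list")
    path = Path(path)
    chunks: list[str] = []
    for g in geoms:
        lines = [str(g.n_atoms)]
        if format == "xyz":
            lines.append("")
            for s, xyz in zip(g.symbols, g.coords):
                lines.append(
                    f"{s:<3s} " + " ".join(f"{c: .12e}" for c in xyz)
                )
        else:
            props = "species:S:1:pos:R:3"
            if g.forces is not None:
                props += ":forces:R:3"
            tokens = [f"Properties={props}"]
            if g.energy is not None:
                tokens.append(f"energy={g.energy:.12e}")
            for k, v in g.metadata.items():
                tokens.append(f"{k}={_format_value(v)}")
            lines.append(" ".join(tokens))
            for a in range(g.n_atoms):
                row = f"{g.symbols[a]:<3s} " + " ".join(
                    f"{c: .12e}" for c in g.coords[a]
                )
                if g.forces is not None:
                    row += " " + " ".join(f"{c: .12e}" for c in g.forces[a])
                lines.append(row)
        chunks.append("\n".join(lines))
    path.write_text("\n".join(chunks) + "\n")


def write_candidates(candidates: CandidateSet, path) -> None:
    """Write a candidate set with provenance serialized per frame."""
    tagged = []
    for g, prov in zip(candidates.items, candidates.provenance):
        g = g.copy()
        g.metadata["source"] = prov.source
        if prov.xi is not None:
            g.metadata["xi"] = float(prov.xi)
        if prov.parent is not None:
            g.metadata["parent"] = int(prov.parent)
        tagged.append(g)
    write_geometries(tagged, path)


def read_candidates(path) -> CandidateSet:
    """Read a candidate set written by :func:`write_candidates`."""
    out = CandidateSet()
    for g in read_geometries(path):
        source = g.metadata.pop("source", "nms")
        xi = g.metadata.pop("xi", None)
        parent = g.metadata.pop("parent", None)
        out.append(
            g,
            Provenance(
                source=str(source),
                xi=None if xi is None else float(xi),
                parent=None if parent is None else int(parent),
            ),
        )
    return out


def read_hessian(path, n_atoms: int | None = None) -> np.ndarray:
    """Read a whitespace-delimited square Hessian (eV/Å²) from text."""
    h = np.loadtxt(path)
    h = np.atleast_2d(h)
    if h.shape[0] != h.shape[1]:
        raise ValueError(f"Hessian in {path} is not square: {h.shape}")
    if n_atoms is not None and h.shape[0] != 3 * n_atoms:
        raise ValueError(
            f"Hessian dimension {h.shape[0]} does not match 3N = {3 * n_atoms}"
        )
    return h


def write_hessian(hessian: np.ndarray, path) -> None:
    """Write a Hessian matrix as whitespace-delimited text."""
    hessian = np.asarray(hessian)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ValueError("Hessian must be a square matrix")
    np.savetxt(path, hessian, fmt="% .16e")
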