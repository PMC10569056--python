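"""Molecular geometry containers and provenance-tracking collections.

A :class:`Geometry` is the basic datum the whole pipeline moves around:
element symbols, per-atom masses (amu), Cartesian coordinates (Å) and,
when available, a potential energy (eV) and forces (eV/Å).

:class:`CandidateSet` and :class:`TrainingSet` are ordered collections of
geometries with the bookkeeping the active-learning loop needs: where a
candidate came from (plain normal-mode sampling, the on-path part of the
transition tube, or an endpoint cap) and at which iteration a training
entry was labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

# Conventional atomic weights (IUPAC 2021), amu. "X" is a unit-mass dummy
# particle used for low-dimensional model potentials.
ATOMIC_MASSES: dict[str, float] = {
    "X": 1.0,
    "H": 1.008, "D": 2.014101778, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011,
    "N": 14.007, "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815384, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.95,
    "K": 39.0983, "Ca": 40.078, "Ti": 47.867, "Cr": 51.9961,
    "Mn": 54.938043, "Fe": 55.845, "Ni": 58.6934, "Cu": 63.546,
    "Zn": 65.38, "Br": 79.904, "I": 126.90447,
}

#: allowed provenance sources for candidate geometries
PROVENANCE_SOURCES = ("nms", "tts-path", "tts-cap")


class UnknownElementError(KeyError):
    """Raised when no mass is known for an element symbol."""


def masses_for(symbols: Sequence[str]) -> np.ndarray:
    """Look up per-atom masses (amu) for a sequence of element symbols."""
    out = np.empty(len(symbols))
    for i, s in enumerate(symbols):
        try:
            out[i] = ATOMIC_MASSES[s]
        except KeyError:
            raise UnknownElementError(
                f"no mass known for element {s!r}; pass masses explicitly"
            ) from None
    return out


@dataclass
class Geometry:
    """A molecular configuration with optional energy/force labels.

    Parameters
    ----------
    symbols:
        Element labels, length ``N``.
    coords:
        Cartesian coordinates, Å, shape ``(N, 3)``.
    masses:
        Per-atom masses, amu.  Filled from the built-in element table when
        omitted; an unknown element is then an error, never a silent default.
    energy:
        Potential energy in eV, optional.
    forces:
        Forces in eV/Å, shape ``(N, 3)``, optional.
    metadata:
        Free-form tags (provenance, ξ, parent control point, ...).
    """

    symbols: list[str]
    coords: np.ndarray
    masses: np.ndarray | None = None
    energy: float | None = None
    forces: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = [str(s) for s in self.symbols]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.symbols), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.symbols)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.masses is None:
            self.masses = masses_for(self.symbols)
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (len(self.symbols),):
                raise ValueError("masses length must match number of atoms")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")
        if self.energy is not None:
            self.energy = float(self.energy)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.coords.shape:
                raise ValueError(
                    f"forces shape {self.forces.shape} does not match coords "
                    f"shape {self.coords.shape}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def copy(self) -> "Geometry":
        return Geometry(
            symbols=list(self.symbols),
            coords=self.coords.copy(),
            masses=self.masses.copy(),
            energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
            metadata=dict(self.metadata),
        )

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        """Copy of this geometry with new coordinates and no stale labels."""
        g = self.copy()
        g.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        g.energy = None
        g.forces = None
        return g

    def flat(self) -> np.ndarray:
        """Coordinates flattened to shape ``(3N,)``."""
        return self.coords.reshape(-1)

    def mass_weighted(self) -> np.ndarray:
        """Mass-weighted coordinates ``√m · x``, shape ``(3N,)``, Å·√amu."""
        return self.flat() * np.sqrt(np.repeat(self.masses, 3))


@dataclass(frozen=True)
class Provenance:
    """Where a candidate geometry came from.

    ``source`` is one of ``nms`` (plain thermal normal-mode sampling),
    ``tts-path`` (perpendicular distortion of an on-path reference geometry)
    or ``tts-cap`` (half-Gaussian endpoint cap).  ``xi`` is the reaction
    coordinate of the reference geometry and ``parent`` the index of the
    control point whose local modes generated the distortion.
    """

    source: str
    xi: float | None = None
    parent: int | None = None

    def __post_init__(self) -> None:
        if self.source not in PROVENANCE_SOURCES:
            raise ValueError(
                f"provenance source must be one of {PROVENANCE_SOURCES}, "
                f"got {self.source!r}"
            )
        if self.source == "tts-path":
            if self.xi is None or not (0.0 <= self.xi <= 1.0):
                raise ValueError("tts-path provenance requires xi in [0, 1]")


class CandidateSet:
    """Ordered pool of candidate geometries with per-item provenance."""

    def __init__(
        self,
        items: Sequence[Geometry] = (),
        provenance: Sequence[Provenance] = (),
    ) -> None:
        self.items: list[Geometry] = list(items)
        self.provenance: list[Provenance] = list(provenance)
        if len(self.items) != len(self.provenance):
            raise ValueError("every candidate needs a provenance record")

    def append(self, geometry: Geometry, provenance: Provenance) -> None:
        self.items.append(geometry)
        self.provenance.append(provenance)

    def extend(self, other: "CandidateSet") -> None:
        self.items.extend(other.items)
        self.provenance.extend(other.provenance)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i: int) -> Geometry:
        return self.items[i]

    def __iter__(self) -> Iterator[Geometry]:
        return iter(self.items)


class TrainingSet:
    """Labeled geometries with the QbC iteration at which each was added.

    Every entry must carry both an energy and forces; iteration indices are
    non-decreasing in insertion order.  ``log`` collects the per-iteration
    disagreement records emitted by the active-learning loop.
    """

    def __init__(self) -> None:
        self.entries: list[Geometry] = []
        self.iterations: list[int] = []
        self.log: list[dict] = []

    def add(self, geometry: Geometry, iteration: int) -> None:
        if geometry.energy is None or geometry.forces is None:
            raise ValueError("training entries must carry energy and forces")
        if self.iterations and iteration < self.iterations[-1]:
            raise ValueError(
                "iteration indices must be non-decreasing in insertion order"
            )
        self.entries.append(geometry)
        self.iterations.append(iteration)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> Geometry:
        return self.entries[i]

    def __iter__(self) -> Iterator[Geometry]:
        return iter(self.entries)
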