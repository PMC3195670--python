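"""Core containers for two-helix coordinate data.

Coordinates are in Angstrom throughout.  A :class:`Structure` is one labelled
conformation, a :class:`Trajectory` is an ordered stack of coordinate
snapshots over a fixed topology, and an :class:`Ensemble` is a bag of either,
e.g. the end states of many independent self-assembly simulations.

By convention the bilayer normal is +z; this frame is established by the
density-map fitting step (see :mod:`helixpack.ensemble`), not enforced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Ensemble",
    "HelixSelector",
    "SelectionError",
    "select",
]


class SelectionError(ValueError):
    """An atom selection resolved to nothing or to a missing chain."""


@dataclass(frozen=True)
class Atom:
    """One labelled atom: (chain, author residue number, residue name, atom name)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class Structure:
    """One conformation: parallel arrays of atom labels and positions (A).

    ``meta`` carries free-form construction bookkeeping (synthetic generators
    record their ground truth there).
    """

    atoms: list[Atom]
    coords: np.ndarray  # (n_atoms, 3) float64, Angstrom
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.atoms) == 0:
            raise ValueError("Structure must contain at least one atom")
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def copy(self) -> "Structure":
        return Structure(list(self.atoms), self.coords.copy(), self.label, dict(self.meta))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out


@dataclass
class Trajectory:
    """Ordered frames over one topology.

    ``frames`` is (n_frames, n_atoms, 3); ``frame_times`` (ns) is optional and
    must be strictly increasing.
    """

    topology: Structure
    frames: np.ndarray
    frame_times: np.ndarray | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with topology "
                f"of {self.topology.n_atoms} atoms"
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValueError("frame_times length does not match frame count")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times(self) -> np.ndarray:
        """Frame times in ns, defaulting to the frame index."""
        if self.frame_times is not None:
            return self.frame_times
        return np.arange(self.n_frames, dtype=float)

    def frame(self, i: int) -> Structure:
        """Materialize frame ``i`` as a Structure sharing the topology labels."""
        s = self.topology.copy()
        s.coords = self.frames[i].copy()
        return s


@dataclass
class Ensemble:
    """Unordered bag of Structures and/or Trajectories with per-member provenance."""

    members: list
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [{} for _ in self.members]
        if len(self.provenance) != len(self.members):
            raise ValueError("provenance length must match member count")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def structures(self, member_index: int) -> list[Structure]:
        """All conformations of one member (a Structure yields itself)."""
        m = self.members[member_index]
        if isinstance(m, Trajectory):
            return [m.frame(i) for i in range(m.n_frames)]
        return [m]


@dataclass(frozen=True)
class HelixSelector:
    """Names one helix: chain id, inclusive TM residue range, backbone atom subset."""

    chain_id: str
    residue_range: tuple[int, int]
    atom_names: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if lo > hi:
            raise ValueError(f"residue_range {self.residue_range} is inverted")


def select(
    structure: Structure,
    chain: str,
    residue_range: tuple[int, int] | None = None,
    atom_names: Iterable[str] | None = None,
) -> Structure:
    """Sub-structure matching chain + inclusive residue range + atom-name set.

    Original atom order is preserved.  Raises :class:`SelectionError` when the
    chain is absent or the filters match nothing (an empty helix would break
    axis fitting downstream).
    """
    chains = structure.chain_ids()
    if chain not in chains:
        raise SelectionError(f"chain {chain!r} not present (have {chains})")
    names = set(atom_names) if atom_names is not None else None
    idx = []
    for i, a in enumerate(structure.atoms):
        if a.chain_id != chain:
            continue
        if residue_range is not None and not (
            residue_range[0] <= a.residue_number <= residue_range[1]
        ):
            continue
        if names is not None and a.atom_name not in names:
            continue
        idx.append(i)
    if not idx:
        raise SelectionError(
            f"empty selection: chain={chain!r} residues={residue_range} atoms={atom_names}"
        )
    return Structure(
        [structure.atoms[i] for i in idx],
        structure.coords[idx],
        structure.label,
        dict(structure.meta),
    )


def select_by(structure: Structure, selector: HelixSelector) -> Structure:
    return select(structure, selector.chain_id, selector.residue_range, selector.atom_names)


def selection_indices(topology: Structure, selector: HelixSelector) -> np.ndarray:
    """Indices into a topology's atom list for a helix selector."""
    sub = select_by(topology, selector)
    wanted = {a.key() for a in sub.atoms}
    idx = [i for i, a in enumerate(topology.atoms) if a.key() in wanted]
    return np.asarray(idx, dtype=int)
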