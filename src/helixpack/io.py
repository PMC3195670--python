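"""Structure and ensemble I/O.

Baseline on-disk format is (multi-model) PDB, parsed and written through
gemmi.  Author residue numbering is preserved on read — integrin residues
such as alphaIIb G972/G976 stay addressable exactly as published.  Hydrogens
are dropped by default (all analyses here are heavy-atom) and only the first
alternate location is kept.
"""

from __future__ import annotations

import os
from typing import Sequence

import gemmi
import numpy as np

from .core import Atom, Ensemble, Structure, Trajectory

__all__ = [
    "read_structure",
    "read_ensemble",
    "read_trajectory",
    "write_structure",
    "write_ensemble",
    "write_trajectory",
]


def _is_hydrogen(atom: gemmi.Atom) -> bool:
    h = atom.element.is_hydrogen
    return h() if callable(h) else bool(h)


def _model_to_structure(
    model: gemmi.Model, label: str, keep_hydrogens: bool
) -> Structure:
    atoms: list[Atom] = []
    xyz: list[tuple[float, float, float]] = []
    seen: set[tuple[str, int, str]] = set()
    for chain in model:
        for residue in chain:
            for atom in residue:
                if not keep_hydrogens and _is_hydrogen(atom):
                    continue
                key = (chain.name, residue.seqid.num, atom.name)
                if key in seen:  # first altloc wins
                    continue
                seen.add(key)
                atoms.append(
                    Atom(chain.name, residue.seqid.num, residue.name, atom.name)
                )
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not atoms:
        raise ValueError(f"no atoms parsed from {label}")
    return Structure(atoms, np.array(xyz, dtype=float), label=label)


def _read_models(path: str, keep_hydrogens: bool) -> list[Structure]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    models = []
    for i, model in enumerate(st):
        models.append(
            _model_to_structure(model, f"{os.path.basename(path)}#model{i}", keep_hydrogens)
        )
    if not models:
        raise ValueError(f"{path}: no MODEL records parsed")
    return models


def read_structure(
    path: str, model_index: int | None = None, keep_hydrogens: bool = False
) -> Structure:
    """Read one model from a (possibly multi-model) PDB file.

    ``model_index`` is 0-based; default is the first model.
    """
    models = _read_models(path, keep_hydrogens)
    i = 0 if model_index is None else model_index
    if not (0 <= i < len(models)):
        raise IndexError(
            f"model_index {i} out of range for {path} with {len(models)} model(s)"
        )
    return models[i]


def read_ensemble(
    paths: Sequence[str],
    required_chains: Sequence[str] | None = None,
    keep_hydrogens: bool = False,
) -> Ensemble:
    """Read an ensemble, expanding every model of every file into one member.

    Chain naming must be consistent: when ``required_chains`` is given, any
    member missing one of those chains raises (never silently reindexed).
    """
    members: list[Structure] = []
    provenance: list[dict] = []
    for path in paths:
        for i, s in enumerate(_read_models(path, keep_hydrogens)):
            if required_chains is not None:
                have = set(s.chain_ids())
                missing = [c for c in required_chains if c not in have]
                if missing:
                    raise ValueError(
                        f"{path} model {i}: missing required chain(s) {missing}"
                    )
            members.append(s)
            provenance.append({"source": str(path), "model_index": i})
    return Ensemble(members, provenance)


def read_trajectory(
    path: str, frame_times: np.ndarray | None = None, keep_hydrogens: bool = False
) -> Trajectory:
    """Read a multi-model PDB as an ordered trajectory (one model per frame)."""
    models = _read_models(path, keep_hydrogens)
    top = models[0]
    keys = [a.key() for a in top.atoms]
    frames = np.empty((len(models), top.n_atoms, 3))
    for i, m in enumerate(models):
        if [a.key() for a in m.atoms] != keys:
            raise ValueError(f"{path} model {i}: topology differs from model 0")
        frames[i] = m.coords
    return Trajectory(top, frames, frame_times, label=os.path.basename(path))


def _structures_to_gemmi(structures: Sequence[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structures[0].label or "helixpack"
    for mi, s in enumerate(structures):
        model = gemmi.Model(mi + 1)
        chains: dict[str, gemmi.Chain] = {}
        residues: dict[tuple[str, int], gemmi.Residue] = {}
        for atom, pos in zip(s.atoms, s.coords):
            if atom.chain_id not in chains:
                chains[atom.chain_id] = gemmi.Chain(atom.chain_id)
            rkey = (atom.chain_id, atom.residue_number)
            if rkey not in residues:
                res = gemmi.Residue()
                res.name = atom.residue_name
                res.seqid = gemmi.SeqId(atom.residue_number, " ")
                chains[atom.chain_id].add_residue(res)
                residues[rkey] = chains[atom.chain_id][-1]
            ga = gemmi.Atom()
            ga.name = atom.atom_name
            ga.element = gemmi.Element(atom.atom_name[:1])
            ga.pos = gemmi.Position(*pos)
            residues[rkey].add_atom(ga)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
    return st


def write_structure(structure: Structure, path: str) -> None:
    """Write a single-model PDB file."""
    _structures_to_gemmi([structure]).write_pdb(str(path))


def write_ensemble(ensemble: Ensemble, path: str) -> None:
    """Write an ensemble of Structures as a multi-model PDB (MODEL/ENDMDL)."""
    structures = []
    for i in range(len(ensemble)):
        structures.extend(ensemble.structures(i))
    _structures_to_gemmi(structures).write_pdb(str(path))


def write_trajectory(trajectory: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB, one model per frame."""
    frames = [trajectory.frame(i) for i in range(trajectory.n_frames)]
    _structures_to_gemmi(frames).write_pdb(str(path))
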