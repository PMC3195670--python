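"""Helix/helix interface characterization.

Which residues form the packing interface, and which way do they point?
Right-handed GxxxG-mediated dimers bury the glycine face (e.g. G972/G976 of
an alphaIIb-like helix) against bulky partner side chains (M701/I704-like),
while the left-handed alternative turns that face away — so residue
orientation relative to the partner axis, together with the inter-chain
contact set, discriminates packing modes and lets a predicted interface be
compared against an experimental one by set overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import Structure, select
from .geometry import HelixAxis, fit_helix_axis, segment_closest_points

__all__ = [
    "ContactSet",
    "OrientationReport",
    "contact_map",
    "interface_residues",
    "residue_orientation",
    "interface_overlap",
]

#: atoms that never define a side-chain "heavy atom beyond CB"
_BACKBONE_LIKE = {"N", "CA", "C", "O", "CB", "BB", "OXT"}


@dataclass(frozen=True)
class ContactSet:
    """Inter-chain residue contacts at a distance cutoff.

    Each contact is (residue_a, residue_b, minimum distance A), recorded
    once per pair.  ``mode`` records the distance definition used:
    ``heavy`` (minimum heavy-atom distance, atomistic structures) or
    ``center`` (Calpha-Calpha distance, backbone-only or CG-like inputs).
    """

    contacts: frozenset[tuple[int, int, float]]
    cutoff: float
    chain_a: str
    chain_b: str
    mode: str

    def pairs(self) -> set[tuple[int, int]]:
        return {(a, b) for a, b, _ in self.contacts}


@dataclass(frozen=True)
class OrientationReport:
    """Does a residue's side chain point at the partner helix?

    ``azimuth_to_partner`` is the in-plane angle (deg, [0, 180]) between the
    side-chain direction and the direction from the residue to the partner
    axis; below 60 deg counts as "toward", above 120 deg as "away",
    otherwise "lateral" (thresholds configurable).
    """

    residue: tuple[str, int]
    azimuth_to_partner: float
    facing: str


def _has_sidechain_atoms(s: Structure) -> bool:
    return any(a.atom_name not in _BACKBONE_LIKE for a in s.atoms)


def contact_map(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    cutoff: float | None = None,
) -> ContactSet:
    """All inter-chain residue pairs within a distance cutoff.

    With full atomistic chains the distance is the minimum heavy-atom
    distance (default cutoff 4.5 A); when either chain carries only
    backbone-level atoms (CA/CB and the like) a residue-centre
    (Calpha-Calpha) distance with a 7 A default cutoff is used instead.
    Pass ``cutoff`` explicitly to override either default.
    """
    sa = select(structure, chain_a)
    sb = select(structure, chain_b)
    heavy = _has_sidechain_atoms(sa) and _has_sidechain_atoms(sb)
    if heavy:
        mode = "heavy"
        cut = 4.5 if cutoff is None else cutoff
        ca_sel, cb_sel = sa, sb
    else:
        mode = "center"
        cut = 7.0 if cutoff is None else cutoff
        ca_sel = select(structure, chain_a, atom_names={"CA"})
        cb_sel = select(structure, chain_b, atom_names={"CA"})
    res_a = np.array([a.residue_number for a in ca_sel.atoms])
    res_b = np.array([a.residue_number for a in cb_sel.atoms])
    d = cdist(ca_sel.coords, cb_sel.coords)
    contacts = {}
    for i, j in zip(*np.nonzero(d <= cut)):
        key = (int(res_a[i]), int(res_b[j]))
        val = float(d[i, j])
        if key not in contacts or val < contacts[key]:
            contacts[key] = val
    return ContactSet(
        frozenset((a, b, dist) for (a, b), dist in contacts.items()),
        cut,
        chain_a,
        chain_b,
        mode,
    )


def interface_residues(contacts: ContactSet) -> tuple[list[int], list[int]]:
    """Project the contact pairs onto each chain (sorted residue numbers)."""
    a = sorted({p[0] for p in contacts.contacts})
    b = sorted({p[1] for p in contacts.contacts})
    return a, b


def residue_orientation(
    structure: Structure,
    residue: tuple[str, int],
    partner_axis: HelixAxis,
    toward_threshold: float = 60.0,
    away_threshold: float = 120.0,
) -> OrientationReport:
    """Classify one residue as facing toward/away from the partner helix.

    The side-chain direction is Calpha->Cbeta; for glycine (no Cbeta) the
    outward radial vector from the residue's own helix axis through the
    Calpha is used.  Both that direction and the Calpha->partner-axis vector
    are projected onto the plane normal to the residue's own helix axis
    before measuring the angle.
    """
    chain, resnum = residue
    own = select(structure, chain, atom_names={"CA"})
    own_axis = fit_helix_axis(own.coords)
    try:
        ca = select(structure, chain, (resnum, resnum), {"CA"}).coords[0]
    except Exception as exc:
        raise ValueError(f"residue {residue} has no Calpha") from exc
    try:
        cb = select(structure, chain, (resnum, resnum), {"CB"}).coords[0]
        side = cb - ca
    except Exception:
        # glycine-style fallback: radial vector from the own axis through CA
        foot = own_axis.anchor + (
            (ca - own_axis.anchor) @ own_axis.direction
        ) * own_axis.direction
        side = ca - foot
    pa, pb = segment_closest_points(
        ca, ca, partner_axis.start, partner_axis.end
    )
    to_partner = pb - ca
    n = own_axis.direction

    def project(v: np.ndarray) -> np.ndarray:
        return v - (v @ n) * n

    sp = project(side)
    tp = project(to_partner)
    if np.linalg.norm(sp) < 1e-9 or np.linalg.norm(tp) < 1e-9:
        raise ValueError(f"degenerate orientation geometry for residue {residue}")
    cosang = float(sp @ tp / (np.linalg.norm(sp) * np.linalg.norm(tp)))
    azim = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if azim < toward_threshold:
        facing = "toward"
    elif azim > away_threshold:
        facing = "away"
    else:
        facing = "lateral"
    return OrientationReport((chain, resnum), azim, facing)


def interface_overlap(set_a, set_b) -> float:
    """Jaccard index of two interface residue sets (1.0 when both empty)."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
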