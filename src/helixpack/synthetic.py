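"""Synthetic two-helix systems with full construction bookkeeping.

Every generator here emulates one class of input the analysis pipeline
consumes — idealized TM helices, dimers at prescribed crossing angle and
interface orientation, mode-mixture ensembles, diffusion/association
trajectories, drifting trajectories, and rotation scans — and records its
ground truth in ``meta``/provenance so each analysis is testable as
parameter recovery.

There is no physics here: no forcefield, no lipids, no thermodynamics.  The
geometry is an idealized alpha-helix (1.5 A rise, 100 deg twist per residue,
2.3 A Calpha radius — textbook values) threaded with a user sequence so that
key residues (e.g. glycines of a GxxxG motif at 972/976-like positions) sit
at chosen azimuths of the helix face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .core import Atom, Ensemble, Structure, Trajectory, HelixSelector, select
from .geometry import fit_helix_axis, kabsch_superpose

__all__ = [
    "HelixSpec",
    "DimerSpec",
    "ModeSpec",
    "EnsembleSpec",
    "build_ideal_helix",
    "build_dimer",
    "generate_mode_ensemble",
    "generate_assembly_trajectory",
    "generate_drift_trajectory",
    "generate_rotation_scan",
    "residue_azimuth",
    "alpha_like_spec",
    "beta_like_spec",
    "default_ensemble_spec",
    "DEFAULT_MODES",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class HelixSpec:
    """Geometry and labelling of one ideal helix.

    ``sequence`` is a 1-letter string (defaults to poly-leucine); glycines
    get no pseudo-Cbeta.  ``start_residue`` sets author numbering so that
    published residue numbers (G972/G976, M701/I704/G708) are addressable.
    """

    n_residues: int = 24
    sequence: str | None = None
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    radius: float = 2.3
    cbeta: bool = True
    start_residue: int = 1
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.n_residues < 8:
            raise ValueError("n_residues must be >= 8")
        if self.rise_per_residue <= 0 or self.radius <= 0:
            raise ValueError("rise and radius must be positive")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")

    def resolved_sequence(self) -> str:
        return self.sequence if self.sequence is not None else "L" * self.n_residues


@dataclass(frozen=True)
class DimerSpec:
    """Placement of helix B relative to helix A.

    ``interface_azimuth_*`` select which intrinsic helix face (see
    :func:`residue_azimuth`) points at the partner; ``omega_target`` is the
    signed crossing angle imposed by rotating helix B about the interhelix
    connector (negative = right-handed).
    """

    omega_target: float = -30.0
    axis_separation: float = 10.0
    interface_azimuth_a: float = 0.0
    interface_azimuth_b: float = 0.0
    z_offset: float = 0.0


@dataclass(frozen=True)
class ModeSpec:
    """One packing mode of a mixture ensemble.

    ``azimuth`` is the position of the mobile helix around the reference
    helix, measured in the reference helix's own frame — distinct modes
    occupy distinct faces of the reference, which is exactly what the
    spatial density map resolves.  ``face_offset`` spins the mobile helix
    about its own axis relative to its default partner-facing orientation:
    0 keeps its labelled face (e.g. the GxxxG glycines) pointed at the
    partner, 180 turns it away — the geometric difference between the
    right- and left-handed dimers.
    """

    label: str
    weight: float
    omega_mean: float
    omega_sd: float
    azimuth: float  # placement azimuth of the mobile helix, degrees
    positional_sd: float = 1.5  # arc-length jitter of the placement, A
    face_offset: float = 0.0  # mobile-helix spin away from partner-facing, deg


#: Default mixture emulating the bimodal CG ensemble: a 70% right-handed
#: mode centred at -30 deg with the glycine face buried, and a 30%
#: left-handed mode centred at +30 deg on the opposite reference face with
#: the glycine face turned away.  The 70/30 weights and the -30 deg RH
#: centre are the published values; the LH centre and the spreads are
#: documented choices.
DEFAULT_MODES = (
    ModeSpec("RH1", 0.70, -30.0, 8.0, 0.0, 1.5, 0.0),
    ModeSpec("LH", 0.30, +30.0, 10.0, 180.0, 1.5, 180.0),
)


@dataclass(frozen=True)
class EnsembleSpec:
    """Mixture-ensemble recipe: modes, size, seed, and the dimer geometry."""

    modes: tuple[ModeSpec, ...] = DEFAULT_MODES
    n_members: int = 1000
    seed: int = 0
    axis_separation: float = 10.0
    helix_a: HelixSpec | None = None
    helix_b: HelixSpec | None = None

    def __post_init__(self) -> None:
        w = np.array([m.weight for m in self.modes])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mode weights must be >= 0 and sum to 1")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


def alpha_like_spec() -> HelixSpec:
    """alphaIIb-like helix: chain A, residues 963-986, glycines at 972/976."""
    seq = list("L" * 24)
    seq[972 - 963] = "G"
    seq[976 - 963] = "G"
    seq[980 - 963] = "L"
    return HelixSpec(n_residues=24, sequence="".join(seq), start_residue=963, chain_id="A")


def beta_like_spec() -> HelixSpec:
    """beta3-like helix: chain B, residues 692-714, M701/I704/G708 markers."""
    seq = list("L" * 23)
    seq[701 - 692] = "M"
    seq[704 - 692] = "I"
    seq[708 - 692] = "G"
    return HelixSpec(n_residues=23, sequence="".join(seq), start_residue=692, chain_id="B")


def default_ensemble_spec(n_members: int = 1000, seed: int = 0) -> EnsembleSpec:
    return EnsembleSpec(
        modes=DEFAULT_MODES,
        n_members=n_members,
        seed=seed,
        helix_a=alpha_like_spec(),
        helix_b=beta_like_spec(),
    )


def residue_azimuth(spec: HelixSpec, residue_number: int) -> float:
    """Intrinsic azimuth (deg, [0, 360)) of a residue's Calpha on the helix face.

    Residue i (0-based from ``start_residue``) sits at ``i * twist`` degrees
    in the helix's own frame; a DimerSpec interface azimuth equal to this
    value points that residue straight at the partner helix.
    """
    i = residue_number - spec.start_residue
    if not (0 <= i < spec.n_residues):
        raise ValueError(f"residue {residue_number} outside spec range")
    return float((i * spec.twist_per_residue) % 360.0)


def build_ideal_helix(spec: HelixSpec) -> Structure:
    """Ideal alpha-helix along +z, N->C with increasing z, centroid at origin.

    Calpha atoms lie on a helical curve of the given rise/twist/radius;
    non-glycine residues optionally get a pseudo-Cbeta 1.5 A radially
    outward from the Calpha, giving every residue a defined side-chain
    direction without building side chains.
    """
    seq = spec.resolved_sequence()
    atoms: list[Atom] = []
    xyz: list[np.ndarray] = []
    for i in range(spec.n_residues):
        phi = math.radians(i * spec.twist_per_residue)
        z = i * spec.rise_per_residue
        ca = np.array([spec.radius * math.cos(phi), spec.radius * math.sin(phi), z])
        resnum = spec.start_residue + i
        resname = _ONE_TO_THREE.get(seq[i].upper(), "UNK")
        atoms.append(Atom(spec.chain_id, resnum, resname, "CA"))
        xyz.append(ca)
        if spec.cbeta and seq[i].upper() != "G":
            radial = np.array([math.cos(phi), math.sin(phi), 0.0])
            atoms.append(Atom(spec.chain_id, resnum, resname, "CB"))
            xyz.append(ca + 1.5 * radial)
    coords = np.array(xyz)
    ca_mask = np.array([a.atom_name == "CA" for a in atoms])
    coords -= coords[ca_mask].mean(axis=0)
    # a finite helix's principal axis tilts slightly off the construction
    # axis (partial-turn asymmetry); re-align so the *fitted* axis is
    # exactly +z and downstream angle targets are met without bias
    fitted = fit_helix_axis(coords[ca_mask])
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(fitted.direction, z)
    s_norm = np.linalg.norm(v)
    if s_norm > 1e-12:
        ang = math.degrees(math.atan2(s_norm, float(fitted.direction @ z)))
        coords = coords @ _rotation_about(v, ang).T
        coords -= coords[ca_mask].mean(axis=0)
    s = Structure(atoms, coords, label=f"ideal-helix:{spec.chain_id}")
    s.meta["helix_spec"] = spec
    return s


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    return Rotation.from_rotvec(
        np.radians(angle_deg) * axis / np.linalg.norm(axis)
    ).as_matrix()


def _merge(a: Structure, b: Structure, label: str = "") -> Structure:
    return Structure(a.atoms + b.atoms, np.vstack([a.coords, b.coords]), label=label)


def build_dimer(
    spec_a: HelixSpec, spec_b: HelixSpec, dimer: DimerSpec
) -> Structure:
    """Construct a two-helix dimer with prescribed crossing angle and faces.

    Helix A stands on +z at the origin, spun so its ``interface_azimuth_a``
    face points at B (+x).  Helix B is spun so its ``interface_azimuth_b``
    face points back at A, rotated by ``omega_target`` about the interhelix
    connector (which sets the signed crossing angle by construction), and
    placed at ``axis_separation`` along +x.  Construction parameters are
    recorded in ``meta``.
    """
    if spec_a.chain_id == spec_b.chain_id:
        spec_b = replace(spec_b, chain_id=spec_a.chain_id + "2")
    ha = build_ideal_helix(spec_a)
    hb = build_ideal_helix(spec_b)
    z = np.array([0.0, 0.0, 1.0])
    ha.coords = ha.coords @ _rotation_about(z, -dimer.interface_azimuth_a).T
    hb.coords = hb.coords @ _rotation_about(z, 180.0 - dimer.interface_azimuth_b).T
    offset = np.array([dimer.axis_separation, 0.0, dimer.z_offset])
    connector = offset / np.linalg.norm(offset)
    hb.coords = hb.coords @ _rotation_about(connector, dimer.omega_target).T
    hb.coords = hb.coords + offset
    if dimer.axis_separation <= 2 * max(spec_a.radius, spec_b.radius):
        raise ValueError("axis_separation must exceed twice the helix radius")
    from scipy.spatial.distance import cdist

    if cdist(ha.coords, hb.coords).min() < 2.0:
        raise ValueError("infeasible dimer geometry: interhelix clash (< 2 A)")
    s = _merge(ha, hb, label=f"dimer omega={dimer.omega_target:+.1f}")
    s.meta.update(
        {
            "dimer_spec": dimer,
            "spec_a": spec_a,
            "spec_b": spec_b,
            "omega_true": dimer.omega_target,
        }
    )
    return s


def glycine_face_azimuth(spec: HelixSpec) -> float:
    """Intrinsic azimuth of the midpoint of the G972/G976-like glycine face.

    Falls back to the azimuth midway between the first two glycines of the
    sequence, or 0 for a glycine-free helix.
    """
    seq = spec.resolved_sequence().upper()
    gly = [spec.start_residue + i for i, c in enumerate(seq) if c == "G"]
    if not gly:
        return 0.0
    if len(gly) == 1:
        return residue_azimuth(spec, gly[0])
    a1 = residue_azimuth(spec, gly[0])
    a2 = residue_azimuth(spec, gly[1])
    # midpoint along the shorter arc
    diff = (a2 - a1 + 180.0) % 360.0 - 180.0
    return float((a1 + diff / 2.0) % 360.0)


def generate_mode_ensemble(spec: EnsembleSpec | None = None) -> Ensemble:
    """Sample a mixture ensemble of dimers from packing modes.

    The reference helix (``helix_b``, the beta3-like chain) stands on +z at
    the origin; each member picks a mode by weight, draws a crossing angle
    from Normal(omega_mean, omega_sd), and places the mobile helix
    (``helix_a``) around the reference at the mode azimuth with arc-length
    jitter Normal(0, positional_sd).  The mobile helix keeps its glycine
    face pointed at the partner, offset by the mode's ``face_offset``, and
    is tilted about the interhelix connector so the measured signed crossing
    angle equals the drawn one.  Seeded and reproducible; the true mode
    label, angle, and azimuth go to provenance.
    """
    spec = spec or default_ensemble_spec()
    rng = np.random.default_rng(spec.seed)
    ha = spec.helix_a or alpha_like_spec()
    hb = spec.helix_b or beta_like_spec()
    if ha.chain_id == hb.chain_id:
        raise ValueError("the two helices must have distinct chain ids")
    weights = np.array([m.weight for m in spec.modes])
    mode_idx = rng.choice(len(spec.modes), size=spec.n_members, p=weights)
    z = np.array([0.0, 0.0, 1.0])
    ref = build_ideal_helix(hb)
    mob0 = build_ideal_helix(ha)
    face_a = glycine_face_azimuth(ha)
    members: list[Structure] = []
    provenance: list[dict] = []
    for k in range(spec.n_members):
        mode = spec.modes[mode_idx[k]]
        omega = float(rng.normal(mode.omega_mean, mode.omega_sd))
        arc_sd_deg = math.degrees(mode.positional_sd / spec.axis_separation)
        azimuth = float(mode.azimuth + rng.normal(0.0, arc_sd_deg))
        mob = mob0.copy()
        # spin so the (offset) glycine face points from the mobile helix
        # back toward the reference at the origin
        spin = (azimuth + 180.0) - (face_a + mode.face_offset)
        mob.coords = mob.coords @ _rotation_about(z, spin).T
        connector = np.array(
            [math.cos(math.radians(azimuth)), math.sin(math.radians(azimuth)), 0.0]
        )
        mob.coords = mob.coords @ _rotation_about(connector, omega).T
        mob.coords = mob.coords + spec.axis_separation * connector
        d = _merge(mob, ref, label=f"member{k}:{mode.label}")
        d.meta.update(
            {
                "mode": mode.label,
                "omega_true": omega,
                "placement_azimuth": azimuth,
                "face_offset": mode.face_offset,
            }
        )
        members.append(d)
        provenance.append(
            {"mode": mode.label, "omega_true": omega, "azimuth": azimuth, "index": k}
        )
    return Ensemble(members, provenance)


def generate_assembly_trajectory(
    initial_separation: float = 60.0,
    step_sd: float = 1.0,
    n_frames: int = 300,
    bind_frame: int | None = None,
    seed: int | None = 0,
    dt_ns: float = 1.0,
    spec_a: HelixSpec | None = None,
    spec_b: HelixSpec | None = None,
    contact_distance: float = 8.0,
    bound_separation: float = 7.0,
    tilt_sd: float = 1.0,
) -> Trajectory:
    """Diffusion/association trajectory of two helices in the bilayer plane.

    The helices start exactly ``initial_separation`` apart (axis centroids,
    xy plane), stand near-vertical with small tilt jitter, and their relative
    centre performs a seeded 2D random walk.  With ``bind_frame`` set the
    centres are steered so the first approach below ``contact_distance``
    happens at exactly that frame and the pair stays bound afterwards.
    """
    if initial_separation <= contact_distance:
        raise ValueError("initial_separation must exceed contact_distance")
    rng = np.random.default_rng(seed)
    ha = build_ideal_helix(spec_a or alpha_like_spec())
    hb = build_ideal_helix(spec_b or beta_like_spec())
    top = _merge(ha, hb, label="assembly")
    is_b = np.array([a.chain_id in hb.chain_ids() for a in top.atoms])

    # relative-walk polar coordinates of helix B's centre around helix A
    steps = rng.normal(0.0, step_sd, size=(n_frames, 2))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0) + np.array([initial_separation, 0.0])
    theta = np.arctan2(walk[:, 1], walk[:, 0])
    if bind_frame is None:
        r = np.linalg.norm(walk, axis=1)
    else:
        if not (0 < bind_frame < n_frames):
            raise ValueError("bind_frame must lie inside the trajectory")
        t = np.arange(n_frames, dtype=float)
        approach = initial_separation + (9.0 - initial_separation) * t / bind_frame
        noise = rng.normal(0.0, 0.3 * step_sd, size=n_frames)
        noise[0] = 0.0
        # pre-bind: steered approach, floored safely above the contact cutoff;
        # post-bind: held below it
        r = np.maximum(contact_distance + 1.5, approach + noise)
        bound = bound_separation + np.clip(
            rng.normal(0.0, 0.2, size=n_frames), -0.5, 0.5
        )
        r[bind_frame:] = np.minimum(bound[bind_frame:], contact_distance - 0.5)
        r[0] = initial_separation

    ca_mask = np.array([a.atom_name == "CA" for a in top.atoms])
    frames = np.empty((n_frames, top.n_atoms, 3))
    for i in range(n_frames):
        coords = top.coords.copy()
        if i > 0 and tilt_sd > 0:
            # small independent tilts about each helix's Calpha centroid keep
            # the axis anchors (hence the separation series) untouched
            for mask in (~is_b, is_b):
                a = rng.uniform(0, 2 * math.pi)
                axis = np.array([math.cos(a), math.sin(a), 0.0])
                R = _rotation_about(axis, rng.normal(0.0, tilt_sd))
                c = coords[mask & ca_mask].mean(axis=0)
                coords[mask] = (coords[mask] - c) @ R.T + c
        target = np.array([r[i] * math.cos(theta[i]), r[i] * math.sin(theta[i]), 0.0])
        coords[is_b] += target - coords[is_b & ca_mask].mean(axis=0)
        frames[i] = coords
    traj = Trajectory(
        top,
        frames,
        frame_times=np.arange(n_frames) * dt_ns,
        label="assembly-trajectory",
        meta={
            "bind_frame": bind_frame,
            "initial_separation": initial_separation,
            "contact_distance": contact_distance,
            "separations": r,
        },
    )
    return traj


def generate_drift_trajectory(
    start: Structure,
    terminal_rmsd: float,
    n_frames: int = 60,
    mode: str = "plateau",
    noise_sd: float = 0.2,
    seed: int | None = 0,
    time_span_ns: float = 30.0,
) -> Trajectory:
    """Trajectory whose superposed-RMSD-from-start series is shaped on purpose.

    ``plateau`` ramps quickly (first 10% of frames) to ``terminal_rmsd`` and
    fluctuates there — the signature of a conformationally stable model;
    ``ramp`` grows linearly so the final frame sits at ``terminal_rmsd`` —
    the steady rise of an unstable one.  The deformation is a fixed random
    per-atom displacement field scaled per frame, calibrated by root-finding
    so the quoted RMSDs are the post-superposition values.
    """
    if terminal_rmsd < 0:
        raise ValueError("terminal_rmsd must be >= 0")
    if mode not in ("plateau", "ramp"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    ref = start.coords
    n = ref.shape[0]
    field_dir = rng.normal(size=(n, 3))
    field_dir /= np.sqrt((field_dir**2).mean())

    def superposed_rmsd(s: float) -> float:
        return kabsch_superpose(ref + s * field_dir, ref).rmsd

    if terminal_rmsd == 0:
        s_star = 0.0
    else:
        hi = terminal_rmsd
        while superposed_rmsd(hi) < terminal_rmsd:
            hi *= 2.0
            if hi > 1e4:
                raise RuntimeError("displacement calibration failed")
        s_star = brentq(lambda s: superposed_rmsd(s) - terminal_rmsd, 0.0, hi)

    t = np.arange(n_frames, dtype=float)
    if mode == "plateau":
        ramp_len = max(1, int(0.1 * n_frames))
        scale = s_star * np.minimum(1.0, t / ramp_len)
    else:
        scale = s_star * t / max(1, n_frames - 1)
    frames = ref[None, :, :] + scale[:, None, None] * field_dir[None, :, :]
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=frames.shape)
        noise[0] = 0.0
        frames = frames + noise
    times = np.linspace(0.0, time_span_ns, n_frames)
    return Trajectory(
        start.copy(),
        frames,
        frame_times=times,
        label=f"drift-{mode}",
        meta={"mode": mode, "terminal_rmsd": terminal_rmsd, "scale": scale},
    )


def generate_rotation_scan(
    base: Structure,
    increment: float = 15.0,
    n: int = 24,
    helix: HelixSelector | str = "B",
) -> Ensemble:
    """Rotation-scan initial configurations: spin one helix about its own axis.

    Member ``i`` is the base structure with the designated helix rotated by
    ``i * increment`` degrees about its fitted axis; every other coordinate
    is bit-identical to the base.  Emulates scan protocols that re-start a
    simulation with one helix rotated by a fixed increment each time.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    chain = helix.chain_id if isinstance(helix, HelixSelector) else helix
    ca = select(base, chain, atom_names={"CA"})
    axis = fit_helix_axis(ca.coords)
    mask = np.array([a.chain_id == chain for a in base.atoms])
    members: list[Structure] = []
    provenance: list[dict] = []
    for i in range(n):
        s = base.copy()
        R = _rotation_about(axis.direction, i * increment)
        s.coords[mask] = (s.coords[mask] - axis.anchor) @ R.T + axis.anchor
        s.label = f"{base.label}|scan{i}"
        s.meta["scan_rotation"] = i * increment
        members.append(s)
        provenance.append({"scan_index": i, "rotation_deg": i * increment})
    return Ensemble(members, provenance)
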