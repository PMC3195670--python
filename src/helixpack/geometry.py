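"""Helix-axis fitting and the core geometric observables.

The signed crossing angle Omega between two packed transmembrane helices is
the central quantity: its magnitude is the acute angle between the two helix
axes and its sign encodes packing handedness — negative for right-handed
(RH) packing, positive for left-handed (LH), the convention under which the
alphaIIb/beta3 integrin dimer and other GxxxG-mediated dimers come out near
-30 degrees.

The sign is the sign of the chirality triple product
``(d_a x d_b) . u`` where ``d_a``, ``d_b`` are the N->C axis directions and
``u`` is the unit vector between the closest-approach points of the two
finite axis segments (from a to b).  This product is invariant under
swapping the two helices and under flipping either axis direction, and it
changes sign under a mirror reflection of the dimer — exactly the behaviour
packing handedness must have.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Structure, Trajectory, HelixSelector, selection_indices

__all__ = [
    "HelixAxis",
    "CrossingGeometry",
    "SuperpositionResult",
    "fit_helix_axis",
    "crossing_geometry",
    "kabsch_superpose",
    "rmsd_series",
    "segment_closest_points",
]


@dataclass(frozen=True)
class HelixAxis:
    """Fitted axis: midpoint anchor, unit N->C direction, half length (A)."""

    anchor: np.ndarray
    direction: np.ndarray
    half_length: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction not unit length (|d|={n})")
        object.__setattr__(self, "direction", d)
        if not self.half_length > 0:
            raise ValueError("half_length must be positive")

    @property
    def start(self) -> np.ndarray:
        return self.anchor - self.half_length * self.direction

    @property
    def end(self) -> np.ndarray:
        return self.anchor + self.half_length * self.direction


@dataclass(frozen=True)
class CrossingGeometry:
    """Signed crossing angle in (-90, +90] with handedness and closest approach."""

    omega: float
    handedness: str  # "RH" | "LH" | "indeterminate"
    closest_distance: float
    closest_points: tuple[np.ndarray, np.ndarray]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper-rotation superposition: ``x -> R x + t`` and the RMSD (A)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def fit_helix_axis(calpha_positions: Sequence[np.ndarray] | np.ndarray) -> HelixAxis:
    """Fit a straight axis to ordered Calpha positions of one helix.

    The axis direction is the dominant principal direction of the centred
    points, sign-fixed so that it points N->C (``direction . (last-first) > 0``);
    the anchor is the centroid.  Adequate for single-span TM helices, which
    are straight to within the noise of the ensembles analysed here; kinked
    helices are out of scope.
    """
    pts = np.asarray(calpha_positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of positions")
    if pts.shape[0] < 5:
        raise ValueError(f"need >= 5 points to fit a helix axis, got {pts.shape[0]}")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] < 1e-8:
        raise ValueError("degenerate (coincident) points: no axis")
    direction = vt[0]
    span = pts[-1] - pts[0]
    if float(direction @ span) < 0:
        direction = -direction
    proj = centred @ direction
    half_length = float(max(proj.max(), -proj.min()))
    if half_length <= 0:
        raise ValueError("degenerate axis: zero extent")
    return HelixAxis(centroid, direction, half_length)


def segment_closest_points(
    p0: np.ndarray, p1: np.ndarray, q0: np.ndarray, q1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closest points between two finite segments [p0,p1] and [q0,q1].

    Standard clamped quadratic minimization; parallel segments resolved by
    clamping, degenerate segments collapse to points.
    """
    p0, p1, q0, q1 = (np.asarray(x, dtype=float) for x in (p0, p1, q0, q1))
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-12
    if a <= eps and e <= eps:
        return p0.copy(), q0.copy()
    if a <= eps:
        s = 0.0
        t = np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= eps:
            t = 0.0
            s = np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t = 1.0
                s = np.clip((b - c) / a, 0.0, 1.0)
    return p0 + s * d1, q0 + t * d2


def crossing_geometry(
    axis_a: HelixAxis, axis_b: HelixAxis, sign_tolerance: float = 2.0
) -> CrossingGeometry:
    """Signed crossing angle and handedness for a pair of fitted axes.

    Frames within ``sign_tolerance`` degrees of zero are classified
    ``indeterminate`` (neither RH nor LH); callers exclude those from
    handedness fractions.  Exactly parallel coincident axes have undefined
    chirality and return omega = 0, indeterminate.
    """
    pa, pb = segment_closest_points(axis_a.start, axis_a.end, axis_b.start, axis_b.end)
    u = pb - pa
    dist = float(np.linalg.norm(u))
    da, db = axis_a.direction, axis_b.direction
    cross = np.cross(da, db)
    if dist < 1e-9:
        # intersecting or coincident axes: no offset vector, chirality undefined
        cos_t = abs(float(da @ db))
        omega = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
        if omega > 90.0:
            omega = 180.0 - omega
        return CrossingGeometry(omega, "indeterminate", dist, (pa, pb))
    u_hat = u / dist
    sin_term = float(cross @ u_hat)
    cos_term = float(da @ db)
    omega = float(np.degrees(np.arctan2(sin_term, cos_term)))
    # fold into (-90, +90]: equivalent to flipping one axis direction, which
    # leaves the chirality product invariant
    if omega > 90.0:
        omega -= 180.0
    elif omega <= -90.0:
        omega += 180.0
    if abs(omega) <= sign_tolerance:
        hand = "indeterminate"
    elif omega < 0:
        hand = "RH"
    else:
        hand = "LH"
    return CrossingGeometry(omega, hand, dist, (pa, pb))


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det = +1; reflections never allowed) and
    translation minimizing the RMSD, plus that minimal RMSD.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape:
        raise ValueError(f"point count mismatch: {mob.shape} vs {ref.shape}")
    if mob.ndim != 2 or mob.shape[1] != 3 or mob.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    rmsd = float(rssd / np.sqrt(mob.shape[0]))
    return SuperpositionResult(R, t, rmsd)


def rmsd_series(
    trajectory: Trajectory,
    reference: Structure,
    selection: HelixSelector | Sequence[HelixSelector],
) -> np.ndarray:
    """Per-frame Calpha (or chosen-subset) RMSD to a reference after superposition.

    Returns an (n_frames, 2) array of (time ns, rmsd A).  When the reference
    is the first frame the series starts at zero.
    """
    selectors = [selection] if isinstance(selection, HelixSelector) else list(selection)
    idx = np.concatenate([selection_indices(trajectory.topology, s) for s in selectors])
    ref_idx = np.concatenate([selection_indices(reference, s) for s in selectors])
    if len(idx) != len(ref_idx):
        raise ValueError(
            f"selection resolves to {len(idx)} atoms in trajectory but "
            f"{len(ref_idx)} in reference"
        )
    ref = reference.coords[ref_idx]
    times = trajectory.times()
    out = np.empty((trajectory.n_frames, 2))
    for i in range(trajectory.n_frames):
        sup = kabsch_superpose(trajectory.frames[i][idx], ref)
        out[i] = (times[i], sup.rmsd)
    return out
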