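"""Ensemble-level characterization of helix-dimer packing.

Given a bag of two-helix conformations (end states of many independent
self-assembly runs, frames of trajectories, or an NMR ensemble) this module
computes:

* the signed crossing-angle distribution with right-/left-handed fractions
  and per-handedness mode means (the bimodal distribution of the CG
  ensembles: ~70% right-handed near -30 deg, ~30% left-handed),
* the 2D spatial probability density of the mobile helix's backbone around
  the reference-fitted partner helix in the bilayer (xy) plane, with its
  maxima — the packing modes (RH1/RH2/LH style) — ranked by basin mass,
* a representative conformation per packing mode, and
* a subsample-vs-full convergence check (Jensen-Shannon divergence of
  crossing-angle histograms), the formalization of "results converge after
  using half of the simulations".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.spatial.distance import jensenshannon
from scipy.spatial.transform import Rotation

from .core import Ensemble, Structure, Trajectory, HelixSelector, select_by
from .geometry import crossing_geometry, fit_helix_axis, kabsch_superpose

__all__ = [
    "AngleDistribution",
    "DensityMap",
    "DensityMode",
    "ConvergenceReport",
    "member_crossing_angles",
    "angle_distribution",
    "spatial_density_map",
    "representative_structure",
    "convergence_check",
    "save_density_map",
    "load_density_map",
]

_EDGE = 90.0  # crossing angles live in (-90, +90]


@dataclass
class AngleDistribution:
    """Crossing-angle samples, histogram, and handedness summary.

    ``samples`` flattens every frame of every member; ``weights`` make each
    ensemble member contribute equal total mass so long trajectories do not
    dominate the handedness fractions or mode means.  ``fraction_rh`` and
    ``fraction_lh`` are computed over determinate frames only (frames within
    the sign tolerance of 0 deg belong to neither class).
    """

    samples: np.ndarray
    weights: np.ndarray
    member_index: np.ndarray
    bin_width: float
    bin_edges: np.ndarray
    histogram: np.ndarray
    fraction_rh: float
    fraction_lh: float
    mode_means: dict[str, float]
    sign_tolerance: float = 2.0


@dataclass(frozen=True)
class DensityMode:
    """One packing mode: a maximum of the spatial density map."""

    position: tuple[float, float]  # A, in the fitted (bilayer-plane) frame
    peak_density: float
    basin_mass: float
    label: str
    minor: bool


@dataclass
class DensityMap:
    """Normalized 2D occupancy of the mobile helix around the reference helix.

    ``values[i, j]`` is the probability mass in the cell whose lower corner
    is ``grid_origin + (i, j) * cell_size`` (x indexes axis 0).  ``maxima``
    are ranked by basin mass, largest first.
    """

    grid_origin: np.ndarray
    cell_size: float
    values: np.ndarray
    maxima: list[DensityMode] = field(default_factory=list)
    basin_labels: np.ndarray | None = None
    member_centroids: np.ndarray | None = None  # (n_members, 2), fitted frame

    def cell_center(self, i: int, j: int) -> np.ndarray:
        return self.grid_origin + (np.array([i, j]) + 0.5) * self.cell_size


@dataclass(frozen=True)
class ConvergenceReport:
    """Subsample-vs-full ensemble agreement of crossing-angle histograms."""

    divergence: float  # mean Jensen-Shannon divergence, bits
    fraction_used: float
    converged: bool
    threshold: float
    n_draws: int


def member_crossing_angles(
    ensemble: Ensemble,
    selector_a: HelixSelector,
    selector_b: HelixSelector,
    sign_tolerance: float = 2.0,
) -> list[np.ndarray]:
    """Per-member arrays of signed crossing angles (one per frame)."""
    out: list[np.ndarray] = []
    for i in range(len(ensemble)):
        omegas = []
        for s in ensemble.structures(i):
            a = fit_helix_axis(select_by(s, selector_a).coords)
            b = fit_helix_axis(select_by(s, selector_b).coords)
            omegas.append(crossing_geometry(a, b, sign_tolerance).omega)
        out.append(np.asarray(omegas))
    return out


def angle_distribution(
    ensemble: Ensemble,
    selector_a: HelixSelector,
    selector_b: HelixSelector,
    bin_width: float = 5.0,
    sign_tolerance: float = 2.0,
) -> AngleDistribution:
    """Crossing-angle distribution with sign-classified RH/LH fractions.

    Handedness fractions use sign classes (RH: omega < -tol, LH: omega >
    +tol) rather than fitted mixture models; ``mode_means`` holds the
    weighted mean angle of each class.
    """
    per_member = member_crossing_angles(ensemble, selector_a, selector_b, sign_tolerance)
    samples = np.concatenate(per_member)
    weights = np.concatenate(
        [np.full(len(v), 1.0 / len(v)) for v in per_member if len(v)]
    )
    member_index = np.concatenate(
        [np.full(len(v), i, dtype=int) for i, v in enumerate(per_member)]
    )
    rh = samples < -sign_tolerance
    lh = samples > sign_tolerance
    det = rh | lh
    if not det.any():
        raise ValueError("all frames have indeterminate handedness")
    wdet = float(weights[det].sum())
    fraction_rh = float(weights[rh].sum() / wdet)
    fraction_lh = float(weights[lh].sum() / wdet)
    mode_means = {}
    if rh.any():
        mode_means["RH"] = float(np.average(samples[rh], weights=weights[rh]))
    if lh.any():
        mode_means["LH"] = float(np.average(samples[lh], weights=weights[lh]))
    edges = np.arange(-_EDGE, _EDGE + bin_width / 2, bin_width)
    hist, _ = np.histogram(samples, bins=edges)
    return AngleDistribution(
        samples=samples,
        weights=weights,
        member_index=member_index,
        bin_width=bin_width,
        bin_edges=edges,
        histogram=hist,
        fraction_rh=fraction_rh,
        fraction_lh=fraction_lh,
        mode_means=mode_means,
        sign_tolerance=sign_tolerance,
    )


def _canonical_transform(
    ref_coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform placing a reference helix in the canonical frame.

    Axis to +z through the origin; azimuth pinned by rotating the first
    backbone atom (the N-terminal Calpha of the TM range) into the +x
    half-plane.  Returns (R, t) with ``x -> R x + t``.
    """
    axis = fit_helix_axis(ref_coords)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis.direction, z)
    s = np.linalg.norm(v)
    c = float(axis.direction @ z)
    if s < 1e-12:
        R1 = np.eye(3) if c > 0 else Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
    else:
        R1 = Rotation.from_rotvec(v / s * np.arctan2(s, c)).as_matrix()
    marker = R1 @ (ref_coords[0] - axis.anchor)
    phi = np.arctan2(marker[1], marker[0])
    R2 = Rotation.from_rotvec([0, 0, -phi]).as_matrix()
    R = R2 @ R1
    t = -R @ axis.anchor
    return R, t


def _fitted_mobile_xy(
    ensemble: Ensemble,
    selector_ref: HelixSelector,
    selector_mobile: HelixSelector,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-member projected mobile-backbone xy points in the canonical frame."""
    first = ensemble.structures(0)[0]
    ref0 = select_by(first, selector_ref).coords
    R0, t0 = _canonical_transform(ref0)
    canonical_ref = ref0 @ R0.T + t0
    per_member_xy: list[np.ndarray] = []
    centroids = np.empty((len(ensemble), 2))
    for i in range(len(ensemble)):
        pts = []
        for s in ensemble.structures(i):
            ref = select_by(s, selector_ref).coords
            if ref.shape != canonical_ref.shape:
                raise ValueError(
                    f"member {i}: reference-helix backbone atom count "
                    f"{ref.shape[0]} differs from member 0 ({canonical_ref.shape[0]})"
                )
            sup = kabsch_superpose(ref, canonical_ref)
            mob = sup.apply(select_by(s, selector_mobile).coords)
            pts.append(mob[:, :2])
        xy = np.vstack(pts)
        per_member_xy.append(xy)
        centroids[i] = xy.mean(axis=0)
    return per_member_xy, centroids


def spatial_density_map(
    ensemble: Ensemble,
    selector_ref: HelixSelector,
    selector_mobile: HelixSelector,
    cell_size: float = 1.0,
    margin: float = 3.0,
    merge_distance: float = 3.0,
    minor_threshold: float = 0.05,
) -> DensityMap:
    """Probability density of the mobile helix around the reference helix.

    Every member's reference-chain backbone is Kabsch-superposed onto the
    canonical reference (axis on +z through the origin); the mobile-chain
    backbone positions are projected onto the bilayer (xy) plane and
    accumulated, each member contributing equal total mass.  The grid is
    sized from the data plus a margin, so all mass is always contained.
    Maxima are detected on a 3x3-smoothed copy, merged when closer than
    ``merge_distance``, and assigned basins by steepest ascent; modes below
    ``minor_threshold`` basin mass are flagged minor.
    """
    per_member_xy, centroids = _fitted_mobile_xy(ensemble, selector_ref, selector_mobile)
    allpts = np.vstack(per_member_xy)
    lo = np.floor((allpts.min(axis=0) - margin) / cell_size) * cell_size
    hi = np.ceil((allpts.max(axis=0) + margin) / cell_size) * cell_size
    nx = int(round((hi[0] - lo[0]) / cell_size))
    ny = int(round((hi[1] - lo[1]) / cell_size))
    xedges = lo[0] + np.arange(nx + 1) * cell_size
    yedges = lo[1] + np.arange(ny + 1) * cell_size
    values = np.zeros((nx, ny))
    for xy in per_member_xy:
        h, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(xedges, yedges))
        values += h / len(xy)
    values /= values.sum()
    dmap = DensityMap(lo, cell_size, values, member_centroids=centroids)
    _detect_maxima(dmap, merge_distance, minor_threshold)
    return dmap


def _detect_maxima(
    dmap: DensityMap,
    merge_distance: float,
    minor_threshold: float,
    rel_prominence: float = 0.5,
) -> None:
    """Watershed the smoothed grid into basins around its maxima.

    Cells are visited in descending order of the 3x3-smoothed density and
    assigned by steepest ascent.  Two merging rules keep elongated, noisy
    density ridges from fragmenting: a peak is absorbed into a higher
    neighbouring basin when the saddle connecting them is high (the lower
    peak's prominence is below ``rel_prominence`` of its height), or when
    the two peaks lie closer than ``merge_distance``.  Genuinely distinct
    packing modes are separated by near-empty density and survive both.
    """
    v = uniform_filter(dmap.values, size=3, mode="constant")
    nx, ny = v.shape
    order = np.argsort(v, axis=None)[::-1]
    basin = -np.ones(v.shape, dtype=int)
    peaks: list[tuple[int, int]] = []
    parent: list[int] = []

    def find(k: int) -> int:
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    neigh = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    for flat in order:
        i, j = divmod(int(flat), ny)
        if v[i, j] <= 0 and dmap.values[i, j] <= 0:
            continue
        roots: list[int] = []
        best_root = None
        best_v = v[i, j]
        for di, dj in neigh:
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny and basin[a, b] >= 0 and v[a, b] >= v[i, j]:
                r = find(basin[a, b])
                if r not in roots:
                    roots.append(r)
                if v[a, b] > best_v or best_root is None:
                    best_v = v[a, b]
                    best_root = r
        if best_root is None:
            peaks.append((i, j))
            parent.append(len(peaks) - 1)
            basin[i, j] = len(peaks) - 1
            continue
        basin[i, j] = best_root
        # this cell is a saddle between any further adjoining basins
        for r in roots:
            if r == best_root or find(r) == find(best_root):
                continue
            lo, hi = sorted((find(r), find(best_root)), key=lambda k: v[peaks[k]])
            saddle = v[i, j]
            if v[peaks[lo]] - saddle < rel_prominence * v[peaks[lo]]:
                parent[lo] = hi
    for flat in order:  # path-compress assignments to final roots
        i, j = divmod(int(flat), ny)
        if basin[i, j] >= 0:
            basin[i, j] = find(basin[i, j])
    # distance-based merge of surviving peaks
    roots = sorted({find(k) for k in range(len(peaks))})
    centers = {k: dmap.cell_center(*peaks[k]) for k in roots}
    for k in sorted(roots, key=lambda k: v[peaks[k]]):
        for k2 in sorted(roots, key=lambda k: v[peaks[k]], reverse=True):
            if find(k2) == find(k):
                continue
            if v[peaks[k2]] > v[peaks[k]] and np.linalg.norm(
                centers[k] - centers[k2]
            ) < merge_distance:
                parent[find(k)] = find(k2)
                break
    masses: dict[int, float] = {}
    for flat in order:
        i, j = divmod(int(flat), ny)
        if basin[i, j] >= 0:
            basin[i, j] = find(basin[i, j])
            masses[basin[i, j]] = masses.get(basin[i, j], 0.0) + float(
                dmap.values[i, j]
            )
    modes = [
        (tuple(dmap.cell_center(*peaks[r])), float(v[peaks[r]]), m, r)
        for r, m in masses.items()
        if m > 0
    ]
    modes.sort(key=lambda m: m[2], reverse=True)
    out = []
    labels = -np.ones_like(basin)
    for rank, (pos, peak, mass, root) in enumerate(modes, start=1):
        out.append(
            DensityMode(pos, peak, mass, f"mode{rank}", minor=mass < minor_threshold)
        )
        labels[basin == root] = rank - 1
    dmap.maxima = out
    dmap.basin_labels = labels


def representative_structure(
    ensemble: Ensemble,
    dmap: DensityMap,
    mode_label: str,
    selector_ref: HelixSelector | None = None,
    selector_mobile: HelixSelector | None = None,
) -> tuple[int, Structure]:
    """Member whose mobile-helix projected centroid is nearest a mode position.

    Uses the centroids cached on the map when available (ties broken by
    lowest member index); for a trajectory member the first frame is
    returned as the representative conformation.
    """
    mode = next((m for m in dmap.maxima if m.label == mode_label), None)
    if mode is None:
        raise KeyError(f"no mode labelled {mode_label!r} in map")
    if mode.basin_mass <= 0:
        raise ValueError(f"mode {mode_label!r} has an empty basin")
    if dmap.member_centroids is not None and len(dmap.member_centroids) == len(ensemble):
        centroids = dmap.member_centroids
    else:
        if selector_ref is None or selector_mobile is None:
            raise ValueError("selectors required when the map carries no centroids")
        _, centroids = _fitted_mobile_xy(ensemble, selector_ref, selector_mobile)
    d = np.linalg.norm(centroids - np.asarray(mode.position), axis=1)
    idx = int(np.argmin(d))  # argmin returns the first (lowest-index) minimum
    member = ensemble.members[idx]
    structure = member.frame(0) if isinstance(member, Trajectory) else member
    return idx, structure


def convergence_check(
    ensemble: Ensemble,
    selector_a: HelixSelector,
    selector_b: HelixSelector,
    fraction: float = 0.5,
    n_draws: int = 20,
    seed: int | None = 0,
    threshold: float = 0.05,
    bin_width: float = 5.0,
) -> ConvergenceReport:
    """Does a random subsample reproduce the full crossing-angle distribution?

    The divergence is the mean (over ``n_draws`` seeded subsamples drawn
    without replacement) Jensen-Shannon divergence in bits between the
    subsample and full-ensemble angle histograms; the ensemble is declared
    converged when it falls below ``threshold``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if len(ensemble) < 4:
        raise ValueError("need at least 4 members for a convergence check")
    m = int(round(fraction * len(ensemble)))
    if m < 2:
        raise ValueError("fraction * ensemble size must be >= 2 members")
    per_member = member_crossing_angles(ensemble, selector_a, selector_b)
    edges = np.arange(-_EDGE, _EDGE + bin_width / 2, bin_width)

    def hist_of(indices: Sequence[int]) -> np.ndarray:
        vals = np.concatenate([per_member[i] for i in indices])
        h, _ = np.histogram(vals, bins=edges)
        return h.astype(float)

    full = hist_of(range(len(ensemble)))
    if fraction == 1.0:
        return ConvergenceReport(0.0, 1.0, True, threshold, n_draws)
    rng = np.random.default_rng(seed)
    divs = []
    for _ in range(n_draws):
        sub = rng.choice(len(ensemble), size=m, replace=False)
        # scipy returns the JS *distance* (sqrt of the divergence)
        divs.append(jensenshannon(hist_of(sub), full, base=2) ** 2)
    divergence = float(np.mean(divs))
    return ConvergenceReport(divergence, fraction, divergence < threshold, threshold, n_draws)


def save_density_map(dmap: DensityMap, path: str) -> None:
    """Plain-text export: header (origin, cell size) + the probability grid."""
    with open(path, "w") as fh:
        fh.write(f"# origin_x {dmap.grid_origin[0]:.6f}\n")
        fh.write(f"# origin_y {dmap.grid_origin[1]:.6f}\n")
        fh.write(f"# cell_size {dmap.cell_size:.6f}\n")
        for m in dmap.maxima:
            fh.write(
                f"# mode {m.label} x {m.position[0]:.3f} y {m.position[1]:.3f} "
                f"peak {m.peak_density:.6e} basin_mass {m.basin_mass:.4f} "
                f"minor {int(m.minor)}\n"
            )
        np.savetxt(fh, dmap.values, fmt="%.8e")


def load_density_map(path: str) -> DensityMap:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    grid_lines = []
    for line in lines:
        if line.startswith("# mode"):
            continue
        if line.startswith("#"):
            _, key, val = line.split()
            header[key] = float(val)
        else:
            grid_lines.append(line)
    values = np.loadtxt(grid_lines)
    dmap = DensityMap(
        np.array([header["origin_x"], header["origin_y"]]),
        header["cell_size"],
        np.atleast_2d(values),
    )
    _detect_maxima(dmap, merge_distance=3.0, minor_threshold=0.05)
    return dmap
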