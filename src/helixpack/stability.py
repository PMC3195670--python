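"""Per-simulation conformational-stability assessment.

A stable membrane-protein model shows a Calpha RMSD series that rapidly
reaches a plateau below ~3 A; an unstable one rises steadily over the run,
reaching 5-7 A after a few tens of ns, with a wide crossing-angle spread.
This module turns those empirical markers into an explicit, configurable
classifier, detects dimerization events in diffusion/association
trajectories, and compares two trajectories by pairwise cross-RMSD over
their final windows (the convergence check used when two independently
started runs settle into the same structure).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import theilslopes

from .core import Trajectory, HelixSelector, selection_indices
from .geometry import fit_helix_axis, kabsch_superpose, segment_closest_points

__all__ = [
    "StabilityReport",
    "DimerizationEvent",
    "assess_stability",
    "angle_spread",
    "detect_dimerization",
    "pairwise_ensemble_rmsd",
    "axis_separation_series",
]

NO_EVENT = "none"


@dataclass(frozen=True)
class StabilityReport:
    """Plateau level, drift rate, class, and crossing-angle spread of one run."""

    rmsd_series: np.ndarray  # (n, 2): time ns, rmsd A
    plateau_value: float  # mean over the final window, A
    drift_rate: float  # Theil-Sen slope over the final half, A/ns
    classification: str  # "stable" | "unstable" | "indeterminate"
    angle_spread: tuple[float, float, float] | None  # (min, max, stddev) deg


@dataclass(frozen=True)
class DimerizationEvent:
    """First persistent interhelix approach below the contact cutoff."""

    event_time: float | str  # ns, or "none"
    first_contact_frame: int | None
    stable_from_frame: int | None


def assess_stability(
    rmsd_series: np.ndarray,
    angle_series: Sequence[float] | None = None,
    stable_threshold: float = 3.0,
    drift_threshold: float = 0.05,
    final_window_fraction: float = 0.25,
    sign_tolerance: float = 2.0,
) -> StabilityReport:
    """Classify an RMSD time series as stable / unstable / indeterminate.

    Stable: the final-window mean (plateau) sits below ``stable_threshold``
    (default 3 A) and the robust slope over the final half is below
    ``drift_threshold`` in magnitude.  Unstable: the plateau exceeds the
    threshold while the series is still rising.  Everything else is
    indeterminate.  The drift is a Theil-Sen slope so single spikes do not
    flip the call.
    """
    series = np.asarray(rmsd_series, dtype=float)
    if series.ndim != 2 or series.shape[1] != 2:
        raise ValueError("rmsd_series must be an (n, 2) array of (time, rmsd)")
    n = series.shape[0]
    t, r = series[:, 0], series[:, 1]
    if n < 10 or (t[-1] - t[0]) < 2.0:
        raise ValueError("need >= 10 samples spanning >= 2 ns")
    n_win = max(2, int(np.ceil(final_window_fraction * n)))
    plateau = float(r[-n_win:].mean())
    half = n // 2
    slope = float(theilslopes(r[half:], t[half:])[0])
    if plateau < stable_threshold and abs(slope) < drift_threshold:
        cls = "stable"
    elif plateau > stable_threshold and slope > drift_threshold:
        cls = "unstable"
    else:
        cls = "indeterminate"
    spread = None
    if angle_series is not None:
        spread = angle_spread(angle_series, sign_tolerance)
    return StabilityReport(series, plateau, slope, cls, spread)


def angle_spread(
    angle_series: Sequence[float], sign_tolerance: float = 2.0
) -> tuple[float, float, float]:
    """(min, max, population stddev) of the determinate crossing angles.

    Wide spreads (e.g. a full -60..0 or +10..+60 range) are the signature of
    loose helix packing; frames within the sign tolerance of zero are
    excluded as handedness-indeterminate.
    """
    a = np.asarray(angle_series, dtype=float)
    det = a[np.abs(a) > sign_tolerance]
    if det.size < 2:
        raise ValueError("need >= 2 determinate angle samples")
    return (float(det.min()), float(det.max()), float(det.std()))


def axis_separation_series(
    trajectory: Trajectory,
    selector_a: HelixSelector,
    selector_b: HelixSelector,
) -> np.ndarray:
    """Closest-approach distance between the fitted axis segments, per frame."""
    idx_a = selection_indices(trajectory.topology, selector_a)
    idx_b = selection_indices(trajectory.topology, selector_b)
    out = np.empty(trajectory.n_frames)
    for i in range(trajectory.n_frames):
        a = fit_helix_axis(trajectory.frames[i][idx_a])
        b = fit_helix_axis(trajectory.frames[i][idx_b])
        pa, pb = segment_closest_points(a.start, a.end, b.start, b.end)
        out[i] = np.linalg.norm(pb - pa)
    return out


def detect_dimerization(
    trajectory: Trajectory,
    selector_a: HelixSelector,
    selector_b: HelixSelector,
    contact_distance: float = 8.0,
    persistence: int = 10,
) -> DimerizationEvent:
    """First persistent encounter of the two helices in an assembly run.

    Contact is defined at helix scale — closest approach between the fitted
    axis segments below ``contact_distance`` — not atom-atom distance.  The
    event frame is the start of the first run of at least ``persistence``
    consecutive contact frames; with no such run the sentinel "none" is
    returned.
    """
    d = axis_separation_series(trajectory, selector_a, selector_b)
    below = d < contact_distance
    first_contact = int(np.argmax(below)) if below.any() else None
    stable_from = None
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= persistence:
            stable_from = i - persistence + 1
            break
    if stable_from is None:
        return DimerizationEvent(NO_EVENT, first_contact, None)
    times = trajectory.times()
    return DimerizationEvent(float(times[stable_from]), first_contact, stable_from)


def pairwise_ensemble_rmsd(
    traj_a: Trajectory,
    traj_b: Trajectory,
    selection: HelixSelector | Sequence[HelixSelector],
    window: float = 0.5,
) -> tuple[float, float, float]:
    """(min, max, mean) Calpha RMSD over all cross pairs of final-window frames.

    Two runs that converged to the same structure give cross-RMSDs within
    the range of their own fluctuations (published comparisons land at
    1-3 A); disjoint end states push the minimum well above that.
    """
    if not (0 < window <= 1):
        raise ValueError("window must be in (0, 1]")
    selectors = [selection] if isinstance(selection, HelixSelector) else list(selection)
    idx_a = np.concatenate([selection_indices(traj_a.topology, s) for s in selectors])
    idx_b = np.concatenate([selection_indices(traj_b.topology, s) for s in selectors])
    if len(idx_a) != len(idx_b):
        raise ValueError("selection resolves to different atom counts in the two runs")
    a0 = traj_a.n_frames - max(1, int(window * traj_a.n_frames))
    b0 = traj_b.n_frames - max(1, int(window * traj_b.n_frames))
    vals = []
    for i in range(a0, traj_a.n_frames):
        for j in range(b0, traj_b.n_frames):
            vals.append(
                kabsch_superpose(traj_a.frames[i][idx_a], traj_b.frames[j][idx_b]).rmsd
            )
    v = np.asarray(vals)
    return (float(v.min()), float(v.max()), float(v.mean()))
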