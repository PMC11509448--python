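"""Flow displacement, rotational angle and their systolic summaries.

Flow displacement (FD) measures eccentricity of the forward jet: the
distance between the lumen's geometric centroid and the antegrade
velocity-weighted centre of velocity (COV), normalised by the effective
lumen diameter ``d_eff = 2 * sqrt(area / pi)`` and expressed in percent.
The rotational angle (RA) is the direction of the centroid-to-COV vector in
the image plane, measured counterclockwise from the +column axis with the
row axis flipped to standard orientation, and unwrapped over time so that
successive frames never jump by more than 180 degrees.

Frames whose FD falls at or below a gate (default 12%) are considered to
have no meaningful jet direction and are excluded from rotational-angle
work; the FD averages themselves are not gated.  The rotational-angle
change dRA is the signed difference between RA at end systole and RA at the
first post-peak frame where the angle stabilised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import CardiacPhases
from .series import LumenMaskSeries, VelocitySeries

__all__ = [
    "DisplacementTrace",
    "EccentricityIndices",
    "center_of_velocity",
    "displacement_trace",
    "fd_averages",
    "rotational_angle_change",
]

FD_GATE_PCT_DEFAULT = 12.0


@dataclass
class DisplacementTrace:
    """Per-systolic-frame flow displacement and jet direction.

    Arrays are indexed parallel to ``frames`` (the systolic frame indices).
    ``ra_deg`` is unwrapped; entries are NaN where the COV is undefined
    (no antegrade pixel) or coincides with the centroid.
    """

    frames: np.ndarray
    cov_px: np.ndarray  # (n, 2) (row, col), NaN where undefined
    centroid_px: np.ndarray  # (n, 2)
    d_eff_mm: np.ndarray
    fd_pct: np.ndarray
    ra_deg: np.ndarray
    gated: np.ndarray  # True where fd_pct <= gate
    gate_pct: float = FD_GATE_PCT_DEFAULT

    def to_frame_table(self):
        """Per-frame table (frame, fd_pct, ra_deg, gated) for plot export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frames,
                "fd_pct": self.fd_pct,
                "ra_deg": self.ra_deg,
                "gated": self.gated,
            }
        )


@dataclass
class EccentricityIndices:
    fds_avg_pct: float
    fdls_avg_pct: float
    delta_ra_deg: float
    stabilization_frame: int
    stabilization_fallback: bool = False


def center_of_velocity(
    velocity: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """Antegrade-velocity-weighted mean pixel position (row, col).

    Weights are ``max(v, 0)``: the displacement describes the forward jet,
    so retrograde pixels carry no weight.  Raises when the frame has no
    antegrade pixel.
    """
    if not mask.any():
        raise ValueError("empty mask")
    w = np.where(mask, np.maximum(velocity, 0.0), 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no antegrade pixel in mask; COV undefined")
    rows, cols = np.nonzero(w > 0)
    ww = w[rows, cols]
    return float(rows @ ww / total), float(cols @ ww / total)


def _mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def _unwrap_with_nans(angles_deg: np.ndarray) -> np.ndarray:
    """np.unwrap over the defined entries only, leaving NaNs in place."""
    out = angles_deg.copy()
    valid = np.isfinite(angles_deg)
    if valid.sum() > 1:
        out[valid] = np.degrees(np.unwrap(np.radians(angles_deg[valid])))
    return out


def displacement_trace(
    vel: VelocitySeries,
    masks: LumenMaskSeries,
    phases: CardiacPhases,
    gate_pct: float = FD_GATE_PCT_DEFAULT,
    normalization: str = "diameter",
) -> DisplacementTrace:
    """Flow displacement and rotational angle over the systolic window.

    ``fd_pct = 100 * ||cov - centroid||_mm / d_eff`` with
    ``d_eff = 2*sqrt(A/pi)`` (or ``sqrt(A/pi)`` under radius
    normalization).  The angle is atan2 of the centroid-to-COV vector with
    the row axis flipped (counterclockwise positive, 0 along +columns),
    then unwrapped across frames.
    """
    if normalization not in ("diameter", "radius"):
        raise ValueError("normalization must be 'diameter' or 'radius'")
    frames = phases.systole
    if len(frames) == 0:
        raise ValueError("empty systolic window")
    sp_r, sp_c = vel.pixel_spacing_mm
    a_px = sp_r * sp_c

    n = len(frames)
    cov = np.full((n, 2), np.nan)
    cen = np.full((n, 2), np.nan)
    d_eff = np.full(n, np.nan)
    fd = np.full(n, np.nan)
    ra = np.full(n, np.nan)
    for i, k in enumerate(frames):
        m = masks[k]
        cen[i] = _mask_centroid(m)
        area_mm2 = m.sum() * a_px
        d = 2.0 * np.sqrt(area_mm2 / np.pi)
        if normalization == "radius":
            d /= 2.0
        d_eff[i] = d
        try:
            cov[i] = center_of_velocity(vel.velocity[k], m)
        except ValueError:
            continue
        drow_mm = (cov[i, 0] - cen[i, 0]) * sp_r
        dcol_mm = (cov[i, 1] - cen[i, 1]) * sp_c
        dist = float(np.hypot(drow_mm, dcol_mm))
        fd[i] = 100.0 * dist / d
        if dist > 0:
            ra[i] = np.degrees(np.arctan2(-drow_mm, dcol_mm))
    ra = _unwrap_with_nans(ra)
    gated = np.where(np.isfinite(fd), fd <= gate_pct, True)
    return DisplacementTrace(
        frames=frames,
        cov_px=cov,
        centroid_px=cen,
        d_eff_mm=d_eff,
        fd_pct=fd,
        ra_deg=ra,
        gated=gated,
        gate_pct=gate_pct,
    )


def fd_averages(
    trace: DisplacementTrace, phases: CardiacPhases
) -> tuple[float, float]:
    """(FDs_avg, FDls_avg): mean FD over systole and over late systole.

    No gating is applied here; the 12% gate affects only angle work.
    """
    fd = trace.fd_pct
    if not np.isfinite(fd).any():
        raise ValueError("no defined FD value in systole")
    late = np.isin(trace.frames, phases.late_systole)
    if not np.isfinite(fd[late]).any():
        raise ValueError("no defined FD value in late systole")
    return float(np.nanmean(fd)), float(np.nanmean(fd[late]))


def rotational_angle_change(
    trace: DisplacementTrace,
    phases: CardiacPhases,
    stab_tol_deg: float = 15.0,
    stab_len: int = 2,
) -> tuple[float, int, bool]:
    """Signed RA change from post-peak stabilisation to end systole.

    Gated frames (FD <= gate) are removed before the search.  The
    stabilisation frame is the first ungated frame after the peak from
    which ``stab_len`` consecutive steps of the ungated angle sequence stay
    within ``stab_tol_deg``.  If no such frame exists the first ungated
    post-peak frame is used and the fallback flag is set.

    Returns ``(delta_ra_deg, stabilization_frame, fallback)``.
    """
    in_window = (trace.frames > phases.peak) & (trace.frames <= phases.end_sys)
    usable = in_window & ~trace.gated & np.isfinite(trace.ra_deg)
    idx = np.flatnonzero(usable)
    if len(idx) < 2:
        raise ValueError(
            "rotational angle undefined: fewer than two ungated frames "
            "between peak and end systole (FD <= gate throughout?)"
        )
    ra = trace.ra_deg[idx]
    steps = np.abs(np.diff(ra))
    stab_pos = None
    for i in range(len(idx) - 1):
        run = steps[i : i + stab_len]
        if len(run) >= 1 and np.all(run <= stab_tol_deg):
            stab_pos = i
            break
    fallback = stab_pos is None
    if fallback:
        stab_pos = 0
    delta = float(ra[-1] - ra[stab_pos])
    return delta, int(trace.frames[idx[stab_pos]]), fallback
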