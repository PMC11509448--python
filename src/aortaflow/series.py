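"""Core data containers for velocity-encoded cine series and lumen masks.

A :class:`VelocitySeries` holds a stack of 2D through-plane velocity maps
(one per cardiac frame, signed, in cm/s, positive = antegrade) together with
the acquisition metadata needed to turn pixel sums into physical flow rates.
A :class:`LumenMaskSeries` holds the matching per-frame binary lumen masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VelocitySeries", "LumenMaskSeries"]


@dataclass
class VelocitySeries:
    """Through-plane velocity cine stack with acquisition metadata.

    Parameters
    ----------
    velocity : ndarray, shape (n_frames, n_rows, n_cols)
        Signed through-plane velocity in cm/s; positive is antegrade.
    pixel_spacing_mm : tuple of float
        (row, col) pixel spacing in millimetres.
    frame_times_ms : ndarray, shape (n_frames,)
        Trigger time of each frame in milliseconds, strictly increasing.
    venc_cm_s : float
        Velocity-encoding limit of the acquisition.
    rr_ms : float, optional
        Cardiac cycle length; used to close the last frame's duration.
    unwrapped : bool
        Set when |velocity| may legitimately exceed venc (data already
        unwrapped upstream).  Without it, super-venc values draw a warning.
    case_id : str
        Identifier carried through to output tables.
    """

    velocity: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    frame_times_ms: np.ndarray
    venc_cm_s: float
    rr_ms: float | None = None
    unwrapped: bool = False
    case_id: str = "case"

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)
        if self.velocity.ndim != 3:
            raise ValueError("velocity must be (frames, rows, cols)")
        if self.velocity.shape[0] < 4:
            raise ValueError("need at least 4 cardiac frames")
        if len(self.frame_times_ms) != self.velocity.shape[0]:
            raise ValueError("frame_times_ms length must match frame count")
        if np.any(np.diff(self.frame_times_ms) <= 0):
            raise ValueError("frame_times_ms must be strictly increasing")
        if not (self.venc_cm_s > 0):
            raise ValueError("venc_cm_s must be positive")
        sp = tuple(float(s) for s in self.pixel_spacing_mm)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ValueError("pixel_spacing_mm must be two positive values")
        self.pixel_spacing_mm = sp

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.velocity.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1]

    def frame_durations_ms(self) -> np.ndarray:
        """Per-frame durations; the last frame closes the cycle.

        When ``rr_ms`` is known the final duration is ``rr - t_last + t_0``
        (retrospective gating covers the full R-R interval); otherwise the
        mean inter-frame spacing is reused.
        """
        dt = np.diff(self.frame_times_ms)
        if self.rr_ms is not None:
            last = self.rr_ms - self.frame_times_ms[-1] + self.frame_times_ms[0]
            if last <= 0:
                raise ValueError("rr_ms inconsistent with frame_times_ms")
        else:
            last = float(np.mean(dt))
        return np.concatenate([dt, [last]])


@dataclass
class LumenMaskSeries:
    """Per-frame binary lumen masks on the grid of a paired VelocitySeries."""

    masks: np.ndarray = field()

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim != 3:
            raise ValueError("masks must be (frames, rows, cols)")
        if m.dtype != bool:
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("masks must be binary (0/1)")
            m = m.astype(bool)
        if not m.any(axis=(1, 2)).all():
            empty = np.flatnonzero(~m.any(axis=(1, 2)))
            raise ValueError(f"empty lumen mask at frame(s) {empty.tolist()}")
        self.masks = m

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.masks.shape

    def __getitem__(self, k: int) -> np.ndarray:
        return self.masks[k]

    def check_compatible(self, vel: VelocitySeries) -> None:
        if self.masks.shape != vel.velocity.shape:
            raise ValueError(
                f"mask grid {self.masks.shape} does not match "
                f"velocity grid {vel.velocity.shape}"
            )
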