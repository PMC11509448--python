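"""Flow curve, cardiac-phase detection and the simple flow indices.

The volumetric flow rate in frame ``k`` is the mask-restricted velocity sum
scaled to physical units,

    q_k = sum_{p in mask_k} v_p * a_pixel / 100        [mL/s]

with v in cm/s and the pixel area in mm^2.  Phase detection reads the
systolic window off this curve: the peak is the flow maximum, onset is where
the curve last rose above a fraction (default 10%) of the peak, and end
systole is the first non-positive crossing after the peak (falling back to
the post-peak minimum on strictly positive curves).

Two sign conventions coexist deliberately.  Aortic forward/backward volumes
integrate the *net* per-frame rate split by its sign over the whole cycle;
systolic forward/retrograde flow (SFF/SRF) integrate *pixelwise* signed
velocities over the systolic window only, so antegrade and retrograde pixels
within one frame both contribute.  SFF therefore always bounds the systolic
net-positive volume from above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import LumenMaskSeries, VelocitySeries

__all__ = [
    "FlowCurve",
    "CardiacPhases",
    "SimpleFlowIndices",
    "ComplexScalarIndices",
    "compute_flow_curve",
    "detect_phases",
    "compute_simple_indices",
    "compute_max_area",
    "compute_sfrr",
    "INDEX_COLUMNS",
]

#: Column contract for per-case index tables, in output order.
INDEX_COLUMNS = [
    "ao_forward_mL",
    "ao_backward_mL",
    "sff_mL",
    "srf_mL",
    "vs_avg_cm_s",
    "vs_peak_cm_s",
    "ao_max_area_cm2",
    "sfrr_pct",
    "fds_avg_pct",
    "fdls_avg_pct",
    "delta_ra_deg",
]


@dataclass
class FlowCurve:
    """Per-frame net volumetric flow rate (mL/s) and frame durations (ms)."""

    q_mL_s: np.ndarray
    dt_ms: np.ndarray

    def __post_init__(self) -> None:
        self.q_mL_s = np.asarray(self.q_mL_s, dtype=float)
        self.dt_ms = np.asarray(self.dt_ms, dtype=float)
        if self.q_mL_s.shape != self.dt_ms.shape:
            raise ValueError("q and dt must have one entry per frame")
        if np.any(self.dt_ms <= 0):
            raise ValueError("frame durations must be positive")
        if not np.all(np.isfinite(self.q_mL_s)):
            raise ValueError("non-finite flow rate")

    @property
    def n_frames(self) -> int:
        return len(self.q_mL_s)

    def cycle_volume_mL(self) -> float:
        """Net volume over the cycle, sum(q * dt)."""
        return float(np.sum(self.q_mL_s * self.dt_ms) / 1000.0)


@dataclass
class CardiacPhases:
    """Frame-index partition of the cycle read off the flow curve.

    ``systole`` spans [onset, end_sys] inclusive, ``late_systole`` spans
    [peak, end_sys], and diastole is the complement of systole.
    """

    onset: int
    peak: int
    end_sys: int
    n_frames: int

    def __post_init__(self) -> None:
        if not (0 <= self.onset <= self.peak <= self.end_sys < self.n_frames):
            raise ValueError("require 0 <= onset <= peak <= end_sys < n_frames")

    @property
    def systole(self) -> np.ndarray:
        return np.arange(self.onset, self.end_sys + 1)

    @property
    def late_systole(self) -> np.ndarray:
        return np.arange(self.peak, self.end_sys + 1)

    @property
    def diastole(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_frames), self.systole)


@dataclass
class SimpleFlowIndices:
    ao_forward_mL: float
    ao_backward_mL: float
    sff_mL: float
    srf_mL: float
    vs_avg_cm_s: float
    vs_peak_cm_s: float


@dataclass
class ComplexScalarIndices:
    ao_max_area_cm2: float
    ao_max_area_frame: int
    sfrr_pct: float | None = None


def compute_flow_curve(vel: VelocitySeries, masks: LumenMaskSeries) -> FlowCurve:
    """Net volumetric flow rate per frame from mask-restricted velocity sums."""
    masks.check_compatible(vel)
    a = vel.pixel_area_mm2
    q = np.array(
        [vel.velocity[k][masks[k]].sum() * a / 100.0 for k in range(vel.n_frames)]
    )
    return FlowCurve(q_mL_s=q, dt_ms=vel.frame_durations_ms())


def detect_phases(curve: FlowCurve, onset_frac: float = 0.10) -> CardiacPhases:
    """Locate systole on the flow curve.

    peak = argmax q; onset = earliest frame of the contiguous run above
    ``onset_frac * max(q)`` ending at the peak (backward search); end systole
    = first frame after the peak with q <= 0, or the post-peak argmin when
    the curve never crosses zero.
    """
    q = curve.q_mL_s
    qmax = q.max()
    if qmax <= 0:
        raise ValueError("flow curve has no positive systolic flow")
    peak = int(np.argmax(q))
    thr = onset_frac * qmax

    onset = peak
    while onset > 0 and q[onset - 1] > thr:
        onset -= 1

    post = q[peak + 1 :]
    nonpos = np.flatnonzero(post <= 0)
    if len(nonpos):
        end_sys = peak + 1 + int(nonpos[0])
    elif len(post):
        end_sys = peak + 1 + int(np.argmin(post))
    else:
        end_sys = peak
    return CardiacPhases(onset=onset, peak=peak, end_sys=end_sys, n_frames=len(q))


def compute_simple_indices(
    vel: VelocitySeries,
    masks: LumenMaskSeries,
    curve: FlowCurve,
    phases: CardiacPhases,
    vs_peak_mode: str = "max",
) -> SimpleFlowIndices:
    """Forward/backward volumes, SFF/SRF and systolic velocity statistics.

    ``vs_peak_mode='p95'`` replaces the single maximum pixel velocity by the
    95th percentile over systolic in-mask velocities (robust variant).
    """
    masks.check_compatible(vel)
    sys_frames = phases.systole
    if len(sys_frames) == 0:
        raise ValueError("empty systolic window")

    q, dt = curve.q_mL_s, curve.dt_ms
    ao_forward = float(np.sum(np.maximum(q, 0.0) * dt) / 1000.0)
    ao_backward = float(np.sum(-np.minimum(q, 0.0) * dt) / 1000.0)

    a = vel.pixel_area_mm2
    sff = srf = 0.0
    vels = []
    for k in sys_frames:
        v = vel.velocity[k][masks[k]]
        sff += np.maximum(v, 0.0).sum() * a / 100.0 * dt[k] / 1000.0
        srf += -np.minimum(v, 0.0).sum() * a / 100.0 * dt[k] / 1000.0
        vels.append(v)
    allv = np.concatenate(vels)
    if vs_peak_mode == "p95":
        vs_peak = float(np.percentile(allv, 95.0))
    elif vs_peak_mode == "max":
        vs_peak = float(allv.max())
    else:
        raise ValueError("vs_peak_mode must be 'max' or 'p95'")
    return SimpleFlowIndices(
        ao_forward_mL=ao_forward,
        ao_backward_mL=ao_backward,
        sff_mL=float(sff),
        srf_mL=float(srf),
        vs_avg_cm_s=float(allv.mean()),
        vs_peak_cm_s=vs_peak,
    )


def compute_max_area(
    masks: LumenMaskSeries, pixel_spacing_mm: tuple[float, float]
) -> ComplexScalarIndices:
    """Maximum lumen cross-sectional area over the cycle, in cm^2.

    Ties break to the first frame attaining the maximum.
    """
    a_mm2 = pixel_spacing_mm[0] * pixel_spacing_mm[1]
    areas = masks.masks.sum(axis=(1, 2)) * a_mm2
    k = int(np.argmax(areas))
    return ComplexScalarIndices(
        ao_max_area_cm2=float(areas[k] / 100.0), ao_max_area_frame=k
    )


def compute_sfrr(simple: SimpleFlowIndices, denominator: str = "sff") -> float:
    """Systolic flow reversal ratio, 100 * SRF / SFF (percent).

    ``denominator='sff_plus_srf'`` switches to 100 * SRF / (SFF + SRF),
    the bounded-fraction variant.
    """
    if simple.sff_mL <= 0:
        raise ValueError("sFRR undefined: systolic forward flow is zero")
    if denominator == "sff":
        return 100.0 * simple.srf_mL / simple.sff_mL
    if denominator == "sff_plus_srf":
        return 100.0 * simple.srf_mL / (simple.sff_mL + simple.srf_mL)
    raise ValueError("denominator must be 'sff' or 'sff_plus_srf'")
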