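"""One-call quantification of a case: velocity stack + masks -> index row."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .displacement import displacement_trace, fd_averages, rotational_angle_change
from .flow import (
    INDEX_COLUMNS,
    compute_flow_curve,
    compute_max_area,
    compute_simple_indices,
    compute_sfrr,
    detect_phases,
)
from .series import LumenMaskSeries, VelocitySeries

__all__ = ["FlowIndexRecord", "quantify_case", "records_to_table"]


@dataclass
class FlowIndexRecord:
    """The full per-case index record (the Table-1 set of indices).

    ``delta_ra_deg`` is NaN when the systolic flow displacement never
    exceeded the gate, i.e. no jet direction was measurable.
    """

    case_id: str
    ao_forward_mL: float
    ao_backward_mL: float
    sff_mL: float
    srf_mL: float
    vs_avg_cm_s: float
    vs_peak_cm_s: float
    ao_max_area_cm2: float
    sfrr_pct: float
    fds_avg_pct: float
    fdls_avg_pct: float
    delta_ra_deg: float
    stabilization_frame: int = -1
    stabilization_fallback: bool = False

    def to_row(self) -> dict:
        """Row dict under the CSV column contract (case_id + 11 indices)."""
        return {"case_id": self.case_id} | {
            c: getattr(self, c) for c in INDEX_COLUMNS
        }

    @classmethod
    def columns(cls) -> list[str]:
        return ["case_id"] + list(INDEX_COLUMNS)


def quantify_case(
    vel: VelocitySeries,
    masks: LumenMaskSeries,
    config: RunConfig | None = None,
) -> FlowIndexRecord:
    """Run the full quantification chain on one case.

    Computes the flow curve, detects the cardiac phases, and derives all
    simple and complex indices under the thresholds in ``config``.
    """
    config = config or RunConfig()
    curve = compute_flow_curve(vel, masks)
    phases = detect_phases(curve, onset_frac=config.onset_frac)
    simple = compute_simple_indices(
        vel, masks, curve, phases, vs_peak_mode=config.vs_peak_mode
    )
    area = compute_max_area(masks, vel.pixel_spacing_mm)
    sfrr = compute_sfrr(simple, denominator=config.sfrr_denominator)
    trace = displacement_trace(
        vel,
        masks,
        phases,
        gate_pct=config.fd_gate_pct,
        normalization=config.normalization,
    )
    fds_avg, fdls_avg = fd_averages(trace, phases)
    try:
        delta_ra, stab_frame, fallback = rotational_angle_change(
            trace, phases, config.stab_tol_deg, config.stab_len
        )
    except ValueError:
        delta_ra, stab_frame, fallback = np.nan, -1, False
    return FlowIndexRecord(
        case_id=vel.case_id,
        ao_forward_mL=simple.ao_forward_mL,
        ao_backward_mL=simple.ao_backward_mL,
        sff_mL=simple.sff_mL,
        srf_mL=simple.srf_mL,
        vs_avg_cm_s=simple.vs_avg_cm_s,
        vs_peak_cm_s=simple.vs_peak_cm_s,
        ao_max_area_cm2=area.ao_max_area_cm2,
        sfrr_pct=sfrr,
        fds_avg_pct=fds_avg,
        fdls_avg_pct=fdls_avg,
        delta_ra_deg=delta_ra,
        stabilization_frame=stab_frame,
        stabilization_fallback=fallback,
    )


def records_to_table(records) -> pd.DataFrame:
    """Stack FlowIndexRecords into a per-case table (column contract order)."""
    return pd.DataFrame([r.to_row() for r in records])[FlowIndexRecord.columns()]
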