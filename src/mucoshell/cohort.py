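"""Cohort-level comparison of solid oral-cavity vs mucosal-shell dosimetry.

The headline quantity is the per-patient percent reduction in mean mucosal
dose when the shell (MSC) replaces the solid contour (OCC),

    reduction = 100 * (mean_OCC - mean_MSC) / mean_OCC,

reported as the cohort median with its range, plus pointwise median DVH
curves with min/max range envelopes across patients. The dose comparison
pairs the MSC against the full solid OCC; the derived OCC-surface annulus
participates in the geometry comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dosimetry import (
    DEFAULT_DVH_BIN_GY,
    DVHCurve,
    compute_dvh,
    eqd2_convert,
    sample_dose,
    summarise_dose,
)
from .geometry import ShellParams, derive_occ_surface, overlap_volume, resample_mask
from .grids import DoseGrid, FractionationScheme, StructureMask

__all__ = [
    "PatientComparison",
    "CohortSummary",
    "percent_reduction",
    "cohort_reduction_stats",
    "median_dvh",
    "build_patient_comparison",
    "summarise_cohort",
]


@dataclass
class PatientComparison:
    """Per-patient OCC-vs-MSC geometry and dose comparison."""

    patient_id: str
    mean_occ_gy: float
    mean_msc_gy: float
    reduction_pct: float
    occ_max_gy: float
    occ_max_in_ptv: bool
    occ_max_in_msc: bool
    vol_occ_cm3: float
    vol_occ_surface_cm3: float
    vol_msc_cm3: float
    overlap_occ_ptv_cm3: float
    overlap_msc_ptv_cm3: float
    dvh_occ: DVHCurve | None = None
    dvh_msc: DVHCurve | None = None


@dataclass
class CohortSummary:
    """Cohort medians and ranges of the per-patient comparisons."""

    n_patients: int
    reduction_median_pct: float
    reduction_min_pct: float
    reduction_max_pct: float
    dvh_axis_gy: np.ndarray
    dvh_median_occ: np.ndarray
    dvh_min_occ: np.ndarray
    dvh_max_occ: np.ndarray
    dvh_median_msc: np.ndarray
    dvh_min_msc: np.ndarray
    dvh_max_msc: np.ndarray

    def __post_init__(self) -> None:
        if not (
            self.reduction_min_pct
            <= self.reduction_median_pct
            <= self.reduction_max_pct
        ):
            raise ValueError("cohort reduction min <= median <= max violated")


def percent_reduction(mean_occ: float, mean_msc: float) -> float:
    """Percent reduction of the MSC mean relative to the OCC baseline.

    Negative when the shell mean exceeds the solid-contour mean.
    """
    if not (mean_occ > 0):
        raise ValueError(f"mean_occ must be > 0 Gy to define a relative reduction, got {mean_occ}")
    return 100.0 * (mean_occ - mean_msc) / mean_occ


def cohort_reduction_stats(reductions: np.ndarray) -> tuple[float, float, float]:
    """(median, min, max) of per-patient reductions; midpoint median for even counts."""
    arr = np.asarray(reductions, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cohort_reduction_stats needs at least one patient")
    return float(np.median(arr)), float(arr.min()), float(arr.max())


def median_dvh(
    curves: list[DVHCurve], bin_width: float = DEFAULT_DVH_BIN_GY
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise median and min/max envelope of DVH curves across patients.

    Curves are re-evaluated on a common axis spanning 0 to the global maximum
    dose (exact for sample-backed curves, which are step functions of their
    samples). Returns ``(axis, median, min, max)``; each output is itself a
    valid cumulative curve, and the envelopes contain every input pointwise.
    """
    if not curves:
        raise ValueError("median_dvh needs at least one curve")
    top = max(c.dose_axis[-1] for c in curves)
    axis = np.arange(int(round(top / bin_width)) + 1) * bin_width
    if axis[-1] < top:
        axis = np.append(axis, axis[-1] + bin_width)
    stack = np.vstack([c.evaluate(axis) for c in curves])
    return axis, np.median(stack, axis=0), stack.min(axis=0), stack.max(axis=0)


def build_patient_comparison(
    occ: StructureMask,
    msc: StructureMask,
    ptv: StructureMask,
    dose: DoseGrid,
    scheme: FractionationScheme,
    *,
    patient_id: str = "patient",
    occ_surface: StructureMask | None = None,
    shell_params: ShellParams = ShellParams(),
    dvh_bin_width: float = DEFAULT_DVH_BIN_GY,
    use_eqd2: bool = True,
    keep_dvh: bool = True,
) -> PatientComparison:
    """Full per-patient pipeline: geometry, EQD2 dosimetry and flags.

    Masks are resampled to the dose grid if needed. ``occ_surface`` is
    derived from the solid at ``shell_params.thickness`` when not supplied.
    ``use_eqd2=False`` computes means and the reduction on physical dose
    instead (the DVHs and maxima stay EQD2).
    """
    if occ.is_empty or msc.is_empty:
        raise ValueError("OCC and MSC masks must be non-empty")
    occ, msc, ptv = (
        resample_mask(m, dose.grid) if not m.grid.same_frame_as(dose.grid) else m
        for m in (occ, msc, ptv)
    )
    if occ_surface is None:
        occ_surface = derive_occ_surface(occ, shell_params)
    elif not occ_surface.grid.same_frame_as(dose.grid):
        occ_surface = resample_mask(occ_surface, dose.grid)

    eqd2 = eqd2_convert(dose, scheme)
    summary_occ = summarise_dose(dose, occ, scheme)
    summary_msc = summarise_dose(dose, msc, scheme)
    if use_eqd2:
        mean_occ, mean_msc = summary_occ.mean_gy, summary_msc.mean_gy
    else:
        mean_occ = float(sample_dose(dose, occ).mean())
        mean_msc = float(sample_dose(dose, msc).mean())

    max_idx = summary_occ.max_index
    return PatientComparison(
        patient_id=patient_id,
        mean_occ_gy=mean_occ,
        mean_msc_gy=mean_msc,
        reduction_pct=percent_reduction(mean_occ, mean_msc),
        occ_max_gy=summary_occ.max_gy,
        occ_max_in_ptv=bool(ptv.occupancy[max_idx]),
        occ_max_in_msc=bool(msc.occupancy[max_idx]),
        vol_occ_cm3=occ.volume_cm3(),
        vol_occ_surface_cm3=occ_surface.volume_cm3(),
        vol_msc_cm3=msc.volume_cm3(),
        overlap_occ_ptv_cm3=overlap_volume(occ, ptv),
        overlap_msc_ptv_cm3=overlap_volume(msc, ptv),
        dvh_occ=compute_dvh(sample_dose(eqd2, occ), dvh_bin_width) if keep_dvh else None,
        dvh_msc=compute_dvh(sample_dose(eqd2, msc), dvh_bin_width) if keep_dvh else None,
    )


def summarise_cohort(
    comparisons: list[PatientComparison],
    dvh_bin_width: float = DEFAULT_DVH_BIN_GY,
) -> CohortSummary:
    """Aggregate per-patient comparisons into cohort medians, ranges and DVH envelopes."""
    if not comparisons:
        raise ValueError("summarise_cohort needs at least one patient")
    med, lo, hi = cohort_reduction_stats([c.reduction_pct for c in comparisons])
    if any(c.dvh_occ is None or c.dvh_msc is None for c in comparisons):
        raise ValueError("cohort DVH envelopes need per-patient DVH curves (keep_dvh=True)")
    axis_occ, med_occ, min_occ, max_occ = median_dvh(
        [c.dvh_occ for c in comparisons], dvh_bin_width
    )
    axis_msc, med_msc, min_msc, max_msc = median_dvh(
        [c.dvh_msc for c in comparisons], dvh_bin_width
    )
    # put both on the longer common axis (curves are 0 beyond their own top)
    if axis_occ.size >= axis_msc.size:
        axis = axis_occ
        pad = axis.size - axis_msc.size
        med_msc, min_msc, max_msc = (
            np.pad(v, (0, pad)) for v in (med_msc, min_msc, max_msc)
        )
    else:
        axis = axis_msc
        pad = axis.size - axis_occ.size
        med_occ, min_occ, max_occ = (
            np.pad(v, (0, pad)) for v in (med_occ, min_occ, max_occ)
        )
    return CohortSummary(
        n_patients=len(comparisons),
        reduction_median_pct=med,
        reduction_min_pct=lo,
        reduction_max_pct=hi,
        dvh_axis_gy=axis,
        dvh_median_occ=med_occ,
        dvh_min_occ=min_occ,
        dvh_max_occ=max_occ,
        dvh_median_msc=med_msc,
        dvh_min_msc=min_msc,
        dvh_max_msc=max_msc,
    )
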