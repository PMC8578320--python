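"""End-to-end analysis orchestration: spectra → QC → curve → PEG₁/₂.

Thin glue over the ingest, QC, quantification and fitting modules so the
whole chain can be run in one call from scripts, tests and the CLI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .quality_control import QCFlags, ReferenceStats, compile_reference_stats, flag_outliers
from .quantification import QuantConfig, SolubilityCurve, build_curve
from .reader_ingest import AnnotatedPlate, SpectraPlate, annotate_layout, smooth_spectra
from .solubility_fit import (
    DerivedSolubility,
    FitResult,
    bootstrap_ci,
    extrapolate_apparent_solubility,
    fit_sigmoid,
    normalize_curve,
)

__all__ = ["AnalysisResult", "analyze_plate"]


@dataclass
class AnalysisResult:
    """Everything the analysis chain produces for one plate."""

    curve: SolubilityCurve
    normalized_curve: SolubilityCurve
    initial_fit: FitResult
    fit: FitResult  # normalized two-parameter fit, with bootstrap CIs
    flags: QCFlags
    derived: DerivedSolubility | None


def analyze_plate(
    plate: SpectraPlate,
    layout: pd.DataFrame | str,
    quant: QuantConfig | None = None,
    qc_ref: ReferenceStats | None = None,
    smooth: bool = True,
    smooth_window: int = 11,
    smooth_polyorder: int = 3,
    readout: str = "concentration",
    blank_mode: str = "matched",
    n_boot: int = 500,
    seed: int | None = None,
) -> AnalysisResult:
    """Run smoothing, QC, quantification, fitting and the bootstrap.

    Without *qc_ref*, reference statistics are compiled from the input plate
    itself (warned: a single run is a weak reference ensemble — compile one
    from several clean runs of your own instrument for production use).
    """
    quant = quant or QuantConfig()
    if smooth:
        plate = smooth_spectra(plate, smooth_window, smooth_polyorder)
    annotated = annotate_layout(plate, layout)
    if qc_ref is None:
        warnings.warn(
            "no QC reference supplied; compiling reference statistics from "
            "the input plate itself"
        )
        qc_ref = compile_reference_stats([annotated])
    flags = flag_outliers(annotated, qc_ref)
    curve = build_curve(annotated, flags, quant, readout=readout, blank_mode=blank_mode)
    initial = fit_sigmoid(curve)
    norm, norm_fit = normalize_curve(curve, initial)
    fit = bootstrap_ci(norm, norm_fit, n_cycles=n_boot, seed=seed)
    derived = None
    try:
        derived = extrapolate_apparent_solubility(curve, initial)
    except ValueError:
        pass
    return AnalysisResult(
        curve=curve,
        normalized_curve=norm,
        initial_fit=initial,
        fit=fit,
        flags=flags,
        derived=derived,
    )
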