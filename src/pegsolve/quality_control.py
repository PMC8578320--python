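"""Spectral quality control and pipetting-accuracy checks.

Two outlier criteria catch wells whose spectra are distorted by air bubbles
or other broad scattering artifacts rather than by genuine protein
precipitation: the absorbance at 310 nm must lie within mean ± 4 SD of a
reference ensemble, and the mean absorbance over 350-400 nm within
mean ± 7 SD.  Reference statistics are compiled by pooling raw wells from
several runs; the defaults shipped with the simulator emulate that pooling
and MUST be recompiled against a user's own instrument for real data.

A dye-titration check quantifies pipetting accuracy: free fluorophore added
to the top PEG stock makes fluorescence a linear reporter of realized PEG
concentration, so departures from the fitted line translate directly into
% w/v titration errors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reader_ingest import AnnotatedPlate, SpectraPlate, SpectrumRead

__all__ = [
    "ReferenceStats",
    "QCFlags",
    "DyeLinearityReport",
    "compile_reference_stats",
    "flag_outliers",
    "dye_linearity_check",
]

A310 = 310.0
BAND = (350.0, 400.0)


@dataclass
class ReferenceStats:
    """Pooled mean/SD of A310 and of the per-well 350-400 nm band mean."""

    mean_310: float
    sd_310: float
    mean_350_400: float
    sd_350_400: float
    n_sources: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceStats":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class QCFlags:
    """Per-well outlier decisions with z-scores for both criteria."""

    table: pd.DataFrame  # index well; columns flagged, reasons, z310, z350_400

    @property
    def flagged_wells(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])

    def is_flagged(self, well: str) -> bool:
        return bool(self.table.loc[well, "flagged"])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.table.copy()
        out["reasons"] = out["reasons"].map(lambda r: ";".join(sorted(r)))
        out.to_csv(path, index_label="well")
        return path


def _reads(plate: SpectraPlate | AnnotatedPlate) -> dict[str, SpectrumRead]:
    if isinstance(plate, AnnotatedPlate):
        return plate.plate.reads
    return plate.reads


def compile_reference_stats(
    plates: Iterable[SpectraPlate | AnnotatedPlate],
) -> ReferenceStats:
    """Pool every well of every plate into reference mean/SD.

    Sample SD (n−1 denominator) is used for robustness at small well counts.
    """
    plates = list(plates)
    if not plates:
        raise ValueError("need at least one plate to compile reference stats")
    a310, band = [], []
    for plate in plates:
        for read in _reads(plate).values():
            a310.append(read.value_at(A310))
            band.append(read.band_mean(*BAND))
    a310 = np.asarray(a310)
    band = np.asarray(band)
    sd = lambda v: float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return ReferenceStats(
        mean_310=float(a310.mean()),
        sd_310=sd(a310),
        mean_350_400=float(band.mean()),
        sd_350_400=sd(band),
        n_sources=len(plates),
    )


def flag_outliers(
    plate: SpectraPlate | AnnotatedPlate,
    ref: ReferenceStats,
    k310: float = 4.0,
    k350400: float = 7.0,
) -> QCFlags:
    """Apply the two spectral outlier criteria to every well.

    A well is flagged iff |A310 − mean| > k310·SD or the 350-400 nm band mean
    deviates by more than k350400·SD.  Values exactly at the threshold are
    inside the accepted range.  A criterion with zero reference SD is skipped
    with a warning; if both SDs are zero the call is rejected.
    """
    use310 = ref.sd_310 > 0
    use_band = ref.sd_350_400 > 0
    if not (use310 or use_band):
        raise ValueError("both reference SDs are zero; cannot flag outliers")
    if not use310:
        warnings.warn("sd_310 is zero; skipping the 310 nm criterion")
    if not use_band:
        warnings.warn("sd_350_400 is zero; skipping the 350-400 nm criterion")
    rows = {}
    for well, read in _reads(plate).items():
        z310 = (
            (read.value_at(A310) - ref.mean_310) / ref.sd_310 if use310 else 0.0
        )
        zband = (
            (read.band_mean(*BAND) - ref.mean_350_400) / ref.sd_350_400
            if use_band
            else 0.0
        )
        reasons = set()
        # strict inequality with a float-safe margin: a value computed to sit
        # exactly on the k·σ boundary must stay inside the accepted range
        eps = 1e-12
        if use310 and abs(z310) * ref.sd_310 > k310 * ref.sd_310 + eps:
            reasons.add("a310_out_of_range")
        if use_band and abs(zband) * ref.sd_350_400 > k350400 * ref.sd_350_400 + eps:
            reasons.add("a350_400_out_of_range")
        rows[well] = {
            "flagged": bool(reasons),
            "reasons": frozenset(reasons),
            "z310": z310,
            "z350_400": zband,
        }
    return QCFlags(pd.DataFrame.from_dict(rows, orient="index"))


@dataclass
class DyeLinearityReport:
    """Least-squares line through fluorescence vs expected PEG %, with the
    per-point realized-concentration errors it implies."""

    alpha: float  # intercept, AU
    beta: float  # slope, AU per % w/v
    r_squared: float
    realized_peg: np.ndarray  # % w/v back-computed from the line
    errors: np.ndarray  # |realized − expected|, % w/v
    median_error: float  # % w/v


def dye_linearity_check(
    expected_peg: Sequence[float], fluorescence: Sequence[float]
) -> DyeLinearityReport:
    """Fit fluorescence = α + β·PEG and report per-point titration errors.

    The realized PEG of each point is (F − α)/β; its error is the absolute
    deviation from the expected concentration, in % w/v.
    """
    x = np.asarray(expected_peg, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("expected PEG concentrations are all equal")
    beta, alpha = np.polyfit(x, y, 1)
    if beta == 0:
        raise ValueError("degenerate fit: zero slope")
    fitted = alpha + beta * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    realized = (y - alpha) / beta
    errors = np.abs(realized - x)
    return DyeLinearityReport(
        alpha=float(alpha),
        beta=float(beta),
        r_squared=r2,
        realized_peg=realized,
        errors=errors,
        median_error=float(np.median(errors)),
    )
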