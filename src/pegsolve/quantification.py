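"""Soluble-protein quantification from blanked absorbance spectra.

Concentration follows Beer-Lambert from the blanked A280 with a scattering
correction subtracted at 340 nm:

    c = (A280 − A340) / (ε · l) · dilution_factor

with ε the extinction coefficient (per mg/mL per cm), l the optical path
(cm) and the dilution factor mapping the measurement well back to the
supernatant.  Turbidity is the blanked A500.  Per-PEG-concentration means
over QC-passing wells assemble the solubility curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .quality_control import QCFlags
from .reader_ingest import AnnotatedPlate, SpectrumRead

__all__ = [
    "QuantConfig",
    "SolubilityCurve",
    "subtract_blank",
    "concentration_from_absorbance",
    "turbidity",
    "build_curve",
]


@dataclass
class QuantConfig:
    """Optical and dilution constants for concentration readout.

    ``dilution_factor`` maps the measurement-well concentration back to the
    supernatant ((prefill + transferred)/transferred for a prefilled
    destination well); it must match the actual transfer geometry.
    """

    extinction_coeff: float = 1.0  # AU per (mg/mL) per cm at 280 nm
    path_length: float = 0.4  # cm
    dilution_factor: float = 16.0 / 6.0
    correction_wavelength: float = 340.0  # nm

    def __post_init__(self) -> None:
        for name in ("extinction_coeff", "path_length", "dilution_factor",
                     "correction_wavelength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SolubilityCurve:
    """Soluble concentration (or turbidity) vs PEG % w/v.

    ``replicate_values[i]`` holds the per-well values behind point *i*, which
    the bootstrap resamples as technical-replicate cases;
    ``blank_values[i]`` the per-blank-well readout (same units) whose mean
    was subtracted, so blank-estimation error can be resampled as well.
    """

    peg_pct: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_wells: np.ndarray
    n_excluded: np.ndarray
    replicate_values: list[np.ndarray] | None = None
    blank_values: list[np.ndarray] | None = None
    protein_id: str = ""
    readout: str = "concentration"  # or "turbidity", "normalized"

    def __post_init__(self) -> None:
        self.peg_pct = np.asarray(self.peg_pct, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_wells = np.asarray(self.n_wells, dtype=int)
        self.n_excluded = np.asarray(self.n_excluded, dtype=int)
        if np.any(np.diff(self.peg_pct) <= 0):
            raise ValueError("peg_pct must be strictly increasing")
        if np.any(self.n_wells < 1):
            raise ValueError("every retained point needs at least one well")

    def __len__(self) -> int:
        return self.peg_pct.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peg_pct": self.peg_pct,
                "conc_mean": self.mean,
                "conc_sd": self.sd,
                "n_wells": self.n_wells,
                "n_excluded": self.n_excluded,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def subtract_blank(
    sample: SpectrumRead, blanks: Sequence[SpectrumRead]
) -> SpectrumRead:
    """Subtract the mean blank spectrum (same PEG concentration) pointwise."""
    if not blanks:
        raise ValueError("no blank spectra supplied")
    for b in blanks:
        if not np.array_equal(b.wavelengths, sample.wavelengths):
            raise ValueError(
                f"blank {b.well_id} wavelength grid differs from sample {sample.well_id}"
            )
    blank_mean = np.mean([b.absorbance for b in blanks], axis=0)
    return SpectrumRead(
        sample.well_id, sample.wavelengths, sample.absorbance - blank_mean
    )


def concentration_from_absorbance(blanked: SpectrumRead, q: QuantConfig) -> float:
    """Supernatant concentration (mg/mL) from a blanked spectrum.

    Negative corrected absorbance (over-blanking of a fully precipitated
    well) clamps to zero with a warning — soluble protein cannot be negative.
    """
    a280 = blanked.value_at(280.0)
    a_corr = blanked.value_at(q.correction_wavelength)
    c = (a280 - a_corr) / (q.extinction_coeff * q.path_length) * q.dilution_factor
    if c < 0:
        warnings.warn(
            f"well {blanked.well_id}: negative corrected absorbance; clamping to 0"
        )
        return 0.0
    return c


def turbidity(sample: SpectrumRead, blanks: Sequence[SpectrumRead]) -> float:
    """Blanked absorbance at 500 nm (scattering-based aggregation readout)."""
    return subtract_blank(sample, blanks).value_at(500.0)


def _blanks_for(
    plate: AnnotatedPlate, peg: float, exclude: set[str], blank_mode: str
) -> list[SpectrumRead]:
    ann = plate.annotations
    is_blank = ann["role"] == "blank"
    if blank_mode == "matched":
        sel = ann.index[is_blank & (ann["peg_pct"] == peg)]
        wells = [w for w in sel if w not in exclude]
        if wells:
            return [plate.plate.reads[w] for w in wells]
        warnings.warn(
            f"no usable blank at {peg:g}% PEG; falling back to the pooled blanks"
        )
    wells = [w for w in ann.index[is_blank] if w not in exclude]
    if not wells:
        raise ValueError(f"no usable blank wells for peg_pct {peg:g}")
    return [plate.plate.reads[w] for w in wells]


def build_curve(
    plate: AnnotatedPlate,
    flags: QCFlags | None,
    q: QuantConfig,
    readout: str = "concentration",
    blank_mode: str = "matched",
    min_points: int = 4,
    protein_id: str | None = None,
) -> SolubilityCurve:
    """Assemble the per-PEG-concentration solubility curve.

    Each sample well is blanked against the blanks at its PEG concentration
    and converted to a supernatant concentration (or turbidity).  QC-flagged
    wells are excluded and counted; a concentration whose wells are all
    flagged is dropped with a warning.  Fewer than *min_points* surviving
    concentrations make the downstream sigmoid fit infeasible and raise.
    """
    if readout not in ("concentration", "turbidity"):
        raise ValueError("readout must be 'concentration' or 'turbidity'")
    flagged = set(flags.flagged_wells) if flags is not None else set()
    ann = plate.annotations
    sample_wells = plate.wells_with_role("sample")
    pegs, means, sds, ns, nexs, reps, blank_vals = [], [], [], [], [], [], []
    for peg in sorted(set(ann.loc[sample_wells, "peg_pct"])):
        wells = [w for w in sample_wells if ann.loc[w, "peg_pct"] == peg]
        kept = [w for w in wells if w not in flagged]
        n_excluded = len(wells) - len(kept)
        if not kept:
            warnings.warn(f"all wells flagged at {peg:g}% PEG; point dropped")
            continue
        blanks = _blanks_for(plate, peg, flagged, blank_mode)
        values = []
        for w in kept:
            blanked = subtract_blank(plate.plate.reads[w], blanks)
            if readout == "concentration":
                values.append(concentration_from_absorbance(blanked, q))
            else:
                values.append(blanked.value_at(500.0))
        values = np.asarray(values)
        # per-blank-well readout in the same units, for blank-error resampling
        if readout == "concentration":
            scale = q.dilution_factor / (q.extinction_coeff * q.path_length)
            bvals = np.array(
                [(b.value_at(280.0) - b.value_at(q.correction_wavelength)) * scale
                 for b in blanks]
            )
        else:
            bvals = np.array([b.value_at(500.0) for b in blanks])
        pegs.append(peg)
        means.append(float(values.mean()))
        sds.append(float(np.std(values, ddof=1)) if values.size > 1 else 0.0)
        ns.append(values.size)
        nexs.append(n_excluded)
        reps.append(values)
        blank_vals.append(bvals)
    if len(pegs) < min_points:
        raise ValueError(
            f"only {len(pegs)} usable PEG concentrations (< {min_points}); "
            "sigmoid fit infeasible"
        )
    if protein_id is None:
        ids = set(ann.loc[sample_wells, "protein_id"]) - {""}
        protein_id = ids.pop() if len(ids) == 1 else ""
    return SolubilityCurve(
        peg_pct=np.array(pegs),
        mean=np.array(means),
        sd=np.array(sds),
        n_wells=np.array(ns),
        n_excluded=np.array(nexs),
        replicate_values=reps,
        blank_values=blank_vals,
        protein_id=protein_id,
        readout=readout,
    )
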