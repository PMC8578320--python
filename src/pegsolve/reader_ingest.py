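"""Plate-reader spectra ingestion.

Parses per-well absorbance spectra (220-700 nm) exported as delimited text
in either a long (``well,wavelength_nm,absorbance``) or wide (wells as rows,
wavelengths as columns) layout, joins the plate-layout table onto the wells,
and applies Savitzky-Golay smoothing along the wavelength axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

log = logging.getLogger(__name__)

__all__ = [
    "SpectrumRead",
    "SpectraPlate",
    "AnnotatedPlate",
    "parse_platereader_export",
    "write_long_csv",
    "smooth_spectra",
    "annotate_layout",
]

LAYOUT_COLUMNS = ["well", "role", "peg_pct", "replicate", "protein_id"]


@dataclass
class SpectrumRead:
    """Absorbance spectrum of one well."""

    well_id: str
    wavelengths: np.ndarray  # nm, strictly increasing
    absorbance: np.ndarray  # AU, same length

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError(f"well {self.well_id}: wavelength/absorbance length mismatch")
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise ValueError(f"well {self.well_id}: spectrum must be a non-empty vector")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError(f"well {self.well_id}: wavelengths not strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError(f"well {self.well_id}: non-finite absorbance")

    def value_at(self, wavelength: float, tol: float = 0.5) -> float:
        """Absorbance at the grid point nearest *wavelength* (within *tol* nm)."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) > tol:
            raise ValueError(
                f"well {self.well_id}: wavelength grid has no point near {wavelength} nm"
            )
        return float(self.absorbance[i])

    def band_mean(self, lo: float, hi: float) -> float:
        """Mean absorbance over grid points in [lo, hi] nm (inclusive)."""
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise ValueError(
                f"well {self.well_id}: wavelength grid has no points in [{lo}, {hi}] nm"
            )
        return float(self.absorbance[mask].mean())


@dataclass
class SpectraPlate:
    """Collection of per-well spectra sharing one wavelength grid."""

    reads: dict[str, SpectrumRead]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError("plate has no reads")
        grid = self.wavelengths
        bad = [
            w for w, r in self.reads.items()
            if r.wavelengths.shape != grid.shape or not np.array_equal(r.wavelengths, grid)
        ]
        if bad:
            raise ValueError(f"wells on a different wavelength grid: {bad}")

    @property
    def wavelengths(self) -> np.ndarray:
        return next(iter(self.reads.values())).wavelengths

    @property
    def wells(self) -> list[str]:
        return list(self.reads)

    def to_long_frame(self) -> pd.DataFrame:
        grid = self.wavelengths
        frames = [
            pd.DataFrame(
                {"well": w, "wavelength_nm": grid, "absorbance": r.absorbance}
            )
            for w, r in self.reads.items()
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass
class AnnotatedPlate:
    """Spectra plus the per-well layout (role, PEG %, replicate, protein id)."""

    plate: SpectraPlate
    annotations: pd.DataFrame  # indexed by well

    def wells_with_role(self, role: str) -> list[str]:
        return list(self.annotations.index[self.annotations["role"] == role])

    def peg_of(self, well: str) -> float:
        return float(self.annotations.loc[well, "peg_pct"])


def _plate_from_matrix(mat: pd.DataFrame, metadata: dict | None = None) -> SpectraPlate:
    grid = np.asarray(mat.columns, dtype=float)
    order = np.argsort(grid)
    grid = grid[order]
    reads = {
        str(well): SpectrumRead(str(well), grid, mat.loc[well].to_numpy(dtype=float)[order])
        for well in mat.index
    }
    return SpectraPlate(reads, metadata or {})


def parse_platereader_export(
    path: str | Path, dialect: str = "long_csv", metadata: dict | None = None
) -> SpectraPlate:
    """Parse a delimited spectra export into a :class:`SpectraPlate`.

    ``long_csv`` expects columns ``well,wavelength_nm,absorbance``; ``wide_csv``
    expects a ``well`` column followed by one column per wavelength.  All wells
    must share one wavelength grid; ragged files are rejected with the
    offending wells named.
    """
    path = Path(path)
    if dialect == "long_csv":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"well", "wavelength_nm", "absorbance"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: long_csv needs columns {sorted(required)}")
        for col in ("wavelength_nm", "absorbance"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric {col} at data row {int(bad[0]) + 2}"
                )
            df[col] = coerced
        if df[["well", "wavelength_nm", "absorbance"]].isna().any().any():
            raise ValueError(f"{path}: missing values in export")
        counts = df.groupby("well", sort=False)["wavelength_nm"].apply(tuple)
        grids = counts.unique()
        if len(grids) > 1:
            majority = counts.value_counts().idxmax()
            offending = sorted(counts.index[counts != majority])
            raise ValueError(f"{path}: ragged wavelength grids for wells {offending}")
        mat = df.pivot(index="well", columns="wavelength_nm", values="absorbance")
        # preserve file order of wells
        mat = mat.loc[pd.unique(df["well"])]
        return _plate_from_matrix(mat, metadata)
    if dialect == "wide_csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.columns[0] != "well":
            raise ValueError(f"{path}: wide_csv must start with a 'well' column")
        mat = df.set_index("well")
        try:
            mat = mat.astype(float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric absorbance value ({exc})") from exc
        if not np.all(np.isfinite(mat.to_numpy())):
            raise ValueError(f"{path}: missing/non-finite absorbance values")
        return _plate_from_matrix(mat, metadata)
    raise ValueError(f"unknown dialect {dialect!r} (expected long_csv or wide_csv)")


def write_long_csv(plate: SpectraPlate, path: str | Path) -> Path:
    """Serialize a plate to the normalized long-CSV layout (parse round-trips)."""
    path = Path(path)
    # %.17g keeps doubles exact through the text round-trip
    plate.to_long_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def smooth_spectra(
    plate: SpectraPlate, window: int = 11, polyorder: int = 3, mode: str = "mirror"
) -> SpectraPlate:
    """Savitzky-Golay smoothing along the wavelength axis of every well.

    The filter preserves polynomials up to *polyorder* exactly, so flat and
    gently curved spectral regions pass through unchanged while uncorrelated
    noise is attenuated.  The wavelength grid is untouched.
    """
    n = plate.wavelengths.size
    if window % 2 == 0 or window <= polyorder or window > n:
        raise ValueError(
            f"window must be odd, > polyorder and ≤ spectrum length "
            f"(got window={window}, polyorder={polyorder}, n={n})"
        )
    reads = {
        w: SpectrumRead(
            w, r.wavelengths, savgol_filter(r.absorbance, window, polyorder, mode=mode)
        )
        for w, r in plate.reads.items()
    }
    return SpectraPlate(reads, dict(plate.metadata))


def annotate_layout(
    plate: SpectraPlate, layout: str | Path | pd.DataFrame
) -> AnnotatedPlate:
    """Join a plate-layout table onto the spectra.

    Layout wells missing from the plate raise; plate wells absent from the
    layout are dropped with a logged warning.
    """
    if not isinstance(layout, pd.DataFrame):
        layout = pd.read_csv(layout)
    missing_cols = set(LAYOUT_COLUMNS[:4]) - set(layout.columns)
    if missing_cols:
        raise ValueError(f"layout missing columns: {sorted(missing_cols)}")
    layout = layout.copy()
    if "protein_id" not in layout.columns:
        layout["protein_id"] = ""
    layout["well"] = layout["well"].astype(str)
    unknown = sorted(set(layout["well"]) - set(plate.reads))
    if unknown:
        raise ValueError(f"layout references wells absent from the plate: {unknown}")
    bad_roles = sorted(set(layout["role"]) - {"sample", "blank"})
    if bad_roles:
        raise ValueError(f"layout roles must be sample/blank, got {bad_roles}")
    dropped = sorted(set(plate.reads) - set(layout["well"]))
    if dropped:
        log.warning("dropping %d unannotated wells: %s", len(dropped), dropped)
    ann = layout.set_index("well")
    ann["peg_pct"] = ann["peg_pct"].astype(float)
    reads = {w: plate.reads[w] for w in ann.index}
    sample_pegs = set(ann.loc[ann["role"] == "sample", "peg_pct"])
    blank_pegs = set(ann.loc[ann["role"] == "blank", "peg_pct"])
    if sample_pegs and not blank_pegs:
        raise ValueError("layout contains samples but no blank wells")
    return AnnotatedPlate(SpectraPlate(reads, dict(plate.metadata)), ann)
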