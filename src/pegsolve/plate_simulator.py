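"""Synthetic plate generator with known ground truth.

Emulates the measurement plate of a PEG-precipitation run end to end: the
true soluble concentration follows the same logistic law the fitting module
assumes (c(x) = c0 / (1 + exp(s·(x − PEG₁/₂)))), each measurement well gets
a full 220-700 nm absorbance spectrum composed of

* a protein band peaking at 280 nm (truncated Gaussian with compact
  support, so it contributes nothing at or beyond the 340 nm scattering
  correction or the 350-400 nm QC band),
* a PEG-dependent scattering baseline rising like λ⁻⁴ toward the UV,
  shared between sample and blank wells at the same PEG concentration,
* optional bubble artifacts: a broad λ⁻² scattering offset large enough to
  violate the 310 nm / 350-400 nm outlier bands,
* i.i.d. Gaussian read noise per wavelength, and
* multiplicative per-well concentration noise (pipetting/path-length
  variability) at 3 % by default.

Evaporation concentrates the supernatant by 1/(1 − evaporation_frac).
Outputs use exactly the CSV dialects the ingest module consumes, with the
truth stored in a JSON sidecar.  Fixed seed ⇒ byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_design import (
    DesignConfig,
    TransferConfig,
    plan_assay,
    plan_supernatant_transfer,
)
from .quantification import QuantConfig
from .reader_ingest import SpectraPlate, SpectrumRead

__all__ = ["SimTruth", "OpticsModel", "SimulatedAssay", "simulate_assay",
           "simulate_dye_titration", "write_simulated_assay"]

WAVELENGTHS = np.arange(220.0, 701.0)  # 1 nm grid, as recorded by the reader


@dataclass
class SimTruth:
    """Ground-truth parameters of one simulated assay."""

    peg_half_true: float = 12.0  # % w/v
    s_true: float = 1.5  # per % w/v
    c0: float = 1.0  # mg/mL soluble at 0% PEG
    noise_sd: float = 0.002  # AU additive read noise per wavelength
    conc_noise_frac: float = 0.03  # multiplicative per-well concentration noise
    bubble_rate: float = 0.0  # probability a well carries a bubble artifact
    evaporation_frac: float = 0.0  # fraction of source volume lost
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bubble_rate <= 1:
            raise ValueError("bubble_rate must be in [0, 1]")
        if not 0 <= self.evaporation_frac < 1:
            raise ValueError("evaporation_frac must be in [0, 1)")
        if self.noise_sd < 0 or self.conc_noise_frac < 0:
            raise ValueError("noise scales must be ≥ 0")


@dataclass
class OpticsModel:
    """Spectral shape constants of the forward model (fixed so tests are stable)."""

    band_center: float = 280.0  # nm
    band_sigma: float = 14.0  # nm
    band_halfwidth: float = 55.0  # nm; absorbance is exactly 0 beyond this
    scatter_per_peg: float = 0.002  # AU per % w/v PEG at the reference wavelength
    scatter_ref: float = 400.0  # nm
    bubble_amplitude: float = 0.8  # AU at the bubble reference wavelength
    bubble_ref: float = 310.0  # nm

    def protein_band(self, wl: np.ndarray) -> np.ndarray:
        """Unit-peak truncated Gaussian: exactly zero beyond ±band_halfwidth."""
        d = wl - self.band_center
        cut = np.exp(-0.5 * (self.band_halfwidth / self.band_sigma) ** 2)
        band = (np.exp(-0.5 * (d / self.band_sigma) ** 2) - cut) / (1.0 - cut)
        return np.where(np.abs(d) < self.band_halfwidth, band, 0.0)

    def peg_baseline(self, wl: np.ndarray, peg_pct: float) -> np.ndarray:
        return self.scatter_per_peg * peg_pct * (self.scatter_ref / wl) ** 4

    def bubble(self, wl: np.ndarray) -> np.ndarray:
        return self.bubble_amplitude * (self.bubble_ref / wl) ** 2


@dataclass
class SimulatedAssay:
    """A simulated measurement plate with its layout and ground truth."""

    plate: SpectraPlate
    layout: pd.DataFrame
    truth: dict


def true_concentration(peg_pct, truth: SimTruth) -> np.ndarray:
    """True soluble supernatant concentration at each PEG % (after evaporation)."""
    x = np.asarray(peg_pct, dtype=float)
    z = np.clip(truth.s_true * (x - truth.peg_half_true), -500, 500)
    return truth.c0 / (1.0 + np.exp(z)) / (1.0 - truth.evaporation_frac)


def simulate_assay(
    design: DesignConfig,
    truth: SimTruth,
    quant: QuantConfig | None = None,
    optics: OpticsModel | None = None,
    transfer: TransferConfig | None = None,
    protein_id: str = "sim-protein",
) -> SimulatedAssay:
    """Simulate the measurement plate produced by one full assay run.

    The assay plate is planned from *design*, the supernatant transfer maps
    each source well to its measurement wells, and every measurement well
    receives a synthetic spectrum consistent with *quant*'s optics (so the
    quantification module inverts the forward model exactly in the
    noiseless limit).
    """
    quant = quant or QuantConfig()
    optics = optics or OpticsModel()
    rng = np.random.default_rng(truth.seed)
    plan = plan_assay(design)
    transfers = plan_supernatant_transfer(plan, design, transfer)
    by_source = {w.well_id: w for w in plan}

    wl = WAVELENGTHS
    band = optics.protein_band(wl)
    eps_l = quant.extinction_coeff * quant.path_length

    reads: dict[str, SpectrumRead] = {}
    layout_rows = []
    well_truth = {}
    rep_counter: dict[tuple, int] = {}
    for t in transfers:
        src = by_source[t.source_well]
        c_sup = float(true_concentration(src.peg_target, truth)) if src.role == "sample" else 0.0
        for dest in t.dest_wells:
            key = (src.peg_target, src.role)
            rep = rep_counter.get(key, 0)
            rep_counter[key] = rep + 1
            c_well = c_sup
            if src.role == "sample" and truth.conc_noise_frac > 0:
                c_well = max(0.0, c_well * (1.0 + truth.conc_noise_frac * rng.standard_normal()))
            c_meas = c_well / quant.dilution_factor
            spectrum = eps_l * c_meas * band + optics.peg_baseline(wl, src.peg_target)
            bubble = bool(rng.random() < truth.bubble_rate)
            if bubble:
                spectrum = spectrum + optics.bubble(wl)
            if truth.noise_sd > 0:
                spectrum = spectrum + rng.normal(0.0, truth.noise_sd, wl.size)
            reads[dest] = SpectrumRead(dest, wl, spectrum)
            layout_rows.append(
                [dest, src.role, src.peg_target, rep,
                 protein_id if src.role == "sample" else ""]
            )
            well_truth[dest] = {
                "role": src.role,
                "peg_pct": src.peg_target,
                "true_supernatant_conc": c_well,
                "bubble": bubble,
            }
    layout = pd.DataFrame(
        layout_rows, columns=["well", "role", "peg_pct", "replicate", "protein_id"]
    )
    truth_record = {**asdict(truth), "protein_id": protein_id, "wells": well_truth}
    return SimulatedAssay(SpectraPlate(reads), layout, truth_record)


def write_simulated_assay(sim: SimulatedAssay, outdir: str | Path, stem: str = "plate"):
    """Write plate CSV (long), layout CSV and the ``*.truth.json`` sidecar."""
    from .reader_ingest import write_long_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plate_path = write_long_csv(sim.plate, outdir / f"{stem}.csv")
    layout_path = outdir / f"{stem}.layout.csv"
    sim.layout.to_csv(layout_path, index=False)
    truth_path = outdir / f"{stem}.truth.json"
    truth_path.write_text(json.dumps(sim.truth, indent=2))
    return plate_path, layout_path, truth_path


def simulate_dye_titration(
    design: DesignConfig,
    volume_error_sd: float = 0.0,
    seed: int = 0,
    gain: float = 1000.0,
) -> pd.DataFrame:
    """Simulate the fluorophore-spiked titration used to validate pipetting.

    Dye travels with the PEG stock, so fluorescence is strictly proportional
    to the realized PEG concentration.  Each planned transfer is perturbed by
    Gaussian volume noise (truncated at zero) of scale *volume_error_sd* µL;
    the realized PEG % follows from the realized volumes.  Returns the table
    ``well,expected_peg_pct,fluorescence``.
    """
    if volume_error_sd < 0:
        raise ValueError("volume_error_sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    plan = plan_assay(design)
    rows = []
    for w in plan:
        if w.role != "sample":
            continue
        planned = np.array([float(w.v_peg), float(w.v_buffer), float(w.v_protein)])
        realized = planned.copy()
        for i, v in enumerate(planned):
            if v > 0 and volume_error_sd > 0:
                realized[i] = max(0.0, v + rng.normal(0.0, volume_error_sd))
        total = realized.sum()
        realized_peg = realized[0] * w.peg_stock_used / total if total > 0 else 0.0
        rows.append([w.well_id, w.peg_target, gain * realized_peg])
    return pd.DataFrame(rows, columns=["well", "expected_peg_pct", "fluorescence"])
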