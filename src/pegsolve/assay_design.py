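"""Titration planning for PEG-precipitation solubility assays.

Computes per-well recipes for mixing PEG stocks, buffer and protein to a
fixed final well volume, the supernatant-transfer map into the measurement
plate, consumables totals, and machine-readable worklists for a
liquid-handling robot.

Volumes are handled as exact rationals (:class:`fractions.Fraction`)
internally, so conservation invariants (volumes sum to the well volume,
realized PEG % equals the target) hold exactly; worklists round to 0.001 µL.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DesignConfig",
    "WellPlan",
    "TransferConfig",
    "TransferPlan",
    "Consumables",
    "InfeasibleTargetError",
    "plan_assay",
    "max_achievable_peg",
    "summarize_consumables",
    "plan_supernatant_transfer",
    "emit_worklist",
    "emit_transfer_worklist",
    "parse_worklist",
    "write_layout",
    "well_name",
]

#: default titration: 12 concentrations spanning the achievable 0-33% range
DEFAULT_PEG_TARGETS = tuple(float(3 * i) for i in range(12))


class InfeasibleTargetError(ValueError):
    """A PEG target cannot be reached with the available stocks and volumes."""


def _frac(x) -> Fraction:
    """Exact rational from a numeric input (floats snapped to ≤1e-6 denominator)."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(x).limit_denominator(1_000_000)


def well_name(index: int, n_cols: int = 24) -> str:
    """Row-major well coordinate ('A1', 'A2', ...) for a plate with *n_cols* columns."""
    row, col = divmod(index, n_cols)
    if row >= 26:
        raise ValueError(f"well index {index} beyond plate rows")
    return f"{chr(ord('A') + row)}{col + 1}"


@dataclass
class DesignConfig:
    """Parameters of one titration run.

    Defaults reflect a standard low-volume 384-well run: 10 µL final volume,
    1 mg/mL final protein from a 3 mg/mL stock, PEG stocks at 15/30/50 % w/v,
    twelve PEG concentrations with two replicates and one blank each, and a
    0.33 µL minimum pipettable volume.
    """

    final_well_volume: float = 10.0  # µL
    final_protein_conc: float = 1.0  # mg/mL
    protein_stock_conc: float = 3.0  # mg/mL
    peg_stock_concs: Sequence[float] = (15.0, 30.0, 50.0)  # % w/v
    peg_targets: Sequence[float] = DEFAULT_PEG_TARGETS  # % w/v final
    replicates_per_conc: int = 2
    blanks_per_conc: int = 1
    min_transfer_volume: float = 0.33  # µL
    plate_columns: int = 24  # 384-well geometry by default
    plate_rows: int = 16

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.final_well_volume <= 0:
            raise ValueError("final_well_volume must be positive")
        if not 0 <= self.final_protein_conc <= self.protein_stock_conc:
            raise ValueError("final_protein_conc must be in [0, protein_stock_conc]")
        targets = list(self.peg_targets)
        if any(t < 0 for t in targets):
            raise ValueError("peg_targets must be non-negative")
        if any(b <= a for a, b in zip(targets, targets[1:])):
            raise ValueError("peg_targets must be strictly increasing")
        stocks = list(self.peg_stock_concs)
        if not stocks or any(s <= 0 for s in stocks):
            raise ValueError("peg_stock_concs must be positive")
        if sorted(stocks) != stocks:
            raise ValueError("peg_stock_concs must be sorted ascending")
        if self.replicates_per_conc < 1 or self.blanks_per_conc < 0:
            raise ValueError("need ≥1 replicate and ≥0 blanks per concentration")
        if self.min_transfer_volume < 0:
            raise ValueError("min_transfer_volume must be ≥ 0")

    @property
    def protein_volume_per_well(self) -> Fraction:
        """µL of protein stock needed per sample well (mass conservation)."""
        return (
            _frac(self.final_well_volume)
            * _frac(self.final_protein_conc)
            / _frac(self.protein_stock_conc)
        )


@dataclass
class WellPlan:
    """Recipe for a single assay-plate well."""

    well_id: str
    role: str  # "sample" | "blank"
    peg_target: float  # % w/v final
    peg_stock_used: float  # % w/v of the stock dispensed (0 for 0% target)
    v_peg: Fraction  # µL
    v_buffer: Fraction  # µL
    v_protein: Fraction  # µL
    replicate: int


@dataclass
class TransferConfig:
    """Supernatant-transfer settings (assay plate → prefilled measurement plate)."""

    v_per_transfer: float = 3.0  # µL aspirated per transfer step
    n_transfers: int = 2  # transfer steps per source well
    prefill_volume: float = 10.0  # µL of buffer pre-dispensed per destination
    dest_rows: int = 16
    dest_cols: int = 24
    evaporation_headroom: float = 2.0  # µL that may be lost before transfer


@dataclass
class TransferPlan:
    """Transfers out of one source well."""

    source_well: str
    dest_wells: list[str]
    v_per_transfer: float
    n_transfers: int
    prefill_volume: float


@dataclass
class Consumables:
    """Reagent totals for a planned run."""

    total_protein_volume: float  # µL of protein stock
    total_protein_mass: float  # µg
    peg_volumes: dict[float, float]  # stock % w/v -> µL
    total_buffer: float  # µL
    n_wells: int

    def to_dict(self) -> dict:
        return {
            "total_protein_volume_ul": self.total_protein_volume,
            "total_protein_mass_ug": self.total_protein_mass,
            "peg_volumes_ul": {f"{k:g}": v for k, v in self.peg_volumes.items()},
            "total_buffer_ul": self.total_buffer,
            "n_wells": self.n_wells,
        }


def _choose_stock(
    target: Fraction,
    volume: Fraction,
    budget: Fraction,
    stocks: Sequence[float],
    min_v: Fraction,
) -> tuple[Fraction, Fraction]:
    """Pick the PEG stock for one target: lowest concentration whose required
    volume fits the PEG+buffer budget and is pipettable.  Lower stocks need
    larger volumes, so this choice maximizes the transferred volume and hence
    pipetting accuracy with viscous PEG."""
    for stock in stocks:  # ascending
        v_peg = target * volume / _frac(stock)
        if min_v <= v_peg <= budget:
            return _frac(stock), v_peg
    raise InfeasibleTargetError(
        f"PEG target {float(target):g}% w/v is not achievable: no stock in "
        f"{list(stocks)} gives a volume within [{float(min_v):g}, {float(budget):g}] µL"
    )


def plan_assay(config: DesignConfig) -> list[WellPlan]:
    """Compute the per-well recipes for one run.

    One well per (target × replicate) plus the configured blanks per target,
    assigned row-major with replicates adjacent and blanks following them.
    Blanks carry the same PEG recipe with the protein volume replaced by
    buffer.  The minimum-transfer constraint applies to the PEG and protein
    dispenses; a small residual buffer top-up below it is allowed (the
    realized PEG % and protein concentration are set by their own transfers).
    """
    config.validate()
    volume = _frac(config.final_well_volume)
    v_protein = config.protein_volume_per_well
    budget = volume - v_protein
    min_v = _frac(config.min_transfer_volume)
    if v_protein > 0 and v_protein < min_v:
        raise InfeasibleTargetError(
            f"protein volume {float(v_protein):g} µL below the "
            f"{config.min_transfer_volume:g} µL minimum transfer"
        )

    plans: list[WellPlan] = []
    idx = 0
    for target in config.peg_targets:
        t = _frac(target)
        if t == 0:
            stock, v_peg = Fraction(0), Fraction(0)
        else:
            stock, v_peg = _choose_stock(
                t, volume, budget, config.peg_stock_concs, min_v
            )
        for rep in range(config.replicates_per_conc):
            plans.append(
                WellPlan(
                    well_id=well_name(idx, config.plate_columns),
                    role="sample",
                    peg_target=float(target),
                    peg_stock_used=float(stock),
                    v_peg=v_peg,
                    v_buffer=volume - v_peg - v_protein,
                    v_protein=v_protein,
                    replicate=rep,
                )
            )
            idx += 1
        for rep in range(config.blanks_per_conc):
            plans.append(
                WellPlan(
                    well_id=well_name(idx, config.plate_columns),
                    role="blank",
                    peg_target=float(target),
                    peg_stock_used=float(stock),
                    v_peg=v_peg,
                    v_buffer=volume - v_peg,
                    v_protein=Fraction(0),
                    replicate=rep,
                )
            )
            idx += 1
    if idx > config.plate_rows * config.plate_columns:
        raise InfeasibleTargetError(
            f"plan needs {idx} wells but plate holds "
            f"{config.plate_rows * config.plate_columns}"
        )
    return plans


def max_achievable_peg(config: DesignConfig) -> float:
    """Highest final PEG % reachable once the protein volume is committed.

    The whole non-protein budget filled from the strongest stock:
    ``max(stocks) * (V - v_protein) / V``.
    """
    config.validate()
    volume = _frac(config.final_well_volume)
    budget = volume - config.protein_volume_per_well
    return float(_frac(max(config.peg_stock_concs)) * budget / volume)


def summarize_consumables(plan: Iterable[WellPlan], config: DesignConfig) -> Consumables:
    """Total reagent requirements for a plan (protein mass in µg)."""
    plan = list(plan)
    v_protein = sum((w.v_protein for w in plan), Fraction(0))
    v_buffer = sum((w.v_buffer for w in plan), Fraction(0))
    peg: dict[float, Fraction] = {}
    for w in plan:
        if w.v_peg > 0:
            peg[w.peg_stock_used] = peg.get(w.peg_stock_used, Fraction(0)) + w.v_peg
    return Consumables(
        total_protein_volume=float(v_protein),
        total_protein_mass=float(v_protein * _frac(config.protein_stock_conc)),
        peg_volumes={k: float(v) for k, v in sorted(peg.items())},
        total_buffer=float(v_buffer),
        n_wells=len(plan),
    )


def plan_supernatant_transfer(
    plan: Sequence[WellPlan],
    config: DesignConfig,
    transfer: TransferConfig | None = None,
) -> list[TransferPlan]:
    """Map each assay well to measurement-plate destinations.

    Each source well yields ``n_transfers`` aliquots of ``v_per_transfer`` µL
    into separate prefilled destination wells (each aliquot is a technical
    replicate).  Destinations are assigned row-major in source order.  The
    total removed must leave headroom for evaporation losses in the source.
    """
    transfer = transfer or TransferConfig()
    if transfer.n_transfers == 0:
        return []
    removed = transfer.n_transfers * transfer.v_per_transfer
    if removed > config.final_well_volume - transfer.evaporation_headroom:
        raise ValueError(
            f"removing {removed:g} µL exceeds the {config.final_well_volume:g} µL "
            f"well minus {transfer.evaporation_headroom:g} µL evaporation headroom"
        )
    capacity = transfer.dest_rows * transfer.dest_cols
    needed = len(plan) * transfer.n_transfers
    if needed > capacity:
        raise ValueError(
            f"transfer needs {needed} destination wells but plate holds {capacity}"
        )
    out: list[TransferPlan] = []
    dest = 0
    for w in plan:
        dests = [
            well_name(dest + i, transfer.dest_cols) for i in range(transfer.n_transfers)
        ]
        dest += transfer.n_transfers
        out.append(
            TransferPlan(
                source_well=w.well_id,
                dest_wells=dests,
                v_per_transfer=transfer.v_per_transfer,
                n_transfers=transfer.n_transfers,
                prefill_volume=transfer.prefill_volume,
            )
        )
    return out


WORKLIST_HEADER = [
    "step",
    "source_labware",
    "source_well",
    "dest_labware",
    "dest_well",
    "volume_ul",
    "reagent",
]


def emit_worklist(plans: Sequence[WellPlan], destination: str | Path) -> Path:
    """Write the sample-preparation worklist (one row per liquid transfer).

    Row order is execution order: all PEG transfers first, then buffer, then
    protein last so the incubation clock starts with the final dispense.
    Zero-volume transfers are omitted; volumes are rounded to 0.001 µL.
    """
    destination = Path(destination)
    rows = []
    step = 1
    for phase, reagent_of, vol_of in (
        ("peg", lambda w: f"peg_stock_{w.peg_stock_used:g}pct", lambda w: w.v_peg),
        ("buffer", lambda w: "buffer", lambda w: w.v_buffer),
        ("protein", lambda w: "protein_stock", lambda w: w.v_protein),
    ):
        for w in plans:
            v = vol_of(w)
            if v == 0:
                continue
            rows.append(
                [step, reagent_of(w), "A1", "assay_plate", w.well_id,
                 f"{float(v):.3f}", phase]
            )
            step += 1
    with destination.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(WORKLIST_HEADER)
        writer.writerows(rows)
    return destination


def emit_transfer_worklist(
    transfers: Sequence[TransferPlan], destination: str | Path
) -> Path:
    """Write the supernatant-transfer worklist (prefill rows, then aliquots)."""
    destination = Path(destination)
    rows = []
    step = 1
    for t in transfers:
        for d in t.dest_wells:
            if t.prefill_volume > 0:
                rows.append(
                    [step, "buffer", "A1", "measurement_plate", d,
                     f"{t.prefill_volume:.3f}", "prefill"]
                )
                step += 1
    for t in transfers:
        for d in t.dest_wells:
            rows.append(
                [step, "assay_plate", t.source_well, "measurement_plate", d,
                 f"{t.v_per_transfer:.3f}", "supernatant"]
            )
            step += 1
    with destination.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(WORKLIST_HEADER)
        writer.writerows(rows)
    return destination


def parse_worklist(path: str | Path) -> pd.DataFrame:
    """Read a worklist back; volumes as floats, ordered by step."""
    df = pd.read_csv(path)
    missing = set(WORKLIST_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"worklist missing columns: {sorted(missing)}")
    return df.sort_values("step").reset_index(drop=True)


def write_layout(
    plans: Sequence[WellPlan],
    path: str | Path,
    protein_id: str = "protein",
    transfers: Sequence[TransferPlan] | None = None,
) -> Path:
    """Write the plate-layout table (``well,role,peg_pct,replicate,protein_id``).

    With *transfers* given, the layout describes the measurement plate
    (destination wells inherit role and PEG % from their source); otherwise it
    describes the assay plate itself.
    """
    path = Path(path)
    rows = []
    if transfers is None:
        for w in plans:
            rows.append([w.well_id, w.role, w.peg_target, w.replicate,
                         protein_id if w.role == "sample" else ""])
    else:
        by_well = {w.well_id: w for w in plans}
        counter: dict[tuple, int] = {}
        for t in transfers:
            src = by_well[t.source_well]
            for d in t.dest_wells:
                key = (src.peg_target, src.role)
                rep = counter.get(key, 0)
                counter[key] = rep + 1
                rows.append([d, src.role, src.peg_target, rep,
                             protein_id if src.role == "sample" else ""])
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "role", "peg_pct", "replicate", "protein_id"])
        writer.writerows(rows)
    return path
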