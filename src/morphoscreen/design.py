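"""Plate layout of the phenotypic-reversion screen.

The screen plates one 384-well plate per (knock-out sub-clone, compound
concentration) pair.  Each plate carries every library compound in one well,
plus vehicle-treated wild-type wells (the positive control / focus class),
vehicle-treated knock-out wells (the negative control) and a small number of
untreated knock-out wells.  Control wells are interleaved across the plate
rather than clustered at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PLATE_ROWS = 16
PLATE_COLS = 24

WT_VEHICLE = "VEHICLE"
KO_VEHICLE = "VEHICLE"
UNTREATED = "UNTREATED"

METADATA_COLUMNS = [
    "plate_id",
    "well",
    "subclone_id",
    "genotype",
    "treatment",
    "concentration_nM",
    "field",
]


class LayoutCapacityError(ValueError):
    """Raised when the requested wells do not fit on a 384-well plate."""


@dataclass(frozen=True)
class ScreenDesign:
    """Layout parameters of the screen.

    One plate is seeded per (sub-clone, concentration) pair, so
    ``n_plates = n_subclones * len(concentrations)``.
    """

    n_subclones: int = 3
    concentrations: tuple[float, ...] = (100.0, 300.0, 1000.0)
    n_compounds: int = 330
    wt_vehicle_wells_per_plate: int = 24
    ko_vehicle_wells_per_plate: int = 16
    ko_untreated_wells_per_plate: int = 6
    fields_per_well: int = 4
    plate_rows: int = PLATE_ROWS
    plate_cols: int = PLATE_COLS

    @property
    def n_plates(self) -> int:
        return self.n_subclones * len(self.concentrations)

    @property
    def n_control_wells_per_plate(self) -> int:
        return (
            self.wt_vehicle_wells_per_plate
            + self.ko_vehicle_wells_per_plate
            + self.ko_untreated_wells_per_plate
        )

    @property
    def wells_per_plate(self) -> int:
        return self.n_compounds + self.n_control_wells_per_plate

    @property
    def compound_ids(self) -> list[str]:
        return [f"C{i + 1:03d}" for i in range(self.n_compounds)]


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A01'-style coordinate."""
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def _interleave(counts: dict[str, int]) -> list[str]:
    """Deterministically interleave labels in proportion to their counts.

    Each label j of count c_j is given fractional positions (i+1)/(c_j+1);
    sorting those fractions yields a balanced, non-clustered ordering.
    """
    keyed = []
    for label, count in counts.items():
        for i in range(count):
            keyed.append(((i + 1) / (count + 1), label, i))
    keyed.sort()
    return [label for _, label, _ in keyed]


def build_design(
    n_subclones: int = 3,
    concentrations: tuple[float, ...] = (100.0, 300.0, 1000.0),
    n_compounds: int = 330,
    wt_vehicle_wells_per_plate: int = 24,
    ko_vehicle_wells_per_plate: int = 16,
    ko_untreated_wells_per_plate: int = 6,
    fields_per_well: int = 4,
) -> ScreenDesign:
    """Validate counts and return the screen design.

    Raises
    ------
    LayoutCapacityError
        If the occupied wells exceed the 384-well plate capacity.
    ValueError
        If any count is non-positive.
    """
    for name, value in [
        ("n_subclones", n_subclones),
        ("n_compounds", n_compounds),
        ("wt_vehicle_wells_per_plate", wt_vehicle_wells_per_plate),
        ("ko_vehicle_wells_per_plate", ko_vehicle_wells_per_plate),
        ("fields_per_well", fields_per_well),
    ]:
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")
    if ko_untreated_wells_per_plate < 0:
        raise ValueError("ko_untreated_wells_per_plate must be >= 0")
    if len(concentrations) == 0:
        raise ValueError("at least one concentration is required")

    design = ScreenDesign(
        n_subclones=n_subclones,
        concentrations=tuple(float(c) for c in concentrations),
        n_compounds=n_compounds,
        wt_vehicle_wells_per_plate=wt_vehicle_wells_per_plate,
        ko_vehicle_wells_per_plate=ko_vehicle_wells_per_plate,
        ko_untreated_wells_per_plate=ko_untreated_wells_per_plate,
        fields_per_well=fields_per_well,
    )
    capacity = design.plate_rows * design.plate_cols
    if design.wells_per_plate > capacity:
        raise LayoutCapacityError(
            f"{n_compounds} compound wells + {design.n_control_wells_per_plate} "
            f"control wells = {design.wells_per_plate} wells exceed the "
            f"{capacity}-well plate capacity"
        )
    return design


def plate_layout(design: ScreenDesign) -> pd.DataFrame:
    """Within-plate well assignment, identical on every plate.

    Returns a frame with columns well, genotype, treatment.  Control wells
    are interleaved among the compound wells in row-major plate order.
    """
    n_occ = design.wells_per_plate
    coords = [
        well_name(r, c)
        for r in range(design.plate_rows)
        for c in range(design.plate_cols)
    ][:n_occ]

    control_seq = _interleave(
        {
            "WT_VEHICLE": design.wt_vehicle_wells_per_plate,
            "KO_VEHICLE": design.ko_vehicle_wells_per_plate,
            "KO_UNTREATED": design.ko_untreated_wells_per_plate,
        }
    )
    n_controls = len(control_seq)
    # evenly spaced control positions among the occupied wells
    if n_controls:
        step = n_occ / n_controls
        control_pos = sorted({int(round(i * step + step / 2)) for i in range(n_controls)})
        # rounding collisions are resolved by shifting right
        while len(control_pos) < n_controls:
            for i in range(n_occ):
                if i not in control_pos:
                    control_pos.append(i)
                    break
            control_pos.sort()
        control_pos = control_pos[:n_controls]
    else:
        control_pos = []
    control_pos_set = set(control_pos)

    rows = []
    compound_iter = iter(design.compound_ids)
    control_iter = iter(control_seq)
    for idx, well in enumerate(coords):
        if idx in control_pos_set:
            kind = next(control_iter)
            if kind == "WT_VEHICLE":
                rows.append((well, "WT", WT_VEHICLE))
            elif kind == "KO_VEHICLE":
                rows.append((well, "KO", KO_VEHICLE))
            else:
                rows.append((well, "KO", UNTREATED))
        else:
            rows.append((well, "KO", next(compound_iter)))
    return pd.DataFrame(rows, columns=["well", "genotype", "treatment"])


def screen_layout(design: ScreenDesign) -> pd.DataFrame:
    """Full well-level layout across all plates.

    One plate per (sub-clone, concentration); columns plate_id, well,
    subclone_id, genotype, treatment, concentration_nM.  Vehicle and
    untreated wells carry concentration 0.
    """
    base = plate_layout(design)
    frames = []
    plate_no = 0
    for s in range(design.n_subclones):
        subclone = f"SC{s + 1}"
        for conc in design.concentrations:
            plate_no += 1
            plate = base.copy()
            plate.insert(0, "plate_id", f"P{plate_no:02d}")
            plate.insert(2, "subclone_id", subclone)
            is_compound = ~plate["treatment"].isin([WT_VEHICLE, UNTREATED])
            plate["concentration_nM"] = 0.0
            plate.loc[is_compound, "concentration_nM"] = conc
            frames.append(plate)
    out = pd.concat(frames, ignore_index=True)
    return out[["plate_id", "well", "subclone_id", "genotype", "treatment", "concentration_nM"]]
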