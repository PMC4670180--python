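"""Plate-map / measurement I/O and tidy-table joins for 96-well screens.

Schemas (CSV, long format):

* plate map:      plate_id, well_id, payload_type, payload_id, si_key,
                  sirna_ids, pooled
* measurements:   plate_id, well_id, arm, replicate, fi
* results:        written via :func:`write_results` with a stable column
                  order and 6-significant-digit floats.

Well IDs are row letter (A-H) plus zero-padded column ("B02"); the
96-well geometry is fixed. All readers accept gzip-compressed input
(pandas handles that transparently by extension).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

ROWS = "ABCDEFGH"
N_COLS = 12
_WELL_RE = re.compile(r"^([A-H])(0[1-9]|1[0-2])$")

MEASUREMENT_COLUMNS = ["plate_id", "well_id", "arm", "replicate", "fi"]
PLATEMAP_COLUMNS = [
    "plate_id",
    "well_id",
    "payload_type",
    "payload_id",
    "si_key",
    "sirna_ids",
    "pooled",
]


class SchemaError(ValueError):
    """A table is missing required columns or violates its schema."""


class QCError(ValueError):
    """A plate fails a structural quality-control requirement."""


def well_id(row: str, col: int) -> str:
    """Format a (row letter, 1-based column) pair as a canonical well ID."""
    if row not in ROWS or not 1 <= col <= N_COLS:
        raise ValueError(f"invalid well position ({row!r}, {col})")
    return f"{row}{col:02d}"


def parse_well(well: str) -> tuple[str, int]:
    """Parse "B02" into ("B", 2); reject anything outside A-H / 1-12."""
    m = _WELL_RE.match(well)
    if m is None:
        raise ValueError(f"malformed well id {well!r}")
    return m.group(1), int(m.group(2))


def is_edge_well(well: str) -> bool:
    row, col = parse_well(well)
    return row in ("A", "H") or col in (1, N_COLS)


def inner_wells(rows: str = "BCDEFG", cols: range = range(2, 12)) -> list[str]:
    """The library wells: rows B-G crossed with columns 2-11 (60 wells)."""
    return [well_id(r, c) for r in rows for c in cols]


def outer_wells() -> list[str]:
    """Border wells in deterministic order (row A, row H, then side columns)."""
    wells = [well_id("A", c) for c in range(1, N_COLS + 1)]
    wells += [well_id("H", c) for c in range(1, N_COLS + 1)]
    wells += [well_id(r, c) for r in "BCDEFG" for c in (1, N_COLS)]
    return wells


@dataclass
class SiRNALibrary:
    """An arrayed siRNA library: payload wells plus control wells.

    ``wells`` columns: gene_id, sirna_ids (semicolon-joined), plate_id,
    well_id, pooled (bool), si_key (payload selector used by the
    simulator: "pooled", "single:<i>", or "pair:<i>,<j>").
    ``controls`` columns: control_name, plate_id, well_id.
    """

    wells: pd.DataFrame
    controls: pd.DataFrame
    n_plates: int
    meta: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.wells["gene_id"]))

    @property
    def n_duplexes(self) -> int:
        return int(self.wells["sirna_ids"].str.count(";").sum() + len(self.wells))

    def platemap(self) -> pd.DataFrame:
        """Long-format plate map covering payload and control wells."""
        lib = self.wells.assign(payload_type="library", payload_id=self.wells["gene_id"])
        lib = lib[["plate_id", "well_id", "payload_type", "payload_id", "si_key",
                   "sirna_ids", "pooled"]]
        ctl = self.controls.assign(
            payload_type="control",
            payload_id=self.controls["control_name"],
            si_key="control",
            sirna_ids=self.controls["control_name"],
            pooled=False,
        )[["plate_id", "well_id", "payload_type", "payload_id", "si_key",
           "sirna_ids", "pooled"]]
        # unassigned wells carry untransfected cells: measured, not analyzed
        all_wells = [well_id(r, c) for r in ROWS for c in range(1, N_COLS + 1)]
        taken = {(p, w) for p, w in
                 zip(pd.concat([lib, ctl]).plate_id, pd.concat([lib, ctl]).well_id)}
        plates = sorted(set(lib["plate_id"]) | set(ctl["plate_id"]))
        empty = pd.DataFrame(
            [{"plate_id": p, "well_id": w, "payload_type": "empty",
              "payload_id": "", "si_key": "empty", "sirna_ids": "",
              "pooled": False}
             for p in plates for w in all_wells if (p, w) not in taken])
        out = pd.concat([lib, ctl, empty], ignore_index=True)
        return out.sort_values(["plate_id", "well_id"], kind="stable").reset_index(drop=True)


def library_from_platemap(platemap: pd.DataFrame) -> SiRNALibrary:
    """Rebuild a :class:`SiRNALibrary` from a long-format plate map."""
    _require_columns(platemap, PLATEMAP_COLUMNS, "plate map")
    lib = platemap[platemap["payload_type"] == "library"]
    ctl = platemap[platemap["payload_type"] == "control"]
    wells = lib.rename(columns={"payload_id": "gene_id"})[
        ["gene_id", "sirna_ids", "plate_id", "well_id", "pooled", "si_key"]
    ].reset_index(drop=True)
    controls = ctl.rename(columns={"payload_id": "control_name"})[
        ["control_name", "plate_id", "well_id"]
    ].reset_index(drop=True)
    return SiRNALibrary(wells=wells, controls=controls,
                        n_plates=int(platemap["plate_id"].nunique()))


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {', '.join(missing)}")


def validate_measurements(df: pd.DataFrame) -> None:
    _require_columns(df, MEASUREMENT_COLUMNS, "measurement table")
    if (df["fi"] <= 0).any():
        bad = df.loc[df["fi"] <= 0].head(3)
        raise SchemaError(f"non-positive FI values found, e.g.:\n{bad}")
    for w in df["well_id"].unique():
        parse_well(w)
    dup = df.duplicated(subset=["plate_id", "well_id", "arm", "replicate"])
    if dup.any():
        raise SchemaError(
            f"{int(dup.sum())} duplicate (plate, well, arm, replicate) rows"
        )


def read_screen(platemap_path, measurements_path) -> pd.DataFrame:
    """Join a plate map with its measurement table into one tidy table.

    Returns the inner join on (plate_id, well_id). Measured wells that
    lack annotation are attached to ``result.attrs["orphans"]``; a plate
    referenced by measurements but absent from the map raises, as does a
    plate with fewer than 2 GL2 wells.
    """
    platemap = pd.read_csv(platemap_path)
    meas = pd.read_csv(measurements_path)
    _require_columns(platemap, PLATEMAP_COLUMNS, "plate map")
    validate_measurements(meas)

    unknown_plates = set(meas["plate_id"]) - set(platemap["plate_id"])
    if unknown_plates:
        raise SchemaError(
            "measurements reference unknown plate(s): "
            + ", ".join(str(p) for p in sorted(unknown_plates))
        )
    gl2 = platemap[(platemap["payload_type"] == "control")
                   & (platemap["payload_id"] == "GL2")]
    for plate, grp in platemap.groupby("plate_id"):
        n_gl2 = len(gl2[gl2["plate_id"] == plate])
        if n_gl2 < 2:
            raise QCError(f"plate {plate} has {n_gl2} GL2 wells (need >= 2)")

    joined = meas.merge(platemap, on=["plate_id", "well_id"], how="left")
    orphans = joined[joined["payload_type"].isna()]
    joined = joined.dropna(subset=["payload_type"]).reset_index(drop=True)
    joined.attrs["orphans"] = orphans.reset_index(drop=True)
    return joined


def write_results(table: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a result table deterministically: stable column order, sorted
    rows, floats at 6 significant digits."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    sort_cols = [c for c in ("gene_id", "sirna_id", "plate_id", "well_id",
                             "arm", "replicate") if c in table.columns]
    out = table.sort_values(sort_cols, kind="stable") if sort_cols else table
    out.to_csv(path, sep="," if format == "csv" else "\t", index=False,
               float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).rstrip(".gz").endswith(".tsv") else ","
    return pd.read_csv(path, sep=sep)
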