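"""Core domain types and text readers/writers.

Formats owned by this module:

* plate layout tables (delimited text; one row per well),
* per-field count tables (delimited text),
* dose-response and growth-curve tables (delimited text, via pandas),
* GMT gene-set collections,
* genes-by-samples expression matrices with a one-line phenotype sidecar.

Comma vs tab delimiters are auto-detected from the file extension
(``.csv`` -> comma, everything else -> tab).
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LayoutError",
    "ParseError",
    "DuplicateRecordError",
    "WellRole",
    "PlateLayout",
    "WellRecord",
    "GeneSetCollection",
    "ExpressionMatrix",
    "normalize_well_address",
    "well_row_col",
    "read_plate_layouts",
    "write_plate_layouts",
    "read_plate_counts",
    "write_plate_counts",
    "read_gene_sets",
    "write_gene_sets",
    "read_expression",
    "write_expression",
    "read_table",
    "write_table",
]


class LayoutError(ValueError):
    """A well address or role is inconsistent with the plate layout."""


class ParseError(ValueError):
    """A text file could not be parsed; message carries the line number."""


class DuplicateRecordError(ValueError):
    """The same (plate, well, channel, field) key occurred twice."""


_CHANNEL_SYNONYMS = {
    "green": "green",
    "gfp": "green",
    "red": "red",
    "mcherry": "red",
}

_WELL_RE = re.compile(r"^([A-Za-z])([0-9]{1,2})$")


def normalize_well_address(address: str) -> str:
    """Normalize a well address to row-letter + zero-padded column ("A01").

    Accepts unpadded input ("A1") and lowercase row letters.
    """
    m = _WELL_RE.match(address.strip())
    if m is None or int(m.group(2)) == 0:
        raise LayoutError(f"malformed well address: {address!r}")
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


def well_row_col(address: str) -> tuple[int, int]:
    """Return 0-based row index and 1-based column number for an address."""
    norm = normalize_well_address(address)
    return string.ascii_uppercase.index(norm[0]), int(norm[1:])


def normalize_channel(label: str) -> str:
    try:
        return _CHANNEL_SYNONYMS[label.strip().lower()]
    except KeyError:
        raise ParseError(
            f"unknown channel label {label!r}; expected one of "
            f"{sorted(_CHANNEL_SYNONYMS)}"
        ) from None


@dataclass(frozen=True)
class WellRole:
    """Role of one well on a plate.

    ``kind`` is one of ``compound``, ``vehicle``, ``positive_control``,
    ``empty``.  Compound wells carry a compound identifier and a
    concentration; vehicle wells carry neither.
    """

    kind: str
    compound_id: str | None = None
    concentration: float | None = None
    concentration_unit: str = "nM"

    _KINDS = frozenset({"compound", "vehicle", "positive_control", "empty"})

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise LayoutError(f"unknown well kind {self.kind!r}")
        if self.kind == "compound":
            if not self.compound_id or self.concentration is None:
                raise LayoutError(
                    "compound wells require compound_id and concentration"
                )
        if self.kind == "vehicle":
            if self.compound_id is not None or self.concentration is not None:
                raise LayoutError("vehicle wells must not carry a compound")


@dataclass
class PlateLayout:
    """Map from well address to :class:`WellRole` for one plate.

    Default geometry is a 96-well plate (rows A-H, columns 1-12).
    """

    plate_id: str
    wells: dict[str, WellRole] = field(default_factory=dict)
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self) -> None:
        self.wells = {
            normalize_well_address(a): r for a, r in self.wells.items()
        }
        self.validate()

    def validate(self) -> None:
        for address in self.wells:
            self._check_geometry(address)
        if not any(r.kind == "vehicle" for r in self.wells.values()):
            raise LayoutError(
                f"plate {self.plate_id}: at least one vehicle well required"
            )

    def _check_geometry(self, address: str) -> None:
        row, col = well_row_col(address)
        if row >= self.n_rows or col > self.n_cols:
            raise LayoutError(
                f"plate {self.plate_id}: well {address} outside "
                f"{self.n_rows}x{self.n_cols} geometry"
            )

    def wells_of_kind(self, kind: str) -> list[str]:
        return sorted(a for a, r in self.wells.items() if r.kind == kind)

    def role(self, address: str) -> WellRole:
        return self.wells[normalize_well_address(address)]


@dataclass(frozen=True)
class WellRecord:
    """One per-field, per-channel cell count."""

    plate_id: str
    well: str
    channel: str
    field_index: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ParseError(f"negative count {self.count} in well {self.well}")
        if self.field_index < 1:
            raise ParseError(f"field index must be >= 1, got {self.field_index}")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.plate_id, self.well, self.channel, self.field_index)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. a hallmark collection)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if len(genes) < 1:
                raise ParseError(f"gene set {set_name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ParseError(f"gene set {set_name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class ExpressionMatrix:
    """Genes-by-samples real matrix with a binary phenotype per sample."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    phenotype: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.samples if s not in self.phenotype]
        if missing:
            raise ValueError(f"samples without phenotype label: {missing}")
        classes: dict[str, int] = {}
        for s in self.samples:
            classes[self.phenotype[s]] = classes.get(self.phenotype[s], 0) + 1
        for cls, n in classes.items():
            if n < 2:
                raise ValueError(f"phenotype class {cls!r} has < 2 samples")

    @property
    def classes(self) -> list[str]:
        return sorted({self.phenotype[s] for s in self.samples})

    def class_mask(self, cls: str) -> np.ndarray:
        return np.array([self.phenotype[s] == cls for s in self.samples])


# ---------------------------------------------------------------------------
# delimited-text helpers


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a delimited table, checking for required columns."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# plate layouts


def write_plate_layouts(layouts: Iterable[PlateLayout], path: str | Path) -> None:
    rows = []
    for layout in layouts:
        for address in sorted(layout.wells):
            role = layout.wells[address]
            rows.append(
                {
                    "plate_id": layout.plate_id,
                    "well": address,
                    "kind": role.kind,
                    "compound_id": role.compound_id or "",
                    "concentration": (
                        "" if role.concentration is None else role.concentration
                    ),
                    "concentration_unit": role.concentration_unit,
                    "n_rows": layout.n_rows,
                    "n_cols": layout.n_cols,
                }
            )
    write_table(pd.DataFrame(rows), path)


def read_plate_layouts(path: str | Path) -> list[PlateLayout]:
    df = read_table(path, required=["plate_id", "well", "kind"])
    layouts = []
    for plate_id, group in df.groupby("plate_id", sort=True):
        wells = {}
        n_rows, n_cols = 8, 12
        for _, row in group.iterrows():
            if "n_rows" in group.columns and not pd.isna(row["n_rows"]):
                n_rows, n_cols = int(row["n_rows"]), int(row["n_cols"])
            compound = row.get("compound_id")
            compound = None if pd.isna(compound) or compound == "" else str(compound)
            conc = row.get("concentration")
            conc = None if conc is None or pd.isna(conc) or conc == "" else float(conc)
            unit = row.get("concentration_unit", "nM")
            unit = "nM" if pd.isna(unit) else str(unit)
            wells[str(row["well"])] = WellRole(
                kind=str(row["kind"]),
                compound_id=compound,
                concentration=conc,
                concentration_unit=unit,
            )
        layouts.append(
            PlateLayout(str(plate_id), wells, n_rows=n_rows, n_cols=n_cols)
        )
    return layouts


# ---------------------------------------------------------------------------
# per-field counts


def read_plate_counts(
    path: str | Path,
    layout: PlateLayout | Mapping[str, PlateLayout],
) -> list[WellRecord]:
    """Read a per-field count table and validate it against plate layouts.

    ``layout`` is a single :class:`PlateLayout` or a mapping plate_id ->
    layout.  Channel labels are normalized (GFP -> green, mCherry -> red).

    Raises
    ------
    LayoutError
        For a well address not present in the layout.
    ParseError
        For a negative or non-integer count (message names the line).
    DuplicateRecordError
        When a (plate, well, channel, field) key repeats.
    """
    layouts: Mapping[str, PlateLayout]
    if isinstance(layout, PlateLayout):
        layouts = {layout.plate_id: layout}
    else:
        layouts = layout

    sep = _sep_for(path)
    records: list[WellRecord] = []
    seen: set[tuple[str, str, str, int]] = set()
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if header is None:
                header = [h.strip() for h in parts]
                required = {"plate_id", "well", "channel", "field", "count"}
                if not required.issubset(header):
                    raise ParseError(
                        f"{path}: header missing {sorted(required - set(header))}"
                    )
                idx = {name: header.index(name) for name in required}
                continue
            plate_id = parts[idx["plate_id"]].strip()
            if plate_id not in layouts:
                raise LayoutError(f"line {lineno}: unknown plate {plate_id!r}")
            plate_layout = layouts[plate_id]
            well = normalize_well_address(parts[idx["well"]])
            if well not in plate_layout.wells:
                raise LayoutError(
                    f"line {lineno}: well {well} not in layout of plate {plate_id}"
                )
            channel = normalize_channel(parts[idx["channel"]])
            try:
                field_index = int(parts[idx["field"]])
                raw_count = parts[idx["count"]].strip()
                count = int(raw_count)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-integer field/count in {line!r}"
                ) from None
            if count < 0:
                raise ParseError(f"line {lineno}: negative count {count}")
            record = WellRecord(plate_id, well, channel, field_index, count)
            if record.key in seen:
                raise DuplicateRecordError(
                    f"line {lineno}: duplicate record key {record.key}"
                )
            seen.add(record.key)
            records.append(record)
    return records


def write_plate_counts(records: Iterable[WellRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "plate_id": r.plate_id,
                "well": r.well,
                "channel": r.channel,
                "field": r.field_index,
                "count": r.count,
            }
            for r in records
        ]
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path, name: str = "") -> GeneSetCollection:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ...

    Duplicate genes within one set are collapsed with a logged warning.
    An empty file yields an empty collection.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path} line {lineno}: GMT lines need >= 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            set_name = parts[0]
            genes: list[str] = []
            seen_genes: set[str] = set()
            for g in parts[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen_genes:
                    logger.warning(
                        "gene set %s: duplicate gene %s collapsed", set_name, g
                    )
                    continue
                seen_genes.add(g)
                genes.append(g)
            sets[set_name] = genes
    return GeneSetCollection(sets, name=name or Path(path).stem)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for set_name, genes in collection:
            fh.write("\t".join([set_name, collection.name or "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# expression matrix + phenotype sidecar


def read_expression(
    matrix_path: str | Path, phenotype_path: str | Path
) -> ExpressionMatrix:
    """Read a genes-by-samples matrix and its one-line phenotype sidecar.

    The sidecar's single non-comment line holds whitespace-separated class
    labels, one per sample, in matrix column order.
    """
    df = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    labels: list[str] = []
    with open(phenotype_path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                labels = line.split()
                break
    samples = [str(s) for s in df.columns]
    if len(labels) != len(samples):
        raise ParseError(
            f"{phenotype_path}: {len(labels)} labels for {len(samples)} samples"
        )
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=samples,
        values=df.to_numpy(dtype=float),
        phenotype=dict(zip(samples, labels)),
    )


def write_expression(
    matrix: ExpressionMatrix, matrix_path: str | Path, phenotype_path: str | Path
) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.samples)
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(matrix_path, sep=_sep_for(matrix_path), index_label="gene")
    with open(phenotype_path, "w") as fh:
        fh.write("# phenotype labels, one per sample in matrix column order\n")
        fh.write(" ".join(matrix.phenotype[s] for s in matrix.samples) + "\n")
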