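"""Morphometric ratio indices, comparative range tables, and dichotomous keys.

Nematode taxonomy summarizes raw micrometer measurements into the classical
de Man-style ratio indices (a = L/BD, b = L/NL, c = L/T, c' = T/ABD,
V = VA/L x 100) plus the genus-specific derived percentages (D% = EP/PL x 100,
E% = EP/T x 100, SW% = SL/ABD x 100, GS% = GL/SL x 100, H% = H/T x 100, ...).
Species hypotheses are then screened against compiled per-species,
per-life-stage range tables and a dichotomous identification key.

Range membership uses closed intervals: printed range endpoints are attained
values. D% is EP/PL x 100 throughout; one published table labels the row
EP/NL x 100 but its printed values are EP/PL, and the packaged fixtures
document that correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import MorphometricsError

STAGES = ("male", "hermaphrodite", "female", "IJ")

#: index code -> (numerator character, denominator character, scale factor)
INDEX_DEFINITIONS: dict[str, tuple[str, str, float]] = {
    "a": ("L", "BD", 1.0),
    "b": ("L", "NL", 1.0),
    "c": ("L", "T", 1.0),
    "c_prime": ("T", "ABD", 1.0),
    "V": ("VA", "L", 100.0),
    "D_pct": ("EP", "PL", 100.0),
    "E_pct": ("EP", "T", 100.0),
    "SW_pct": ("SL", "ABD", 100.0),
    "GS_pct": ("GL", "SL", 100.0),
    "H_pct": ("H", "T", 100.0),
    "NR_pct": ("NR", "NL", 100.0),
    "EP_pct": ("EP", "NL", 100.0),
    "rectum_pct": ("R", "ABD", 100.0),
    "stoma_lip": ("stoma", "lip", 1.0),
}


@dataclass
class MorphometricRecord:
    """One specimen: raw characters in micrometers plus derived ratio indices."""

    specimen_id: str
    stage: str
    characters: dict[str, float]
    derived: dict[str, float] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise MorphometricsError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        bad = {k: v for k, v in self.characters.items() if v is not None and v < 0}
        if bad:
            raise MorphometricsError(f"negative raw characters: {bad}")


def compute_indices(
    record: MorphometricRecord,
    indices: Mapping[str, tuple[str, str, float]] = INDEX_DEFINITIONS,
) -> MorphometricRecord:
    """Fill the derived index map for every index whose operands are present.

    A zero-valued denominator is recorded as a per-index error; the remaining
    indices are still computed. Values are kept at full precision — rounding
    to the conventional printed precision happens only at reporting time.
    """
    derived = dict(record.derived)
    errors = dict(record.errors)
    for code, (num, den, scale) in indices.items():
        if num not in record.characters or den not in record.characters:
            continue
        denominator = record.characters[den]
        if denominator == 0:
            errors[code] = f"division by zero-valued {den}"
            continue
        derived[code] = scale * record.characters[num] / denominator
    return replace(record, derived=derived, errors=errors)


def read_measurements(path: str | Path, stage_column: str = "stage") -> list[MorphometricRecord]:
    """Read specimens from delimited text: one row each, columns = character codes."""
    table = pd.read_csv(path, sep="\t")
    records = []
    for _, row in table.iterrows():
        characters = {}
        for col in table.columns:
            if col in ("specimen_id", stage_column, "species", "population") or pd.isna(row[col]):
                continue
            try:
                characters[col] = float(row[col])
            except (TypeError, ValueError):
                continue  # non-numeric metadata column
        records.append(
            MorphometricRecord(
                specimen_id=str(row["specimen_id"]),
                stage=str(row[stage_column]),
                characters=characters,
            )
        )
    return records


# ---------------------------------------------------------------------------
# comparative range tables


def _parse_cell(cell: str) -> tuple[float | None, float | None, str]:
    """Parse one printed table cell into (min, max, note).

    Handles 'lo-hi' ranges, single values (stored degenerate, min == max),
    computed-value markers (* and **, recorded in the note), 'NA' for missing
    cells, and the handful of typeset intervals printed with min > max (swapped
    and flagged).
    """
    cell = str(cell).strip()
    if cell in ("", "NA", "nan", "-"):
        return None, None, ""
    note = ""
    while cell.endswith("*"):
        cell = cell[:-1]
        note = "computed-from-mean" if not note else note
    parts = cell.split("-")
    # rejoin decimals like '1.0-3.4' handled fine; negative values never occur
    if len(parts) == 1:
        value = float(parts[0])
        return value, value, note
    lo, hi = float(parts[0]), float(parts[1])
    if lo > hi:
        lo, hi = hi, lo
        note = (note + ";" if note else "") + "printed-interval-inverted"
    return lo, hi, note


_STAGE_FILES = {
    "male": "ranges_males.tsv",
    "hermaphrodite": "ranges_hermaphrodites.tsv",
    "female": "ranges_females.tsv",
    "IJ": "ranges_infective_juveniles.tsv",
}

_META_COLUMNS = {"species", "listed_as", "country", "reference"}


class RangeTable:
    """Species x stage x character -> closed (min, max) intervals with provenance.

    Long-format frame with columns: species, listed_as (synonym name under
    which a row was originally published), stage, character, min, max, note,
    country, reference. A species may contribute several rows per stage (one
    per published description); each row keeps its own identity.
    """

    def __init__(self, frame: pd.DataFrame, inventory: pd.DataFrame | None = None):
        self.frame = frame
        # one row per published description, including descriptions whose
        # printed cells are all missing (they still occupy a table row)
        self.inventory = (
            inventory
            if inventory is not None
            else frame[["species", "listed_as", "stage", "reference"]].drop_duplicates()
        )

    def stages(self) -> list[str]:
        return sorted(self.inventory["stage"].unique())

    def n_rows(self, stage: str) -> int:
        """Number of printed table rows (species descriptions) for a stage."""
        return int((self.inventory["stage"] == stage).sum())

    def species(self, stage: str) -> list[str]:
        return sorted(self.frame.loc[self.frame["stage"] == stage, "species"].unique())

    def interval(self, species: str, stage: str, character: str) -> tuple[float, float]:
        """The (min, max) for a species' primary row (first matching description)."""
        sub = self.frame[
            (self.frame["species"] == species)
            & (self.frame["stage"] == stage)
            & (self.frame["character"] == character)
        ]
        if sub.empty:
            raise KeyError((species, stage, character))
        row = sub.iloc[0]
        return float(row["min"]), float(row["max"])


def load_reference_tables(directory: str | Path | None = None) -> RangeTable:
    """Load the packaged comparative morphometric tables for all four stages."""
    frames = []
    inventory = []
    for stage, filename in _STAGE_FILES.items():
        if directory is not None:
            raw = pd.read_csv(Path(directory) / filename, sep="\t", dtype=str)
        else:
            source = resources.files("nemadelim.data").joinpath(filename)
            with resources.as_file(source) as fp:
                raw = pd.read_csv(fp, sep="\t", dtype=str)
        characters = [c for c in raw.columns if c not in _META_COLUMNS]
        for idx, row in raw.iterrows():
            inventory.append(
                {
                    "species": row["species"],
                    "listed_as": row.get("listed_as") or row["species"],
                    "stage": stage,
                    "reference": row.get("reference", ""),
                }
            )
            for char in characters:
                try:
                    lo, hi, note = _parse_cell(row[char])
                except (ValueError, TypeError) as exc:
                    raise MorphometricsError(
                        f"{filename} row {idx + 2} ({row['species']}), column {char}: "
                        f"unparseable cell {row[char]!r}"
                    ) from exc
                if lo is None:
                    continue
                frames.append(
                    {
                        "species": row["species"],
                        "listed_as": row.get("listed_as") or row["species"],
                        "stage": stage,
                        "character": char,
                        "min": lo,
                        "max": hi,
                        "note": note,
                        "country": row.get("country", ""),
                        "reference": row.get("reference", ""),
                    }
                )
    return RangeTable(pd.DataFrame(frames), inventory=pd.DataFrame(inventory))


@dataclass
class SpeciesVerdict:
    """Per-description comparison outcome for one candidate species row."""

    species: str
    listed_as: str
    reference: str
    inside: dict[str, bool]
    skipped: list[str]

    @property
    def consistent(self) -> bool:
        return all(self.inside.values())


@dataclass
class DiscriminationReport:
    """compare_to_ranges output: row-level verdicts plus species-level summary.

    A species is *excluded* when at least one measured character falls outside
    the range in every one of its published descriptions; it is *consistent*
    when at least one description admits all measured characters.
    """

    record_id: str
    stage: str
    verdicts: list[SpeciesVerdict]

    def species_status(self) -> dict[str, str]:
        status: dict[str, str] = {}
        for verdict in self.verdicts:
            if verdict.consistent:
                status[verdict.species] = "consistent"
            else:
                status.setdefault(verdict.species, "excluded")
        return status

    def consistent_species(self) -> list[str]:
        return sorted(s for s, v in self.species_status().items() if v == "consistent")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            for char, ok in v.inside.items():
                rows.append(
                    {
                        "species": v.species, "listed_as": v.listed_as,
                        "reference": v.reference, "character": char,
                        "inside": ok,
                    }
                )
        return pd.DataFrame(rows)


def compare_to_ranges(record: MorphometricRecord, table: RangeTable) -> DiscriminationReport:
    """Compare a specimen's characters and indices against all candidate species.

    Uses closed intervals. Characters present in the record but absent from a
    species row (or vice versa) are skipped and listed per row.
    """
    sub = table.frame[table.frame["stage"] == record.stage]
    if sub.empty:
        raise MorphometricsError(f"range table has no rows for stage {record.stage!r}")
    measured = {**record.characters, **record.derived}
    verdicts = []
    for (species, listed_as, reference), grp in sub.groupby(
        ["species", "listed_as", "reference"], sort=True
    ):
        ranged = {row["character"]: (row["min"], row["max"]) for _, row in grp.iterrows()}
        inside = {
            char: lo <= measured[char] <= hi
            for char, (lo, hi) in ranged.items()
            if char in measured
        }
        verdicts.append(
            SpeciesVerdict(
                species=species, listed_as=listed_as, reference=reference,
                inside=inside,
                skipped=sorted((set(ranged) - set(measured)) | (set(measured) - set(ranged))),
            )
        )
    return DiscriminationReport(record.specimen_id, record.stage, verdicts)


# ---------------------------------------------------------------------------
# dichotomous keys


@dataclass
class KeyResult:
    species: str | None
    path: list[tuple[str, str, bool]]  # (character, predicate text, outcome)
    missing_character: str | None = None

    @property
    def indeterminate(self) -> bool:
        return self.species is None


class KeySpec:
    """A dichotomous identification key as an explicit decision tree.

    Internal nodes compare one character or index against a constant with a
    declared boundary side ('lt', 'le', 'gt' or 'ge' — each node states which
    side an exact tie falls on); leaves name species. Keys are shipped as
    editable JSON data, and this class is a generic interpreter.
    """

    _OPS = {
        "lt": (lambda v, t: v < t, "<"),
        "le": (lambda v, t: v <= t, "<="),
        "gt": (lambda v, t: v > t, ">"),
        "ge": (lambda v, t: v >= t, ">="),
    }

    def __init__(self, tree: dict, name: str = ""):
        self.tree = tree
        self.name = name
        self._validate(tree)

    @classmethod
    def from_json(cls, path: str | Path) -> "KeySpec":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["root"], name=payload.get("name", ""))

    @classmethod
    def packaged(cls, filename: str = "key_bacteriophora_group.json") -> "KeySpec":
        source = resources.files("nemadelim.data").joinpath(filename)
        with resources.as_file(source) as fp:
            return cls.from_json(fp)

    def _validate(self, node: dict) -> None:
        if "species" in node:
            return
        for required in ("character", "op", "threshold", "if_true", "if_false"):
            if required not in node:
                raise MorphometricsError(f"key node missing field {required!r}: {node}")
        if node["op"] not in self._OPS:
            raise MorphometricsError(f"key node op must declare a boundary side: {node['op']!r}")
        self._validate(node["if_true"])
        self._validate(node["if_false"])


def run_key(record: MorphometricRecord, key: KeySpec) -> KeyResult:
    """Deterministic traversal of a key; indeterminate if a path character is absent."""
    measured = {**record.characters, **record.derived}
    node = key.tree
    path: list[tuple[str, str, bool]] = []
    while "species" not in node:
        char = node["character"]
        if char not in measured:
            return KeyResult(species=None, path=path, missing_character=char)
        test, symbol = KeySpec._OPS[node["op"]]
        outcome = test(measured[char], node["threshold"])
        path.append((char, f"{char} {symbol} {node['threshold']}", outcome))
        node = node["if_true"] if outcome else node["if_false"]
    return KeyResult(species=node["species"], path=path)


def summary_statistics(records: list[MorphometricRecord]) -> pd.DataFrame:
    """Population mean +/- sd (range) per character; descriptive only, never
    used for exclusion decisions."""
    rows = []
    characters = sorted({c for r in records for c in {**r.characters, **r.derived}})
    for char in characters:
        values = [
            {**r.characters, **r.derived}[char]
            for r in records
            if char in r.characters or char in r.derived
        ]
        series = pd.Series(values, dtype=float)
        rows.append(
            {
                "character": char, "n": len(values), "mean": series.mean(),
                "sd": series.std(ddof=1) if len(values) > 1 else 0.0,
                "min": series.min(), "max": series.max(),
            }
        )
    return pd.DataFrame(rows)
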