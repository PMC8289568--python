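"""Domain containers and CSV I/O for exposure, guideline, and toxicity data.

Three tables drive a tiered sediment risk assessment:

* :class:`ExposureTable` — station-by-element mean concentrations (with
  optional replicate standard deviations) from a sediment survey;
* :class:`GuidelineSet` — low/high sediment-quality trigger values per
  element (e.g. the Australian interim sediment quality guidelines,
  ISQG-Low / ISQG-High);
* :class:`ToxicityDataset` — per-species sediment toxicity endpoints for a
  single element, the input to a species sensitivity distribution (SSD).

CSV dialect: comma-separated, header row, period decimal separator, UTF-8.
All concentrations are strictly positive mass fractions on a dry-weight
basis.  The canonical internal unit is mg/kg; see :mod:`sedrisk.units`.
"""

from __future__ import annotations

import importlib.resources
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .units import CANONICAL_UNIT, check_unit, convert_units

__all__ = [
    "ExposureTable",
    "GuidelineSet",
    "ToxicityDataset",
    "GuidelineWarning",
    "DataError",
    "read_exposure_table",
    "write_exposure_table",
    "read_guidelines",
    "write_guidelines",
    "read_toxicity",
    "write_toxicity",
    "load_wami_exposure",
    "load_isqg_guidelines",
]

#: Element symbols given canonical capitalisation on input.
KNOWN_ELEMENTS = ("As", "Cd", "Cr", "Cu", "Pb", "Zn")
_CANONICAL_CASE = {e.lower(): e for e in KNOWN_ELEMENTS}


class DataError(ValueError):
    """Raised for malformed or invalid input tables."""


class GuidelineWarning(UserWarning):
    """Warns about anomalous guideline rows (e.g. high trigger <= low)."""


def normalize_element(symbol: str) -> str:
    """Case-normalise known element symbols; unknown symbols pass through."""
    return _CANONICAL_CASE.get(symbol.strip().lower(), symbol.strip())


@dataclass(frozen=True)
class ExposureTable:
    """Station x element concentration matrix with optional replicate SDs.

    ``mean`` is indexed by station (order preserved from the source) with one
    column per element; ``sd`` shares the layout or is ``None``.  All means
    are strictly positive, all SDs non-negative, every cell populated.
    """

    mean: pd.DataFrame
    sd: pd.DataFrame | None = None
    unit: str = CANONICAL_UNIT

    def __post_init__(self) -> None:
        check_unit(self.unit)
        if self.mean.empty:
            raise DataError("exposure table has no data")
        bad = self.mean.isna() | (self.mean <= 0)
        if bad.any().any():
            station, element = _first_bad_cell(bad)
            raise DataError(
                f"non-positive or missing concentration at station {station!r}, "
                f"element {element!r}"
            )
        if self.sd is not None:
            if list(self.sd.index) != list(self.mean.index) or list(
                self.sd.columns
            ) != list(self.mean.columns):
                raise DataError("sd table layout does not match mean table")
            badsd = self.sd.isna() | (self.sd < 0)
            if badsd.any().any():
                station, element = _first_bad_cell(badsd)
                raise DataError(
                    f"negative or missing SD at station {station!r}, element {element!r}"
                )

    @property
    def stations(self) -> list:
        return list(self.mean.index)

    @property
    def elements(self) -> list[str]:
        return list(self.mean.columns)

    def column(self, element: str) -> np.ndarray:
        """Station means for one element, in table order."""
        element = normalize_element(element)
        if element not in self.mean.columns:
            raise KeyError(f"element {element!r} not in table")
        return self.mean[element].to_numpy(dtype=float)

    def to_unit(self, unit: str) -> "ExposureTable":
        if unit == self.unit:
            return self
        mean = convert_units(self.mean, self.unit, unit)
        sd = None if self.sd is None else convert_units(self.sd, self.unit, unit)
        return ExposureTable(mean=mean, sd=sd, unit=unit)


def _first_bad_cell(mask: pd.DataFrame) -> tuple:
    rows, cols = np.nonzero(mask.to_numpy())
    return mask.index[rows[0]], mask.columns[cols[0]]


@dataclass(frozen=True)
class GuidelineSet:
    """Low/high trigger concentrations per element.

    ``table`` is indexed by element with ``low`` and ``high`` columns.
    ``warnings`` records anomalies found on load (a high trigger not above
    the low one is kept as printed but flagged, never silently corrected).
    """

    table: pd.DataFrame
    unit: str = CANONICAL_UNIT
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        check_unit(self.unit)
        if self.table.empty:
            raise DataError("guideline set is empty")
        for col in ("low", "high"):
            if col not in self.table.columns:
                raise DataError(f"guideline table missing {col!r} column")
            vals = self.table[col]
            if vals.isna().any() or (vals <= 0).any():
                el = self.table.index[(vals.isna() | (vals <= 0)).to_numpy()][0]
                raise DataError(f"element {el!r} has a missing or non-positive {col} trigger")

    @property
    def elements(self) -> list[str]:
        return list(self.table.index)

    def low(self, element: str) -> float:
        return float(self.table.loc[normalize_element(element), "low"])

    def high(self, element: str) -> float:
        return float(self.table.loc[normalize_element(element), "high"])

    def to_unit(self, unit: str) -> "GuidelineSet":
        if unit == self.unit:
            return self
        return GuidelineSet(
            table=convert_units(self.table, self.unit, unit),
            unit=unit,
            warnings=self.warnings,
        )


@dataclass(frozen=True)
class ToxicityDataset:
    """Per-species toxicity endpoints for one element (SSD input).

    ``records`` holds one endpoint concentration per species in the declared
    unit; ``species`` and ``endpoint`` are optional parallel labels.
    At least 3 records are required for any distribution fitting.
    """

    element: str
    concentrations: np.ndarray
    species: tuple[str, ...] | None = None
    endpoints: tuple[str, ...] | None = None
    unit: str = CANONICAL_UNIT

    def __post_init__(self) -> None:
        check_unit(self.unit)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        if conc.size == 0:
            raise DataError("toxicity dataset has no records")
        if np.any(~np.isfinite(conc)) or np.any(conc <= 0):
            i = int(np.flatnonzero(~np.isfinite(conc) | (conc <= 0))[0])
            raise DataError(f"non-positive endpoint concentration in record {i}")
        for labels, name in ((self.species, "species"), (self.endpoints, "endpoints")):
            if labels is not None and len(labels) != conc.size:
                raise DataError(f"{name} labels do not match record count")

    def __len__(self) -> int:
        return int(self.concentrations.size)

    def to_unit(self, unit: str) -> "ToxicityDataset":
        if unit == self.unit:
            return self
        return ToxicityDataset(
            element=self.element,
            concentrations=convert_units(self.concentrations, self.unit, unit),
            species=self.species,
            endpoints=self.endpoints,
            unit=unit,
        )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_csv(source) -> pd.DataFrame:
    # round_trip parsing so write-then-read reproduces values bit-exactly
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return pd.read_csv(source, float_precision="round_trip")
    return pd.read_csv(io.StringIO(str(source)), float_precision="round_trip")


def read_exposure_table(source, unit: str = CANONICAL_UNIT) -> ExposureTable:
    """Read a station-by-element exposure CSV.

    Expected columns: ``station`` plus ``<El>_mean`` (and optionally
    ``<El>_sd``) per element.  Values are interpreted in ``unit``.
    """
    check_unit(unit)
    df = _read_csv(source)
    if "station" not in df.columns:
        raise DataError("exposure CSV must have a 'station' column")
    df = df.set_index("station")
    mean_cols = [c for c in df.columns if c.endswith("_mean")]
    if not mean_cols:
        raise DataError("exposure CSV has no '<element>_mean' columns")
    elements = [normalize_element(c[: -len("_mean")]) for c in mean_cols]
    mean = df[mean_cols].copy()
    mean.columns = elements
    sd_cols = {c[: -len("_sd")]: c for c in df.columns if c.endswith("_sd")}
    sd = None
    if sd_cols:
        missing = [e for e in elements if normalize_element(e) not in
                   {normalize_element(k) for k in sd_cols}]
        if missing:
            raise DataError(f"SD columns present but missing for element(s) {missing}")
        sd = pd.DataFrame(
            {e: df[sd_cols[raw[: -len('_mean')]]] for e, raw in zip(elements, mean_cols)},
            index=df.index,
        )
    for frame, kind in ((mean, "mean"), (sd, "sd")):
        if frame is None:
            continue
        nonnum = frame.apply(pd.to_numeric, errors="coerce")
        bad = nonnum.isna() & frame.notna()
        if bad.any().any():
            station, element = _first_bad_cell(bad)
            raise DataError(
                f"non-numeric {kind} value at station {station!r}, element {element!r}"
            )
        frame[:] = nonnum
    return ExposureTable(mean=mean.astype(float),
                         sd=None if sd is None else sd.astype(float),
                         unit=unit)


def write_exposure_table(table: ExposureTable, path) -> None:
    out = pd.DataFrame(index=table.mean.index)
    for el in table.elements:
        out[f"{el}_mean"] = table.mean[el]
        if table.sd is not None:
            out[f"{el}_sd"] = table.sd[el]
    out.index.name = "station"
    out.to_csv(path)


def read_guidelines(source) -> GuidelineSet:
    """Read a guideline CSV with columns ``element,low,high,unit``.

    Rows whose high trigger is not strictly above the low trigger load with
    a :class:`GuidelineWarning` attached to the result (and emitted), never
    silently corrected: printed guideline tables occasionally carry such
    anomalies and the assessment must surface them.
    """
    df = _read_csv(source)
    if df.empty:
        raise DataError("guideline CSV is empty")
    required = {"element", "low", "high"}
    if not required.issubset(df.columns):
        raise DataError(f"guideline CSV must have columns {sorted(required)}")
    if df["low"].isna().any() or df["high"].isna().any():
        el = df.loc[df["low"].isna() | df["high"].isna(), "element"].iloc[0]
        raise DataError(f"element {el!r} is missing a trigger value")
    units = set(df["unit"]) if "unit" in df.columns else {CANONICAL_UNIT}
    if len(units) != 1:
        raise DataError("guideline CSV mixes units; one unit per file")
    unit = check_unit(units.pop())
    table = df.assign(element=df["element"].map(normalize_element)).set_index(
        "element"
    )[["low", "high"]].astype(float)
    notes = []
    for el, row in table.iterrows():
        if row["high"] < row["low"]:
            notes.append(f"{el}: high trigger {row['high']} below low trigger {row['low']}")
        elif row["high"] == row["low"]:
            notes.append(f"{el}: high trigger equals low trigger ({row['low']})")
    result = GuidelineSet(table=table, unit=unit, warnings=tuple(notes))
    for note in notes:
        warnings.warn(note, GuidelineWarning, stacklevel=2)
    return result


def write_guidelines(gs: GuidelineSet, path) -> None:
    out = gs.table.copy()
    out["unit"] = gs.unit
    out.index.name = "element"
    out.to_csv(path)


def read_toxicity(source, element: str, unit: str = CANONICAL_UNIT) -> ToxicityDataset:
    """Read a per-species toxicity CSV for one element.

    Columns: ``species,endpoint,concentration`` plus an optional per-row
    ``unit`` column; all values are normalised to the canonical internal
    unit (mg/kg dry weight).  ``unit`` gives the default when no unit column
    is present.
    """
    check_unit(unit)
    df = _read_csv(source)
    if df.empty or "concentration" not in df.columns:
        raise DataError("toxicity CSV must have a 'concentration' column and >= 1 row")
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    if conc.isna().any():
        raise DataError(f"non-numeric concentration in row {int(conc.isna().idxmax())}")
    if "unit" in df.columns:
        vals = np.array([
            convert_units(v, check_unit(str(u)), CANONICAL_UNIT)
            for v, u in zip(conc.to_numpy(dtype=float), df["unit"])
        ])
    else:
        vals = convert_units(conc.to_numpy(dtype=float), unit, CANONICAL_UNIT)
    return ToxicityDataset(
        element=normalize_element(element),
        concentrations=vals,
        species=tuple(df["species"].astype(str)) if "species" in df.columns else None,
        endpoints=tuple(df["endpoint"].astype(str)) if "endpoint" in df.columns else None,
        unit=CANONICAL_UNIT,
    )


def write_toxicity(tox: ToxicityDataset, path) -> None:
    n = len(tox)
    out = pd.DataFrame(
        {
            "species": tox.species if tox.species is not None else [f"sp{i+1}" for i in range(n)],
            "endpoint": tox.endpoints if tox.endpoints is not None else ["endpoint"] * n,
            "concentration": tox.concentrations,
            "unit": tox.unit,
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures: the Wami Estuary survey and the ISQG trigger table
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return importlib.resources.files("sedrisk.fixtures") / name


def load_wami_exposure() -> ExposureTable:
    """The packaged Wami Estuary survey: 20 stations x 6 elements, mg/kg dw."""
    return read_exposure_table(str(_fixture_path("wami_table3.csv")), unit="mg/kg")


def load_isqg_guidelines() -> GuidelineSet:
    """The packaged Australian interim sediment quality guideline triggers."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GuidelineWarning)
        return read_guidelines(str(_fixture_path("isqg_table2.csv")))
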