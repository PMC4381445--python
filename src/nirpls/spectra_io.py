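"""Spectral and constituent table containers plus their CSV / JSON serialization.

The on-disk dialect is deliberately plain: one row per sample, first column
``sample_id``, remaining column headers are wavenumbers in cm^-1.  Absorbance
values are rendered with 17 significant digits so that a write/read cycle is
the identity on the float payload.  Fitted models are stored as JSON with the
same bit-stability guarantee (Python's ``repr`` of a float round-trips).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraMatrix",
    "ConstituentTable",
    "SpectraError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_constituents_csv",
    "write_constituents_csv",
    "average_duplicates",
    "save_model",
    "load_model",
]

#: permitted unit tags for constituent columns
UNIT_TAGS = ("wt%_dry", "g_per_g", "fraction")

#: relative tolerance for the "uniform wavenumber grid" invariant
GRID_RTOL = 1e-6

_REP_SUFFIX = re.compile(r"_rep\d+$")


class SpectraError(ValueError):
    """Raised for malformed spectra/constituent data or files."""


def _check_uniform_axis(wavenumbers: np.ndarray) -> None:
    if wavenumbers.ndim != 1 or wavenumbers.size < 2:
        raise SpectraError("wavenumber axis must be 1-D with at least 2 points")
    d = np.diff(wavenumbers)
    if np.any(d == 0) or not (np.all(d > 0) or np.all(d < 0)):
        raise SpectraError("wavenumber axis must be strictly monotone")
    spacing = d.mean()
    if np.max(np.abs(d - spacing)) > GRID_RTOL * abs(spacing):
        j = int(np.argmax(np.abs(d - spacing)))
        raise SpectraError(
            f"wavenumber axis not uniformly spaced: step at column {j} "
            f"({wavenumbers[j]:.3f} -> {wavenumbers[j + 1]:.3f}) deviates from "
            f"mean spacing {spacing:.6g}"
        )


@dataclass
class SpectraMatrix:
    """Samples x wavenumbers absorbance matrix with a uniform axis.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers (one per row).
    wavenumbers
        Strictly monotone, uniformly spaced axis in cm^-1.
    absorbance
        ``(n_samples, n_wavenumbers)`` array of absorbance (dimensionless).
    """

    sample_ids: list[str]
    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.sample_ids) == 0:
            raise SpectraError("no samples")
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise SpectraError(f"duplicate sample id: {dupes[0]!r}")
        _check_uniform_axis(self.wavenumbers)
        if self.absorbance.shape != (len(self.sample_ids), self.wavenumbers.size):
            raise SpectraError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavenumbers.size} wavenumbers"
            )
        if not np.all(np.isfinite(self.absorbance)):
            i, j = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise SpectraError(
                f"non-finite absorbance for sample {self.sample_ids[i]!r} "
                f"at wavenumber {self.wavenumbers[j]:.3f}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def spacing(self) -> float:
        """Signed grid spacing (positive for an increasing axis)."""
        return float(np.diff(self.wavenumbers).mean())

    def select_samples(self, ids: Sequence[str]) -> "SpectraMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as e:
            raise SpectraError(f"unknown sample id: {e.args[0]!r}") from None
        return SpectraMatrix(list(ids), self.wavenumbers.copy(), self.absorbance[rows])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.absorbance, other.absorbance)
        )


@dataclass
class ConstituentTable:
    """Per-sample reference values with per-column unit tags.

    Units are one of ``wt%_dry`` (composition, 0-100), ``g_per_g`` (sugar
    release per gram dry biomass, >= 0) or ``fraction`` (yield, >= 0).
    """

    sample_ids: list[str]
    constituent_names: list[str]
    values: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.constituent_names = [str(c) for c in self.constituent_names]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise SpectraError(f"duplicate sample id: {dupes[0]!r}")
        if self.values.shape != (len(self.sample_ids), len(self.constituent_names)):
            raise SpectraError("values shape does not match ids x constituents")
        for name in self.constituent_names:
            unit = self.units.get(name)
            if unit is None:
                raise SpectraError(f"missing unit tag for constituent {name!r}")
            if unit not in UNIT_TAGS:
                raise SpectraError(f"unknown unit tag {unit!r} for {name!r}")
        if not np.all(np.isfinite(self.values)):
            raise SpectraError("non-finite constituent value")
        for j, name in enumerate(self.constituent_names):
            col = self.values[:, j]
            unit = self.units[name]
            if unit == "wt%_dry":
                bad = (col < 0) | (col > 100)
            else:  # g_per_g, fraction
                bad = col < 0
            if np.any(bad):
                i = int(np.argmax(bad))
                raise SpectraError(
                    f"value {col[i]} of {name!r} (sample {self.sample_ids[i]!r}) "
                    f"out of range for unit {unit!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.constituent_names.index(name)
        except ValueError:
            raise SpectraError(f"unknown constituent: {name!r}") from None
        return self.values[:, j]

    def subset(self, names: Sequence[str]) -> "ConstituentTable":
        cols = np.column_stack([self.column(n) for n in names])
        return ConstituentTable(
            list(self.sample_ids), list(names), cols,
            {n: self.units[n] for n in names},
        )

    def select_samples(self, ids: Sequence[str]) -> "ConstituentTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as e:
            raise SpectraError(f"unknown sample id: {e.args[0]!r}") from None
        return ConstituentTable(
            list(ids), list(self.constituent_names),
            self.values[rows], dict(self.units),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.constituent_names,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConstituentTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.constituent_names == other.constituent_names
            and np.array_equal(self.values, other.values)
            and self.units == other.units
        )


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for s in items:
        if s in seen:
            out.append(s)
        seen.add(s)
    return out


def _fmt17(x: float) -> str:
    return format(float(x), ".17g")


def _fmt_wavenumber(w: float) -> str:
    """3-decimal header when lossless, else full precision."""
    s = format(float(w), ".3f")
    return s if float(s) == float(w) else _fmt17(w)


# ---------------------------------------------------------------------------
# Spectra CSV
# ---------------------------------------------------------------------------

def write_spectra_csv(spectra: SpectraMatrix, path: str | Path) -> Path:
    """Write a :class:`SpectraMatrix` to CSV (rows = samples)."""
    spectra.validate()
    path = Path(path)
    header = "sample_id," + ",".join(_fmt_wavenumber(w) for w in spectra.wavenumbers)
    lines = [header]
    for sid, row in zip(spectra.sample_ids, spectra.absorbance):
        if "," in sid or "\n" in sid:
            raise SpectraError(f"sample id {sid!r} contains a CSV delimiter")
        lines.append(sid + "," + ",".join(_fmt17(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_spectra_csv(path: str | Path) -> SpectraMatrix:
    """Read a spectra CSV written in the package dialect."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        if len(header) < 3 or header[0] != "sample_id":
            raise SpectraError(
                f"{path}: malformed header (expected 'sample_id' then >=2 wavenumbers)"
            )
        try:
            wavenumbers = np.array([float(h) for h in header[1:]])
        except ValueError:
            bad = next(h for h in header[1:] if not _is_float(h))
            raise SpectraError(f"{path}: non-numeric wavenumber header {bad!r}") from None
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != len(header):
                raise SpectraError(
                    f"{path}: row {lineno} has {len(cells)} cells, expected {len(header)}"
                )
            sample_ids.append(cells[0])
            try:
                rows.append(np.array([float(c) for c in cells[1:]]))
            except ValueError:
                j = next(i for i, c in enumerate(cells[1:]) if not _is_float(c))
                raise SpectraError(
                    f"{path}: non-numeric cell at row {lineno}, "
                    f"column {header[j + 1]!r}: {cells[j + 1]!r}"
                ) from None
    if not sample_ids:
        raise SpectraError(f"{path}: no samples")
    return SpectraMatrix(sample_ids, wavenumbers, np.vstack(rows))


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Constituent CSV
# ---------------------------------------------------------------------------

def write_constituents_csv(table: ConstituentTable, path: str | Path) -> Path:
    table.validate()
    path = Path(path)
    lines = ["sample_id," + ",".join(table.constituent_names)]
    for sid, row in zip(table.sample_ids, table.values):
        lines.append(sid + "," + ",".join(_fmt17(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_constituents_csv(path: str | Path, units_map: Mapping[str, str]) -> ConstituentTable:
    """Read a constituent CSV; every non-id column must appear in *units_map*."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise SpectraError(f"{path}: missing 'sample_id' column")
    names = [c for c in df.columns if c != "sample_id"]
    unknown = [c for c in names if c not in units_map]
    if unknown:
        raise SpectraError(f"{path}: unknown constituent {unknown[0]!r} (not in units map)")
    values = df[names].to_numpy(dtype=float)
    return ConstituentTable(
        list(df["sample_id"]), names, values, {n: units_map[n] for n in names}
    )


# ---------------------------------------------------------------------------
# Duplicate-scan averaging
# ---------------------------------------------------------------------------

def average_duplicates(
    spectra: SpectraMatrix,
    replicate_map: Mapping[str, str] | None = None,
) -> SpectraMatrix:
    """Average replicate scans into one spectrum per physical sample.

    Samples are scanned more than once (typically in duplicate, from two
    separate cuvette fillings) and the absorbance spectra averaged.  By
    default replicate rows are recognised by a ``_rep<k>`` id suffix; an
    explicit ``replicate_map`` (row id -> base id) overrides that convention.
    Averaging is idempotent: ids without a suffix map to themselves.
    """
    if replicate_map is None:
        replicate_map = {s: _REP_SUFFIX.sub("", s) for s in spectra.sample_ids}
    base_ids: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(spectra.sample_ids):
        base = replicate_map.get(sid, sid)
        if base not in groups:
            groups[base] = []
            base_ids.append(base)
        groups[base].append(i)
    out = np.empty((len(base_ids), spectra.wavenumbers.size))
    for k, base in enumerate(base_ids):
        out[k] = spectra.absorbance[groups[base]].mean(axis=0)
    return SpectraMatrix(base_ids, spectra.wavenumbers.copy(), out)


# ---------------------------------------------------------------------------
# Model JSON serialization
# ---------------------------------------------------------------------------

MODEL_SCHEMA_VERSION = 1


def save_model(model, path: str | Path) -> Path:
    """Serialize a fitted PLS model to JSON (bit-stable float round-trip)."""
    path = Path(path)
    payload = {"schema_version": MODEL_SCHEMA_VERSION}
    payload.update(model.to_dict())
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return path


def load_model(path: str | Path):
    from .pls_core import PLSModel  # local import to avoid a cycle

    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise SpectraError(f"{path}: corrupt model file ({e})") from None
    version = payload.pop("schema_version", None)
    if version != MODEL_SCHEMA_VERSION:
        raise SpectraError(
            f"{path}: model schema version {version!r} != {MODEL_SCHEMA_VERSION}"
        )
    return PLSModel.from_dict(payload)
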