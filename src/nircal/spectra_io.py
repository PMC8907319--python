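"""Reading, writing and aligning NIR spectra matrices and reference tables.

Spectra travel through the pipeline as :class:`SpectraSet`: a wavenumber
grid (cm^-1, canonically descending from the high end of the NIR range
toward 4000 cm^-1) plus a samples x wavenumbers absorbance matrix.
Reference chemistry (component content in %) is carried per component by
:class:`ReferenceTable`. Both are plain-CSV backed so round trips are
bit-stable to formatting precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "ReferenceTable",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_reference_csv",
    "align",
]

#: tolerance when matching wavenumber grids across files, in cm^-1
WAVENUMBER_TOL = 1e-6


class SpectraValidationError(ValueError):
    """Raised when a spectra matrix or reference table violates its contract."""


@dataclass
class SpectraSet:
    """A wavenumber grid with an absorbance matrix and per-row identifiers.

    Parameters
    ----------
    wavenumbers : array of float
        Strictly monotone grid in cm^-1. Ascending input is accepted and
        normalized to the canonical descending direction (columns of
        ``absorbance`` are permuted consistently).
    absorbance : array, shape (n_rows, n_wavenumbers)
        Unitless absorbance values; must be finite.
    row_ids : list of str
        Unique identifier per row (sample or replicate scan).
    replicate_of : dict, optional
        Maps row_id -> sample_id, grouping replicate scans of one sample.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    row_ids: list[str]
    replicate_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.row_ids = [str(r) for r in self.row_ids]
        if self.wavenumbers.ndim != 1:
            raise SpectraValidationError("wavenumbers must be one-dimensional")
        n_wn = self.wavenumbers.size
        if self.absorbance.size == 0:
            self.absorbance = self.absorbance.reshape(len(self.row_ids), n_wn)
        if self.absorbance.shape != (len(self.row_ids), n_wn):
            raise SpectraValidationError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.row_ids)} rows x {n_wn} wavenumbers"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraValidationError("absorbance contains non-finite values")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise SpectraValidationError("row_ids are not unique")
        if n_wn >= 2:
            diffs = np.diff(self.wavenumbers)
            if np.all(diffs > 0):  # ascending input: normalize to descending
                self.wavenumbers = self.wavenumbers[::-1].copy()
                self.absorbance = self.absorbance[:, ::-1].copy()
            elif not np.all(diffs < 0):
                raise SpectraValidationError("wavenumbers are not strictly monotone")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    def row(self, row_id: str) -> np.ndarray:
        return self.absorbance[self.row_ids.index(row_id)]

    def subset_rows(self, ids: list[str]) -> "SpectraSet":
        idx = [self.row_ids.index(i) for i in ids]
        rep = None
        if self.replicate_of is not None:
            rep = {i: self.replicate_of[i] for i in ids if i in self.replicate_of}
        return SpectraSet(self.wavenumbers.copy(), self.absorbance[idx], list(ids), rep)


@dataclass
class ReferenceTable:
    """Per-sample content (%) of one named component."""

    component: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for sid, v in self.values.items():
            v = float(v)
            if not np.isfinite(v):
                raise SpectraValidationError(
                    f"reference value for {sid!r} is not finite"
                )
            if v < 0:
                raise SpectraValidationError(
                    f"reference value for {sid!r} is negative ({v})"
                )
            if str(sid) in clean:
                raise SpectraValidationError(f"duplicate sample id {sid!r}")
            clean[str(sid)] = v
        self.values = clean

    def array(self, order: list[str]) -> np.ndarray:
        return np.array([self.values[s] for s in order], dtype=float)


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide spectra CSV (header = wavenumbers, first column = row ids).

    Wavenumber order in the file may be ascending or descending; the result
    is normalized to descending.
    """
    df = pd.read_csv(path, index_col=0)
    try:
        wavenumbers = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise SpectraValidationError(
            f"{path}: header column {exc} is not a wavenumber"
        ) from None
    if not df.empty:
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number))).to_numpy()
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SpectraValidationError(
                f"{path}: malformed number at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}"
            )
    row_ids = [str(i) for i in df.index]
    if len(set(row_ids)) != len(row_ids):
        dupes = sorted({r for r in row_ids if row_ids.count(r) > 1})
        raise SpectraValidationError(f"{path}: duplicate row ids {dupes}")
    return SpectraSet(wavenumbers, df.to_numpy(dtype=float), row_ids)


def write_spectra_csv(s: SpectraSet, path) -> None:
    """Write a SpectraSet as wide CSV at full double precision (17 sig. digits)."""
    df = pd.DataFrame(
        s.absorbance,
        index=pd.Index(s.row_ids, name="sample_id"),
        columns=[repr(float(w)) for w in s.wavenumbers],
    )
    df.to_csv(path, float_format="%.17g")


def read_reference_csv(path, component: str) -> ReferenceTable:
    """Read one component's reference values from a wide reference CSV.

    The file must have a ``sample_id`` column (or index) and one numeric
    column per component.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SpectraValidationError(f"{path}: no 'sample_id' column")
    if component not in df.columns:
        avail = [c for c in df.columns if c != "sample_id"]
        raise SpectraValidationError(
            f"{path}: no column {component!r}; available components: {avail}"
        )
    col = pd.to_numeric(df[component], errors="coerce")
    if col.isna().any():
        bad = df.loc[col.isna(), "sample_id"].iloc[0]
        raise SpectraValidationError(
            f"{path}: non-numeric {component} value for sample {bad!r}"
        )
    return ReferenceTable(component, dict(zip(df["sample_id"].astype(str), col)))


def write_reference_csv(tables: list[ReferenceTable], path) -> None:
    """Write one or more components' reference tables as a wide CSV."""
    ids: list[str] = []
    for t in tables:
        for sid in t.values:
            if sid not in ids:
                ids.append(sid)
    df = pd.DataFrame({"sample_id": ids})
    for t in tables:
        df[t.component] = [t.values.get(sid, np.nan) for sid in ids]
    df.to_csv(path, index=False, float_format="%.17g")


def align(s: SpectraSet, r: ReferenceTable) -> tuple[SpectraSet, ReferenceTable]:
    """Restrict spectra and references to their common sample ids, same order.

    Order follows the spectra set's row order. Raises if the intersection
    is empty.
    """
    common = [sid for sid in s.row_ids if sid in r.values]
    if not common:
        raise SpectraValidationError(
            "no common sample ids between spectra and reference table"
        )
    sub = s.subset_rows(common)
    return sub, ReferenceTable(r.component, {sid: r.values[sid] for sid in common})
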