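"""Readers, writers and QC filtering for EEMs, absorbance spectra and sample tables.

All file formats are plain CSV.  The wide EEM dialect follows the common
Aqualog-style export: the first row holds excitation wavelengths (nm), the
first column emission wavelengths (nm), and the body holds fluorescence
intensities in arbitrary (spectrally corrected) units.  The long dialect is a
three-column ``ex,em,intensity`` table on a rectilinear grid.

Sample tables are per-sample records of DOC (mg C/L), decadic A254 (1/m) and
optional derived optical quantities.  QC filtering applies the configurable
exclusion rules used when compiling multi-instrument data sets (maximum
plausible SUVA, maximum DOC, declarative group exclusions) and logs every
removal.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EEM",
    "AbsorbanceSpectrum",
    "SampleTable",
    "QCRules",
    "read_eem",
    "write_eem",
    "read_absorbance",
    "read_sample_table",
    "write_sample_table",
    "qc_filter",
]

#: canonical numeric columns of a sample table, with their units
SAMPLE_COLUMNS = {
    "doc": "mg C/L (= g/m^3)",
    "a254": "decadic absorbance per meter (1/m)",
    "suva": "m^2/g C",
    "arix": "dimensionless",
    "fi": "dimensionless",
    "hix": "dimensionless",
    "hix1999": "dimensionless",
    "bix": "dimensionless",
    "freshness": "dimensionless",
    "s275_295": "1/nm",
    "s380_443": "1/nm",
    "a275": "Napierian 1/m",
    "a350": "Napierian 1/m",
}


@dataclass
class EEM:
    """A corrected fluorescence excitation–emission matrix.

    Parameters
    ----------
    sample_id : str
        Identifier of the measured sample.
    excitation : ndarray
        Strictly increasing excitation wavelengths, nm.
    emission : ndarray
        Strictly increasing emission wavelengths, nm.
    intensities : ndarray, shape (n_emission, n_excitation)
        Fluorescence intensities in arbitrary units.  Small negatives from
        blank subtraction are allowed; all values must be finite.
    corrected : bool
        Asserts that instrument correction and scatter handling were applied
        upstream; index extraction assumes fully corrected EEMs.
    """

    sample_id: str
    excitation: np.ndarray
    emission: np.ndarray
    intensities: np.ndarray
    corrected: bool = True

    def __post_init__(self) -> None:
        self.excitation = np.asarray(self.excitation, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        for name, grid in (("excitation", self.excitation), ("emission", self.emission)):
            if grid.ndim != 1 or grid.size < 2:
                raise ValueError(f"{name} grid must be 1-D with at least 2 points")
            if np.any(grid <= 0):
                raise ValueError(f"{name} wavelengths must be positive")
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} grid must be strictly increasing")
        if self.intensities.shape != (self.emission.size, self.excitation.size):
            raise ValueError(
                "intensities must have shape (n_emission, n_excitation); got "
                f"{self.intensities.shape}, expected "
                f"({self.emission.size}, {self.excitation.size})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass
class AbsorbanceSpectrum:
    """Decadic absorbance versus wavelength, with the cell path length in meters."""

    sample_id: str
    wavelength: np.ndarray
    absorbance: np.ndarray
    path_length: float  # meters

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.path_length <= 0:
            raise ValueError("path_length must be positive (meters)")
        if self.wavelength.ndim != 1 or self.wavelength.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.absorbance.shape != self.wavelength.shape:
            raise ValueError("absorbance and wavelength must have equal length")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass
class SampleTable:
    """An ordered collection of per-sample records with an exclusion log.

    The record store is a pandas DataFrame with one row per sample; canonical
    columns are listed in :data:`SAMPLE_COLUMNS` and unknown columns ride
    along as metadata.  ``exclusion_log`` records every sample dropped by
    :func:`qc_filter` together with the rule that removed it.
    """

    df: pd.DataFrame
    exclusion_log: list[dict] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if "sample_id" not in self.df.columns:
            raise ValueError("sample table requires a 'sample_id' column")
        ids = self.df["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValueError(f"duplicate sample_id values: {dupes}")
        if "doc" in self.df.columns:
            doc = pd.to_numeric(self.df["doc"], errors="coerce")
            if (doc <= 0).any():
                bad = self.df.loc[doc <= 0, "sample_id"].tolist()
                raise ValueError(f"DOC must be positive; offending samples: {bad}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def suva(self) -> pd.Series:
        """SUVA (m^2/g C) = A254 / DOC, computed on demand.

        Uses the stored ``suva`` column where present, otherwise A254/DOC.
        """
        if "suva" in self.df.columns and self.df["suva"].notna().all():
            return self.df["suva"].astype(float)
        return self.df["a254"].astype(float) / self.df["doc"].astype(float)

    def check_suva_consistency(self, rtol: float = 1e-9) -> pd.Series:
        """Flag rows where a stored SUVA disagrees with A254/DOC.

        Returns a boolean Series (True = inconsistent).  Rows lacking any of
        the three columns are never flagged.
        """
        cols = {"suva", "a254", "doc"}
        if not cols.issubset(self.df.columns):
            return pd.Series(False, index=self.df.index)
        computed = self.df["a254"].astype(float) / self.df["doc"].astype(float)
        stored = self.df["suva"].astype(float)
        with np.errstate(invalid="ignore"):
            bad = ~np.isclose(stored, computed, rtol=rtol, atol=0.0)
        return pd.Series(bad & stored.notna() & computed.notna(), index=self.df.index)


@dataclass(frozen=True)
class QCRules:
    """Exclusion thresholds applied before regression analyses.

    Defaults drop samples with implausibly high SUVA (> 7 m^2/g C) or
    extremely high DOC (> 120 mg/L); group exclusions drop whole categories
    (for example estuarine samples whose fluorescence falls below detection).
    """

    max_suva: float | None = 7.0
    max_doc: float | None = 120.0
    exclude_groups: tuple[str, ...] = ()
    group_column: str = "dataset_label"


def _parse_float_cell(text: str, context: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell {text!r} in {context}") from exc


def read_eem(path, layout: str = "wide", sample_id: str | None = None,
             transpose: bool = False) -> EEM:
    """Read an EEM from CSV.

    ``layout='wide'``: first row excitation nm (corner cell blank or
    ``em\\ex``), first column emission nm, body intensities.  ``transpose``
    flips a file stored excitation-rows-first into the canonical orientation.
    ``layout='long'``: columns ``ex,em,intensity`` covering a full
    rectilinear grid; duplicate or missing (ex, em) pairs are errors.
    """
    path = str(path)
    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    if layout == "wide":
        raw = pd.read_csv(path, header=None, dtype=str).values
        if transpose:
            raw = raw.T
        ex = np.array([_parse_float_cell(c, "excitation header") for c in raw[0, 1:]])
        em = np.array([_parse_float_cell(c, "emission column") for c in raw[1:, 0]])
        body = np.array(
            [[_parse_float_cell(c, "intensity body") for c in row] for row in raw[1:, 1:]]
        )
        ex_order = np.argsort(ex)
        em_order = np.argsort(em)
        return EEM(sample_id, ex[ex_order], em[em_order], body[np.ix_(em_order, ex_order)])
    if layout == "long":
        df = pd.read_csv(path)
        if df.shape[1] != 3:
            raise ValueError("long EEM layout requires exactly three columns: ex,em,intensity")
        df.columns = ["ex", "em", "intensity"]
        if df.duplicated(subset=["ex", "em"]).any():
            raise ValueError("duplicate (ex, em) pairs in long EEM input")
        ex = np.sort(df["ex"].unique())
        em = np.sort(df["em"].unique())
        if len(df) != ex.size * em.size:
            raise ValueError("non-rectilinear grid: long EEM input is missing (ex, em) combinations")
        wide = df.pivot(index="em", columns="ex", values="intensity")
        if wide.isna().any().any():
            raise ValueError("non-rectilinear grid: long EEM input is missing (ex, em) combinations")
        return EEM(sample_id, ex.astype(float), em.astype(float), wide.values.astype(float))
    raise ValueError(f"unknown EEM layout {layout!r}; expected 'wide' or 'long'")


def write_eem(eem: EEM, path) -> None:
    """Write an EEM in the wide CSV dialect; round-trips with :func:`read_eem`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("em\\ex," + ",".join(repr(float(v)) for v in eem.excitation) + "\n")
        for em_val, row in zip(eem.emission, eem.intensities):
            fh.write(repr(float(em_val)) + ","
                     + ",".join(repr(float(v)) for v in row) + "\n")


def read_absorbance(path, path_length: float | None = None,
                    sample_id: str | None = None) -> AbsorbanceSpectrum:
    """Read a two-column wavelength/decadic-absorbance CSV.

    The path length (meters) comes from the argument or from a header comment
    line ``# path_length_cm=...`` / ``# path_length_m=...``; an explicit
    argument wins over the header.
    """
    path = str(path)
    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    header_length = None
    data_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                key_val = stripped.lstrip("#").strip()
                if "=" in key_val:
                    key, val = (s.strip() for s in key_val.split("=", 1))
                    if key == "path_length_cm":
                        header_length = float(val) / 100.0
                    elif key == "path_length_m":
                        header_length = float(val)
                continue
            data_lines.append(stripped)
    if not data_lines:
        raise ValueError(f"empty absorbance file: {path}")
    df = pd.read_csv(_io.StringIO("\n".join(data_lines)), header=None)
    if df.shape[1] < 2:
        raise ValueError("absorbance CSV must have two columns: wavelength, absorbance")
    # tolerate a header row of column names
    if not np.issubdtype(np.asarray(df.iloc[0]).dtype, np.number):
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:]
    wl = df.iloc[:, 0].astype(float).values
    ab = df.iloc[:, 1].astype(float).values
    order = np.argsort(wl)
    length = path_length if path_length is not None else header_length
    if length is None:
        raise ValueError("path length not given as argument nor in file header")
    return AbsorbanceSpectrum(sample_id, wl[order], ab[order], float(length))


def read_sample_table(path) -> SampleTable:
    """Read a sample table CSV; column units are as documented, never converted."""
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    return SampleTable(df, provenance=str(path))


def write_sample_table(table: SampleTable, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        table.df.to_csv(fh, index=False)


def qc_filter(table: SampleTable, rules: QCRules = QCRules()) -> SampleTable:
    """Apply exclusion rules, returning a new table with an appended exclusion log.

    The input table is not modified.  Idempotent: filtering an already
    filtered table removes nothing further.
    """
    df = table.df
    keep = pd.Series(True, index=df.index)
    log = list(table.exclusion_log)

    def _drop(mask: pd.Series, rule: str) -> None:
        nonlocal keep
        for sid in df.loc[mask & keep, "sample_id"]:
            log.append({"sample_id": sid, "rule": rule})
        keep &= ~mask

    if rules.max_suva is not None:
        suva = table.suva() if {"a254", "doc"}.issubset(df.columns) or "suva" in df.columns \
            else pd.Series(np.nan, index=df.index)
        _drop(pd.Series(suva > rules.max_suva, index=df.index).fillna(False),
              f"max_suva>{rules.max_suva}")
    if rules.max_doc is not None and "doc" in df.columns:
        _drop(df["doc"].astype(float) > rules.max_doc, f"max_doc>{rules.max_doc}")
    if rules.exclude_groups and rules.group_column in df.columns:
        _drop(df[rules.group_column].isin(rules.exclude_groups).fillna(False),
              f"group_exclusion:{','.join(rules.exclude_groups)}")

    return SampleTable(df.loc[keep].reset_index(drop=True), exclusion_log=log,
                       provenance=table.provenance)
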