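"""Reading, writing and basic transforms of thermal-denaturation data.

The central container is :class:`SpectralMatrix`, a wavelength x condition
intensity grid (fluorescence, CD, FTIR ... spectra collected while ramping
temperature or following a kinetic trace).  Two-column experiments (DSC
thermograms, single-signal melts, isothermal traces) travel as
:class:`Dataset` objects, which are also what the global fit consumes.

File dialect: spectral matrices are stored with wavelengths down the first
column and condition values (temperature in degC, time in s) across the first
row; CSV uses RFC-4180 with '.' decimals, xlsx one matrix per sheet.  Results
are exported as a multi-sheet xlsx workbook with fixed sheet names.
"""

from __future__ import annotations

import enum
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence, Union

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - type-only imports
    from .global_fit import FitResult
    from .svd_engine import SVDResult

__all__ = [
    "AxisKind",
    "DatasetKind",
    "SpectralMatrix",
    "ExperimentMeta",
    "Dataset",
    "ParseError",
    "ValidationError",
    "read_spectral_matrix",
    "write_spectral_matrix",
    "read_xy_dataset",
    "derive_conventional_signal",
    "export_workbook",
]


class ParseError(ValueError):
    """A file could not be parsed into numbers."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant."""


class AxisKind(str, enum.Enum):
    """What the condition axis of a spectral matrix means."""

    TEMPERATURE_SCAN = "temperature_scan"
    KINETICS = "kinetics"
    GENERIC = "generic"


class DatasetKind(str, enum.Enum):
    """Experimental curve type; decides the forward model in the global fit."""

    DSC = "dsc"
    SPECTROSCOPY = "spectroscopy"
    KINETICS = "kinetics"
    SPECTROSCOPY_SVD = "spectroscopy_svd"
    KINETICS_SVD = "kinetics_svd"


@dataclass
class ExperimentMeta:
    """Per-experiment metadata.

    scan_rate (degC/min) is required for temperature scans, iso_temperature
    (degC) for isothermal kinetics.
    """

    scan_rate: Optional[float] = None
    iso_temperature: Optional[float] = None
    signal_name: str = ""

    def validate_for(self, kind: Union[AxisKind, DatasetKind]) -> None:
        needs_rate = kind in (
            AxisKind.TEMPERATURE_SCAN,
            DatasetKind.SPECTROSCOPY,
            DatasetKind.SPECTROSCOPY_SVD,
            DatasetKind.DSC,
        )
        needs_temp = kind in (
            AxisKind.KINETICS,
            DatasetKind.KINETICS,
            DatasetKind.KINETICS_SVD,
        )
        if needs_rate:
            if self.scan_rate is None:
                raise ValidationError(f"{kind.value} data require a scan_rate")
            if not np.isfinite(self.scan_rate) or self.scan_rate <= 0:
                raise ValidationError("scan_rate must be a positive finite number")
        if needs_temp and self.iso_temperature is None:
            raise ValidationError(f"{kind.value} data require an iso_temperature")


@dataclass
class SpectralMatrix:
    """Wavelength x condition intensity grid with axis metadata.

    Parameters
    ----------
    wavelengths : array, shape (m,)
        Strictly increasing wavelengths in nm (rows are re-sorted on
        construction if supplied in decreasing order).
    conditions : array, shape (n,)
        Condition values: temperature (degC) for scans, time (s) for
        kinetics; left in acquisition order.
    intensities : array, shape (m, n)
        Signal in instrument units; must be finite.
    """

    wavelengths: np.ndarray
    conditions: np.ndarray
    intensities: np.ndarray
    axis_kind: AxisKind = AxisKind.GENERIC
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.axis_kind = AxisKind(self.axis_kind)
        m, n = self.m, self.n
        if m < 2 or n < 2:
            raise ValidationError(
                f"spectral matrix needs at least 2 wavelengths and 2 conditions, got {m}x{n}"
            )
        if self.intensities.shape != (m, n):
            raise ValidationError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{m} wavelengths x {n} conditions"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities contain non-finite values")
        if np.unique(self.wavelengths).size != m:
            raise ValidationError("duplicate wavelength values")
        # accept descending wavelength order but store ascending
        if np.all(np.diff(self.wavelengths) < 0):
            self.wavelengths = self.wavelengths[::-1].copy()
            self.intensities = self.intensities[::-1].copy()
        elif not np.all(np.diff(self.wavelengths) > 0):
            order = np.argsort(self.wavelengths)
            self.wavelengths = self.wavelengths[order]
            self.intensities = self.intensities[order]
        if self.axis_kind in (AxisKind.TEMPERATURE_SCAN, AxisKind.KINETICS):
            d = np.diff(self.conditions)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValidationError(
                    f"{self.axis_kind.value} condition axis must be strictly monotone"
                )

    @property
    def m(self) -> int:
        return self.wavelengths.size

    @property
    def n(self) -> int:
        return self.conditions.size


@dataclass
class Dataset:
    """A typed experimental curve used in global fitting.

    ``y`` is a vector for scalar signals and an (n_points x k) matrix of
    amplitude curves for the ``*_svd`` kinds.  ``weight`` is filled by the
    global fit; ``norm_offset``/``norm_scale`` record the affine transform
    applied by normalization so it can be inverted.
    """

    kind: DatasetKind
    x: np.ndarray
    y: np.ndarray
    meta: ExperimentMeta = field(default_factory=ExperimentMeta)
    weight: Optional[float] = None
    label: str = ""
    norm_offset: Optional[np.ndarray] = None
    norm_scale: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.kind = DatasetKind(self.kind)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1:
            raise ValidationError("x must be one-dimensional")
        if self.kind in (DatasetKind.SPECTROSCOPY_SVD, DatasetKind.KINETICS_SVD):
            if self.y.ndim == 1:
                self.y = self.y[:, None]
            if self.y.ndim != 2 or self.y.shape[1] < 1:
                raise ValidationError("*_svd datasets need an (n x k) amplitude matrix")
        elif self.y.ndim != 1:
            raise ValidationError(f"{self.kind.value} dataset needs a 1-D signal")
        if self.y.shape[0] != self.x.size:
            raise ValidationError(
                f"x has {self.x.size} points but y has {self.y.shape[0]} rows"
            )
        if self.x.size < 2:
            raise ValidationError("dataset needs at least 2 points")
        d = np.diff(self.x)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("x axis must be strictly monotone")
        self.meta.validate_for(self.kind)

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def n_components(self) -> int:
        return 1 if self.y.ndim == 1 else self.y.shape[1]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _frame_to_matrix(
    df: pd.DataFrame, source: str, axis_kind: AxisKind, label: str
) -> SpectralMatrix:
    if df.shape[0] < 2 or df.shape[1] < 3:
        raise ValidationError(
            f"{source}: matrix needs >=2 wavelength rows and >=2 condition columns"
        )
    try:
        conditions = pd.to_numeric(df.columns[1:], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{source}: non-numeric condition header: {exc}") from None
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(body.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"{source}: non-numeric cell at data row {r + 1}, column {c + 1} "
            f"(value {df.iat[r, c]!r})"
        )
    arr = body.to_numpy(dtype=float)
    return SpectralMatrix(
        wavelengths=arr[:, 0],
        conditions=np.asarray(conditions, dtype=float),
        intensities=arr[:, 1:],
        axis_kind=axis_kind,
        label=label,
    )


def read_spectral_matrix(
    path: Union[str, Path],
    dialect: Optional[str] = None,
    sheet: Union[int, str] = 0,
    axis_kind: Union[AxisKind, str] = AxisKind.GENERIC,
    label: str = "",
) -> SpectralMatrix:
    """Read a wavelength x condition matrix from CSV or xlsx.

    First column: wavelengths (nm).  First row, after the corner cell:
    condition values.  ``dialect`` is ``matrix_csv`` or ``matrix_xlsx``;
    inferred from the file suffix when omitted.  ``sheet`` selects the
    worksheet for xlsx input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "matrix_xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "matrix_csv"
    if dialect == "matrix_xlsx":
        df = pd.read_excel(path, sheet_name=sheet, header=0)
    elif dialect == "matrix_csv":
        # sniff the delimiter, then parse with correctly-rounded floats
        first = path.read_text().splitlines()[0] if path.stat().st_size else ""
        sep = ";" if ";" in first else ("\t" if "\t" in first else ",")
        df = pd.read_csv(path, header=0, sep=sep, float_precision="round_trip")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _frame_to_matrix(df, str(path), AxisKind(axis_kind), label or path.stem)


def write_spectral_matrix(
    sm: SpectralMatrix,
    path: Union[str, Path],
    sheet: str = "Sheet1",
    corner: str = "lambda",
) -> Path:
    """Write a matrix in the dialect :func:`read_spectral_matrix` expects."""
    path = Path(path)
    df = pd.DataFrame(sm.intensities, columns=sm.conditions)
    df.insert(0, corner, sm.wavelengths)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df.to_excel(path, sheet_name=sheet, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.17g")
    return path


_NUMERIC_SPLIT = re.compile(r"[,\s;]+")


def read_xy_dataset(
    path: Union[str, Path],
    kind: Union[DatasetKind, str],
    meta: Optional[ExperimentMeta] = None,
    label: str = "",
) -> Dataset:
    """Read a two-column (x, y) file: DSC thermogram, melt curve or kinetic trace.

    Delimiters (comma, whitespace, semicolon) are sniffed per line; an optional
    single non-numeric header line is skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = [p for p in _NUMERIC_SPLIT.split(line) if p]
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            if lineno == 1 and not rows:  # header line
                continue
            raise ParseError(f"{path}: non-numeric value on line {lineno}") from None
        if len(vals) != 2:
            raise ValidationError(
                f"{path}: expected 2 columns, found {len(vals)} on line {lineno}"
            )
        rows.append(vals)
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    return Dataset(
        kind=DatasetKind(kind),
        x=arr[:, 0],
        y=arr[:, 1],
        meta=meta if meta is not None else ExperimentMeta(),
        label=label or path.stem,
    )


# ---------------------------------------------------------------------------
# conventional 2-D signals derived from spectra
# ---------------------------------------------------------------------------

def derive_conventional_signal(
    sm: SpectralMatrix,
    which: str,
    num_wl: float = 350.0,
    den_wl: float = 330.0,
    meta: Optional[ExperimentMeta] = None,
) -> Dataset:
    """Reduce a spectral matrix to a conventional scalar melt signal.

    ``which``:
      * ``ratio`` — intensity ratio I(num_wl)/I(den_wl), linearly
        interpolated between grid wavelengths (the nanoDSF I350/I330 signal);
      * ``bcm``   — barycentric mean wavelength, sum(lambda*I)/sum(I);
      * ``area``  — trapezoidal integral of the spectrum over wavelength.
    """
    lam, X = sm.wavelengths, sm.intensities
    if which == "ratio":
        for wl in (num_wl, den_wl):
            if not (lam[0] <= wl <= lam[-1]):
                raise ValidationError(f"wavelength {wl} nm outside grid [{lam[0]}, {lam[-1]}]")
        num = np.array([np.interp(num_wl, lam, X[:, j]) for j in range(sm.n)])
        den = np.array([np.interp(den_wl, lam, X[:, j]) for j in range(sm.n)])
        if np.any(den == 0):
            raise ValidationError(f"zero intensity at {den_wl} nm; ratio undefined")
        y = num / den
        name = f"I{num_wl:g}/I{den_wl:g}"
    elif which == "bcm":
        if np.any(X < 0):
            raise ValidationError("bcm requires non-negative intensities")
        tot = X.sum(axis=0)
        if np.any(tot == 0):
            raise ValidationError("all-zero spectrum column; bcm undefined")
        y = (lam[:, None] * X).sum(axis=0) / tot
        name = "BCM"
    elif which == "area":
        y = np.trapezoid(X, lam, axis=0)
        name = "area"
    else:
        raise ValueError(f"unknown signal {which!r}: use ratio, bcm or area")
    if meta is None:
        meta = ExperimentMeta(scan_rate=1.0, signal_name=name)
        meta.signal_name = name
    kind = (
        DatasetKind.KINETICS
        if sm.axis_kind is AxisKind.KINETICS
        else DatasetKind.SPECTROSCOPY
    )
    if kind is DatasetKind.KINETICS and meta.iso_temperature is None:
        meta.iso_temperature = 25.0
    return Dataset(kind=kind, x=sm.conditions.copy(), y=y, meta=meta, label=f"{sm.label}:{name}")


# ---------------------------------------------------------------------------
# export workbook
# ---------------------------------------------------------------------------

def export_workbook(
    path: Union[str, Path],
    svd: Optional["SVDResult"] = None,
    fit: Optional["FitResult"] = None,
) -> Path:
    """Write SVD and/or fit results to a multi-sheet xlsx workbook.

    Sheets (when the corresponding result is present): RawData,
    SingularValues, BasisSpectra, Amplitudes, Reconstruction, FitParameters,
    StateFractions, Residuals, StateSpectra.
    """
    if svd is None and fit is None:
        raise ValueError("need at least one result object to export")
    path = Path(path)
    from .svd_engine import reconstruct  # local import avoids a cycle

    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        if svd is not None:
            sm = svd.source
            raw = pd.DataFrame(sm.intensities, index=sm.wavelengths, columns=sm.conditions)
            raw.index.name = "wavelength_nm"
            raw.to_excel(xl, sheet_name="RawData")
            comp = np.arange(1, svd.S.size + 1)
            pd.DataFrame(
                {
                    "component": comp,
                    "singular_value": svd.S,
                    "normalized_value": svd.S / svd.S[0] if svd.S[0] > 0 else svd.S,
                    "explained_variance": svd.explained,
                    "autocorr_basis": svd.autocorr_u,
                    "autocorr_amplitude": svd.autocorr_v,
                    "significant": svd.significant,
                }
            ).to_excel(xl, sheet_name="SingularValues", index=False)
            basis = pd.DataFrame(
                svd.U, index=sm.wavelengths, columns=[f"u{i}" for i in comp]
            )
            basis.index.name = "wavelength_nm"
            basis.to_excel(xl, sheet_name="BasisSpectra")
            amps = pd.DataFrame(
                svd.V * svd.S, index=sm.conditions, columns=[f"sv{i}" for i in comp]
            )
            amps.index.name = "condition"
            amps.to_excel(xl, sheet_name="Amplitudes")
            rec = pd.DataFrame(
                reconstruct(svd, svd.n_selected), index=sm.wavelengths, columns=sm.conditions
            )
            rec.index.name = "wavelength_nm"
            rec.to_excel(xl, sheet_name="Reconstruction")
        if fit is not None:
            fit.parameters_frame().to_excel(xl, sheet_name="FitParameters", index=False)
            fit.fractions_frame().to_excel(xl, sheet_name="StateFractions", index=False)
            fit.residuals_frame().to_excel(xl, sheet_name="Residuals", index=False)
            sf = fit.state_spectra_frame()
            if sf is not None:
                sf.to_excel(xl, sheet_name="StateSpectra")
    return path
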