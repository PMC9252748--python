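"""Singular value decomposition of spectral series with rank diagnostics.

A wavelength x condition matrix X is factorized as X = U S V^T: the columns
of U are basis spectra (wavelength loadings), the columns of V amplitude
vectors (evolution over temperature or time), and S the component
magnitudes.  Beyond the bare factorization this module provides the
diagnostics used to decide how many components carry signal — explained
variance fractions and lag-1 autocorrelations of both singular vectors,
with the conventional 0.8 significance threshold — plus a constrained
variant where the first basis spectrum is pinned to the measured spectrum
of a known state (typically the native protein), so the remaining
components become interpretable relative to that reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .spectra_io import (
    AxisKind,
    Dataset,
    DatasetKind,
    ExperimentMeta,
    SpectralMatrix,
    ValidationError,
)

__all__ = [
    "SVDResult",
    "ReferenceSpectrum",
    "decompose",
    "explained_variance",
    "autocorrelation",
    "flag_significant",
    "apply_reference",
    "reconstruct",
    "component_curves",
    "select_by_cumulative_variance",
]

#: default autocorrelation threshold above which a component counts as signal
SIGNIFICANCE_THRESHOLD = 0.8


@dataclass
class ReferenceSpectrum:
    """Measured spectrum of a known macrostate, used to constrain the SVD."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    state_label: str = "native"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape or self.wavelengths.ndim != 1:
            raise ValidationError("reference spectrum needs matching 1-D vectors")

    def on_grid(self, wavelengths: np.ndarray) -> np.ndarray:
        """Interpolate onto the target wavelength grid (no extrapolation)."""
        lo, hi = self.wavelengths.min(), self.wavelengths.max()
        if wavelengths.min() < lo - 1e-9 or wavelengths.max() > hi + 1e-9:
            raise ValidationError(
                f"reference covers [{lo}, {hi}] nm but data need "
                f"[{wavelengths.min()}, {wavelengths.max()}] nm"
            )
        order = np.argsort(self.wavelengths)
        return np.interp(wavelengths, self.wavelengths[order], self.intensities[order])


@dataclass
class SVDResult:
    """Thin SVD of a spectral matrix plus component diagnostics.

    U (m x r) holds unit-norm basis spectra, S the non-increasing singular
    values, V (n x r) unit-norm amplitude vectors, r = min(m, n).  When
    ``reference_applied`` the first column of U is the unit-normalized
    reference spectrum and only components 2..r come from an SVD (of the
    deflated residual); the all-component reconstruction stays exact either
    way.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    explained: np.ndarray
    autocorr_u: np.ndarray
    autocorr_v: np.ndarray
    significant: np.ndarray
    n_selected: int
    source: SpectralMatrix
    reference_applied: bool = False
    reference_label: str = ""
    warnings_: list = field(default_factory=list)

    @property
    def r(self) -> int:
        return self.S.size


def explained_variance(S: np.ndarray) -> np.ndarray:
    """Fraction of total data variation carried by each component: S_i^2 / sum S_j^2."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValidationError("singular values must be non-negative")
    total = float(np.sum(S**2))
    if total == 0:
        raise ValidationError("all singular values are zero (degenerate matrix)")
    return S**2 / total


def autocorrelation(v: np.ndarray) -> float:
    """Lag-1 autocorrelation normalized by total power.

    C(v) = sum_{i<n} v_i v_{i+1} / sum_i v_i^2.  Smooth vectors score near 1
    (a constant vector of length n scores (n-1)/n), white noise near 0,
    alternating vectors near -1.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValidationError("autocorrelation needs at least 2 points")
    power = float(np.dot(v, v))
    if power == 0:
        raise ValidationError("autocorrelation of the zero vector is undefined")
    return float(np.dot(v[:-1], v[1:]) / power)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> None:
    """Deterministic sign convention, in place.

    The largest-magnitude element of each U column is made positive (first
    such index on ties); the matching V column is flipped to compensate, so
    U S V^T is unchanged and repeated decompositions agree bit-for-bit.
    """
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]


def _diagnose(
    U: np.ndarray,
    S: np.ndarray,
    V: np.ndarray,
    sm: SpectralMatrix,
    threshold: float,
    reference_applied: bool = False,
    reference_label: str = "",
) -> SVDResult:
    explained = explained_variance(S)
    acu = np.array([autocorrelation(U[:, j]) for j in range(S.size)])
    acv = np.array([autocorrelation(V[:, j]) for j in range(S.size)])
    significant = (acu > threshold) & (acv > threshold)
    n_selected = max(1, int(significant.sum()))
    return SVDResult(
        U=U,
        S=S,
        V=V,
        explained=explained,
        autocorr_u=acu,
        autocorr_v=acv,
        significant=significant,
        n_selected=n_selected,
        source=sm,
        reference_applied=reference_applied,
        reference_label=reference_label,
    )


def decompose(sm: SpectralMatrix, threshold: float = SIGNIFICANCE_THRESHOLD) -> SVDResult:
    """Thin SVD of the raw (uncentered) spectral matrix with diagnostics.

    All r = min(m, n) components are kept; ``n_selected`` starts at the
    number of components whose basis-spectrum *and* amplitude
    autocorrelations both exceed ``threshold`` (at least 1).
    """
    X = sm.intensities
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt.T
    _fix_signs(U, V)
    return _diagnose(U, S, V, sm, threshold)


def flag_significant(res: SVDResult, threshold: float = SIGNIFICANCE_THRESHOLD) -> np.ndarray:
    """Components whose both autocorrelations exceed ``threshold``."""
    return (res.autocorr_u > threshold) & (res.autocorr_v > threshold)


def select_by_cumulative_variance(res: SVDResult, cumulative: float = 0.98) -> int:
    """Alternative selector: smallest k whose cumulative explained variance
    reaches ``cumulative`` (e.g. 0.98)."""
    csum = np.cumsum(res.explained)
    return int(np.searchsorted(csum, cumulative - 1e-12) + 1)


def apply_reference(
    sm: SpectralMatrix,
    ref: ReferenceSpectrum,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> SVDResult:
    """Recompute the factorization with the first basis spectrum pinned to ``ref``.

    u1 = ref/||ref||; its amplitude row is the least-squares projection
    u1^T X; components 2..r are the thin SVD of the deflated residual
    X - u1 (u1^T X).  The full reconstruction is exact by construction.  If
    the reference is (numerically) orthogonal to the data column space the
    result carries a warning rather than failing.
    """
    X = sm.intensities
    u1 = ref.on_grid(sm.wavelengths).astype(float)
    norm = np.linalg.norm(u1)
    if norm == 0:
        raise ValidationError("reference spectrum is identically zero")
    u1 = u1 / norm
    a = u1 @ X  # projection amplitudes, length n
    s1 = float(np.linalg.norm(a))
    total_power = float(np.sum(X**2))
    res_warnings = []
    if s1**2 < 1e-12 * total_power:
        warn = (
            "reference spectrum is orthogonal to the data column space; "
            "first component carries no signal"
        )
        warnings.warn(warn, stacklevel=2)
        res_warnings.append(warn)
        v1 = np.zeros(sm.n)
        v1[0] = 1.0  # arbitrary unit vector; s1 ~ 0 so contribution vanishes
    else:
        v1 = a / s1
    R = X - np.outer(u1, a)
    Ur, Sr, Vrt = np.linalg.svd(R, full_matrices=False)
    Vr = Vrt.T
    # the deflated residual lives in the (m-1)-dim subspace orthogonal to u1,
    # so rank(R) <= min(m-1, n); keeping that many components keeps the
    # all-component reconstruction exact even when the reference points
    # outside the data column space (total components then min(m,n)+1)
    keep = min(sm.m - 1, sm.n)
    Ur, Sr, Vr = Ur[:, :keep], Sr[:keep], Vr[:, :keep]
    _fix_signs(Ur, Vr)
    U = np.column_stack([u1, Ur])
    S = np.concatenate([[s1], Sr])
    V = np.column_stack([v1, Vr])
    out = _diagnose(U, S, V, sm, threshold, reference_applied=True,
                    reference_label=ref.state_label)
    out.warnings_ = res_warnings
    return out


def reconstruct(res: SVDResult, k: int) -> np.ndarray:
    """Rank-k reconstruction sum_{i<=k} U_i S_i V_i^T of the source matrix."""
    if not 1 <= k <= res.r:
        raise ValidationError(f"k must be in [1, {res.r}], got {k}")
    return (res.U[:, :k] * res.S[:k]) @ res.V[:, :k].T


def component_curves(
    res: SVDResult, k: Optional[int] = None, meta: Optional[ExperimentMeta] = None
) -> Dataset:
    """Amplitude-scaled right singular vectors as a fit-ready dataset.

    Column i of the returned (n x k) matrix is S_i * V_i — how component i
    evolves over the condition axis.  Only temperature- or time-resolved
    matrices may feed the global fit, so a generic axis is rejected.
    ``meta`` carries the experiment's scan rate / isothermal temperature;
    a placeholder (1 degC/min, 25 degC) is supplied when omitted.
    """
    if k is None:
        k = res.n_selected
    if not 1 <= k <= res.r:
        raise ValidationError(f"k must be in [1, {res.r}], got {k}")
    sm = res.source
    if sm.axis_kind is AxisKind.GENERIC:
        raise ValidationError(
            "SVD components from a generic condition axis cannot enter the "
            "global fit; only temperature- or time-resolved data qualify"
        )
    kind = (
        DatasetKind.SPECTROSCOPY_SVD
        if sm.axis_kind is AxisKind.TEMPERATURE_SCAN
        else DatasetKind.KINETICS_SVD
    )
    if meta is None:
        meta = ExperimentMeta(
            scan_rate=1.0 if kind is DatasetKind.SPECTROSCOPY_SVD else None,
            iso_temperature=25.0 if kind is DatasetKind.KINETICS_SVD else None,
            signal_name="svd_amplitudes",
        )
    return Dataset(
        kind=kind,
        x=sm.conditions.copy(),
        y=res.V[:, :k] * res.S[:k],
        meta=meta,
        label=f"{sm.label}:svd{k}",
    )
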