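"""Global weighted least-squares fitting of heterogeneous denaturation data.

One shared set of thermodynamic/kinetic parameters (melting temperatures,
van't Hoff enthalpies, activation energy ...) is fitted simultaneously to
any mixture of DSC thermograms, scalar melt curves, isothermal kinetic
traces and SVD amplitude curves; each dataset additionally carries its own
linear observable parameters (per-state baselines, or per-component
state coefficients for SVD curves).

Datasets are balanced in the penalty function by the weight
w = 1 / (n_points * span^2), span being the peak-to-peak signal range, so
every dataset's weighted sum of squared residuals is O(1) regardless of
units or length.  Multi-component SVD datasets are weighted per component
with the same rule, otherwise the tiny-but-informative higher components
(which is where a hidden intermediate shows up) would be drowned out by
the first.

The optimizer is a bounded trust-region-reflective least-squares solver
with optional seeded Latin-hypercube multi-start; standard errors come
from the Jacobian at the solution and are approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .spectra_io import Dataset, DatasetKind, ValidationError
from .svd_engine import SVDResult
from .unfolding_models import (
    ModelSpec,
    Scheme,
    SignalParams,
    StateFractionTable,
    ThermoParams,
    dsc_curve,
    spectro_curve,
    state_fractions_isothermal,
    state_fractions_scan,
    svd_component_curve,
)

__all__ = [
    "Parameter",
    "FitOptions",
    "FitProblem",
    "FitResult",
    "normalize_dataset",
    "denormalize",
    "collate_kinetics",
    "dataset_weight",
    "residual_vector",
    "fit_global",
    "reconstruct_fitted_spectra",
    "state_fingerprints",
    "f_ratio",
]

_SVD_KINDS = (DatasetKind.SPECTROSCOPY_SVD, DatasetKind.KINETICS_SVD)

#: default bounds per thermodynamic parameter (degC, kJ/mol, kJ/mol/K)
DEFAULT_THERMO_BOUNDS: Dict[str, Tuple[float, float]] = {
    "tm1": (5.0, 125.0),
    "dh1": (10.0, 3000.0),
    "dcp1": (-10.0, 50.0),
    "tm2": (5.0, 125.0),
    "dh2": (10.0, 3000.0),
    "dcp2": (-10.0, 50.0),
    "ea": (0.0, 3000.0),
    "tf": (5.0, 125.0),
}

_TM_ORDER_PENALTY = 10.0  # soft Tm1 <= Tm2 ordering, in weighted-residual units


# ---------------------------------------------------------------------------
# dataset pre-treatment
# ---------------------------------------------------------------------------

def normalize_dataset(
    d: Dataset, t_range: Optional[Tuple[float, float]] = None
) -> Dataset:
    """Restrict to a temperature range and min-max rescale signals to [0, 1].

    The affine transform (offset, scale per signal column) is recorded on
    the returned dataset so :func:`denormalize` can invert it exactly.
    """
    if d.kind not in (DatasetKind.SPECTROSCOPY, DatasetKind.SPECTROSCOPY_SVD):
        raise ValidationError("normalization applies to spectroscopy(_svd) data only")
    x, y = d.x, d.y
    if t_range is not None:
        lo, hi = t_range
        mask = (x >= lo) & (x <= hi)
        if mask.sum() < 2:
            raise ValidationError(f"temperature range {t_range} retains < 2 points")
        x, y = x[mask], y[mask]
    y2d = y[:, None] if y.ndim == 1 else y
    ymin, ymax = y2d.min(axis=0), y2d.max(axis=0)
    span = ymax - ymin
    if np.any(span == 0):
        raise ValidationError("constant signal column cannot be normalized (zero span)")
    norm = (y2d - ymin) / span
    out = replace(
        d,
        x=x.copy(),
        y=norm[:, 0] if y.ndim == 1 else norm,
        norm_offset=ymin,
        norm_scale=span,
    )
    return out


def denormalize(d: Dataset, y: Optional[np.ndarray] = None) -> np.ndarray:
    """Map normalized signal values back to original units."""
    if d.norm_offset is None or d.norm_scale is None:
        raise ValidationError("dataset carries no normalization transform")
    y = d.y if y is None else np.asarray(y, dtype=float)
    y2d = y[:, None] if y.ndim == 1 else y
    orig = y2d * d.norm_scale + d.norm_offset
    return orig[:, 0] if y.ndim == 1 else orig


def collate_kinetics(
    traces: Sequence[Dataset], endpoint_mode: str = "free"
) -> List[Dataset]:
    """Group isothermal traces into one fitting block.

    ``endpoint_mode='shared_final'`` ties the denatured-baseline intercept
    (the long-time plateau) to a single shared parameter across all traces;
    ``'free'`` leaves each trace its own endpoint.
    """
    if endpoint_mode not in ("shared_final", "free"):
        raise ValueError("endpoint_mode must be 'shared_final' or 'free'")
    traces = list(traces)
    if not traces:
        raise ValidationError("need at least one kinetic trace")
    seen: Dict[float, Dataset] = {}
    for d in traces:
        if d.kind is not DatasetKind.KINETICS:
            raise ValidationError("collate_kinetics accepts kinetics datasets only")
        ti = d.meta.iso_temperature
        if ti in seen and seen[ti].x.size != d.x.size:
            pass  # duplicate temperatures with different grids are fine
        seen[ti] = d
    out = []
    for d in traces:
        nd = replace(d)
        nd.share_endpoint = endpoint_mode == "shared_final"  # type: ignore[attr-defined]
        out.append(nd)
    return out


def dataset_weight(d: Dataset) -> float:
    """Balancing weight w = 1 / (n_points * span^2) of a dataset.

    span is the peak-to-peak range of the (possibly normalized) signal, so
    each dataset contributes an O(1), unit-free share to the penalty.
    """
    y = d.y
    span = float(y.max() - y.min())
    if span == 0:
        raise ValidationError("constant signal has zero span; cannot weight")
    n = y.size
    return 1.0 / (n * span**2)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class Parameter:
    name: str
    value: float
    lo: float = -np.inf
    hi: float = np.inf
    vary: bool = True

    def __post_init__(self):
        if not self.lo <= self.value <= self.hi:
            raise ValidationError(
                f"parameter {self.name}: init {self.value} outside [{self.lo}, {self.hi}]"
            )


@dataclass
class FitOptions:
    max_iter: int = 2000
    tol: float = 1e-10
    multi_start: int = 1
    seed: int = 0


class FitProblem:
    """A global fit: datasets + model + parameter table.

    Thermodynamic parameters are shared across all datasets; each dataset
    gets its own signal parameters, initialized from the curve endpoints
    (intercepts) with zero slopes.  Parameter names: shared ones are bare
    (``tm1`` ...), per-dataset ones are prefixed ``ds{i}.`` (``ds0.a_N``,
    ``ds1.c1_I`` ...).
    """

    def __init__(
        self,
        datasets: Sequence[Dataset],
        model: ModelSpec,
        thermo_init: ThermoParams,
        bounds: Optional[Dict[str, Tuple[float, float]]] = None,
        fixed: Sequence[str] = (),
        vary_dcp: bool = False,
        vary_intermediate_slope: bool = False,
        options: Optional[FitOptions] = None,
    ):
        if not datasets:
            raise ValidationError("need at least one dataset")
        self.datasets = list(datasets)
        self.model = model
        thermo_init.validate_for(model)
        self.options = options or FitOptions()
        bounds = dict(bounds or {})
        fixed = set(fixed)

        self.params: Dict[str, Parameter] = {}
        self.ties: Dict[str, str] = {}  # alias -> canonical parameter name

        # shared thermodynamic parameters
        names = list(model.param_names)
        if "tm1" in names:
            names.insert(names.index("tm1") + 2, "dcp1")
        if "tm2" in names:
            names.insert(names.index("tm2") + 2, "dcp2")
        # reversible isothermal relaxation needs the intrinsic rate
        needs_rate = any(
            d.kind in (DatasetKind.KINETICS, DatasetKind.KINETICS_SVD)
            for d in self.datasets
        )
        if needs_rate and model.scheme is Scheme.TWO_STATE_REV:
            names += ["ea", "tf"]
        for name in names:
            val = getattr(thermo_init, name)
            if val is None:
                raise ValidationError(f"initial value required for {name}")
            lo, hi = bounds.get(name, DEFAULT_THERMO_BOUNDS[name])
            vary = name not in fixed
            if name.startswith("dcp") and not vary_dcp and name not in bounds:
                vary = False
            self.params[name] = Parameter(name, float(val), lo, hi, vary)

        # per-dataset signal parameters
        shared_endpoint_owner: Optional[str] = None
        for i, d in enumerate(self.datasets):
            d.meta.validate_for(d.kind)
            pre = f"ds{i}."
            if d.kind in _SVD_KINDS:
                y = d.y
                for k in range(d.n_components):
                    col = y[:, k]
                    guess = {"N": col[0], "D": col[-1]}
                    if "I" in model.states:
                        guess["I"] = 0.5 * (col[0] + col[-1])
                    for s in model.states:
                        pname = f"{pre}c{k + 1}_{s}"
                        lo, hi = bounds.get(pname, (-np.inf, np.inf))
                        self.params[pname] = Parameter(pname, float(guess[s]), lo, hi)
            else:
                y = d.y
                state_list = ("N", "D") if d.kind is DatasetKind.DSC else model.states
                guess = {"N": y[0], "D": y[-1]}
                if "I" in state_list:
                    guess["I"] = 0.5 * (y[0] + y[-1])
                for s in state_list:
                    an = f"{pre}a_{s}"
                    bn = f"{pre}b_{s}"
                    lo, hi = bounds.get(an, (-np.inf, np.inf))
                    self.params[an] = Parameter(an, float(guess[s]), lo, hi)
                    blo, bhi = bounds.get(bn, (-np.inf, np.inf))
                    vary_b = not (s == "I" and not vary_intermediate_slope)
                    self.params[bn] = Parameter(bn, 0.0, blo, bhi, vary_b)
                if getattr(d, "share_endpoint", False):
                    if shared_endpoint_owner is None:
                        shared_endpoint_owner = f"{pre}a_D"
                    else:
                        self.ties[f"{pre}a_D"] = shared_endpoint_owner
                        self.params[f"{pre}a_D"].vary = False

        # per-dataset balancing weights (per component for SVD blocks)
        self._weights: List[np.ndarray] = []
        for d in self.datasets:
            if d.kind in _SVD_KINDS:
                span = d.y.max(axis=0) - d.y.min(axis=0)
                if np.any(span == 0):
                    raise ValidationError("constant SVD component; cannot weight")
                w = 1.0 / (d.y.shape[0] * span**2)
            else:
                w = np.array([dataset_weight(d)])
            self._weights.append(w)
            d.weight = float(w.mean())

    # -- parameter vector plumbing ------------------------------------------

    @property
    def free_names(self) -> List[str]:
        return [n for n, p in self.params.items() if p.vary]

    def free_vector(self) -> np.ndarray:
        return np.array([self.params[n].value for n in self.free_names])

    def free_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.params[n].lo for n in self.free_names])
        hi = np.array([self.params[n].hi for n in self.free_names])
        return lo, hi

    def set_free(self, x: np.ndarray) -> None:
        for n, v in zip(self.free_names, x):
            self.params[n].value = float(v)
        for alias, canon in self.ties.items():
            self.params[alias].value = self.params[canon].value

    def value(self, name: str) -> float:
        return self.params[name].value

    def thermo_params(self) -> ThermoParams:
        g = lambda n: self.params[n].value if n in self.params else None
        return ThermoParams(
            tm1=g("tm1"), dh1=g("dh1"), dcp1=g("dcp1") or 0.0,
            tm2=g("tm2"), dh2=g("dh2"), dcp2=g("dcp2") or 0.0,
            ea=g("ea"), tf=g("tf"),
        )

    def signal_params(self, i: int) -> SignalParams:
        d = self.datasets[i]
        pre = f"ds{i}."
        if d.kind in _SVD_KINDS:
            C = np.array(
                [
                    [self.value(f"{pre}c{k + 1}_{s}") for s in self.model.states]
                    for k in range(d.n_components)
                ]
            )
            return SignalParams(coefficients=C)
        state_list = ("N", "D") if d.kind is DatasetKind.DSC else self.model.states
        bl = {
            s: (self.value(f"{pre}a_{s}"), self.value(f"{pre}b_{s}"))
            for s in state_list
        }
        return SignalParams(baselines=bl)

    # -- forward model -------------------------------------------------------

    def fractions_for(self, i: int, thermo: Optional[ThermoParams] = None) -> StateFractionTable:
        d = self.datasets[i]
        thermo = thermo if thermo is not None else self.thermo_params()
        if d.kind in (DatasetKind.KINETICS, DatasetKind.KINETICS_SVD):
            return state_fractions_isothermal(self.model, thermo, d.x, d.meta.iso_temperature)
        return state_fractions_scan(self.model, thermo, d.x, d.meta.scan_rate)

    def model_curve(self, i: int, thermo: Optional[ThermoParams] = None) -> np.ndarray:
        d = self.datasets[i]
        thermo = thermo if thermo is not None else self.thermo_params()
        fr = self.fractions_for(i, thermo)
        sp = self.signal_params(i)
        if d.kind is DatasetKind.DSC:
            return dsc_curve(fr, thermo, sp, self.model)
        if d.kind in _SVD_KINDS:
            return np.column_stack(
                [svd_component_curve(fr, sp, k) for k in range(d.n_components)]
            )
        return spectro_curve(fr, sp)

    @property
    def n_points(self) -> int:
        return sum(d.y.size for d in self.datasets)


def residual_vector(x: np.ndarray, problem: FitProblem) -> np.ndarray:
    """Weighted residuals sqrt(w_d) (model_d - y_d), concatenated over datasets.

    A model-evaluation failure (e.g. integrator blow-up at absurd trial
    parameters) yields a large-residual sentinel block instead of raising,
    so the optimizer can back away.  A soft ordering penalty keeps
    Tm1 <= Tm2 for three-state schemes.
    """
    problem.set_free(x)
    thermo = problem.thermo_params()
    blocks = []
    for i, d in enumerate(problem.datasets):
        w = problem._weights[i]
        try:
            m = problem.model_curve(i, thermo)
            if d.kind in _SVD_KINDS:
                r = (m - d.y) * np.sqrt(w)[None, :]
                blocks.append(r.ravel(order="F"))
            else:
                blocks.append(np.sqrt(w[0]) * (m - d.y))
        except (ValidationError, FloatingPointError, OverflowError):
            blocks.append(np.full(d.y.size, 1e6))
    if "tm1" in problem.params and "tm2" in problem.params:
        viol = max(0.0, problem.value("tm1") - problem.value("tm2"))
        blocks.append(np.array([_TM_ORDER_PENALTY * viol]))
    return np.concatenate(blocks)


@dataclass
class FitResult:
    """Outcome of a global fit."""

    params: Dict[str, float]
    stderr: Dict[str, float]
    wssr: float
    init_wssr: float
    per_dataset_rmse: List[float]
    fractions: List[StateFractionTable]
    converged: bool
    n_evals: int
    problem: FitProblem
    reconstructed: Optional[np.ndarray] = None
    fingerprints: Optional[np.ndarray] = None
    fingerprint_wavelengths: Optional[np.ndarray] = None

    @property
    def thermo(self) -> ThermoParams:
        return self.problem.thermo_params()

    def model_curves(self) -> List[np.ndarray]:
        return [self.problem.model_curve(i) for i in range(len(self.problem.datasets))]

    # -- export frames -------------------------------------------------------

    def parameters_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": n,
                "value": p.value,
                "stderr": self.stderr.get(n, np.nan),
                "fixed": not p.vary,
                "lo": p.lo,
                "hi": p.hi,
            }
            for n, p in self.problem.params.items()
        ]
        return pd.DataFrame(rows)

    def fractions_frame(self) -> pd.DataFrame:
        frames = []
        for i, fr in enumerate(self.fractions):
            df = pd.DataFrame(fr.fractions, columns=list(fr.states))
            df.insert(0, "x", fr.x)
            df.insert(0, "dataset", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def residuals_frame(self) -> pd.DataFrame:
        frames = []
        for i, d in enumerate(self.problem.datasets):
            m = self.problem.model_curve(i)
            res = (m - d.y)
            if res.ndim == 2:
                for k in range(res.shape[1]):
                    frames.append(
                        pd.DataFrame(
                            {"dataset": i, "component": k + 1, "x": d.x,
                             "observed": d.y[:, k], "model": m[:, k],
                             "residual": res[:, k]}
                        )
                    )
            else:
                frames.append(
                    pd.DataFrame(
                        {"dataset": i, "component": 0, "x": d.x,
                         "observed": d.y, "model": m, "residual": res}
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def state_spectra_frame(self) -> Optional[pd.DataFrame]:
        if self.fingerprints is None:
            return None
        df = pd.DataFrame(
            self.fingerprints, columns=list(self.problem.model.states)
        )
        if self.fingerprint_wavelengths is not None:
            df.index = self.fingerprint_wavelengths
            df.index.name = "wavelength_nm"
        return df


def fit_global(problem: FitProblem) -> FitResult:
    """Run the bounded least-squares fit, optionally multi-start.

    Starts: the user-supplied init plus (multi_start - 1) Latin-hypercube
    draws over the finite-bounded free parameters (seeded).  The best
    converged solution is kept; the returned wssr never exceeds the wssr at
    the initial values.
    """
    opts = problem.options
    x0 = problem.free_vector()
    lo, hi = problem.free_bounds()
    r0 = residual_vector(x0, problem)
    init_wssr = float(r0 @ r0)

    starts = [x0]
    if opts.multi_start > 1:
        finite = np.isfinite(lo) & np.isfinite(hi)
        sampler = qmc.LatinHypercube(d=int(finite.sum()), seed=opts.seed)
        draws = sampler.random(opts.multi_start - 1)
        for row in draws:
            x = x0.copy()
            x[finite] = lo[finite] + row * (hi[finite] - lo[finite])
            starts.append(x)

    best = None
    n_evals = 0
    for x_start in starts:
        try:
            res = least_squares(
                residual_vector,
                x_start,
                args=(problem,),
                bounds=(lo, hi),
                method="trf",
                xtol=opts.tol,
                ftol=opts.tol,
                gtol=opts.tol,
                max_nfev=opts.max_iter,
                x_scale="jac",
            )
        except Exception:
            continue
        n_evals += res.nfev
        if best is None or res.cost < best.cost:
            best = res

    if best is None or 2.0 * best.cost > init_wssr:
        # optimizer failed to improve: report the initial point honestly
        problem.set_free(x0)
        wssr = init_wssr
        converged = False
        stderr: Dict[str, float] = {}
        jac = None
    else:
        problem.set_free(best.x)
        wssr = float(2.0 * best.cost)
        converged = best.status > 0
        stderr = _stderr_from_jacobian(best.jac, wssr, problem)

    params = {n: p.value for n, p in problem.params.items()}
    rmse, fracs = [], []
    for i, d in enumerate(problem.datasets):
        m = problem.model_curve(i)
        rmse.append(float(np.sqrt(np.mean((m - d.y) ** 2))))
        fracs.append(problem.fractions_for(i))
    return FitResult(
        params=params,
        stderr=stderr,
        wssr=wssr,
        init_wssr=init_wssr,
        per_dataset_rmse=rmse,
        fractions=fracs,
        converged=converged,
        n_evals=n_evals,
        problem=problem,
    )


def _stderr_from_jacobian(jac: np.ndarray, wssr: float, problem: FitProblem) -> Dict[str, float]:
    n, p = jac.shape
    if n <= p:
        return {}
    JtJ = jac.T @ jac
    try:
        cov = np.linalg.inv(JtJ) * (wssr / (n - p))
    except np.linalg.LinAlgError:
        return {}
    diag = np.diag(cov)
    if np.any(diag < 0):
        diag = np.clip(diag, 0, None)
    return dict(zip(problem.free_names, np.sqrt(diag)))


# ---------------------------------------------------------------------------
# spectra from fitted models
# ---------------------------------------------------------------------------

def _find_svd_dataset(problem: FitProblem, dataset_index: Optional[int]) -> int:
    if dataset_index is not None:
        return dataset_index
    for i, d in enumerate(problem.datasets):
        if d.kind in _SVD_KINDS:
            return i
    raise ValidationError("fit contains no SVD dataset")


def reconstruct_fitted_spectra(
    res: FitResult, svdres: SVDResult, dataset_index: Optional[int] = None
) -> np.ndarray:
    """Back-calculate full spectra: X_fit = U[:, :k] @ (fitted component curves)^T."""
    i = _find_svd_dataset(res.problem, dataset_index)
    d = res.problem.datasets[i]
    k = d.n_components
    if k > svdres.r:
        raise ValidationError(
            f"fit uses {k} components but decomposition has only {svdres.r}"
        )
    curves = res.problem.model_curve(i)  # n x k
    xfit = svdres.U[:, :k] @ curves.T
    res.reconstructed = xfit
    return xfit


def state_fingerprints(
    res: FitResult, svdres: SVDResult, dataset_index: Optional[int] = None
) -> np.ndarray:
    """Spectra the model assigns to the pure macrostates.

    fingerprint_s = sum_k U_k c[k, s]; stacking them weighted by the state
    fractions reproduces the fitted spectra column by column.  With a
    native reference applied to the decomposition, the native fingerprint
    approximates the reference spectrum.
    """
    i = _find_svd_dataset(res.problem, dataset_index)
    d = res.problem.datasets[i]
    sp = res.problem.signal_params(i)
    C = sp.coefficients  # k x n_states
    k = C.shape[0]
    F = svdres.U[:, :k] @ C
    res.fingerprints = F
    res.fingerprint_wavelengths = svdres.source.wavelengths
    return F


def f_ratio(
    wssr_small: float, p_small: int, wssr_big: float, p_big: int, n_points: int
) -> float:
    """F statistic for nested model comparison (big model = more parameters)."""
    dof = n_points - p_big
    if wssr_big <= 0 or dof <= 0 or p_big <= p_small:
        return math.inf
    return ((wssr_small - wssr_big) / (p_big - p_small)) / (wssr_big / dof)
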