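"""Forward simulation of thermal-denaturation experiments with known truth.

Generates multi-wavelength fluorescence-style spectra, DSC thermograms and
isothermal kinetic traces from a fully specified unfolding model, so the
SVD engine and the global fit can be exercised and validated end to end
without any instrument data.  Each macrostate contributes a smooth
unimodal emission band (Gaussian by default, log-normal for more realistic
asymmetric fluorescence bands); unfolding red-shifts and quenches the
signal by moving population between bands.  Noise is additive i.i.d.
Gaussian from a seeded ``numpy.random.Generator`` (PCG64), so a fixed seed
reproduces every dataset bit for bit.

Preset scenarios (shipped as YAML files next to this module):

* ``two_state_fluor`` — clean two-state melt, the parameter-recovery
  workhorse.
* ``three_state_hidden_intermediate`` — the hidden-intermediate scenario:
  a scarcely populated intermediate invisible to conventional 2-D signals
  (one apparent transition near 50 degC at 1 degC/min) but exposed by a
  small (~0.2% explained variance) yet smooth third SVD component with two
  transitions.
* ``irreversible_scanrate_series`` — kinetically controlled melt whose
  apparent midpoint moves with the heating rate.
* ``dsc_two_peaks`` — three-state thermogram with two excess-heat peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .spectra_io import (
    AxisKind,
    Dataset,
    DatasetKind,
    ExperimentMeta,
    SpectralMatrix,
    ValidationError,
)
from .unfolding_models import (
    ModelSpec,
    Scheme,
    SignalParams,
    ThermoParams,
    dsc_curve,
    rate_constant,
    spectro_curve,
    state_fractions_isothermal,
    state_fractions_scan,
)

__all__ = [
    "PeakSpec",
    "SyntheticSpec",
    "make_state_spectra",
    "simulate_scan_spectra",
    "simulate_dsc",
    "simulate_kinetics",
    "recovery_harness",
    "load_preset",
    "preset_names",
    "count_transitions",
    "apparent_midpoint",
]

_PRESET_DIR = Path(__file__).parent / "presets"


@dataclass
class PeakSpec:
    """One state's emission band: center (nm), width (nm, ~sd), amplitude."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"  # "gaussian" | "lognormal"

    def evaluate(self, lam: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * ((lam - self.center) / self.width) ** 2)
        if self.shape == "lognormal":
            s = self.width / self.center
            return self.amplitude * np.exp(-0.5 * (np.log(lam / self.center) / s) ** 2)
        raise ValidationError(f"unknown peak shape {self.shape!r}")


@dataclass
class SyntheticSpec:
    """Complete ground truth for one synthetic experiment."""

    model: ModelSpec
    thermo: ThermoParams
    state_spectra: Dict[str, PeakSpec]
    wavelengths: np.ndarray
    t_grid_c: np.ndarray
    scan_rate: float = 1.0            # degC/min
    t_grid_s: Optional[np.ndarray] = None
    iso_temperatures: Tuple[float, ...] = ()
    noise_sd: float = 0.0             # additive Gaussian sigma, signal units
    baseline_drift: Dict[str, float] = field(default_factory=dict)  # per-state, 1/degC
    signal_baselines: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    dsc_baselines: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.t_grid_c = np.asarray(self.t_grid_c, dtype=float)
        if set(self.state_spectra) != set(self.model.states):
            raise ValidationError(
                f"state_spectra keys {sorted(self.state_spectra)} do not match "
                f"model states {self.model.states}"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo, hi = self.wavelengths.min(), self.wavelengths.max()
        for s, pk in self.state_spectra.items():
            if not lo <= pk.center <= hi:
                raise ValidationError(
                    f"state {s}: peak center {pk.center} nm outside grid [{lo}, {hi}]"
                )

    def rng(self, offset: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + offset)


def make_state_spectra(spec: SyntheticSpec) -> np.ndarray:
    """m x n_states matrix of pure-state spectra on the wavelength grid."""
    return np.column_stack(
        [spec.state_spectra[s].evaluate(spec.wavelengths) for s in spec.model.states]
    )


def simulate_scan_spectra(spec: SyntheticSpec, seed_offset: int = 0) -> SpectralMatrix:
    """Spectra while ramping temperature.

    X(lambda, T) = sum_s spectrum_s(lambda) (1 + drift_s (T - T0)) f_s(T) + noise.
    """
    S = make_state_spectra(spec)  # m x n_states
    fr = state_fractions_scan(spec.model, spec.thermo, spec.t_grid_c, spec.scan_rate)
    T = spec.t_grid_c
    drift = np.array([spec.baseline_drift.get(s, 0.0) for s in spec.model.states])
    # m x n: for each state, outer(spectrum, drift-scaled fraction)
    X = np.zeros((spec.wavelengths.size, T.size))
    for j, s in enumerate(spec.model.states):
        X += np.outer(S[:, j], (1.0 + drift[j] * (T - T[0])) * fr.fractions[:, j])
    if spec.noise_sd > 0:
        X = X + spec.rng(seed_offset).normal(0.0, spec.noise_sd, size=X.shape)
    return SpectralMatrix(
        wavelengths=spec.wavelengths.copy(),
        conditions=T.copy(),
        intensities=X,
        axis_kind=AxisKind.TEMPERATURE_SCAN,
        label=spec.label,
    )


def simulate_dsc(spec: SyntheticSpec, seed_offset: int = 1) -> Dataset:
    """DSC thermogram from the same ground truth (kJ/mol/K vs degC)."""
    fr = state_fractions_scan(spec.model, spec.thermo, spec.t_grid_c, spec.scan_rate)
    sp = SignalParams(baselines=dict(spec.dsc_baselines))
    cp = dsc_curve(fr, spec.thermo, sp, spec.model)
    if spec.noise_sd > 0:
        cp = cp + spec.rng(seed_offset).normal(0.0, spec.noise_sd, size=cp.shape)
    return Dataset(
        kind=DatasetKind.DSC,
        x=spec.t_grid_c.copy(),
        y=cp,
        meta=ExperimentMeta(scan_rate=spec.scan_rate, signal_name="Cp"),
        label=f"{spec.label}:dsc",
    )


def simulate_kinetics(spec: SyntheticSpec, seed_offset: int = 2) -> List[Dataset]:
    """Isothermal traces at each ``iso_temperatures`` entry."""
    if spec.t_grid_s is None or not len(spec.iso_temperatures):
        raise ValidationError("kinetics simulation needs t_grid_s and iso_temperatures")
    bl = spec.signal_baselines or _default_signal_baselines(spec.model)
    sp = SignalParams(baselines=bl)
    out = []
    for j, T_iso in enumerate(spec.iso_temperatures):
        fr = state_fractions_isothermal(spec.model, spec.thermo, spec.t_grid_s, T_iso)
        y = spectro_curve(fr, sp)
        if spec.noise_sd > 0:
            y = y + spec.rng(seed_offset + j).normal(0.0, spec.noise_sd, size=y.shape)
        out.append(
            Dataset(
                kind=DatasetKind.KINETICS,
                x=spec.t_grid_s.copy(),
                y=y,
                meta=ExperimentMeta(iso_temperature=float(T_iso), signal_name="I"),
                label=f"{spec.label}:kin{T_iso:g}C",
            )
        )
    return out


def simulate_melt_curve(spec: SyntheticSpec, seed_offset: int = 3) -> Dataset:
    """Scalar melt signal y(T) = sum_s (a_s + b_s T) f_s(T) + noise."""
    fr = state_fractions_scan(spec.model, spec.thermo, spec.t_grid_c, spec.scan_rate)
    bl = spec.signal_baselines or _default_signal_baselines(spec.model)
    y = spectro_curve(fr, SignalParams(baselines=bl))
    if spec.noise_sd > 0:
        y = y + spec.rng(seed_offset).normal(0.0, spec.noise_sd, size=y.shape)
    return Dataset(
        kind=DatasetKind.SPECTROSCOPY,
        x=spec.t_grid_c.copy(),
        y=y,
        meta=ExperimentMeta(scan_rate=spec.scan_rate, signal_name="melt"),
        label=f"{spec.label}:melt",
    )


def _default_signal_baselines(model: ModelSpec) -> Dict[str, Tuple[float, float]]:
    bl = {"N": (1.0, 0.0), "D": (0.3, 0.0)}
    if "I" in model.states:
        bl["I"] = (0.65, 0.0)
    return bl


# ---------------------------------------------------------------------------
# curve-shape diagnostics used in the validation suite
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    window = max(3, window | 1)  # odd, >= 3
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(yp, kernel, mode="valid")


def count_transitions(x: np.ndarray, y: np.ndarray, frac_threshold: float = 0.25) -> int:
    """Count sigmoidal transitions in a curve.

    The smoothed derivative is thresholded at ``frac_threshold`` of its
    peak magnitude; each contiguous same-sign excursion above threshold is
    one transition.  A monotone sigmoid counts 1, a rise-then-fall SVD
    amplitude counts 2, a flat curve 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ys = _smooth(y, max(5, x.size // 15))
    dy = np.gradient(ys, x)
    dys = _smooth(dy, max(5, x.size // 15))
    thr = frac_threshold * np.max(np.abs(dys))
    if thr == 0:
        return 0
    active = np.where(np.abs(dys) > thr, np.sign(dys), 0.0)
    count = 0
    prev = 0.0
    for a in active:
        if a != 0 and a != prev:
            count += 1
        prev = a
    return count


def apparent_midpoint(x: np.ndarray, y: np.ndarray) -> float:
    """Temperature where a melt signal is halfway between its plateaus.

    The curve is smoothed, rescaled by its end plateaus (mean of the outer
    ~10% of points) and the first 0.5 crossing is located by linear
    interpolation.
    """
    x = np.asarray(x, float)
    y = _smooth(np.asarray(y, float), max(5, x.size // 20))
    edge = max(2, x.size // 10)
    y0, y1 = y[:edge].mean(), y[-edge:].mean()
    if y0 == y1:
        raise ValidationError("flat curve has no midpoint")
    z = (y - y0) / (y1 - y0)
    above = z >= 0.5
    idx = np.argmax(above)
    if idx == 0:
        raise ValidationError("curve starts beyond its midpoint")
    x0, x1v = x[idx - 1], x[idx]
    z0, z1 = z[idx - 1], z[idx]
    return float(x0 + (0.5 - z0) / (z1 - z0) * (x1v - x0))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_names() -> List[str]:
    return sorted(p.stem for p in _PRESET_DIR.glob("*.yaml"))


def load_preset(name: str, seed: int = 0, noise_sd: Optional[float] = None) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a shipped preset YAML file."""
    path = _PRESET_DIR / f"{name}.yaml"
    if not path.exists():
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    cfg = yaml.safe_load(path.read_text())
    model = ModelSpec(Scheme(cfg["scheme"]))
    thermo = ThermoParams(**cfg.get("thermo", {}))
    peaks = {
        s: PeakSpec(**pk) for s, pk in cfg.get("state_spectra", {}).items()
    }
    wl = cfg.get("wavelengths", {"start": 300.0, "stop": 450.0, "step": 1.0})
    lam = np.arange(wl["start"], wl["stop"] + 0.5 * wl["step"], wl["step"])
    tg = cfg.get("temperatures", {"start": 20.0, "stop": 90.0, "num": 71})
    t_grid = np.linspace(tg["start"], tg["stop"], int(tg["num"]))
    t_grid_s = None
    if "times" in cfg:
        ts = cfg["times"]
        t_grid_s = np.linspace(ts["start"], ts["stop"], int(ts["num"]))
    return SyntheticSpec(
        model=model,
        thermo=thermo,
        state_spectra=peaks,
        wavelengths=lam,
        t_grid_c=t_grid,
        scan_rate=float(cfg.get("scan_rate", 1.0)),
        t_grid_s=t_grid_s,
        iso_temperatures=tuple(cfg.get("iso_temperatures", ())),
        noise_sd=float(cfg["noise_sd"]) if noise_sd is None else float(noise_sd),
        baseline_drift={k: float(v) for k, v in cfg.get("baseline_drift", {}).items()},
        signal_baselines={
            k: tuple(v) for k, v in cfg.get("signal_baselines", {}).items()
        },
        dsc_baselines={k: tuple(v) for k, v in cfg.get("dsc_baselines", {}).items()},
        seed=seed,
        label=name,
    )


# ---------------------------------------------------------------------------
# end-to-end recovery harness
# ---------------------------------------------------------------------------

def recovery_harness(
    spec: SyntheticSpec,
    n_reps: int = 20,
    seed: int = 0,
    n_components: Optional[int] = None,
    multi_start: int = 1,
) -> Dict[str, dict]:
    """Simulate -> SVD -> select components -> global fit -> compare to truth.

    Returns, per thermodynamic parameter, the per-replicate estimates,
    bias, RMSE and the coverage fraction of the truth by +-2 stderr
    intervals.  Non-converged replicates are reported, not fatal.
    """
    from .global_fit import FitOptions, FitProblem, fit_global
    from .svd_engine import component_curves, decompose

    truth = {k: v for k, v in spec.thermo.as_dict().items()
             if k in spec.model.param_names}
    estimates: Dict[str, List[float]] = {k: [] for k in truth}
    covered: Dict[str, List[bool]] = {k: [] for k in truth}
    failures = 0
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        rep_spec = SyntheticSpec(
            model=spec.model, thermo=spec.thermo, state_spectra=spec.state_spectra,
            wavelengths=spec.wavelengths, t_grid_c=spec.t_grid_c,
            scan_rate=spec.scan_rate, t_grid_s=spec.t_grid_s,
            iso_temperatures=spec.iso_temperatures, noise_sd=spec.noise_sd,
            baseline_drift=spec.baseline_drift,
            signal_baselines=spec.signal_baselines,
            dsc_baselines=spec.dsc_baselines,
            seed=int(rng.integers(0, 2**31 - 1)), label=spec.label,
        )
        sm = simulate_scan_spectra(rep_spec)
        res = decompose(sm)
        k = n_components if n_components is not None else res.n_selected
        curves = component_curves(res, k)
        curves.meta.scan_rate = spec.scan_rate
        init = _jittered_init(spec.thermo, spec.model, rng)
        problem = FitProblem(
            [curves], spec.model, init,
            options=FitOptions(multi_start=multi_start, seed=int(rng.integers(0, 2**31 - 1))),
        )
        fit = fit_global(problem)
        if not fit.converged:
            failures += 1
        for name in truth:
            est = fit.params[name]
            estimates[name].append(est)
            se = fit.stderr.get(name)
            covered[name].append(
                se is not None and abs(est - truth[name]) <= 2.0 * se
            )
    report = {}
    for name, t in truth.items():
        arr = np.asarray(estimates[name])
        report[name] = {
            "truth": t,
            "estimates": arr.tolist(),
            "bias": float(arr.mean() - t),
            "rmse": float(np.sqrt(np.mean((arr - t) ** 2))),
            "coverage_2se": float(np.mean(covered[name])) if covered[name] else float("nan"),
        }
    report["_meta"] = {"n_reps": n_reps, "failures": failures}
    return report


def _jittered_init(thermo: ThermoParams, model: ModelSpec, rng: np.random.Generator) -> ThermoParams:
    """Start the fit near, but not at, the truth (+-2 degC on Tm/Tf, +-15% on energies)."""
    kw = {}
    for name in ("tm1", "tm2", "tf"):
        v = getattr(thermo, name)
        if v is not None:
            kw[name] = v + rng.uniform(-2.0, 2.0)
    for name in ("dh1", "dh2", "ea"):
        v = getattr(thermo, name)
        if v is not None:
            kw[name] = v * rng.uniform(0.85, 1.15)
    kw["dcp1"], kw["dcp2"] = thermo.dcp1, thermo.dcp2
    return ThermoParams(**kw)
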