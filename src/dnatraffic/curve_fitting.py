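"""Decay and binding-isotherm fitting with uncertainties.

Two analysis models back the assay pipeline:

* exponential decay of the borohydride-trappable covalent intermediate,
  ``y = A·exp(−k·t)`` with an optional floating offset, reported with the
  half-life t½ = ln2/k and its propagated standard error;

* a one-site binding isotherm for thermophoresis titrations. Because the
  labeled species (30 nM by default) is not negligible next to the measured
  Kd (~400–600 nM), the default form is the depletion-aware quadratic
  solution of the binding equilibrium; the simple hyperbola is available.

Both are plain nonlinear least squares (scipy) with Jacobian-based standard
errors; an optional seeded bootstrap is provided for small samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import ParameterError

LN2 = math.log(2.0)


@dataclass
class DecayData:
    """A trapping time course: fraction remaining vs. time (min)."""

    times: np.ndarray
    fraction: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.fraction = np.asarray(self.fraction, float)
        if len(self.times) < 4:
            raise ParameterError("need at least 4 time points for a decay fit")
        if not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")
        if len(self.times) != len(self.fraction):
            raise ParameterError("times and fraction length mismatch")


@dataclass
class TitrationCurve:
    """A titration: total ligand (nM) vs. normalized signal.

    ``labeled_conc`` is the fixed concentration of the fluorescent species.
    """

    ligand_total: np.ndarray
    signal: np.ndarray
    labeled_conc: float = 30.0

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, float)
        self.signal = np.asarray(self.signal, float)
        if len(self.ligand_total) != len(self.signal):
            raise ParameterError("ligand and signal length mismatch")
        if len(self.ligand_total) < 6:
            raise ParameterError("need at least 6 titration points")
        pos = self.ligand_total[self.ligand_total > 0]
        if len(pos) == 0 or pos.max() / pos.min() < 100:
            raise ParameterError(
                "titration must span at least 2 orders of magnitude in ligand"
            )
        if self.labeled_conc <= 0:
            raise ParameterError("labeled_conc must be > 0")


@dataclass
class FitResult:
    """Parameter estimates with standard errors and fit diagnostics."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    converged: bool
    residual_rms: float
    half_life: float | None = None
    half_life_se: float | None = None
    flags: list[str] = field(default_factory=list)


def _safe_errors(pcov: np.ndarray, names: list[str]) -> dict[str, float]:
    diag = np.diag(pcov)
    return {n: float(np.sqrt(d)) if np.isfinite(d) and d >= 0 else float("nan")
            for n, d in zip(names, diag)}


def fit_exponential_decay(data: DecayData,
                          model: str = "simple") -> FitResult:
    """Fit y = A·exp(−k·t) (model="simple") or + C (model="offset").

    Initialized by log-linear regression on the positive values, so the
    noiseless case converges to machine precision. Reports
    half_life = ln2/k with the error propagated from se(k).
    """
    if model not in ("simple", "offset"):
        raise ParameterError("model must be 'simple' or 'offset'")
    t, y = data.times, data.fraction
    # log-linear initialization
    c0 = 0.0
    if model == "offset":
        c0 = max(0.0, float(y.min()) - 1e-6)
    pos = (y - c0) > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos] - c0), 1)
        a0, k0 = float(np.exp(intercept)), max(1e-6, -float(slope))
    else:
        a0, k0 = float(max(y.max(), 1e-6)), 0.1

    sigma = None if data.weights is None else 1.0 / np.sqrt(data.weights)
    try:
        if model == "simple":
            f = lambda t, a, k: a * np.exp(-k * t)
            popt, pcov = curve_fit(f, t, y, p0=[a0, k0], sigma=sigma,
                                   maxfev=10000)
            names = ["A", "k"]
        else:
            f = lambda t, a, k, c: a * np.exp(-k * t) + c
            popt, pcov = curve_fit(f, t, y, p0=[a0, k0, c0], sigma=sigma,
                                   maxfev=10000)
            names = ["A", "k", "C"]
    except RuntimeError as exc:
        return FitResult(estimates={}, standard_errors={}, converged=False,
                         residual_rms=float("nan"),
                         flags=[f"non-convergence: {exc}"])
    est = dict(zip(names, (float(v) for v in popt)))
    se = _safe_errors(pcov, names)
    resid = y - f(t, *popt)
    k = est["k"]
    flags: list[str] = []
    if k <= 0:
        flags.append("non-positive rate estimate")
        hl, hl_se = None, None
    else:
        hl = LN2 / k
        hl_se = (LN2 / k ** 2) * se["k"] if np.isfinite(se["k"]) else float("nan")
    return FitResult(estimates=est, standard_errors=se, converged=True,
                     residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                     half_life=hl, half_life_se=hl_se, flags=flags)


def fraction_bound_quadratic(ligand_total, kd: float, labeled_conc: float):
    """Exact fraction of labeled species bound, with ligand depletion.

    Solves [LT] binding at total ligand T and total labeled L0:
    FB = ((L0 + T + Kd) − sqrt((L0 + T + Kd)² − 4·L0·T)) / (2·L0).
    """
    T = np.asarray(ligand_total, float)
    b = labeled_conc + T + kd
    disc = np.maximum(b ** 2 - 4.0 * labeled_conc * T, 0.0)
    return (b - np.sqrt(disc)) / (2.0 * labeled_conc)


def fraction_bound_hyperbolic(ligand_total, kd: float):
    """Simple saturation isotherm T/(T + Kd) (no depletion)."""
    T = np.asarray(ligand_total, float)
    return T / (T + kd)


def fit_one_site_binding(curve: TitrationCurve,
                         depletion: str = "quadratic",
                         bootstrap: int = 0, seed: int = 0) -> FitResult:
    """Fit baseline, amplitude and Kd (nM) of a one-site isotherm.

    ``depletion="quadratic"`` (default) accounts for the labeled species not
    being in trace amounts; ``"hyperbolic"`` is the simple saturation curve.
    A Kd estimate outside the titrated ligand range is flagged as
    extrapolated; a fit driven to the upper parameter bound is reported as
    unconverged rather than as a spurious finite Kd.
    """
    if depletion not in ("quadratic", "hyperbolic"):
        raise ParameterError("depletion must be 'quadratic' or 'hyperbolic'")
    T, y = curve.ligand_total, curve.signal
    if depletion == "quadratic":
        f = lambda T, b, a, kd: b + a * fraction_bound_quadratic(
            T, kd, curve.labeled_conc)
    else:
        f = lambda T, b, a, kd: b + a * fraction_bound_hyperbolic(T, kd)

    b0 = float(y.min())
    a0 = float(y.max() - y.min())
    half = b0 + 0.5 * a0
    order = np.argsort(T)
    kd0 = float(np.interp(half, y[order], T[order]))
    if not np.isfinite(kd0) or kd0 <= 0:
        kd0 = float(np.median(T[T > 0]))
    kd_cap = 1e4 * float(T.max())
    names = ["baseline", "amplitude", "Kd"]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                f, T, y, p0=[b0, max(a0, 1e-9), kd0],
                bounds=([-np.inf, 0.0, 1e-12], [np.inf, np.inf, kd_cap]),
                maxfev=20000,
            )
    except RuntimeError as exc:
        return FitResult(estimates={}, standard_errors={}, converged=False,
                         residual_rms=float("nan"),
                         flags=[f"non-convergence: {exc}"])
    est = dict(zip(names, (float(v) for v in popt)))
    flags: list[str] = []
    converged = True
    if est["Kd"] >= 0.99 * kd_cap:
        flags.append("Kd unbounded (signal indistinguishable from baseline)")
        converged = False
    if est["amplitude"] <= 1e-6:
        flags.append("no detectable binding amplitude; Kd unbounded")
        converged = False
    tpos = T[T > 0]
    if est["Kd"] < tpos.min() or est["Kd"] > tpos.max():
        flags.append("Kd outside the titrated range (extrapolated)")
    se = _safe_errors(pcov, names)
    if bootstrap > 0 and converged:
        rng = np.random.default_rng(seed)
        boots = []
        n = len(T)
        for _ in range(bootstrap):
            pick = rng.integers(0, n, size=n)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pb, _ = curve_fit(
                        f, T[pick], y[pick], p0=popt,
                        bounds=([-np.inf, 0.0, 1e-12], [np.inf, np.inf, kd_cap]),
                        maxfev=20000)
                boots.append(pb)
            except RuntimeError:
                continue
        if len(boots) >= max(10, bootstrap // 2):
            bstd = np.std(np.array(boots), axis=0, ddof=1)
            se = dict(zip(names, (float(v) for v in bstd)))
            flags.append(f"bootstrap errors ({len(boots)} resamples)")
    resid = y - f(T, *popt)
    return FitResult(estimates=est, standard_errors=se, converged=converged,
                     residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                     flags=flags)
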