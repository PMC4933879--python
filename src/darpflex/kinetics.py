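"""Inference of binding constants from fluorescence experiments.

Three fits cover the standard fluorescence workflow for a 1:1 interaction:

* :func:`fit_titration` — equilibrium titration against the tight-binding
  quadratic isotherm, with the probe concentration fixed from metadata;
* :func:`fit_monoexponential` — chase (decay) and association (rise)
  transients; under chase conditions at saturating competitor the fitted
  ``k_obs`` equals ``k_off``, under pseudo-first-order association it
  equals ``k_on [ligand] + k_off``;
* :func:`fit_kobs_line` — the linear ``k_obs`` vs ligand concentration
  model whose slope is ``k_on``.

:func:`rate_ratio_kd` combines rates into the kinetic ``K_D = k_off/k_on``
with first-order error propagation, and :func:`consistency_check` compares
it with the titration value.

Nonlinear fits use damped least squares (Levenberg-Marquardt) with
analytic model evaluation; the quadratic isotherm is fitted from three
``K_D`` starts because its likelihood is flat in the tight-binding regime.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .models import ExponentialParams, IsothermParams, eval_exponential, eval_isotherm

__all__ = [
    "TitrationDataset",
    "KineticTrace",
    "FitResult",
    "RateConstants",
    "fit_titration",
    "fit_monoexponential",
    "fit_kobs_line",
    "rate_ratio_kd",
    "consistency_check",
    "ConsistencyReport",
    "read_titration_csv",
    "write_titration_csv",
    "read_trace_csv",
    "write_trace_csv",
]


class FitError(RuntimeError):
    pass


class NoTransitionError(FitError):
    """The trace amplitude is indistinguishable from noise."""


@dataclass
class TitrationDataset:
    """Equilibrium titration points for one labeled-probe experiment."""

    ligand_conc: np.ndarray  # mol/L
    delta_fluo: np.ndarray   # a.u.
    probe_conc: float        # [D*], mol/L
    label: str = ""

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.delta_fluo = np.asarray(self.delta_fluo, dtype=float)
        if self.ligand_conc.shape != self.delta_fluo.shape:
            raise ValueError("ligand_conc and delta_fluo must have equal length")
        if self.ligand_conc.size < 4:
            raise ValueError("titration needs at least 4 points")
        if np.any(self.ligand_conc < 0):
            raise ValueError("negative ligand concentrations")
        if self.probe_conc <= 0:
            raise ValueError("probe_conc must be > 0")


@dataclass
class KineticTrace:
    """One time-resolved signal trace (chase, association, or SPR segment)."""

    time: np.ndarray    # s, strictly increasing
    signal: np.ndarray  # a.u.
    ligand_conc: float | None = None  # mol/L, for association traces
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.time.size < 8:
            raise ValueError("trace needs at least 8 points")
        if np.any(self.time < 0) or np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")


@dataclass
class FitResult:
    """Generic least-squares fit outcome."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    residual_rms: float
    n_points: int
    converged: bool
    covariance_available: bool
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "estimates": self.estimates,
                "standard_errors": self.standard_errors,
                "residual_rms": self.residual_rms,
                "n_points": self.n_points,
                "converged": self.converged,
                "covariance_available": self.covariance_available,
                "warnings": self.warnings,
            },
            indent=2,
        )


@dataclass(frozen=True)
class RateConstants:
    """Rate constants with SEs and the propagated kinetic K_D (SI units)."""

    k_on: float
    k_on_se: float
    k_off: float
    k_off_se: float
    k_d_kinetic: float
    k_d_kinetic_se: float
    k_d_titration: float | None = None
    k_d_titration_se: float | None = None

    def table_row(self, label: str = "") -> str:
        """Human-readable row in reporting units (nM, 1/s, 1/(M s))."""
        kd_t = (
            f"{self.k_d_titration * 1e9:.3g}" if self.k_d_titration is not None else "n.d."
        )
        return (
            f"{label:<16s} K_D(titr) {kd_t:>8s} nM | "
            f"k_off {self.k_off:.3g} 1/s | k_on {self.k_on:.3g} 1/(M s) | "
            f"k_off/k_on {self.k_d_kinetic * 1e9:.3g} nM"
        )


def _cov_errors(
    names: list[str], popt: np.ndarray, pcov: np.ndarray | None
) -> tuple[dict[str, float], bool]:
    if pcov is None or not np.all(np.isfinite(pcov)):
        return {n: math.nan for n in names}, False
    diag = np.diag(pcov)
    if np.any(diag < 0):
        return {n: math.nan for n in names}, False
    return {n: float(math.sqrt(v)) for n, v in zip(names, diag)}, True


def fit_titration(data: TitrationDataset) -> FitResult:
    """Fit the tight-binding isotherm to a titration; returns K_D, Fluo_Max.

    ``[D*]`` is fixed from the dataset metadata.  Three ``K_D`` starts are
    tried (a half-saturation crossing-point heuristic and 0.1x / 10x of it)
    and the best sum of squares wins.  A warning is attached when the data
    do not reach 60% of the fitted saturation signal.
    """
    t = data.ligand_conc
    y = data.delta_fluo
    d = data.probe_conc

    span = y.max() - y.min()
    if span <= 0 or not np.isfinite(span):
        return FitResult(
            estimates={}, standard_errors={}, residual_rms=float(np.std(y)),
            n_points=t.size, converged=False, covariance_available=False,
            warnings=["degenerate titration: signal has no dynamic range"],
        )

    # K_D is fitted on a log scale: it is a positive scale parameter that can
    # sit many orders of magnitude below 1 mol/L, where finite-difference
    # steps on the linear scale are ill-conditioned.
    def model(tt: np.ndarray, log_k_d: float, fluo_max: float) -> np.ndarray:
        return eval_isotherm(IsothermParams(math.exp(log_k_d), fluo_max, d), tt)

    # crossing-point heuristic: ligand concentration at half-maximal signal,
    # corrected for the probe bound there (free ligand = total - D*/2)
    half = y.min() + 0.5 * span
    order = np.argsort(t)
    t_half = float(np.interp(half, y[order], t[order]))
    kd0 = max(t_half - d / 2.0, 0.05 * d)
    fmax0 = max(float(y.max()), 1e-12)

    best: tuple[float, np.ndarray, np.ndarray | None] | None = None
    for kd_start in (kd0, 0.1 * kd0, 10.0 * kd0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    model, t, y, p0=[math.log(kd_start), fmax0],
                    maxfev=10000,
                )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)

    if best is None:
        return FitResult(
            estimates={}, standard_errors={}, residual_rms=float(np.std(y)),
            n_points=t.size, converged=False, covariance_available=False,
            warnings=["isotherm fit did not converge from any start"],
        )

    ssr, popt, pcov = best
    k_d_hat = float(math.exp(popt[0]))
    names = ["k_d", "fluo_max"]
    errors, cov_ok = _cov_errors(names, popt, pcov)
    if cov_ok:
        errors["k_d"] = k_d_hat * errors["k_d"]  # delta method from log scale
    notes: list[str] = []
    if y.max() < 0.6 * popt[1]:
        notes.append(
            "no saturation coverage: max signal < 60% of fitted Fluo_Max"
        )
    if not cov_ok:
        notes.append("singular covariance: standard errors unavailable")
    return FitResult(
        estimates={"k_d": k_d_hat, "fluo_max": float(popt[1]),
                   "probe_conc": d},
        standard_errors=errors,
        residual_rms=float(math.sqrt(ssr / t.size)),
        n_points=int(t.size),
        converged=True,
        covariance_available=cov_ok,
        warnings=notes,
    )


def _loglinear_kobs_guess(
    t: np.ndarray, y: np.ndarray, direction: str
) -> tuple[float, float, float]:
    """Initialize (baseline, amplitude, k_obs) by log-linear regression."""
    if direction == "decay":
        baseline = float(y[-1])
        amplitude = float(y[0] - baseline)
    else:
        baseline = float(y[0])
        amplitude = float(y[-1] - baseline)
    resid = (y - baseline) if direction == "decay" else (baseline + amplitude - y)
    sign = 1.0 if amplitude >= 0 else -1.0
    z = sign * resid
    mask = z > 1e-3 * abs(amplitude) if amplitude != 0 else np.zeros_like(z, bool)
    if mask.sum() >= 3:
        slope = np.polyfit(t[mask], np.log(z[mask]), 1)[0]
        k0 = max(-float(slope), 1e-12)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-12)
    return baseline, amplitude, k0


def fit_monoexponential(trace: KineticTrace, direction: str) -> FitResult:
    """Fit a mono-exponential transient; returns baseline, amplitude, k_obs.

    Raises :class:`NoTransitionError` when the fitted amplitude is below
    three times the residual RMS (no resolvable transition).  A warning is
    attached when the trace spans fewer than two half-lives.
    """
    if direction not in ("decay", "rise"):
        raise ValueError(f"direction must be 'decay' or 'rise', got {direction!r}")
    t, y = trace.time, trace.signal
    b0, a0, k0 = _loglinear_kobs_guess(t, y, direction)

    def model(tt: np.ndarray, baseline: float, amplitude: float, k_obs: float):
        p = ExponentialParams(baseline, amplitude, max(k_obs, 1e-300), direction)
        return eval_exponential(p, tt)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=[b0, a0 if a0 != 0 else np.ptp(y) or 1.0, k0],
                bounds=([-np.inf, -np.inf, 1e-15], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"mono-exponential fit failed: {exc}") from exc

    resid = model(t, *popt) - y
    rms = float(np.sqrt(np.mean(resid**2)))
    # floor for exactly noise-free flat traces (rms == 0, amplitude == 0)
    threshold = max(3.0 * rms, 1e-10 * max(1.0, abs(popt[0])))
    if abs(popt[1]) < threshold:
        raise NoTransitionError(
            f"amplitude {popt[1]:.3g} indistinguishable from noise (rms {rms:.3g})"
        )
    names = ["baseline", "amplitude", "k_obs"]
    errors, cov_ok = _cov_errors(names, popt, pcov)
    notes: list[str] = []
    if (t[-1] - t[0]) * popt[2] < 2.0 * math.log(2.0):
        notes.append("trace spans fewer than two half-lives of the transition")
    return FitResult(
        estimates=dict(zip(names, map(float, popt))),
        standard_errors=errors,
        residual_rms=rms,
        n_points=int(t.size),
        converged=True,
        covariance_available=cov_ok,
        warnings=notes,
    )


def fit_kobs_line(
    series: list[tuple[float, float]] | list[tuple[float, float, float]],
) -> FitResult:
    """Linear ``k_obs = k_on [ligand] + intercept`` regression.

    Each series element is ``(ligand_conc, k_obs)`` or
    ``(ligand_conc, k_obs, k_obs_se)``.  With SEs present the regression is
    weighted by ``1/SE^2``.  The slope is ``k_on``; the intercept is
    reported but the chase value is the preferred ``k_off``.
    """
    if len(series) < 3:
        raise FitError("k_obs line needs at least 3 concentrations")
    arr = np.asarray([list(row) for row in series], dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 3:
        raise FitError("k_obs line needs at least 3 distinct concentrations")
    if arr.shape[1] >= 3 and np.all(arr[:, 2] > 0):
        w = 1.0 / arr[:, 2] ** 2
    else:
        w = np.ones_like(x)

    # weighted least squares, closed form
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    dof = x.size - 2
    chi2 = (w * resid**2).sum()
    scale = chi2 / dof if dof > 0 else math.nan
    se_slope = math.sqrt(scale / sxx) if dof > 0 else math.nan
    se_intercept = (
        math.sqrt(scale * (1.0 / sw + xbar**2 / sxx)) if dof > 0 else math.nan
    )
    result = FitResult(
        estimates={"k_on": float(slope), "intercept": float(intercept)},
        standard_errors={"k_on": se_slope, "intercept": se_intercept},
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(x.size),
        converged=True,
        covariance_available=dof > 0,
    )
    if slope <= 0:
        result.converged = False
        result.warnings.append("non-physical: fitted k_on slope is not positive")
        raise FitError("non-physical negative k_obs slope (k_on <= 0)")
    return result


def rate_ratio_kd(
    k_off: float, k_on: float, k_off_se: float = 0.0, k_on_se: float = 0.0
) -> tuple[float, float]:
    """Kinetic ``K_D = k_off / k_on`` with first-order SE propagation.

    ``SE = K_D sqrt((SE_koff/k_off)^2 + (SE_kon/k_on)^2)``.
    """
    if k_on <= 0:
        raise ValueError(f"k_on must be > 0, got {k_on!r}")
    if k_off < 0:
        raise ValueError(f"k_off must be >= 0, got {k_off!r}")
    k_d = k_off / k_on
    if k_off == 0:
        return k_d, 0.0
    se = k_d * math.sqrt((k_off_se / k_off) ** 2 + (k_on_se / k_on) ** 2)
    return k_d, se


@dataclass(frozen=True)
class ConsistencyReport:
    ratio: float
    passed: bool
    tolerance_factor: float


def consistency_check(
    k_d_titration: float, k_d_kinetic: float, tolerance_factor: float = 2.0
) -> ConsistencyReport:
    """Agreement between equilibrium and kinetic K_D as a max/min ratio."""
    if k_d_titration <= 0 or k_d_kinetic <= 0:
        raise ValueError("both K_D values must be > 0")
    ratio = max(k_d_titration, k_d_kinetic) / min(k_d_titration, k_d_kinetic)
    return ConsistencyReport(
        ratio=ratio, passed=ratio <= tolerance_factor,
        tolerance_factor=tolerance_factor,
    )


# ---------------------------------------------------------------------------
# CSV I/O. Commented header lines ("# key: value") carry metadata.

def _read_csv_with_meta(text: str) -> tuple[pd.DataFrame, dict[str, str]]:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("# ").rstrip()
            if ":" in stripped:
                key, value = stripped.split(":", 1)
                meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    frame = pd.read_csv(io.StringIO("\n".join(body)), float_precision="round_trip")
    return frame, meta


def write_titration_csv(data: TitrationDataset) -> str:
    lines = [
        f"# label: {data.label}",
        f"# probe_conc_M: {float(data.probe_conc)!r}",
        "concentration_M,signal",
    ]
    lines += [f"{float(c)!r},{float(s)!r}" for c, s in zip(data.ligand_conc, data.delta_fluo)]
    return "\n".join(lines) + "\n"


def read_titration_csv(text: str) -> TitrationDataset:
    frame, meta = _read_csv_with_meta(text)
    if "probe_conc_M" not in meta:
        raise ValueError("titration CSV is missing the probe_conc_M header comment")
    return TitrationDataset(
        ligand_conc=frame["concentration_M"].to_numpy(),
        delta_fluo=frame["signal"].to_numpy(),
        probe_conc=float(meta["probe_conc_M"]),
        label=meta.get("label", ""),
    )


def write_trace_csv(trace: KineticTrace) -> str:
    lines = [f"# label: {trace.label}"]
    if trace.ligand_conc is not None:
        lines.append(f"# ligand_conc_M: {float(trace.ligand_conc)!r}")
    lines.append("time_s,signal")
    lines += [f"{float(t)!r},{float(s)!r}" for t, s in zip(trace.time, trace.signal)]
    return "\n".join(lines) + "\n"


def read_trace_csv(text: str) -> KineticTrace:
    frame, meta = _read_csv_with_meta(text)
    conc = float(meta["ligand_conc_M"]) if "ligand_conc_M" in meta else None
    return KineticTrace(
        time=frame["time_s"].to_numpy(),
        signal=frame["signal"].to_numpy(),
        ligand_conc=conc,
        label=meta.get("label", ""),
    )
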