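"""1:1 Langmuir fitting of SPR sensorgram sets.

Kinetic fitting (per-curve or global across an analyte concentration
series) and the equilibrium plateau analysis.  The fit model is the
closed-form Langmuir sensorgram (flow cell, no analyte depletion, no
mass-transport limitation) with one constant baseline offset per curve as
the only nuisance parameter.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .kinetics import FitResult, rate_ratio_kd
from .models import LangmuirParams, eval_langmuir_sensorgram

__all__ = [
    "Sensorgram",
    "PlateauSeries",
    "fit_langmuir",
    "plateau_kd",
    "extract_plateaus",
    "read_sensorgram_csv",
    "write_sensorgram_csv",
]


class SprFitError(RuntimeError):
    pass


class KdAboveRangeError(SprFitError):
    """The response is linear in concentration: K_D above the tested range."""


@dataclass
class Sensorgram:
    """One SPR trace at a single analyte concentration.

    ``assoc_window`` and ``dissoc_window`` are ``(t0, t1)`` / ``(t1, t2)``
    pairs on the trace's time axis; injection starts at ``t0``.
    """

    time: np.ndarray       # s
    response: np.ndarray   # RU
    analyte_conc: float    # mol/L
    assoc_window: tuple[float, float]
    dissoc_window: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have equal length")
        if self.analyte_conc <= 0:
            raise ValueError("analyte_conc must be > 0")
        t0, t1 = self.assoc_window
        t1b, t2 = self.dissoc_window
        if not (t0 < t1 <= t1b < t2):
            raise ValueError("windows must be ordered: assoc before dissoc")
        if t0 < self.time[0] - 1e-9 or t2 > self.time[-1] + 1e-9:
            raise ValueError("windows must lie within the time range")

    def phase_masks(self) -> tuple[np.ndarray, np.ndarray]:
        t0, t1 = self.assoc_window
        _, t2 = self.dissoc_window
        assoc = (self.time >= t0) & (self.time <= t1)
        dissoc = (self.time > t1) & (self.time <= t2)
        return assoc, dissoc


@dataclass
class PlateauSeries:
    """Plateau response vs analyte concentration for equilibrium analysis."""

    concentrations: np.ndarray  # mol/L
    plateau_response: np.ndarray  # RU

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.plateau_response = np.asarray(self.plateau_response, dtype=float)
        if self.concentrations.shape != self.plateau_response.shape:
            raise ValueError("arrays must have equal length")
        if self.concentrations.size < 3:
            raise ValueError("plateau analysis needs at least 3 concentrations")
        if np.any(self.plateau_response < 0):
            raise ValueError("negative plateau responses")


def _model_curve(
    sg: Sensorgram, k_on: float, k_off: float, r_max: float, offset: float
) -> np.ndarray:
    """Model response over both phases of one sensorgram."""
    t0, _ = sg.assoc_window
    assoc_mask, dissoc_mask = sg.phase_masks()
    params = LangmuirParams(k_on, k_off, r_max, sg.analyte_conc)
    ta = sg.time[assoc_mask] - t0
    td = sg.time[dissoc_mask] - t0
    r_assoc, r_dissoc = eval_langmuir_sensorgram(params, ta, td)
    out = np.empty(assoc_mask.sum() + dissoc_mask.sum())
    out[: r_assoc.size] = r_assoc
    out[r_assoc.size :] = r_dissoc
    return out + offset


def fit_langmuir(
    sensorgrams: list[Sensorgram], mode: str = "global", fit_offsets: bool = True
) -> FitResult:
    """Fit 1:1 Langmuir kinetics to one or more sensorgrams.

    ``mode="global"`` shares ``k_on``, ``k_off`` and ``r_max`` across all
    curves (requires >= 3 concentrations); ``mode="per_curve"`` fits each
    curve independently and reports per-curve estimates under suffixed
    names.  Rates are optimized on a log scale, which keeps them positive
    and conditions the problem across orders of magnitude.  Warnings flag a
    dissociation window shorter than ``0.2 / k_off`` (k_off poorly
    determined) and report the per-curve residual RMS.
    """
    if not sensorgrams:
        raise SprFitError("need at least one sensorgram")
    if mode not in ("global", "per_curve"):
        raise ValueError(f"mode must be 'global' or 'per_curve', got {mode!r}")
    if mode == "per_curve":
        merged_est: dict[str, float] = {}
        merged_se: dict[str, float] = {}
        notes: list[str] = []
        rms_all = []
        for i, sg in enumerate(sensorgrams):
            sub = fit_langmuir([sg], mode="global", fit_offsets=fit_offsets)
            tag = sg.label or f"curve{i}"
            for key, value in sub.estimates.items():
                merged_est[f"{key}[{tag}]"] = value
            for key, value in sub.standard_errors.items():
                merged_se[f"{key}[{tag}]"] = value
            notes += [f"{tag}: {w}" for w in sub.warnings]
            rms_all.append(sub.residual_rms)
        return FitResult(
            estimates=merged_est, standard_errors=merged_se,
            residual_rms=float(np.mean(rms_all)),
            n_points=sum(s.time.size for s in sensorgrams),
            converged=True, covariance_available=True, warnings=notes,
        )

    n_curves = len(sensorgrams)
    if n_curves > 1 and len({sg.analyte_conc for sg in sensorgrams}) < 3:
        raise SprFitError("global mode requires >= 3 distinct concentrations")

    responses = []
    for sg in sensorgrams:
        am, dm = sg.phase_masks()
        responses.append(sg.response[np.concatenate([np.nonzero(am)[0], np.nonzero(dm)[0]])])
    y = np.concatenate(responses)
    span = float(y.max() - y.min())
    if span <= 0 or span < 1e-9 * max(abs(float(y.max())), 1.0):
        raise SprFitError("flat responses: nothing to fit")

    r_max0 = max(span, 1e-9)
    c_mid = float(np.median([sg.analyte_conc for sg in sensorgrams]))
    # crude initial rates: half-life ~ assoc window / 3
    t_assoc = sensorgrams[0].assoc_window[1] - sensorgrams[0].assoc_window[0]
    k_obs0 = 3.0 / t_assoc
    k_off0 = max(0.1 * k_obs0, 1e-6)
    k_on0 = max((k_obs0 - k_off0) / c_mid, 1e-3)

    n_off = n_curves if fit_offsets else 0

    def residuals(theta: np.ndarray) -> np.ndarray:
        k_on, k_off, r_max = np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[2])
        offs = theta[3 : 3 + n_off] if n_off else np.zeros(n_curves)
        parts = []
        for sg, resp, off in zip(sensorgrams, responses, offs):
            parts.append(_model_curve(sg, k_on, k_off, r_max, off) - resp)
        return np.concatenate(parts)

    theta0 = np.concatenate(
        [np.log([k_on0, k_off0, r_max0]), np.zeros(n_off)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = optimize.least_squares(residuals, theta0, method="lm", max_nfev=20000)
    if not sol.success:
        raise SprFitError(f"Langmuir fit did not converge: {sol.message}")

    k_on, k_off, r_max = map(float, np.exp(sol.x[:3]))
    dof = y.size - sol.x.size
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    # covariance on the log/linear parameter vector from the Jacobian
    se = {name: math.nan for name in ("k_on", "k_off", "r_max")}
    cov_ok = False
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (sol.fun @ sol.fun) / dof
            sigma_log = np.sqrt(np.clip(np.diag(cov)[:3], 0, None))
            # delta method back to linear scale
            se = {
                "k_on": k_on * float(sigma_log[0]),
                "k_off": k_off * float(sigma_log[1]),
                "r_max": r_max * float(sigma_log[2]),
            }
            cov_ok = True
        except np.linalg.LinAlgError:
            pass

    k_d, k_d_se = rate_ratio_kd(k_off, k_on, se.get("k_off", 0.0) or 0.0,
                                se.get("k_on", 0.0) or 0.0)
    notes = []
    for sg in sensorgrams:
        t_diss = sg.dissoc_window[1] - sg.dissoc_window[0]
        if t_diss < 0.2 / k_off:
            notes.append(
                f"{sg.label or 'curve'}: dissociation window {t_diss:.3g} s "
                f"< 0.2/k_off; k_off poorly determined"
            )
        k_obs = k_on * sg.analyte_conc + k_off
        t_a = sg.assoc_window[1] - sg.assoc_window[0]
        if t_a * k_obs >= 4.6:  # R(t_end) >= 99% of R_eq
            notes.append(f"{sg.label or 'curve'}: plateau reached")

    estimates = {"k_on": k_on, "k_off": k_off, "r_max": r_max, "k_d": k_d}
    std_errors = {**se, "k_d": k_d_se}
    if n_off:
        for sg, off in zip(sensorgrams, sol.x[3:]):
            estimates[f"offset[{sg.label or 'curve'}]"] = float(off)
    return FitResult(
        estimates=estimates, standard_errors=std_errors,
        residual_rms=rms, n_points=int(y.size),
        converged=True, covariance_available=cov_ok, warnings=notes,
    )


def extract_plateaus(sensorgrams: list[Sensorgram]) -> PlateauSeries:
    """Plateau response per curve: mean of the last 10% of the association
    window, baseline-referenced to the pre-injection response.

    A curve still rising by more than 1% of its plateau over that window is
    allowed but the caller should treat the value as a lower bound (the
    kinetic fit flags plateau attainment explicitly).
    """
    concs, plateaus = [], []
    for sg in sensorgrams:
        t0, t1 = sg.assoc_window
        tail = (sg.time >= t1 - 0.1 * (t1 - t0)) & (sg.time <= t1)
        pre = sg.time < t0
        baseline = float(sg.response[pre].mean()) if pre.any() else 0.0
        concs.append(sg.analyte_conc)
        plateaus.append(float(sg.response[tail].mean()) - baseline)
    return PlateauSeries(np.array(concs), np.array(plateaus))


def plateau_kd(series: PlateauSeries, kinetic_kd: float | None = None) -> FitResult:
    """Equilibrium K_D from plateau responses via ``R_eq = R_max C/(K_D+C)``.

    Raises :class:`KdAboveRangeError` when the responses show no curvature
    (fitted K_D far above the tested concentrations, i.e. the hyperbola is
    indistinguishable from a line).  When ``kinetic_kd`` is given, the
    agreement ratio with it is reported.
    """
    c = series.concentrations
    r = series.plateau_response

    # K_D on a log scale: well-conditioned finite differences for
    # nanomolar-range constants, and positivity for free
    def model(cc: np.ndarray, log_k_d: float, r_max: float) -> np.ndarray:
        return r_max * cc / (np.exp(log_k_d) + cc)

    def _linear_in_conc() -> bool:
        # hyperbola degenerate: responses indistinguishable from a line
        slope, intercept = np.polyfit(c, r, 1)
        resid = r - (slope * c + intercept)
        return float(np.sqrt(np.mean(resid**2))) < 1e-3 * max(float(np.ptp(r)), 1e-12)

    kd0 = float(np.median(c))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        try:
            popt, pcov = optimize.curve_fit(
                model, c, r, p0=[math.log(kd0), float(r.max()) * 1.5 or 1.0],
                maxfev=10000,
            )
        except (RuntimeError, ValueError) as exc:
            if _linear_in_conc():
                raise KdAboveRangeError(
                    "responses linear in concentration; K_D above the "
                    f"tested range (max {c.max():.3g} M)"
                ) from exc
            raise SprFitError(f"plateau fit failed: {exc}") from exc

    popt = np.array([math.exp(popt[0]), popt[1]])
    if pcov is not None and np.all(np.isfinite(pcov)):
        pcov = pcov.copy()
        pcov[0, :] *= popt[0]
        pcov[:, 0] *= popt[0]
    if popt[0] > 20.0 * c.max():
        raise KdAboveRangeError(
            f"responses linear in concentration; K_D (>= {popt[0]:.3g} M) "
            f"above the tested range (max {c.max():.3g} M)"
        )
    names = ["k_d", "r_max"]
    diag = np.diag(pcov)
    cov_ok = bool(np.all(np.isfinite(diag)) and np.all(diag >= 0))
    se = {n: float(math.sqrt(v)) if cov_ok else math.nan
          for n, v in zip(names, diag)}
    resid = model(c, *popt) - r
    result = FitResult(
        estimates={"k_d": float(popt[0]), "r_max": float(popt[1])},
        standard_errors=se,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(c.size),
        converged=True, covariance_available=cov_ok,
    )
    if kinetic_kd is not None and kinetic_kd > 0:
        ratio = max(popt[0], kinetic_kd) / min(popt[0], kinetic_kd)
        result.estimates["agreement_ratio_vs_kinetic"] = float(ratio)
    return result


def write_sensorgram_csv(sg: Sensorgram) -> str:
    lines = [
        f"# label: {sg.label}",
        f"# analyte_conc_M: {float(sg.analyte_conc)!r}",
        f"# assoc_window_s: {float(sg.assoc_window[0])!r} {float(sg.assoc_window[1])!r}",
        f"# dissoc_window_s: {float(sg.dissoc_window[0])!r} {float(sg.dissoc_window[1])!r}",
        "time_s,response_RU",
    ]
    lines += [f"{float(t)!r},{float(r)!r}" for t, r in zip(sg.time, sg.response)]
    return "\n".join(lines) + "\n"


def read_sensorgram_csv(text: str) -> Sensorgram:
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
    aw = tuple(float(v) for v in meta["assoc_window_s"].split())
    dw = tuple(float(v) for v in meta["dissoc_window_s"].split())
    return Sensorgram(
        time=frame["time_s"].to_numpy(),
        response=frame["response_RU"].to_numpy(),
        analyte_conc=float(meta["analyte_conc_M"]),
        assoc_window=aw, dissoc_window=dw,
        label=meta.get("label", ""),
    )
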