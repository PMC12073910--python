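"""Bounded nonlinear least-squares fitting of decay curves.

Each decay curve is fitted by Levenberg-Marquardt least squares (via
lmfit) with an overall scale S0 as a free positive nuisance parameter and
model parameters constrained to the physically admissible box: apparent
diffusivities in (0, 1] um^2/ms (free-metabolite ceiling) and kurtosis
parameters in [0, 3]. The b-range entering the objective depends on the
model: the Gaussian representation uses b < 5 ms/um^2, the kurtosis
representation b < 10, and the stick models all b-values.

Estimates that converge onto their lower bound are flagged; downstream
trajectory analysis excludes them as unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
import pandas as pd
from scipy.special import erf

from .cohort import DecayCurve, SubjectRecord
from .protocol import DiffusionProtocol

__all__ = ["FitSpec", "FitResult", "select_brange", "fit_model", "fit_cohort",
           "MODEL_NAMES", "COHORT_TABLE_COLUMNS"]

log = logging.getLogger(__name__)

MODEL_NAMES = ("monoexp", "kurtosis", "astrosticks", "mod_astrosticks")

# b-range rule per model (exclusive upper cutoff in ms/um^2; None = all b)
_DEFAULT_BMAX = {
    "monoexp": 5.0,
    "kurtosis": 10.0,
    "astrosticks": None,
    "mod_astrosticks": None,
}

_PARAM_BOUNDS = {
    "monoexp": {"ADC": (1e-6, 1.0)},
    "kurtosis": {"ADC": (1e-6, 1.0), "K": (0.0, 3.0)},
    "astrosticks": {"Dintra": (1e-6, 1.0)},
    "mod_astrosticks": {"Dintra": (1e-6, 1.0), "Kintra": (0.0, 3.0)},
}

COHORT_TABLE_COLUMNS = [
    "subject_id", "age", "sex", "region", "metabolite", "model",
    "parameter", "estimate", "stderr", "at_lower_bound", "valid", "n_points",
]


@dataclass(frozen=True)
class FitSpec:
    """Configuration of one model fit.

    ``b_max`` is the exclusive cutoff of the fitted b-range (None keeps
    every b-value); ``bounds`` maps parameter name to (lower, upper);
    ``n_restarts`` seeded random restarts are run in addition to the
    deterministic initialization and the best objective is kept.
    """

    model: str
    b_max: float | None = None
    bounds: dict = field(default_factory=dict)
    n_restarts: int = 5
    max_nfev: int = 2000
    at_bound_tol: float = 1e-4
    weight_by_sd: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        object.__setattr__(
            self, "b_max",
            _DEFAULT_BMAX[self.model] if self.b_max is None else self.b_max,
        )
        merged = {**_PARAM_BOUNDS[self.model], **self.bounds}
        object.__setattr__(self, "bounds", merged)

    @property
    def param_names(self) -> tuple:
        return tuple(_PARAM_BOUNDS[self.model])


@dataclass
class FitResult:
    """Outcome of one bounded least-squares fit."""

    model: str
    params: dict
    stderr: dict
    s0: float
    s0_stderr: float | None
    b_used: np.ndarray
    residuals: np.ndarray
    chisqr: float
    redchi: float
    converged: bool
    at_lower_bound: dict
    valid: bool

    @property
    def n_points(self) -> int:
        return self.b_used.size

    def predict(self, b) -> np.ndarray:
        """Model amplitude S0 * S(b) at the fitted parameters."""
        return self.s0 * _eval_model(self.model, np.asarray(b, float), self.params)


def select_brange(spec: FitSpec, protocol: DiffusionProtocol) -> np.ndarray:
    """b-values of the protocol entering this model's objective."""
    b = protocol.b_array()
    if spec.b_max is not None:
        b = b[b < spec.b_max]
    if b.size == 0:
        raise ValueError(
            f"b-range rule for {spec.model!r} leaves no b-values"
        )
    return b


def _eval_model(model: str, b: np.ndarray, p: dict) -> np.ndarray:
    """Raw forward-model evaluation without validation or warnings.

    Used inside the optimizer where parameters sweep the full bounded box,
    including regions (e.g. beyond the kurtosis turnover) where the public
    API would warn.
    """
    if model == "monoexp":
        return np.exp(-b * p["ADC"])
    if model == "kurtosis":
        bd = b * p["ADC"]
        return np.exp(-bd + bd**2 * p["K"] / 6.0)
    if model == "astrosticks":
        x = np.maximum(b * p["Dintra"], 0.0)
        out = np.empty_like(x)
        small = x < 1e-6
        xs = x[small]
        out[small] = 1.0 - xs / 3.0 + xs**2 / 10.0 - xs**3 / 42.0
        sq = np.sqrt(x[~small])
        out[~small] = (np.sqrt(np.pi) / 2.0) * erf(sq) / sq
        return out
    if model == "mod_astrosticks":
        from .models import _gauss_legendre_01

        c, w = _gauss_legendre_01(96)
        bb = b[:, None]
        deff = p["Dintra"] * (1.0 - p["Kintra"] * p["Dintra"] * bb * c**2)
        return np.exp(-bb * deff * c**2) @ w
    raise ValueError(model)


def _deff_violation(model: str, b: np.ndarray, p: dict) -> float:
    """How far the effective diffusivity dips below zero (0 when valid)."""
    if model != "mod_astrosticks":
        return 0.0
    return max(0.0, p["Kintra"] * p["Dintra"] * float(np.max(b)) - 1.0)


def _loglinear_adc(b: np.ndarray, amp: np.ndarray) -> tuple[float, float]:
    """Seed (ADC, S0) from the two lowest-b points."""
    adc = (np.log(amp[0]) - np.log(amp[1])) / (b[1] - b[0])
    adc = float(np.clip(adc, 1e-5, 1.0 - 1e-5))
    s0 = float(amp[0] * np.exp(b[0] * adc))
    return adc, s0


def _initializations(spec: FitSpec, b: np.ndarray, amp: np.ndarray,
                     seed: int) -> list[dict]:
    """Deterministic seed point plus seeded random restarts within bounds."""
    adc0, s0 = _loglinear_adc(b, amp)
    base = {"monoexp": {"ADC": adc0},
            "kurtosis": {"ADC": adc0, "K": 1.0},
            "astrosticks": {"Dintra": min(3.0 * adc0, 1.0 - 1e-5)},
            "mod_astrosticks": {"Dintra": min(3.0 * adc0, 1.0 - 1e-5),
                                "Kintra": 0.05}}[spec.model]
    inits = [{"S0": s0, **base}]
    rng = np.random.default_rng(seed)
    for _ in range(spec.n_restarts):
        draw = {"S0": s0 * rng.uniform(0.8, 1.2)}
        for name in spec.param_names:
            lo, hi = spec.bounds[name]
            draw[name] = rng.uniform(max(lo, 1e-5), hi)
        inits.append(draw)
    return inits


def fit_model(curve: DecayCurve, spec: FitSpec, seed: int = 0) -> FitResult:
    """Fit one model to one decay curve.

    Minimizes the (by default unweighted) sum of squared residuals between
    measured amplitudes and S0 * S(b; params) over the model's b-range,
    from a deterministic initialization plus ``spec.n_restarts`` seeded
    restarts. Parameter sets driving the modified-stick effective
    diffusivity negative are pushed away by a large smooth penalty and the
    returned result is marked invalid if the optimum still lies there.

    1-sigma uncertainties come from the covariance of the least-squares
    solution; ``at_lower_bound`` flags estimates within ``at_bound_tol``
    of their lower bound.
    """
    mask = np.ones(curve.b.size, dtype=bool)
    if spec.b_max is not None:
        mask = curve.b < spec.b_max
    b = curve.b[mask]
    amp = curve.amplitude[mask]
    n_free = len(spec.param_names) + 1  # + S0
    if b.size < n_free + 1:
        raise ValueError(
            f"{spec.model}: {b.size} points in range for {n_free} parameters"
        )
    if np.any(amp <= 0):
        raise ValueError("amplitudes must be positive")

    weights = None
    if spec.weight_by_sd and curve.amplitude_sd is not None:
        sd = curve.amplitude_sd[mask]
        if np.all(sd > 0):
            weights = 1.0 / sd

    def residual(params: lmfit.Parameters) -> np.ndarray:
        p = {k: params[k].value for k in spec.param_names}
        model_amp = params["S0"].value * _eval_model(spec.model, b, p)
        r = amp - model_amp
        if weights is not None:
            r = r * weights
        viol = _deff_violation(spec.model, b, p)
        if viol > 0.0:
            # smooth, dominating penalty steers LM back into Deff >= 0
            r = r + 1e3 * viol
        return r

    best = None
    for init in _initializations(spec, b, amp, seed):
        params = lmfit.Parameters()
        params.add("S0", value=init["S0"], min=1e-12)
        for name in spec.param_names:
            lo, hi = spec.bounds[name]
            params.add(name, value=init[name], min=lo, max=hi)
        try:
            res = lmfit.minimize(residual, params, method="leastsq",
                                 max_nfev=spec.max_nfev)
        except Exception:  # numerical blow-up on a bad restart
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None:
        nan = {k: np.nan for k in spec.param_names}
        return FitResult(spec.model, nan, dict(nan), np.nan, None, b,
                         np.full_like(b, np.nan), np.nan, np.nan, False,
                         {k: False for k in spec.param_names}, False)

    est = {k: float(best.params[k].value) for k in spec.param_names}
    err = {k: (float(best.params[k].stderr)
               if best.params[k].stderr is not None else np.nan)
           for k in spec.param_names}
    at_lb = {k: est[k] < spec.bounds[k][0] + spec.at_bound_tol
             for k in spec.param_names}
    valid = _deff_violation(spec.model, b, est) == 0.0
    s0err = (float(best.params["S0"].stderr)
             if best.params["S0"].stderr is not None else None)
    return FitResult(
        model=spec.model,
        params=est,
        stderr=err,
        s0=float(best.params["S0"].value),
        s0_stderr=s0err,
        b_used=b,
        residuals=np.asarray(best.residual, dtype=float),
        chisqr=float(best.chisqr),
        redchi=float(best.redchi),
        converged=bool(best.success),
        at_lower_bound=at_lb,
        valid=valid,
    )


def default_specs() -> list[FitSpec]:
    """One FitSpec per model, at the default b-range rules and bounds."""
    return [FitSpec(m) for m in MODEL_NAMES]


def fit_cohort(records: list[SubjectRecord],
               specs: list[FitSpec] | None = None,
               seed: int = 0) -> pd.DataFrame:
    """Fit every (subject, region, metabolite, model) cell of a cohort.

    Returns a tidy table, one row per estimated parameter, with columns
    ``COHORT_TABLE_COLUMNS``. Failed or missing fits yield rows with NaN
    estimates and ``valid=False`` rather than being silently dropped.
    """
    if specs is None:
        specs = default_specs()
    rows = []
    for rec in records:
        for metab, curve in sorted(rec.curves.items()):
            for spec in specs:
                base = dict(subject_id=rec.subject_id, age=rec.age,
                            sex=rec.sex, region=rec.region, metabolite=metab,
                            model=spec.model)
                try:
                    fr = fit_model(curve, spec, seed=seed)
                except Exception as exc:
                    log.warning("fit failed for %s/%s/%s/%s: %s",
                                rec.subject_id, rec.region, metab,
                                spec.model, exc)
                    for pname in spec.param_names:
                        rows.append({**base, "parameter": pname,
                                     "estimate": np.nan, "stderr": np.nan,
                                     "at_lower_bound": False, "valid": False,
                                     "n_points": 0})
                    continue
                for pname in spec.param_names:
                    rows.append({**base, "parameter": pname,
                                 "estimate": fr.params[pname],
                                 "stderr": fr.stderr[pname],
                                 "at_lower_bound": fr.at_lower_bound[pname],
                                 "valid": fr.valid and fr.converged,
                                 "n_points": fr.n_points})
    return pd.DataFrame(rows, columns=COHORT_TABLE_COLUMNS)
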