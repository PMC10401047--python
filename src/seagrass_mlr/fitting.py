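"""Nonlinear least-squares fitting of the photoacclimation sigmoids.

Each of the three photosynthesis–irradiance parameters (P_max, I_k, R)
observed across shading treatments is fitted independently against
instantaneous irradiance with a four-parameter logistic curve, using the
Levenberg–Marquardt algorithm (via lmfit). Fits are per-parameter
univariate least squares without weights; standard errors come from the
local curvature at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import AcclimationModel, SigmoidResponse

__all__ = ["ShadingDataset", "FitResult", "fit_sigmoid", "fit_acclimation_model"]

#: Relative spread of y below which the response is flagged unidentifiable.
FLAT_DATA_RTOL = 1e-8

REQUIRED_COLUMNS = ("percent_si", "irradiance_umol", "pmax", "ik", "r")


@dataclass(frozen=True)
class ShadingDataset:
    """Per-treatment P–I parameter estimates from a shading experiment.

    ``data`` must carry columns ``percent_si``, ``irradiance_umol`` and
    one column per P–I parameter (``pmax``, ``ik``, ``r``); missing
    parameter columns are tolerated and reported by the model fit.
    ``provenance`` records whether the table is synthetic or user-supplied.
    """

    data: pd.DataFrame
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        missing = [c for c in ("percent_si", "irradiance_umol") if c not in self.data]
        if missing:
            raise ValueError(f"shading dataset missing column(s): {missing}")
        si = self.data["percent_si"].to_numpy(dtype=float)
        if np.any((si <= 0) | (si > 100)):
            raise ValueError("percent_si values must lie in (0, 100]")
        # note: the >= 4 distinct light levels needed for a 4-parameter
        # fit are checked at fit time, so diagnostic single-level
        # datasets (e.g. noise calibration draws) remain representable

    @classmethod
    def from_csv(cls, path, provenance: str = "user-supplied") -> "ShadingDataset":
        df = pd.read_csv(path)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"CSV is missing required column(s): {missing}")
        return cls(data=df, provenance=provenance)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one sigmoid fit."""

    curve: SigmoidResponse
    rss: float
    stderr: dict[str, float | None]
    converged: bool
    unidentifiable: bool = False
    message: str = ""


def _sigmoid_model(x, high, low, slope, inflection):
    with np.errstate(over="ignore"):
        return high + (low - high) / (1.0 + np.exp(slope * (x - inflection)))


def fit_sigmoid(
    x: np.ndarray,
    y: np.ndarray,
    init: SigmoidResponse | None = None,
) -> FitResult:
    """Fit the four-parameter logistic response by Levenberg–Marquardt.

    Initialization (when ``init`` is not given): ``high = max(y)``,
    ``low = min(y)``, ``inflection = median(x)``, ``slope = 4/range(x)``
    — the standard logistic start for monotone data. Because steep
    transitions leave only one or two points on the ramp, the start is
    complemented by a deterministic multi-start over slope scales and
    candidate inflection points, keeping the best least-squares optimum.
    Box constraints: slope > 0; high and low in [0, 3·max(y)];
    inflection unconstrained (fitted midpoints may be negative).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4 or np.unique(x).size < 4:
        raise ValueError(
            "under-determined fit: need >= 4 points at >= 4 distinct light levels"
        )

    y_span = float(np.max(y) - np.min(y))
    y_scale = float(np.max(np.abs(y))) or 1.0
    if y_span <= FLAT_DATA_RTOL * y_scale:
        flat = float(np.mean(y))
        curve = SigmoidResponse(
            high=flat, low=flat, slope=4.0 / (np.ptp(x) or 1.0), inflection=float(np.median(x))
        )
        return FitResult(
            curve=curve,
            rss=float(np.sum((y - flat) ** 2)),
            stderr={k: None for k in ("high", "low", "slope", "inflection")},
            converged=True,
            unidentifiable=True,
            message="response is flat: high/low not separately identifiable",
        )

    model = lmfit.Model(_sigmoid_model)
    x_range = float(np.ptp(x)) or 1.0
    base_slope = 4.0 / x_range

    def params_for(slope0: float, inflection0: float) -> lmfit.Parameters:
        p = model.make_params(
            high=float(np.max(y)),
            low=float(np.min(y)),
            slope=slope0,
            inflection=inflection0,
        )
        p["high"].set(min=0.0, max=3.0 * float(np.max(y)))
        p["low"].set(min=0.0, max=3.0 * float(np.max(y)))
        p["slope"].set(min=1e-12)
        return p

    if init is not None:
        starts = [(init.slope, init.inflection)]
    else:
        # slope scales spanning gentle to step-like transitions; candidate
        # midpoints at the overall median and where the mean response
        # jumps most between adjacent light levels (the informative gap
        # for a steep transition)
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        x_distinct, idx = np.unique(xs, return_index=True)
        y_means = np.array(
            [ys[i:j].mean() for i, j in zip(idx, list(idx[1:]) + [len(ys)])]
        )
        jumps = np.abs(np.diff(y_means))
        gap_mids = 0.5 * (x_distinct[:-1] + x_distinct[1:])
        top = np.argsort(jumps)[::-1][:2]
        midpoints = [float(np.median(x))] + [float(gap_mids[i]) for i in top]
        starts = [
            (base_slope * scale, m)
            for scale in (1.0, 100.0)
            for m in midpoints
        ]

    best = None
    for slope0, inflection0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(y, params_for(slope0, inflection0), x=x, method="leastsq")
            except Exception:
                continue
        if best is None or res.chisqr < best.chisqr - 1e-30:
            best = res
    if best is None:
        return FitResult(
            curve=SigmoidResponse(
                high=float(np.max(y)), low=float(np.min(y)),
                slope=base_slope, inflection=float(np.median(x)),
            ),
            rss=float("inf"),
            stderr={k: None for k in ("high", "low", "slope", "inflection")},
            converged=False,
            message="Levenberg-Marquardt failed to converge from every start",
        )
    return _polish(x, y, best)


def _polish(x: np.ndarray, y: np.ndarray, lm_result) -> FitResult:
    """Refine the Levenberg–Marquardt optimum by bounded trust-region
    least squares with per-column Jacobian scaling.

    Steep transitions leave the sum-of-squares surface with a long,
    badly scaled valley in (slope, inflection) where plain LM stalls a
    few percent short of the optimum; Jacobian scaling follows the
    valley to the floor. Started at the LM optimum, so the objective can
    only decrease.
    """
    pv = lm_result.params
    theta0 = np.array(
        [pv["high"].value, pv["low"].value, pv["slope"].value, pv["inflection"].value]
    )
    hi_bound = 3.0 * float(np.max(y))
    lower = np.array([0.0, 0.0, 1e-12, -np.inf])
    upper = np.array([hi_bound, hi_bound, np.inf, np.inf])
    theta0 = np.clip(theta0, lower + 1e-15, upper)

    def residual(theta):
        return _sigmoid_model(x, *theta) - y

    fit = least_squares(
        residual,
        theta0,
        bounds=(lower, upper),
        method="trf",
        x_scale="jac",
        xtol=2.3e-16,
        ftol=2.3e-16,
        gtol=2.3e-16,
        max_nfev=5000,
    )
    rss = float(2.0 * fit.cost)
    names = ("high", "low", "slope", "inflection")
    curve = SigmoidResponse(**dict(zip(names, (float(v) for v in fit.x))))

    # standard errors from the local curvature at the optimum
    stderr: dict[str, float | None] = {k: None for k in names}
    message = ""
    dof = x.size - 4
    jtj = fit.jac.T @ fit.jac
    if dof > 0 and np.linalg.cond(jtj) < 1e12:
        cov = np.linalg.inv(jtj) * rss / dof
        stderr = {k: float(np.sqrt(v)) for k, v in zip(names, np.diag(cov))}
    else:
        message = "covariance not estimated (rank-deficient Jacobian)"
    return FitResult(
        curve=curve,
        rss=rss,
        stderr=stderr,
        converged=bool(fit.status > 0),
        message=message,
    )


def fit_acclimation_model(
    dataset: ShadingDataset,
) -> tuple[AcclimationModel | None, dict[str, FitResult | None]]:
    """Fit all three acclimation curves from a shading dataset.

    Returns the assembled :class:`AcclimationModel` (None when any
    column is absent or its fit failed) together with the per-parameter
    fit results keyed ``pmax``/``ik``/``r`` (None for missing columns),
    so partial datasets still yield a usable report.
    """
    x = dataset.data["irradiance_umol"].to_numpy(dtype=float)
    fits: dict[str, FitResult | None] = {}
    for col in ("pmax", "ik", "r"):
        if col not in dataset.data.columns:
            fits[col] = None
            continue
        fits[col] = fit_sigmoid(x, dataset.data[col].to_numpy(dtype=float))
    if any(f is None or not f.converged for f in fits.values()):
        return None, fits
    model = AcclimationModel(
        pmax_curve=fits["pmax"].curve,
        ik_curve=fits["ik"].curve,
        resp_curve=fits["r"].curve,
    )
    return model, fits
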