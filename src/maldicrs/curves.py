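"""Four-parameter log-logistic (LL.4) concentration–response fitting.

Model:  f(x) = c + (d − c) / (1 + exp(b · (ln x − ln e)))

with lower/upper asymptotes c and d, inflection concentration e (> 0,
enforced by fitting ln e) and slope b.  Under this orientation the response
runs from d at low dose to c at high dose when b > 0, and the other way
round when b < 0; the reported response *direction* is therefore derived
from the fitted curve's monotonicity, which is parameterization-invariant.

Fits are least-squares on per-concentration replicate means.  Zero-dose
(vehicle) points are mapped to a pseudo-concentration one dilution step
below the lowest nonzero dose so they can participate in the log-dose fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import spearmanr

__all__ = ["CurveFit", "fit_ll4", "ll4", "pec50", "log2fc", "replicate_rmse"]


def ll4(x, b: float, c: float, d: float, e: float):
    """Evaluate the four-parameter log-logistic model at dose(s) x > 0."""
    z = np.clip(b * (np.log(x) - np.log(e)), -50.0, 50.0)
    return c + (d - c) / (1.0 + np.exp(z))


@dataclass
class CurveFit:
    """Fitted LL.4 parameters and diagnostics for one m/z feature."""

    b: float
    c: float
    d: float
    e: float
    rmse: float
    converged: bool
    feature_mz: float = float("nan")
    conc_min: float = float("nan")
    conc_max: float = float("nan")
    n_points: int = 0
    zero_dose_pseudo: float | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, x):
        return ll4(np.asarray(x, dtype=float), self.b, self.c, self.d, self.e)

    @property
    def direction_sign(self) -> int:
        """+1 if the response increases with dose, −1 if it decreases, 0 if flat."""
        if not np.isfinite(self.conc_min) or not np.isfinite(self.conc_max):
            return 0
        delta = float(self.predict(self.conc_max) - self.predict(self.conc_min))
        scale = max(abs(self.c), abs(self.d), 1e-300)
        if abs(delta) <= 1e-9 * scale:
            return 0
        return 1 if delta > 0 else -1


def _map_zero_doses(conc: np.ndarray) -> tuple[np.ndarray, float | None]:
    """Replace zero doses by one dilution step below the lowest nonzero dose."""
    nonzero = np.sort(np.unique(conc[conc > 0]))
    if not np.any(conc == 0):
        return conc, None
    step = nonzero[1] / nonzero[0] if len(nonzero) > 1 else 10.0
    pseudo = nonzero[0] / step
    mapped = np.where(conc == 0, pseudo, conc)
    return mapped, float(pseudo)


def fit_ll4(
    conc,
    response,
    weights=None,
    starts=None,
    feature_mz: float = float("nan"),
) -> CurveFit:
    """Fit the LL.4 model by least squares with multi-start initialization.

    Parameters
    ----------
    conc, response : arrays of equal length; concentrations ≥ 0 with at
        least 4 distinct nonzero values (zeros are vehicle controls and are
        mapped to a pseudo-dose one dilution step below the lowest dose).
    weights : optional per-point weights applied to the residuals.
    starts : optional list of (b0, c0, d0, e0) start tuples overriding the
        default two-start (b0 = ±1) initialization.

    Defaults: c0 = min(response), d0 = max(response), e0 = geometric mean of
    the dose range, b0 ∈ {−1, +1} with the best SSE kept; exact SSE ties are
    broken toward the fit whose direction agrees with the Spearman
    correlation of dose vs. response.  The only parameter constraint is
    e > 0 (via ln e).  On optimizer failure a flat fallback fit
    (b = 0, c = d = mean response, converged = False) is returned.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape:
        raise ValueError("conc and response must have the same shape")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if not np.all(np.isfinite(response)):
        raise ValueError("responses must be finite")
    if len(np.unique(conc[conc > 0])) < 4:
        raise ValueError("need at least 4 distinct nonzero concentrations")
    w = np.ones_like(response) if weights is None else np.sqrt(np.asarray(weights, float))

    x, pseudo = _map_zero_doses(conc)
    logx = np.log(x)

    def residuals(theta):
        b, c, d, loge = theta
        z = np.clip(b * (logx - loge), -50.0, 50.0)
        return (c + (d - c) / (1.0 + np.exp(z)) - response) * w

    def jacobian(theta):
        b, c, d, loge = theta
        z = np.clip(b * (logx - loge), -50.0, 50.0)
        s = 1.0 / (1.0 + np.exp(z))
        ds_dz = -s * (1.0 - s)
        jac = np.empty((len(logx), 4))
        jac[:, 0] = (d - c) * ds_dz * (logx - loge) * w
        jac[:, 1] = (1.0 - s) * w
        jac[:, 2] = s * w
        jac[:, 3] = (d - c) * ds_dz * (-b) * w
        return jac

    c0, d0 = float(np.min(response)), float(np.max(response))
    loge0 = float(np.mean(logx))
    if starts is None:
        start_list = [(-1.0, c0, d0, loge0), (1.0, c0, d0, loge0)]
    else:
        start_list = [(b0, cc, dd, np.log(ee)) for (b0, cc, dd, ee) in start_list_from(starts)]

    best = None
    for theta0 in start_list:
        try:
            # trf rather than lm: the MINPACK path can return different
            # points of an exactly-flat SSE valley depending on allocator
            # history, breaking run-to-run reproducibility
            res = least_squares(
                residuals, theta0, jac=jacobian, method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0] * (1 - 1e-12):
            best = (sse, res)
        elif abs(sse - best[0]) <= 1e-12 * max(best[0], 1e-300):
            if np.ptp(response) == 0:
                continue
            # SSE tie between orientations: prefer agreement with the
            # rank correlation of dose vs response
            rho = spearmanr(x, response).statistic
            if np.isfinite(rho) and rho != 0:
                cand_sign = _fit_sign(res.x, logx)
                best_sign = _fit_sign(best[1].x, logx)
                if cand_sign == np.sign(rho) and best_sign != np.sign(rho):
                    best = (sse, res)

    if best is None:
        warnings.warn("LL.4 optimization failed; returning flat fallback fit")
        mean = float(np.mean(response))
        return CurveFit(
            b=0.0, c=mean, d=mean, e=float(np.exp(loge0)),
            rmse=float(np.sqrt(np.mean((response - mean) ** 2))),
            converged=False, feature_mz=feature_mz,
            conc_min=float(np.min(x)), conc_max=float(np.max(x)),
            n_points=len(response), zero_dose_pseudo=pseudo,
        )

    sse, res = best
    b, c, d, loge = (float(v) for v in res.x)
    # (b, c, d) and (−b, d, c) describe the same curve; canonicalize so that
    # c is the lower and d the upper asymptote
    if c > d:
        b, c, d = -b, d, c
    return CurveFit(
        b=b, c=c, d=d, e=float(np.exp(loge)),
        rmse=float(np.sqrt(sse / len(response))),
        converged=bool(res.success),
        feature_mz=feature_mz,
        conc_min=float(np.min(x)), conc_max=float(np.max(x)),
        n_points=len(response), zero_dose_pseudo=pseudo,
    )


def start_list_from(starts):
    return [tuple(map(float, s)) for s in starts]


def _fit_sign(theta, logx) -> float:
    b, c, d, loge = theta
    lo = c + (d - c) / (1 + np.exp(np.clip(b * (logx.min() - loge), -50, 50)))
    hi = c + (d - c) / (1 + np.exp(np.clip(b * (logx.max() - loge), -50, 50)))
    return float(np.sign(hi - lo))


def pec50(f: CurveFit) -> float:
    """Potency: −log10 of the inflection concentration e.

    Conventional pEC50 when concentrations are molar.  Undefined (NaN) for
    non-converged fits.
    """
    if not f.converged or not np.isfinite(f.e) or f.e <= 0:
        return float("nan")
    return float(-np.log10(f.e))


def log2fc(f: CurveFit) -> float:
    """Signed effect size: ±|log2(d / c)|.

    The magnitude is the log2 ratio of the asymptotes; the sign follows the
    direction of the response (+ for up-regulation with dose, − for down).
    """
    if f.c <= 0 or f.d <= 0:
        raise ValueError("log2 fold change requires positive asymptotes")
    magnitude = abs(float(np.log2(f.d / f.c)))
    sign = f.direction_sign
    return float(sign * magnitude) if sign != 0 else 0.0


def replicate_rmse(f: CurveFit, conc, response) -> float:
    """RMS deviation of replicate-level responses from the fitted curve.

    Zero doses are mapped to the same pseudo-concentration used in the fit.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if f.zero_dose_pseudo is not None:
        conc = np.where(conc == 0, f.zero_dose_pseudo, conc)
    elif np.any(conc == 0):
        conc, _ = _map_zero_doses(conc)
    return float(np.sqrt(np.mean((response - f.predict(conc)) ** 2)))
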