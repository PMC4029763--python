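"""Fractional-polynomial mean/SD models and centile arithmetic.

Age-related reference intervals are built here the classical way: a
fractional-polynomial (FP) regression for the mean of the outcome, a second
FP regression for the residual SD, and centiles from

    P-th centile = mean(x) + K * SD(x)

on the modelled scale, where K is the normal equivalent deviate (z-score)
of the centile level.  When the outcome is modelled on the natural-log
scale the centile is exponentiated back.

FP terms use the standard power set {-2, -1, -0.5, 0, 0.5, 1, 2, 3}; power
0 denotes ln x, and a repeated power p contributes the pair
(x^p, x^p * ln x).  Model selection over the degree-1 and degree-2
candidates uses the closed function-selection test on deviance differences,
with an optional lowest-deviance override.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: deviances closer than this are treated as ties in the power search
DEVIANCE_TIE_TOL = 1e-8


class InvalidInputError(ValueError):
    """Covariate/outcome values violate a precondition (e.g. x <= 0)."""


class DegenerateDesignError(ValueError):
    """The FP design matrix is rank-deficient (e.g. constant covariate)."""


class InvalidSDError(ValueError):
    """A fitted or evaluated SD is non-positive."""


def fp_design(x: np.ndarray, powers: Sequence[float]) -> np.ndarray:
    """Design matrix (no intercept column) for the FP term sequence.

    Repeated powers follow the usual recurrence: if p_j == p_{j-1} the term
    is the previous column times ln x.  Power 0 is ln x.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise InvalidInputError("FP covariates must be finite and > 0")
    lnx = np.log(x)
    cols: list[np.ndarray] = []
    prev_p: float | None = None
    for p in powers:
        if prev_p is not None and p == prev_p:
            col = cols[-1] * lnx
        else:
            col = lnx.copy() if p == 0 else x**p
        cols.append(col)
        prev_p = p
    if not cols:
        return np.empty((x.shape[0], 0))
    return np.column_stack(cols)


@dataclass(frozen=True)
class FPModel:
    """A fitted fractional-polynomial curve for a mean or an SD.

    ``predict`` returns values on the modelled scale; use
    ``predict_natural`` for log-scale outcomes mapped back to their
    natural units.
    """

    powers: tuple[float, ...]
    coefficients: tuple[float, ...]
    intercept: float
    outcome_log: bool = False
    covariate_name: str = "x"
    fit_range: tuple[float, float] | None = None
    selection: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.powers) != len(self.coefficients):
            raise InvalidInputError("powers and coefficients must pair up")
        if len(self.powers) > 2:
            raise InvalidInputError("FP degree above 2 is not supported")
        for p in self.powers:
            if p not in FP_POWERS:
                raise InvalidInputError(f"power {p} outside the FP power set")

    def predict(self, x) -> np.ndarray:
        """Evaluate the curve on the modelled scale (vectorised)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        design = fp_design(x, self.powers)
        return self.intercept + design @ np.asarray(self.coefficients)

    def predict_natural(self, x) -> np.ndarray:
        out = self.predict(x)
        return np.exp(out) if self.outcome_log else out

    def in_fit_range(self, x) -> np.ndarray:
        """Boolean mask; False marks extrapolation beyond the fitted span."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.fit_range is None:
            return np.ones_like(x, dtype=bool)
        lo, hi = self.fit_range
        return (x >= lo) & (x <= hi)

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "powers": list(self.powers),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "outcome_log": self.outcome_log,
            "covariate_name": self.covariate_name,
            "fit_range": list(self.fit_range) if self.fit_range else None,
        }
        if self.selection is not None:
            d["selection"] = self.selection
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FPModel":
        return cls(
            powers=tuple(d["powers"]),
            coefficients=tuple(d["coefficients"]),
            intercept=float(d["intercept"]),
            outcome_log=bool(d.get("outcome_log", False)),
            covariate_name=d.get("covariate_name", "x"),
            fit_range=tuple(d["fit_range"]) if d.get("fit_range") else None,
            selection=d.get("selection"),
        )


@dataclass(frozen=True)
class CentileSpec:
    """A centile level and its normal equivalent deviate K.

    K defaults to the exact standard-normal quantile of the level
    (e.g. 1.880794 for the 97th centile); pass K explicitly to use a
    rounded convention such as 1.88.
    """

    level: float
    K: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise InvalidInputError("centile level must be in (0, 1)")
        if self.K is None:
            object.__setattr__(self, "K", float(stats.norm.ppf(self.level)))


MEDIAN = CentileSpec(0.5, 0.0)
CENTILE_3 = CentileSpec(0.03)
CENTILE_97 = CentileSpec(0.97)


@dataclass(frozen=True)
class MeanSDModel:
    """Paired mean and SD curves sharing one covariate.

    Two specialisations appear throughout: a *size model* (outcome CRL in
    mm, covariate GA in weeks, natural scale) and a *dating model*
    (outcome GA in weeks modelled as ln GA, covariate CRL in mm).
    """

    mean: FPModel
    sd: FPModel
    outcome_name: str = "y"

    def __post_init__(self) -> None:
        if self.mean.covariate_name != self.sd.covariate_name:
            raise InvalidInputError("mean and sd must share a covariate")

    @property
    def outcome_log(self) -> bool:
        return self.mean.outcome_log

    @property
    def covariate_name(self) -> str:
        return self.mean.covariate_name

    @property
    def fit_range(self) -> tuple[float, float] | None:
        return self.mean.fit_range

    def predict_centile(self, x, spec: CentileSpec = MEDIAN) -> np.ndarray:
        return predict_centile(self, x, spec)

    def zscores_at(self, x, y) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        s = self.sd.predict(x)
        if np.any(s <= 0):
            raise InvalidSDError("SD model non-positive at requested points")
        y_scale = np.log(y) if self.outcome_log else y
        return (y_scale - self.mean.predict(x)) / s

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "outcome_name": self.outcome_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeanSDModel":
        return cls(
            mean=FPModel.from_dict(d["mean"]),
            sd=FPModel.from_dict(d["sd"]),
            outcome_name=d.get("outcome_name", "y"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "MeanSDModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with an intercept; returns (params, rss).

    params[0] is the intercept.  Raises on rank deficiency.
    """
    X = np.column_stack([np.ones(len(y)), design])
    params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateDesignError("singular FP design matrix")
    resid = y - X @ params
    return params, float(resid @ resid)


def _deviance(rss: float, n: int) -> float:
    # Gaussian deviance up to an additive constant: n * ln(RSS / n)
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n)


def _candidate_powers(degree: int) -> list[tuple[float, ...]]:
    if degree == 0:
        return [()]
    if degree == 1:
        return [(p,) for p in FP_POWERS]
    # 36 degree-2 models including repeated powers
    return [tuple(c) for c in itertools.combinations_with_replacement(FP_POWERS, 2)]


def _fit_fixed(x: np.ndarray, y: np.ndarray, powers: tuple[float, ...]):
    design = fp_design(x, powers)
    params, rss = _ols(design, y)
    return params, rss


def _best_of_degree(x, y, degree, admissible=None):
    """Lowest-deviance admissible candidate of the given degree, or None.

    Ties within DEVIANCE_TIE_TOL go to the lexicographically earlier power
    tuple (candidates are generated in lexicographic order).  ``admissible``
    is an optional predicate on (powers, params) screening out candidates
    (e.g. curves that are implausible where they will be extrapolated).
    """
    best = None
    for powers in _candidate_powers(degree):
        try:
            params, rss = _fit_fixed(x, y, powers)
        except DegenerateDesignError:
            continue
        if admissible is not None and not admissible(powers, params):
            continue
        if best is None or rss < best[2] - DEVIANCE_TIE_TOL:
            best = (powers, params, rss)
    return best


def fit_fp_mean(
    x,
    y,
    outcome_log: bool = False,
    max_degree: int = 2,
    powers: Sequence[float] | None = None,
    selection: str = "closed",
    alpha: float = 0.05,
    covariate_name: str = "x",
    allow_constant: bool = False,
    constraint=None,
) -> FPModel:
    """Fit an FP regression of y on x, searching powers unless fixed.

    With ``selection="closed"`` the degree is chosen by the closed test:
    the best high-degree model must beat the straight line (and, when
    allowed, the constant) on a chi-square deviance test at ``alpha``
    before complexity is accepted; otherwise the search simply takes the
    lowest deviance.  ``outcome_log`` fits ln y.

    ``constraint`` is an optional predicate on a candidate FPModel; power
    tuples whose fitted curve fails it are removed from the search (used to
    demand plausibility — monotonicity, positivity — over a span the curve
    will be extrapolated to).  Fixed ``powers`` bypass the constraint.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-d arrays of equal length")
    if len(x) < 10 and powers is None:
        raise InvalidInputError("need at least 10 observations for a power search")
    if np.any(x <= 0):
        raise InvalidInputError("covariate values must be > 0")
    if max_degree not in (1, 2):
        raise InvalidInputError("max_degree must be 1 or 2")
    if outcome_log:
        if np.any(y <= 0):
            raise InvalidInputError("log-scale outcome requires y > 0")
        y = np.log(y)

    fit_range = (float(x.min()), float(x.max()))
    n = len(x)

    if powers is not None:
        powers = tuple(float(p) for p in powers)
        params, rss = _fit_fixed(x, y, powers)
        return FPModel(
            powers=powers,
            coefficients=tuple(params[1:]),
            intercept=float(params[0]),
            outcome_log=outcome_log,
            covariate_name=covariate_name,
            fit_range=fit_range,
            selection={"method": "fixed", "deviance": _deviance(rss, n)},
        )

    def make_model(powers_sel, params, trace=None):
        return FPModel(
            powers=powers_sel,
            coefficients=tuple(params[1:]),
            intercept=float(params[0]),
            outcome_log=outcome_log,
            covariate_name=covariate_name,
            fit_range=fit_range,
            selection=trace,
        )

    admissible = None
    if constraint is not None:
        admissible = lambda pw, pa: constraint(make_model(pw, pa))  # noqa: E731

    degrees = list(range(0 if allow_constant else 1, max_degree + 1))
    fits = {}
    for d in degrees:
        best = _best_of_degree(x, y, d, admissible)
        if best is not None:
            fits[d] = best
    try:
        lin_params, lin_rss = _fit_fixed(x, y, (1.0,))
        if admissible is None or admissible((1.0,), lin_params):
            fits["linear"] = ((1.0,), lin_params, lin_rss)
    except DegenerateDesignError:
        pass
    if not any(isinstance(k, int) for k in fits):
        raise DegenerateDesignError("no admissible FP model is estimable")
    degrees = [d for d in degrees if d in fits]
    dev = {k: _deviance(rss, n) for k, (_, _, rss) in fits.items()}

    trace: dict = {
        "method": selection,
        "alpha": alpha,
        "deviances": {str(k): dev[k] for k in dev},
    }

    if selection == "lowest_deviance":
        # prefer lower degree on ties
        order = sorted(
            (d for d in degrees),
            key=lambda d: (round(dev[d] / DEVIANCE_TIE_TOL), d),
        )
        chosen = order[0]
    elif selection == "closed":
        chosen = _closed_test(dev, degrees, n, alpha, allow_constant, trace)
    else:
        raise InvalidInputError(f"unknown selection method {selection!r}")

    powers_sel, params, _rss = fits[chosen]
    trace["selected_powers"] = list(powers_sel)
    return make_model(powers_sel, params, trace)


def _closed_test(dev, degrees, n, alpha, allow_constant, trace):
    """Closed function-selection procedure on Gaussian deviances.

    Working down from the most complex candidate: the best FP(m) is tested
    against the constant (4 df at m=2), then the straight line, then the
    best lower-degree FP, each on a chi-square scale; the first
    non-significant comparison stops the descent.
    """
    top = max(d for d in degrees)
    tests = trace.setdefault("tests", [])

    def pval(d_small, d_large, df):
        delta = max(dev[d_small] - dev[d_large], 0.0)
        p = float(stats.chi2.sf(delta, df))
        tests.append(
            {"null": str(d_small), "alt": str(d_large), "df": df, "p": p}
        )
        return p

    if allow_constant and 0 in dev:
        if pval(0, top, 2 * top) > alpha:
            return 0
    if top >= 1 and "linear" in dev:
        if pval("linear", top, 2 * top - 1) > alpha:
            return "linear"
    if top == 2 and 1 in dev:
        if pval(1, 2, 2) > alpha:
            return 1
    return top


def fit_fp_sd(
    x,
    residuals,
    max_degree: int = 1,
    selection: str = "closed",
    covariate_name: str = "x",
    powers: Sequence[float] | None = None,
    positive_range: tuple[float, float] | None = None,
) -> FPModel:
    """SD curve from mean-model residuals via scaled absolute residuals.

    For half-normal |r| with underlying SD sigma, E|r| = sigma*sqrt(2/pi),
    so regressing |r|*sqrt(pi/2) on x estimates sigma(x).  A constant
    (degree-0) model is allowed when no FP term earns its keep.

    An SD curve must be positive wherever the model will be applied, so
    candidates that dip non-positive anywhere on the fit range — extended
    by ``positive_range`` when the curve is destined for extrapolation —
    are screened out of the power search; a constant is always admissible.
    Explicit ``powers`` bypass the screen but a non-positive result raises
    InvalidSDError.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(residuals, dtype=float)
    scaled = np.abs(r) * math.sqrt(math.pi / 2.0)
    lo, hi = float(x.min()), float(x.max())
    if positive_range is not None:
        lo, hi = min(lo, positive_range[0]), max(hi, positive_range[1])
    span = np.linspace(lo, hi, 201)

    def positive_on_span(m: FPModel) -> bool:
        return bool(np.all(m.predict(span) > 0))

    if powers is not None:
        model = fit_fp_mean(
            x, scaled, outcome_log=False, max_degree=max_degree,
            powers=powers, covariate_name=covariate_name,
        )
        if not positive_on_span(model):
            raise InvalidSDError("fitted SD curve non-positive on its span")
        return model

    try:
        return fit_fp_mean(
            x, scaled, outcome_log=False, max_degree=max_degree,
            selection=selection, covariate_name=covariate_name,
            allow_constant=True, constraint=positive_on_span,
        )
    except DegenerateDesignError as exc:
        raise InvalidSDError("no positive SD curve found for any candidate") from exc


def fit_mean_sd(
    x,
    y,
    outcome_log: bool,
    covariate_name: str,
    outcome_name: str,
    max_degree: int = 2,
    sd_max_degree: int = 1,
    selection: str = "closed",
    plausible_span: tuple[float, float] | None = None,
    mean_increasing: bool = False,
) -> MeanSDModel:
    """Convenience: mean fit, residuals, SD fit, bundled together.

    ``plausible_span`` (covariate units) extends the range over which the
    fitted curves must stay plausible — the SD positive and, with
    ``mean_increasing``, the mean strictly increasing.  Use it when the
    model will be extrapolated beyond the data, as the augmentation and
    axis-interchange pipelines do.
    """
    constraint = None
    if plausible_span is not None and mean_increasing:
        x_arr = np.asarray(x, dtype=float)
        lo = min(float(x_arr.min()), plausible_span[0])
        hi = max(float(x_arr.max()), plausible_span[1])
        span = np.linspace(lo, hi, 201)

        def constraint(m: FPModel) -> bool:
            return bool(np.all(np.diff(m.predict(span)) > 0))

    mean = fit_fp_mean(
        x,
        y,
        outcome_log=outcome_log,
        max_degree=max_degree,
        selection=selection,
        covariate_name=covariate_name,
        constraint=constraint,
    )
    y_scale = np.log(np.asarray(y, dtype=float)) if outcome_log else np.asarray(y, dtype=float)
    resid = y_scale - mean.predict(x)
    sd = fit_fp_sd(
        x,
        resid,
        max_degree=sd_max_degree,
        selection=selection,
        covariate_name=covariate_name,
        positive_range=plausible_span,
    )
    return MeanSDModel(mean=mean, sd=sd, outcome_name=outcome_name)


def predict_centile(model: MeanSDModel, x, spec: CentileSpec) -> np.ndarray:
    """mean(x) + K*SD(x) on the modelled scale, back-transformed if log."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    s = model.sd.predict(x)
    if np.any(s <= 0):
        raise InvalidSDError("SD model non-positive at requested points")
    value = model.mean.predict(x) + spec.K * s
    return np.exp(value) if model.outcome_log else value


def zscores(model: MeanSDModel, obs, y=None) -> np.ndarray:
    """z = (outcome on modelled scale - mean(x)) / SD(x).

    ``obs`` may be an ObservationSet-like object exposing ``covariate(name)``
    /``outcome(name)`` column access via ``crl`` and ``ga`` attributes, or a
    plain covariate array with ``y`` given separately.
    """
    if y is None:
        x_vals = np.asarray(obs.crl if model.covariate_name == "crl_mm" else obs.ga)
        y_vals = np.asarray(obs.ga if model.covariate_name == "crl_mm" else obs.crl)
    else:
        x_vals, y_vals = obs, y
    return model.zscores_at(x_vals, y_vals)
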