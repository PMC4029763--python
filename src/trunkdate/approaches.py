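"""Three strategies for fitting a dating chart on GA-truncated data.

All three exploit the fact that truncation of gestational age (GA) only
bites when GA is the *outcome*: a size chart (CRL as a function of GA) can
be fitted on the truncated data without bias, and each approach converts
that size fit into a dating chart differently.

Approach 1 — simulate CRL below the window from the size fit, refit the
dating model on the augmented data with CRL restricted to a window where
the upper truncation cannot distort it, and extrapolate.

Approach 2 — simulate CRL below *and* above the window and fit the dating
model on the fully augmented data with no restriction.

Approach 3 — no simulation: evaluate the size fit's 3rd/50th/97th CRL
centiles on a GA grid, interchange the axes, regress ln GA on each
coordinate set, and recover the SD curve from the averaged half-spreads
of the outer centiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fp import (
    CENTILE_3,
    CENTILE_97,
    MEDIAN,
    CentileSpec,
    FPModel,
    InvalidInputError,
    MeanSDModel,
    fit_fp_mean,
    fit_fp_sd,
    fit_mean_sd,
)
from .simulate import (
    DEFAULT_SEED,
    DatingEquation,
    ObservationSet,
    TruncationWindow,
    simulate_from_size,
)

#: augmentation day grids: 7+0..8+6 below the window, 14+0..17+0 above
DEFAULT_LOW_DAYS: tuple[int, ...] = tuple(range(49, 63))
DEFAULT_HIGH_DAYS: tuple[int, ...] = tuple(range(98, 120))


class InsufficientDataError(ValueError):
    """Too few observations remain after restriction/augmentation."""


class InversionInvalidError(ValueError):
    """Predicted CRL centiles are not strictly increasing in GA."""


class InvalidCentilesError(ValueError):
    """Centile curves violate the c3 < c50 < c97 ordering."""


@dataclass(frozen=True)
class Approach1Config:
    augment_low_days: tuple[int, ...] = DEFAULT_LOW_DAYS
    n_per_day: int = 100
    restrict_crl: tuple[float, float] = (20.0, 65.0)
    sensitivity_cutoffs: tuple[float, ...] = (10.0, 15.0, 20.0)

    def __post_init__(self) -> None:
        if not self.restrict_crl[0] < self.restrict_crl[1]:
            raise InvalidInputError("restrict_crl window is empty")


@dataclass(frozen=True)
class Approach2Config:
    augment_low_days: tuple[int, ...] = DEFAULT_LOW_DAYS
    augment_high_days: tuple[int, ...] = DEFAULT_HIGH_DAYS
    n_per_day: int = 100

    def validate(self, window: TruncationWindow) -> None:
        low = np.asarray(self.augment_low_days, dtype=float) / 7.0
        high = np.asarray(self.augment_high_days, dtype=float) / 7.0
        if np.any(low >= window.ga_low):
            raise InvalidInputError("low augmentation grid overlaps the window")
        if np.any(high < window.ga_high):
            raise InvalidInputError("high augmentation grid overlaps the window")


@dataclass(frozen=True)
class Approach3Config:
    """Axis-interchange settings.

    The size fit is evaluated one point per gestational day from the lower
    edge of the data window upward (9 to 17 weeks by default): the size
    chart is extrapolated only toward larger GA, where its centiles keep
    rising; extrapolating it below the observed window is left to the
    inverted GA-on-CRL regressions instead.
    """

    ga_eval_days: tuple[int, ...] = tuple(range(63, 120))
    centile_levels: tuple[float, ...] = (0.03, 0.50, 0.97)


def fit_size_model(
    obs: ObservationSet,
    selection: str = "closed",
    plausible_span: tuple[float, float] | None = None,
) -> MeanSDModel:
    """Size chart: CRL (mm, natural scale) as an FP function of GA (weeks).

    When the fit will be extrapolated (augmentation, axis interchange) pass
    the GA span it must cover as ``plausible_span``: the power search then
    admits only curves with strictly increasing mean CRL and positive SD
    over that span, mirroring the requirement that extrapolated size
    equations remain physically plausible.
    """
    return fit_mean_sd(
        obs.ga,
        obs.crl,
        outcome_log=False,
        covariate_name="ga_weeks",
        outcome_name="crl_mm",
        selection=selection,
        plausible_span=plausible_span,
        mean_increasing=plausible_span is not None,
    )


def fit_dating_model(
    obs: ObservationSet,
    selection: str = "closed",
    plausible_span: tuple[float, float] | None = None,
) -> MeanSDModel:
    """Dating chart: ln GA as an FP function of CRL, with an SD curve.

    ``plausible_span`` (CRL mm) demands a strictly increasing median and a
    positive SD over the span the chart will be evaluated on — every
    dating chart here must assign older gestations to longer embryos.
    """
    return fit_mean_sd(
        obs.crl,
        obs.ga,
        outcome_log=True,
        covariate_name="crl_mm",
        outcome_name="ga_weeks",
        selection=selection,
        plausible_span=plausible_span,
        mean_increasing=plausible_span is not None,
    )


def run_approach1(
    obs: ObservationSet,
    cfg: Approach1Config = Approach1Config(),
    seed: int = DEFAULT_SEED,
    window: TruncationWindow = TruncationWindow(),
    with_data: bool = False,
):
    """Low-end augmentation, CRL restriction, extrapolation.

    The returned dating model's fit_range records the CRL restriction, so
    predictions beyond it are flagged as extrapolation downstream.  With
    ``with_data=True`` the (model, fitting set) pair is returned; the
    fitting set is what coverage counts are taken over.
    """
    combined = obs
    if len(cfg.augment_low_days) > 0:
        span = (min(cfg.augment_low_days) / 7.0, window.ga_high)
        size = fit_size_model(obs, plausible_span=span)
        aug = simulate_from_size(
            size, np.asarray(cfg.augment_low_days, dtype=float),
            cfg.n_per_day, seed, window,
        )
        combined = obs.concat(aug)
    restricted = combined.restrict_crl(*cfg.restrict_crl)
    if len(restricted) < 10:
        raise InsufficientDataError(
            f"only {len(restricted)} rows inside CRL restriction {cfg.restrict_crl}"
        )
    crl_span = (float(obs.crl.min()), float(obs.crl.max()))
    model = fit_dating_model(restricted, plausible_span=crl_span)
    return (model, restricted) if with_data else model


def run_approach2(
    obs: ObservationSet,
    cfg: Approach2Config = Approach2Config(),
    seed: int = DEFAULT_SEED,
    window: TruncationWindow = TruncationWindow(),
    with_data: bool = False,
):
    """Augmentation at both ends; dating fit on the full augmented set."""
    cfg.validate(window)
    combined = obs
    if len(cfg.augment_low_days) > 0 or len(cfg.augment_high_days) > 0:
        all_days = tuple(cfg.augment_low_days) + tuple(cfg.augment_high_days)
        span = (min(all_days) / 7.0, max(all_days) / 7.0)
        size = fit_size_model(obs, plausible_span=span)
        if len(cfg.augment_low_days) > 0:
            combined = combined.concat(simulate_from_size(
                size, np.asarray(cfg.augment_low_days, dtype=float),
                cfg.n_per_day, seed, window,
            ))
        if len(cfg.augment_high_days) > 0:
            combined = combined.concat(simulate_from_size(
                size, np.asarray(cfg.augment_high_days, dtype=float),
                cfg.n_per_day, seed + 1, window,
            ))
    if len(combined) < 10:
        raise InsufficientDataError("augmented data set too small")
    crl_span = (float(combined.crl.min()), float(combined.crl.max()))
    model = fit_dating_model(combined, plausible_span=crl_span)
    return (model, combined) if with_data else model


def run_approach3(
    obs: ObservationSet,
    cfg: Approach3Config = Approach3Config(),
) -> MeanSDModel:
    """Axis interchange: size-fit centile coordinates re-regressed as GA(CRL).

    Each predicted centile curve must increase strictly in GA to be
    invertible.  Extrapolated FP centiles can turn over at the far ends of
    the evaluation grid; such edge points are trimmed back to the largest
    strictly increasing span that covers the observed GA range.  A
    violation *inside* the observed range is a genuine inversion failure
    and raises InversionInvalidError.
    """
    ga_weeks = np.asarray(cfg.ga_eval_days, dtype=float) / 7.0
    size = fit_size_model(
        obs, plausible_span=(float(ga_weeks.min()), float(ga_weeks.max()))
    )
    ga_lo, ga_hi = float(obs.ga.min()), float(obs.ga.max())
    coords = []
    for level in cfg.centile_levels:
        crl_pred = size.predict_centile(ga_weeks, CentileSpec(level))
        crl_t, ga_t = _monotone_span(crl_pred, ga_weeks, ga_lo, ga_hi, level)
        coords.append((crl_t, ga_t))
    return fit_dating_from_coordinates(coords)


def _monotone_span(crl, ga, ga_lo, ga_hi, level):
    """Largest strictly increasing contiguous run covering [ga_lo, ga_hi]."""
    inside = (ga >= ga_lo) & (ga <= ga_hi)
    lo = int(np.argmax(inside))
    hi = len(ga) - 1 - int(np.argmax(inside[::-1]))
    rising = np.diff(crl) > 0
    if not np.all(rising[lo:hi]):
        raise InversionInvalidError(
            f"predicted CRL at level {level} not strictly increasing in GA "
            "within the observed range"
        )
    while lo > 0 and rising[lo - 1]:
        lo -= 1
    while hi < len(ga) - 1 and rising[hi]:
        hi += 1
    return crl[lo:hi + 1], ga[lo:hi + 1]


def fit_dating_from_coordinates(
    coords: list[tuple[np.ndarray, np.ndarray]],
    k_outer: float = CENTILE_97.K,
    sd_max_degree: int = 1,
) -> MeanSDModel:
    """Dating model from three (CRL, GA) centile coordinate sets.

    Each set is regressed as ln GA on an FP of CRL.  The three fitted
    curves are ordered by predicted GA (the size chart's *low* CRL centile
    becomes the *high* GA centile after interchanging axes); the middle one
    is the median and the outer pair feeds the SD recovery.
    """
    if len(coords) != 3:
        raise InvalidInputError("exactly three centile coordinate sets required")
    fits = []
    crl_lo, crl_hi = -np.inf, np.inf
    for crl_pred, ga in coords:
        crl_pred = np.asarray(crl_pred, dtype=float)
        ga = np.asarray(ga, dtype=float)
        if np.any(np.diff(crl_pred) <= 0):
            raise InversionInvalidError("coordinate CRL values must increase")
        fits.append(
            fit_fp_mean(
                crl_pred, ga, outcome_log=True, covariate_name="crl_mm"
            )
        )
        crl_lo = max(crl_lo, crl_pred.min())
        crl_hi = min(crl_hi, crl_pred.max())
    if not crl_lo < crl_hi:
        raise InversionInvalidError("centile coordinate CRL ranges do not overlap")

    # order curves by predicted GA on the common CRL support
    grid = np.linspace(crl_lo, crl_hi, max(int(round(crl_hi - crl_lo)) + 1, 25))
    curves = [np.exp(f.predict(grid)) for f in fits]
    order = np.argsort([c.mean() for c in curves])
    c3, c50, c97 = (curves[i] for i in order)
    median_fit = fits[order[1]]
    sd = recover_sd_from_centiles(grid, c3, c50, c97, K=k_outer,
                                  max_degree=sd_max_degree)
    return MeanSDModel(mean=median_fit, sd=sd, outcome_name="ga_weeks")


def recover_sd_from_centiles(
    crl,
    c3,
    c50,
    c97,
    K: float = CENTILE_97.K,
    max_degree: int = 1,
) -> FPModel:
    """SD curve from outer centiles: average of the two log half-spreads.

    SD(CRL) = [(ln c97 - ln c50)/K + (ln c50 - ln c3)/K] / 2, regressed on
    CRL as an FP (constant allowed).  With GA modelled on the log scale the
    two half-spreads are equal for an exactly lognormal model.
    """
    crl = np.asarray(crl, dtype=float)
    c3, c50, c97 = (np.asarray(c, dtype=float) for c in (c3, c50, c97))
    if np.any(c3 >= c50) or np.any(c50 >= c97):
        raise InvalidCentilesError("centiles must satisfy c3 < c50 < c97 pointwise")
    sd_vals = (np.log(c97) - np.log(c3)) / (2.0 * K)
    return fit_fp_mean(
        crl,
        sd_vals,
        outcome_log=False,
        max_degree=max_degree,
        covariate_name="crl_mm",
        allow_constant=True,
    )


def sensitivity_lower_cutoff(
    obs: ObservationSet,
    base_cfg: Approach1Config,
    reference: DatingEquation,
    seed: int = DEFAULT_SEED,
    window: TruncationWindow = TruncationWindow(),
    reporting_grid=None,
):
    """Re-run Approach 1 per lower CRL cutoff; tabulate median agreement.

    Returns a DataFrame of (cutoff_mm, max_abs_diff_days, mean_diff_days)
    over the reporting grid (default 20-100 mm in 5 mm steps).
    """
    import pandas as pd

    from .evaluate import agreement_summary, compare_to_reference

    if reporting_grid is None:
        reporting_grid = np.arange(20.0, 101.0, 5.0)
    reporting_grid = np.asarray(reporting_grid, dtype=float)
    rows = []
    for cutoff in base_cfg.sensitivity_cutoffs:
        cfg = Approach1Config(
            augment_low_days=base_cfg.augment_low_days,
            n_per_day=base_cfg.n_per_day,
            restrict_crl=(float(cutoff), base_cfg.restrict_crl[1]),
            sensitivity_cutoffs=base_cfg.sensitivity_cutoffs,
        )
        model = run_approach1(obs, cfg, seed=seed, window=window)
        table = compare_to_reference(model, reference, reporting_grid)
        max_abs, mean = agreement_summary(
            table, (reporting_grid.min(), reporting_grid.max()), "median"
        )
        rows.append(
            {"cutoff_mm": float(cutoff), "max_abs_diff_days": max_abs,
             "mean_diff_days": mean}
        )
    return pd.DataFrame(rows)
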