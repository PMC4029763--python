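"""Agreement tables, coverage counts and summaries for dating models.

Comparison tables put a fitted dating model side by side with a reference
dating equation on a CRL grid: 3rd/50th/97th centile GA from each, and the
difference in days with the convention

    diff_days = (reference - fit) * 7

so a positive value means the reference predicts an older fetus.
Coverage counts assess calibration the chart-making way: the fraction of
observations falling below the 3rd and above the 97th fitted centiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fp import (
    CENTILE_3,
    CENTILE_97,
    MEDIAN,
    InvalidInputError,
    MeanSDModel,
)
from .simulate import DatingEquation, ObservationSet

#: Reporting grid used by the printed tables: CRL 10-100 mm, 5 mm steps
DEFAULT_REPORTING_GRID = tuple(np.arange(10.0, 101.0, 5.0))

_CENTILE_COLUMNS = {"c3": CENTILE_3, "median": MEDIAN, "c97": CENTILE_97}


class InsufficientDataError(ValueError):
    """No observations remain inside the requested CRL range."""


def _as_model(source) -> MeanSDModel:
    if isinstance(source, DatingEquation):
        return source.to_model()
    return source


@dataclass
class ComparisonTable:
    """Per-CRL grid of reference vs fitted centile GA, differences in days.

    ``data`` columns: crl_mm; ref_c3/ref_median/ref_c97 and
    fit_c3/fit_median/fit_c97 (GA, weeks, unrounded); diff_c3/diff_median/
    diff_c97 (days); extrapolated (fit evaluated beyond its fit_range).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def rounded(self, week_dp: int = 2, day_dp: int = 2) -> pd.DataFrame:
        """Table formatted to printed precision (weeks/day columns)."""
        out = self.data.copy()
        for col in out.columns:
            if col.startswith(("ref_", "fit_")):
                out[col] = out[col].round(week_dp)
            elif col.startswith("diff_"):
                out[col] = out[col].round(day_dp)
        return out


@dataclass(frozen=True)
class CoverageSummary:
    """Observed counts outside the fitted outer centiles."""

    n_below_3rd: int
    n_above_97th: int
    n_total: int
    crl_range: tuple[float, float]

    @property
    def pct_below_3rd(self) -> float:
        return 100.0 * self.n_below_3rd / self.n_total

    @property
    def pct_above_97th(self) -> float:
        return 100.0 * self.n_above_97th / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_below_3rd": self.n_below_3rd,
            "n_above_97th": self.n_above_97th,
            "n_total": self.n_total,
            "crl_range_mm": list(self.crl_range),
            "pct_below_3rd": self.pct_below_3rd,
            "pct_above_97th": self.pct_above_97th,
        }


def compare_to_reference(
    model: MeanSDModel,
    ref,
    crl_grid=DEFAULT_REPORTING_GRID,
) -> ComparisonTable:
    """Evaluate both sources' 3rd/50th/97th centiles on the CRL grid."""
    crl_grid = np.asarray(crl_grid, dtype=float)
    if crl_grid.size == 0 or np.any(crl_grid <= 0):
        raise InvalidInputError("crl_grid must be non-empty with values > 0")
    ref_model = _as_model(ref)
    cols: dict = {"crl_mm": crl_grid}
    for name, spec in _CENTILE_COLUMNS.items():
        ref_vals = ref_model.predict_centile(crl_grid, spec)
        fit_vals = model.predict_centile(crl_grid, spec)
        cols[f"ref_{name}"] = ref_vals
        cols[f"fit_{name}"] = fit_vals
        cols[f"diff_{name}"] = (ref_vals - fit_vals) * 7.0
    cols["extrapolated"] = ~model.mean.in_fit_range(crl_grid)
    meta = {
        "fit_range_mm": list(model.fit_range) if model.fit_range else None,
        "n_extrapolated": int(cols["extrapolated"].sum()),
    }
    return ComparisonTable(pd.DataFrame(cols), meta)


def coverage_counts(
    model: MeanSDModel,
    obs: ObservationSet,
    crl_range: tuple[float, float] = (20.0, 100.0),
) -> CoverageSummary:
    """Count observations below the 3rd / above the 97th fitted centile."""
    lo, hi = crl_range
    mask = (obs.crl >= lo) & (obs.crl <= hi)
    crl = obs.crl[mask]
    ga = obs.ga[mask]
    if crl.size == 0:
        raise InsufficientDataError(f"no observations with CRL in [{lo}, {hi}] mm")
    c3 = model.predict_centile(crl, CENTILE_3)
    c97 = model.predict_centile(crl, CENTILE_97)
    return CoverageSummary(
        n_below_3rd=int(np.sum(ga < c3)),
        n_above_97th=int(np.sum(ga > c97)),
        n_total=int(crl.size),
        crl_range=(float(lo), float(hi)),
    )


def agreement_summary(
    table: ComparisonTable,
    crl_window: tuple[float, float],
    centile: str = "median",
) -> tuple[float, float]:
    """(max |diff|, mean diff) in days for one centile column of the table."""
    if centile not in _CENTILE_COLUMNS:
        raise InvalidInputError(f"centile must be one of {list(_CENTILE_COLUMNS)}")
    lo, hi = crl_window
    df = table.data
    mask = (df["crl_mm"] >= lo) & (df["crl_mm"] <= hi)
    if not mask.any():
        raise InvalidInputError(f"CRL window [{lo}, {hi}] misses the grid")
    diffs = df.loc[mask, f"diff_{centile}"].to_numpy()
    return float(np.max(np.abs(diffs))), float(np.mean(diffs))
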