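"""Figure-equivalent tables and accuracy summaries for simulation studies.

The validation studies are summarised by three tables: predicted-vs-empirical
c per scenario (a scatter of calibration of the closed form), the
empirical-minus-predicted difference against within-group skewness (the
binormality-violation diagnostic), and banded accuracy summaries that turn
the scatter into numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .simulation import ScenarioResult

__all__ = [
    "AccuracySummary",
    "figure1_table",
    "figure2_table",
    "accuracy_summary",
    "accuracy_summary_to_frame",
    "DEFAULT_BANDS",
]

logger = logging.getLogger(__name__)

# band edges echo the observed accuracy boundary around predicted c of 0.8-0.9
DEFAULT_BANDS: tuple[float, ...] = (0.8, 0.9)


@dataclass(frozen=True)
class AccuracySummary:
    """Prediction-error summary within one stratum of scenarios."""

    stratum: str
    mean_abs_error: float
    mean_signed_error: float
    n_scenarios: int


def _formula_column(formula: int) -> str:
    if formula not in (1, 2):
        raise ValueError(f"formula must be 1 or 2, got {formula!r}")
    return f"mean_c_formula{formula}"


def _valid_results(results: Sequence[ScenarioResult]) -> list[ScenarioResult]:
    if not results:
        raise ValueError("no scenario results supplied")
    kept = [r for r in results if r.n_valid > 0]
    skipped = len(results) - len(kept)
    if skipped:
        logger.info("skipping %d scenario(s) with no valid replicates", skipped)
    return kept


def figure1_table(results: Sequence[ScenarioResult], formula: int) -> pd.DataFrame:
    """One (predicted c, empirical c) row per scenario, sorted by predicted c."""
    col = _formula_column(formula)
    rows = [
        {
            "family": r.spec.family,
            "dist_param": r.spec.dist_param,
            "beta0": r.spec.beta0,
            "exp_beta1": round(math.exp(r.spec.beta1), 10),
            "predicted_c": getattr(r, col),
            "empirical_c": r.mean_c_empirical,
        }
        for r in _valid_results(results)
    ]
    frame = pd.DataFrame(rows)
    return frame.sort_values("predicted_c", kind="mergesort").reset_index(drop=True)


def figure2_table(results: Sequence[ScenarioResult], formula: int) -> pd.DataFrame:
    """Skewness vs (empirical - predicted) difference, one row per scenario per outcome group."""
    col = _formula_column(formula)
    rows = []
    for r in _valid_results(results):
        diff = r.mean_c_empirical - getattr(r, col)
        for group, skew in (
            ("affected", r.mean_skew_affected),
            ("unaffected", r.mean_skew_unaffected),
        ):
            rows.append(
                {
                    "family": r.spec.family,
                    "dist_param": r.spec.dist_param,
                    "beta0": r.spec.beta0,
                    "exp_beta1": round(math.exp(r.spec.beta1), 10),
                    "group": group,
                    "skewness": skew,
                    "difference": diff,
                }
            )
    if not rows:
        raise ValueError("no scenarios with valid replicates to tabulate")
    return pd.DataFrame(rows)


def accuracy_summary(
    results: Sequence[ScenarioResult],
    formula: int,
    bands: Sequence[float] = DEFAULT_BANDS,
) -> list[AccuracySummary]:
    """Mean absolute and signed (empirical - predicted) error per predicted-c band.

    ``bands`` are strictly increasing cutpoints inside (0.5, 1); they split
    scenarios into len(bands)+1 strata by predicted c.  Empty strata are
    reported with NaN errors and a zero count.
    """
    bands = tuple(bands)
    if any(not 0.5 < b < 1.0 for b in bands) or list(bands) != sorted(set(bands)):
        raise ValueError("bands must be strictly increasing cutpoints within (0.5, 1)")
    col = _formula_column(formula)
    kept = _valid_results(results)
    edges = (0.0, *bands, 1.0)
    out: list[AccuracySummary] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_band = [
            r.mean_c_empirical - getattr(r, col)
            for r in kept
            if lo < getattr(r, col) <= hi
        ]
        label = f"({lo:g}, {hi:g}]"
        if not in_band:
            out.append(AccuracySummary(label, math.nan, math.nan, 0))
            continue
        abs_err = sum(abs(e) for e in in_band) / len(in_band)
        signed = sum(in_band) / len(in_band)
        out.append(AccuracySummary(label, abs_err, signed, len(in_band)))
    return out


def accuracy_summary_to_frame(summaries: Iterable[AccuracySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": s.stratum,
                "mean_abs_error": s.mean_abs_error,
                "mean_signed_error": s.mean_signed_error,
                "n_scenarios": s.n_scenarios,
            }
            for s in summaries
        ]
    )
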