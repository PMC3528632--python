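"""Monte Carlo validation studies of the closed-form c-statistic predictions.

Four full-factorial studies, one per covariate family.  In every scenario a
covariate is drawn for each subject, the outcome is generated from a
Bernoulli draw with logit(p_i) = beta0 + beta1 * x_i, the univariate
logistic model is refit, and the empirical c-statistic is compared with the
two moment-based predictions.  The covariate families and factorial grids:

======== ============================== ====================== =======================
family   covariate draw                 beta0 levels           exp(beta1) levels
======== ============================== ====================== =======================
normal   N(0, sigma), sigma 0.2..4/0.2  -2, -1, 0, 1, 2        1..4 step 0.2 (16)
gamma    shape 0.25..4/0.25, scale 1    -1, 0, 1               1..4 step 0.25 (13)
lognormal log-mean 0, log-SD 0.1..2/0.1 -1, 0, 1               1..4 step 0.25 (13)
uniform  U(-a, a), a 0.2..4/0.2         -2, -1, 0, 1, 2        1..4 step 0.2 (16)
======== ============================== ====================== =======================

giving 1,600 / 624 / 780 / 1,600 scenarios, each defaulting to 500
replicates of 1,000 subjects.  Every scenario and replicate draws from an
independent, deterministically derived RNG substream, so results are
reproducible and independent of execution order or grid thinning.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .empirical import (
    SeparationWarning,
    SubjectData,
    empirical_c_of_model,
    group_moments,
    predicted_c_formula1,
    predicted_c_formula2,
)

__all__ = [
    "FAMILIES",
    "ScenarioSpec",
    "ReplicateResult",
    "ScenarioResult",
    "generate_covariate",
    "generate_outcomes",
    "sample_binormal",
    "run_replicate",
    "run_scenario",
    "build_factorial_grid",
    "run_study",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

FAMILIES = ("normal", "gamma", "lognormal", "uniform")

DEFAULT_N_SUBJECTS = 1000
DEFAULT_N_REPLICATES = 500

# the smallest group size for which every per-replicate quantity
# (variance, skewness) is defined
_MIN_GROUP = 3

RESULT_COLUMNS = [
    "family",
    "dist_param",
    "beta0",
    "exp_beta1",
    "n_subjects",
    "n_replicates",
    "n_valid",
    "n_failed",
    "mean_c_empirical",
    "mean_c_formula1",
    "mean_c_formula2",
    "mean_skew_affected",
    "mean_skew_unaffected",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of a factorial grid.

    ``dist_param`` is family-specific: the SD for ``normal``, the shape for
    ``gamma`` (scale fixed at 1), the SD of the log for ``lognormal``
    (log-mean 0), and the half-range ``a`` for ``uniform`` on (-a, a).
    ``beta1`` is stored on the log-odds scale; grids are specified as odds
    ratios exp(beta1) and converted once at grid construction.
    """

    family: str
    dist_param: float
    beta0: float
    beta1: float
    n_subjects: int = DEFAULT_N_SUBJECTS
    n_replicates: int = DEFAULT_N_REPLICATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown covariate family {self.family!r}; expected one of {FAMILIES}")
        if not (math.isfinite(self.dist_param) and self.dist_param > 0):
            raise ValueError(f"dist_param must be positive, got {self.dist_param!r}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


@dataclass(frozen=True)
class ReplicateResult:
    """Per-dataset quantities from a single simulated replicate."""

    c_empirical: float = math.nan
    c_formula1: float = math.nan
    c_formula2: float = math.nan
    skew_affected: float = math.nan
    skew_unaffected: float = math.nan
    valid: bool = False
    failure_reason: str | None = None


@dataclass(frozen=True)
class ScenarioResult:
    """Means over the valid replicates of one scenario."""

    spec: ScenarioSpec
    mean_c_empirical: float
    mean_c_formula1: float
    mean_c_formula2: float
    mean_skew_affected: float
    mean_skew_unaffected: float
    n_valid: int
    n_failed: int
    sd_c_empirical: float = math.nan


def generate_covariate(
    family: str, dist_param: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n covariate values from the requested family.

    normal: N(0, dist_param); gamma: shape=dist_param, scale=1;
    lognormal: log-mean 0, log-SD dist_param; uniform: U(-a, +a).
    """
    if family == "normal":
        return rng.normal(0.0, dist_param, size=n)
    if family == "gamma":
        return rng.gamma(shape=dist_param, scale=1.0, size=n)
    if family == "lognormal":
        return rng.lognormal(mean=0.0, sigma=dist_param, size=n)
    if family == "uniform":
        return rng.uniform(-dist_param, dist_param, size=n)
    raise ValueError(f"unknown covariate family {family!r}; expected one of {FAMILIES}")


def generate_outcomes(
    x: np.ndarray, beta0: float, beta1: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli outcomes with logit(p_i) = beta0 + beta1 * x_i."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    from scipy.special import expit

    p = expit(beta0 + beta1 * x)
    return (rng.random(x.size) < p).astype(np.int8)


def sample_binormal(
    mu_affected: float,
    mu_unaffected: float,
    sigma: float,
    n_affected: int,
    n_unaffected: int,
    rng: np.random.Generator,
) -> SubjectData:
    """Draw x | y directly from two normals with common SD.

    A generator for validating the closed form independently of the
    logistic outcome-sampling path: group membership is fixed, and the
    covariate is conditionally normal by construction.
    """
    xa = rng.normal(mu_affected, sigma, size=n_affected)
    xu = rng.normal(mu_unaffected, sigma, size=n_unaffected)
    x = np.concatenate([xa, xu])
    y = np.concatenate([np.ones(n_affected, dtype=np.int8), np.zeros(n_unaffected, dtype=np.int8)])
    return SubjectData(x, y)


def run_replicate(spec: ScenarioSpec, rng: np.random.Generator) -> ReplicateResult:
    """Simulate one dataset under ``spec`` and evaluate empirical vs predicted c.

    Degenerate datasets (single-class outcome, an outcome group too small
    for its moments, or a separated/non-converged fit) are recorded as
    invalid with a reason rather than raised.
    """
    x = generate_covariate(spec.family, spec.dist_param, spec.n_subjects, rng)
    y = generate_outcomes(x, spec.beta0, spec.beta1, rng)

    n1 = int(y.sum())
    if n1 < _MIN_GROUP or spec.n_subjects - n1 < _MIN_GROUP:
        return ReplicateResult(valid=False, failure_reason="degenerate outcome")

    data = SubjectData(x, y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", SeparationWarning)
            c_emp, fit = empirical_c_of_model(data)
    except SeparationWarning:
        return ReplicateResult(valid=False, failure_reason="separation")
    except (ValueError, np.linalg.LinAlgError) as exc:
        return ReplicateResult(valid=False, failure_reason=str(exc))

    try:
        c1 = predicted_c_formula1(data)
    except ValueError as exc:
        return ReplicateResult(valid=False, failure_reason=str(exc))
    c2 = predicted_c_formula2(data, fit=fit)
    m = group_moments(data)
    return ReplicateResult(
        c_empirical=c_emp,
        c_formula1=c1,
        c_formula2=c2,
        skew_affected=m.skew_affected,
        skew_unaffected=m.skew_unaffected,
        valid=True,
    )


def _replicate_rng(scenario_seed: int, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([scenario_seed, replicate_index]))


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Run all replicates of one scenario and average over the valid ones.

    Each replicate uses an independent substream keyed by
    (scenario seed, replicate index), so results are reproducible
    bit-for-bit and independent of which other scenarios ran.
    """
    rows = [run_replicate(spec, _replicate_rng(spec.seed, r)) for r in range(spec.n_replicates)]
    valid = [r for r in rows if r.valid]
    n_valid = len(valid)
    if n_valid == 0:
        logger.warning(
            "scenario %s dist_param=%g beta0=%g beta1=%g: all %d replicates invalid",
            spec.family, spec.dist_param, spec.beta0, spec.beta1, spec.n_replicates,
        )
        return ScenarioResult(
            spec=spec,
            mean_c_empirical=math.nan,
            mean_c_formula1=math.nan,
            mean_c_formula2=math.nan,
            mean_skew_affected=math.nan,
            mean_skew_unaffected=math.nan,
            n_valid=0,
            n_failed=spec.n_replicates,
        )
    c_emp = np.array([r.c_empirical for r in valid])
    return ScenarioResult(
        spec=spec,
        mean_c_empirical=float(c_emp.mean()),
        mean_c_formula1=float(np.mean([r.c_formula1 for r in valid])),
        mean_c_formula2=float(np.mean([r.c_formula2 for r in valid])),
        mean_skew_affected=float(np.mean([r.skew_affected for r in valid])),
        mean_skew_unaffected=float(np.mean([r.skew_unaffected for r in valid])),
        n_valid=n_valid,
        n_failed=spec.n_replicates - n_valid,
        sd_c_empirical=float(c_emp.std(ddof=1)) if n_valid >= 2 else math.nan,
    )


def _levels(start: float, stop_count: int, step: float) -> list[float]:
    # integer-indexed construction; repeated addition would drift
    return [round(start + k * step, 10) for k in range(stop_count)]


_GRID_FACTORS: dict[str, dict[str, list[float]]] = {
    "normal": {
        "beta0": [-2.0, -1.0, 0.0, 1.0, 2.0],
        "exp_beta1": _levels(1.0, 16, 0.2),
        "dist_param": _levels(0.2, 20, 0.2),
    },
    "gamma": {
        "beta0": [-1.0, 0.0, 1.0],
        "exp_beta1": _levels(1.0, 13, 0.25),
        "dist_param": _levels(0.25, 16, 0.25),
    },
    "uniform": {
        "beta0": [-2.0, -1.0, 0.0, 1.0, 2.0],
        "exp_beta1": _levels(1.0, 16, 0.2),
        "dist_param": _levels(0.2, 20, 0.2),
    },
    "lognormal": {
        "beta0": [-1.0, 0.0, 1.0],
        "exp_beta1": _levels(1.0, 13, 0.25),
        "dist_param": _levels(0.1, 20, 0.1),
    },
}


def _scenario_seed(master_seed: int, grid_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(grid_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def build_factorial_grid(
    study: str,
    n_subjects: int = DEFAULT_N_SUBJECTS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
    thin: int = 1,
) -> list[ScenarioSpec]:
    """Full cross-product of the factor levels of one study.

    Grid sizes at ``thin=1``: normal 1,600 (5x16x20); gamma 624 (3x13x16);
    uniform 1,600; lognormal 780 (3x13x20).  ``thin=k`` keeps every k-th
    level of each factor (evenly spaced, always including the first), for
    desk-scale runs.  Each scenario's seed is derived from
    ``(master_seed, its index in the full grid)``, so a thinned grid's
    scenarios reproduce the corresponding full-grid cells exactly.
    """
    if study not in _GRID_FACTORS:
        raise ValueError(f"unknown study {study!r}; expected one of {FAMILIES}")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    f = _GRID_FACTORS[study]
    b0_all, or_all, dp_all = f["beta0"], f["exp_beta1"], f["dist_param"]
    specs: list[ScenarioSpec] = []
    grid_index = 0
    for i0, beta0 in enumerate(b0_all):
        for i1, odds_ratio in enumerate(or_all):
            for i2, dist_param in enumerate(dp_all):
                keep = i0 % thin == 0 and i1 % thin == 0 and i2 % thin == 0
                if keep:
                    specs.append(
                        ScenarioSpec(
                            family=study,
                            dist_param=dist_param,
                            beta0=beta0,
                            beta1=math.log(odds_ratio),
                            n_subjects=n_subjects,
                            n_replicates=n_replicates,
                            seed=_scenario_seed(master_seed, grid_index),
                        )
                    )
                grid_index += 1
    return specs


def results_to_frame(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Flatten ScenarioResults into the study output table."""
    rows = []
    for r in results:
        rows.append(
            {
                "family": r.spec.family,
                "dist_param": r.spec.dist_param,
                "beta0": r.spec.beta0,
                "exp_beta1": round(math.exp(r.spec.beta1), 10),
                "n_subjects": r.spec.n_subjects,
                "n_replicates": r.spec.n_replicates,
                "n_valid": r.n_valid,
                "n_failed": r.n_failed,
                "mean_c_empirical": r.mean_c_empirical,
                "mean_c_formula1": r.mean_c_formula1,
                "mean_c_formula2": r.mean_c_formula2,
                "mean_skew_affected": r.mean_skew_affected,
                "mean_skew_unaffected": r.mean_skew_unaffected,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def results_from_frame(frame: pd.DataFrame) -> list[ScenarioResult]:
    """Rebuild ScenarioResults from a study output table (inverse of :func:`results_to_frame`).

    Replicate-level spread (``sd_c_empirical``) is not stored in the table
    and comes back as NaN.
    """
    out: list[ScenarioResult] = []
    for r in frame.itertuples():
        spec = ScenarioSpec(
            family=str(r.family),
            dist_param=float(r.dist_param),
            beta0=float(r.beta0),
            beta1=math.log(float(r.exp_beta1)),
            n_subjects=int(r.n_subjects),
            n_replicates=int(r.n_replicates),
        )
        out.append(
            ScenarioResult(
                spec=spec,
                mean_c_empirical=float(r.mean_c_empirical),
                mean_c_formula1=float(r.mean_c_formula1),
                mean_c_formula2=float(r.mean_c_formula2),
                mean_skew_affected=float(r.mean_skew_affected),
                mean_skew_unaffected=float(r.mean_skew_unaffected),
                n_valid=int(r.n_valid),
                n_failed=int(r.n_failed),
            )
        )
    return out


def run_study(
    study: str,
    n_subjects: int = DEFAULT_N_SUBJECTS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
    thin: int = 1,
    checkpoint: str | Path | None = None,
    progress: bool = False,
) -> list[ScenarioResult]:
    """Run all (or a thinned subset of) scenarios of one study.

    With ``checkpoint`` set, finished scenarios are appended to that CSV as
    they complete and an interrupted run resumes past them; the checkpoint
    key is (dist_param, beta0, exp_beta1).
    """
    specs = build_factorial_grid(study, n_subjects, n_replicates, master_seed, thin)
    done: set[tuple[float, float, float]] = set()
    checkpoint = Path(checkpoint) if checkpoint is not None else None
    if checkpoint is not None and checkpoint.exists():
        prev = pd.read_csv(checkpoint)
        done = {
            (round(r.dist_param, 10), r.beta0, round(r.exp_beta1, 10))
            for r in prev.itertuples()
        }
        logger.info("checkpoint %s: %d scenarios already complete", checkpoint, len(done))

    results: list[ScenarioResult] = []
    for k, spec in enumerate(specs):
        key = (round(spec.dist_param, 10), spec.beta0, round(math.exp(spec.beta1), 10))
        if key in done:
            continue
        res = run_scenario(spec)
        results.append(res)
        if checkpoint is not None:
            frame = results_to_frame([res])
            frame.to_csv(checkpoint, mode="a", header=not checkpoint.exists(), index=False)
        if progress and (k + 1) % 50 == 0:
            logger.info("%s study: %d/%d scenarios done", study, k + 1, len(specs))
    if checkpoint is not None:
        full = pd.read_csv(checkpoint)
        order = {key: i for i, key in enumerate(
            (round(s.dist_param, 10), s.beta0, round(math.exp(s.beta1), 10)) for s in specs
        )}
        full["_ord"] = [
            order.get((round(r.dist_param, 10), r.beta0, round(r.exp_beta1, 10)), -1)
            for r in full.itertuples()
        ]
        full = full.sort_values("_ord").drop(columns="_ord")
        full.to_csv(checkpoint, index=False)
    return results
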