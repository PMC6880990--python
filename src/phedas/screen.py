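"""Per-phecode logistic screen.

For each phecode k the mean model

    logit P(case) = b0 + bm * m_k + ba * age + bs * sex

is fit by maximum likelihood and the aggregate-measure coefficient bm
(written theta downstream) is reported with its Wald confidence interval on
the log-odds scale.  Non-convergence and complete/quasi-complete separation
are flagged on the result, never raised: a phenome-wide screen must survive
individual degenerate tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

try:  # raised by some statsmodels solvers instead of warning
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass

__all__ = ["IntervalEstimate", "ScreenResult", "fit_phecode", "run_screen", "PhecodeScreen"]

# |theta| or SE beyond these on the log-odds scale marks a numerically
# divergent (separated) fit
_SEP_THETA = 15.0
_SEP_SE = 50.0


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate of a log odds ratio with a Wald uncertainty interval."""

    theta_hat: float
    se: float
    lo: float
    hi: float
    level: float
    converged: bool
    n_used: int


@dataclass(frozen=True)
class ScreenResult:
    phecode: str
    estimate: IntervalEstimate | None
    case_carriers: int
    control_carriers: int
    separation: bool = False

    def as_row(self) -> dict:
        est = self.estimate
        row = {
            "phecode": self.phecode,
            "case_carriers": self.case_carriers,
            "control_carriers": self.control_carriers,
            "separation": self.separation,
        }
        if est is None:
            row.update(
                theta=np.nan, se=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                converged=False, n_used=0,
            )
        else:
            row.update(
                theta=est.theta_hat, se=est.se, ci_lo=est.lo, ci_hi=est.hi,
                converged=est.converged, n_used=est.n_used,
            )
        row["or"] = float(np.exp(row["theta"]))
        row["or_lo"] = float(np.exp(row["ci_lo"]))
        row["or_hi"] = float(np.exp(row["ci_hi"]))
        return row


def fit_phecode(
    matrix: pd.DataFrame,
    phecode: str,
    level: float = 0.95,
    use_covariates: bool = True,
) -> ScreenResult:
    """Fit the logistic mean model for one phecode.

    ``matrix`` is the aggregate matrix (one row per subject, phecode columns
    plus ``age``, ``sex``, ``y``).  Covariate columns with no variation are
    dropped from the design.  Returns a ScreenResult; separation and
    non-convergence set flags rather than raising.
    """
    if phecode not in matrix.columns:
        raise KeyError(f"phecode {phecode!r} not in matrix")
    m = matrix[phecode].to_numpy(dtype=float)
    y = matrix["y"].to_numpy(dtype=int)
    carriers = m > 0
    case_carriers = int((carriers & (y == 1)).sum())
    control_carriers = int((carriers & (y == 0)).sum())

    cols = [m]
    if use_covariates:
        for cov in ("age", "sex"):
            if cov in matrix.columns:
                v = matrix[cov].to_numpy(dtype=float)
                if np.nanstd(v) > 0 and not np.isnan(v).any():
                    cols.append(v)
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    n_used = len(y)

    separation = False
    converged = False
    theta = se = np.nan
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            theta = float(res.params[1])
            se = float(res.bse[1])
            converged = bool(res.mle_retvals.get("converged", False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            converged = False
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        separation = True
        converged = False
    if np.isfinite(theta) and (abs(theta) > _SEP_THETA or se > _SEP_SE):
        separation = True
        converged = False
    if not np.isfinite(theta) or not np.isfinite(se):
        separation = True
        converged = False

    z = stats.norm.ppf(1 - (1 - level) / 2)
    est = IntervalEstimate(
        theta_hat=theta, se=se,
        lo=theta - z * se, hi=theta + z * se,
        level=level, converged=converged, n_used=n_used,
    )
    return ScreenResult(
        phecode=phecode, estimate=est,
        case_carriers=case_carriers, control_carriers=control_carriers,
        separation=separation,
    )


def run_screen(
    matrix: pd.DataFrame,
    phecodes: Sequence[str] | None = None,
    level: float = 0.95,
    min_carriers: int = 5,
    use_covariates: bool = True,
) -> tuple[list[ScreenResult], list[dict]]:
    """Screen every phecode; returns (results, skipped).

    A phecode is skipped (with a reason record) when either class has fewer
    than ``min_carriers`` carriers.  Results come back sorted by phecode so
    repeated runs are identical.
    """
    if min_carriers < 0:
        raise ValueError("min_carriers must be >= 0")
    if phecodes is None:
        phecodes = matrix.attrs.get(
            "phecodes",
            [c for c in matrix.columns if c not in ("age", "sex", "y")],
        )
    results: list[ScreenResult] = []
    skipped: list[dict] = []
    y = matrix["y"].to_numpy(dtype=int)
    for phe in sorted(set(phecodes)):
        carriers = matrix[phe].to_numpy(dtype=float) > 0
        cc = int((carriers & (y == 1)).sum())
        kc = int((carriers & (y == 0)).sum())
        if min(cc, kc) < min_carriers:
            skipped.append(
                {
                    "phecode": phe,
                    "reason": f"carriers below threshold "
                    f"(cases {cc}, controls {kc}, min {min_carriers})",
                }
            )
            continue
        results.append(
            fit_phecode(matrix, phe, level=level, use_covariates=use_covariates)
        )
    return results, skipped


class PhecodeScreen(BaseEstimator):
    """Phenome-wide logistic screen as an sklearn-style estimator.

    Parameters
    ----------
    level : float, default 0.95
        Confidence level for the Wald interval on the log-odds scale.
    min_carriers : int, default 5
        Minimum carriers required in each class for a phecode to be fit.
    use_covariates : bool, default True
        Include age and sex in the design when the columns are present.

    Attributes (after ``fit``)
    --------------------------
    results_ : DataFrame
        One row per fitted phecode: theta, se, ci_lo/ci_hi (log-odds),
        or/or_lo/or_hi, carrier counts, convergence and separation flags.
    skipped_ : DataFrame
        Phecodes excluded by the carrier filter, with reasons.
    """

    def __init__(self, level: float = 0.95, min_carriers: int = 5,
                 use_covariates: bool = True):
        self.level = level
        self.min_carriers = min_carriers
        self.use_covariates = use_covariates

    def fit(self, X: pd.DataFrame, y: Iterable[int] | None = None,
            phecodes: Sequence[str] | None = None):
        """Fit one logistic model per phecode column of ``X``.

        ``X`` is the aggregate matrix; ``y`` overrides its ``y`` column when
        given (sklearn calling convention).
        """
        matrix = X.copy()
        if y is not None:
            matrix["y"] = np.asarray(list(y), dtype=int)
        if "y" not in matrix.columns:
            raise ValueError("no case/control labels: pass y or a 'y' column")
        results, skipped = run_screen(
            matrix, phecodes=phecodes, level=self.level,
            min_carriers=self.min_carriers, use_covariates=self.use_covariates,
        )
        self.results_ = pd.DataFrame(
            [r.as_row() for r in results],
            columns=["phecode", "theta", "se", "ci_lo", "ci_hi", "or", "or_lo",
                     "or_hi", "converged", "separation", "case_carriers",
                     "control_carriers", "n_used"],
        )
        self.skipped_ = pd.DataFrame(skipped, columns=["phecode", "reason"])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict ``X`` to the phecodes that produced a converged fit."""
        keep = list(self.results_.loc[self.results_["converged"], "phecode"])
        extra = [c for c in ("age", "sex", "y") if c in X.columns]
        return X[keep + extra]
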