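"""Per-variant additive logistic association within a sex stratum.

Each binary outcome (six pigmentation/sun-sensitivity traits plus
melanoma case/control status) is regressed on minor-allele dosage coded
additively (0/1/2 copies), separately in females and males — and
optionally pooled.  The maximum-likelihood fit uses Newton/IRLS with the
intercept and one slope; the reported standard error comes from the
inverse observed information, so the P value and 95% CI are Wald-type.
Wald beta/SE pairs are exactly what the downstream sex-differentiated
chi-square statistics consume.

No covariate adjustment is applied (the study design frequency-matched
controls by age and found no residual age differences), and missing
dosages or questionnaire answers are dropped per (variant, outcome)
pair (complete-case analysis).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import (
    AssocResult,
    DataError,
    GenotypeMatrix,
    SampleRecord,
    outcome_vector,
    sex_mask,
)

#: maximum |beta| beyond which the likelihood is treated as separated
SEPARATION_BOUND = 15.0
#: standard errors beyond this signal a flat (quasi-separated) likelihood
SE_BOUND = 100.0
#: score convergence tolerance for the Newton/IRLS iterations
SCORE_TOL = 1e-8
MAX_ITER = 50


def fit_additive_logistic(
    dosage: np.ndarray, outcome: np.ndarray
) -> tuple[float, float, str]:
    """Fit ``logit P(y=1) = b0 + b * dosage`` by Newton/IRLS.

    Returns ``(beta, se, flag)`` where flag is ``"ok"``, ``"separated"``
    (slope escaping beyond +/-15, or a flat likelihood with an
    effectively infinite standard error, as under (quasi-)separation) or
    ``"degenerate"`` (single outcome class, constant dosage, or a
    singular information matrix).  Convergence requires the maximum
    absolute score to drop below 1e-8 within 50 iterations.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if d.shape != y.shape:
        raise DataError("dosage and outcome must have equal length")
    if d.size < 2:
        return float("nan"), float("nan"), "degenerate"
    if y.min() == y.max() or d.min() == d.max():
        return float("nan"), float("nan"), "degenerate"
    X = np.column_stack([np.ones_like(d), d])
    theta = np.zeros(2)
    for _ in range(MAX_ITER):
        eta = X @ theta
        p = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - p)
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return float("nan"), float("nan"), "degenerate"
        theta = theta + step
        if abs(theta[1]) > SEPARATION_BOUND:
            return float(theta[1]), float("nan"), "separated"
        if np.max(np.abs(score)) < SCORE_TOL:
            break
    eta = X @ theta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float(theta[1]), float("nan"), "degenerate"
    se = float(np.sqrt(cov[1, 1]))
    if not np.isfinite(se) or se <= 0:
        return float(theta[1]), float("nan"), "degenerate"
    if se > SE_BOUND:
        # flat likelihood: the score converges while the slope wanders
        # towards an infinite (quasi-separated) maximum
        return float(theta[1]), float("nan"), "separated"
    return float(theta[1]), se, "ok"


def or_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio with two-sided Wald confidence interval.

    ``exp(beta -+ z * se)`` with z the two-sided normal quantile
    (1.959964 at level 0.95).
    """
    if not 0 < level < 1:
        raise DataError("level must be in (0,1)")
    if se < 0:
        raise DataError("se must be >= 0")
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def wald_p(beta: float, se: float) -> float:
    """Two-sided Wald P value from the normal reference."""
    if se <= 0:
        raise DataError("se must be > 0")
    return float(2 * stats.norm.sf(abs(beta) / se))


def assoc_scan(
    gm: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    outcome: str,
    stratum: str,
    level: float = 0.95,
) -> list[AssocResult]:
    """Additive logistic scan of one outcome over every variant in a stratum.

    One :class:`AssocResult` per variant, in panel order.  Complete-case
    filtering drops samples with a missing dosage or outcome; per-variant
    degeneracies (single outcome class, separation) are recorded in
    ``status_flag`` and the scan continues.  Output is invariant to the
    order of the input samples.
    """
    if len(samples) != gm.n_samples:
        raise DataError("sample records must match genotype matrix rows")
    mask = sex_mask(samples, stratum)
    if not mask.any():
        raise DataError(f"stratum {stratum!r} is empty")
    y_all = outcome_vector(samples, outcome)
    results: list[AssocResult] = []
    for j, v in enumerate(gm.variants):
        d = gm.dosage[mask, j]
        y = y_all[mask]
        ok = np.isfinite(d) & np.isfinite(y)
        d_cc, y_cc = d[ok], y[ok]
        beta, se, flag = fit_additive_logistic(d_cc, y_cc)
        res = AssocResult(
            rsid=v.rsid,
            stratum=stratum,
            outcome=outcome,
            n_used=int(ok.sum()),
            beta=beta,
            se=se,
            status_flag=flag,
        )
        if flag == "ok":
            res.or_, res.ci_low, res.ci_high = or_ci(beta, se, level)
            res.p = wald_p(beta, se)
        results.append(res)
    return results


def significant(results: Sequence[AssocResult], alpha: float = 0.01) -> list[AssocResult]:
    """Cleanly fitted results with P below ``alpha`` (strict)."""
    return [r for r in results if r.ok and r.p < alpha]
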