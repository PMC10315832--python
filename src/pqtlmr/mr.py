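"""Two-sample MR estimators: Wald ratio and fixed-effect IVW.

A single instrument yields the Wald ratio beta_out / beta_exp with the
first-order delta-method standard error se_out / |beta_exp|.  Two or more
instruments are combined by inverse-variance weighting of the per-instrument
ratios; the default is the fixed-effect estimator (a multiplicative
random-effects variant is available via ``random_effects=True``).  P-values
are two-sided normal, and odds ratios with Wald 95% intervals are reported
per SD increase in the exposure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .gwas_io import HarmonizedPair, usable_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "MRResult",
    "wald_ratio",
    "ivw",
    "mr_estimate",
    "to_odds_ratio",
    "bonferroni_threshold",
    "Z95",
]

#: 97.5% normal quantile used for all 95% Wald intervals.
Z95 = 1.959964

_P_FLOOR = 1e-300  # keep p-values in (0, 1] even for huge z


@dataclass(frozen=True, slots=True)
class MRResult:
    """A causal estimate for one exposure→outcome test.

    ``beta`` is the log odds (or outcome units) per SD of exposure;
    ``odds_ratio``/``ci_low``/``ci_high`` are its exponentiated 95% Wald
    interval.  ``heterogeneity_q`` is Cochran's Q across instruments
    (``None`` for a single instrument); it is reported, not filtered on.
    """

    exposure_id: str
    outcome_id: str
    method: str  # "wald_ratio" or "ivw"
    beta: float
    se: float
    pvalue: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_snps: int
    significant: bool
    heterogeneity_q: Optional[float] = None
    heterogeneity_q_pvalue: Optional[float] = None


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into (OR, 95% CI low, 95% CI high)."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def _two_sided_p(beta: float, se: float) -> float:
    return max(2.0 * sps.norm.sf(abs(beta / se)), _P_FLOOR)


def _build_result(
    beta: float,
    se: float,
    method: str,
    n_snps: int,
    alpha: float,
    exposure_id: str,
    outcome_id: str,
    q: Optional[float] = None,
    q_p: Optional[float] = None,
) -> MRResult:
    p = _two_sided_p(beta, se)
    or_, lo, hi = to_odds_ratio(beta, se)
    return MRResult(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        method=method,
        beta=beta,
        se=se,
        pvalue=p,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        n_snps=n_snps,
        significant=p < alpha,
        heterogeneity_q=q,
        heterogeneity_q_pvalue=q_p,
    )


def wald_ratio(
    pair: HarmonizedPair,
    alpha: float = 0.05,
    exposure_id: str = "",
    outcome_id: str = "",
) -> MRResult:
    """Single-instrument causal estimate beta_out / beta_exp."""
    if not pair.usable:
        raise ValueError(f"{pair.variant_id}: cannot estimate from a dropped pair")
    if pair.beta_exp == 0:
        raise ValueError(f"{pair.variant_id}: exposure beta is zero")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return _build_result(beta, se, "wald_ratio", 1, alpha, exposure_id, outcome_id)


def _ratio_arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray]:
    betas = np.array([p.beta_out / p.beta_exp for p in pairs])
    ses = np.array([p.se_out / abs(p.beta_exp) for p in pairs])
    return betas, ses


def ivw(
    pairs: Sequence[HarmonizedPair],
    alpha: float = 0.05,
    random_effects: bool = False,
    exposure_id: str = "",
    outcome_id: str = "",
) -> MRResult:
    """Inverse-variance-weighted combination of per-instrument Wald ratios.

    Fixed-effect by default; with ``random_effects=True`` the standard error
    is inflated by sqrt(max(1, Q/(k-1))).  Pairs with a zero exposure beta
    are dropped with a warning.
    """
    pairs = usable_pairs(pairs)
    kept = [p for p in pairs if p.beta_exp != 0]
    for p in pairs:
        if p.beta_exp == 0:
            logger.warning("ivw: dropping %s (exposure beta is zero)", p.variant_id)
    if len(kept) < 1:
        raise ValueError("ivw: no usable pairs with nonzero exposure beta")
    if len(kept) < 2:
        return wald_ratio(kept[0], alpha, exposure_id, outcome_id)

    betas, ses = _ratio_arrays(kept)
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (betas - beta) ** 2))
    dof = len(kept) - 1
    q_p = float(sps.chi2.sf(q, dof))
    if random_effects:
        se *= math.sqrt(max(1.0, q / dof))
    logger.debug("ivw: k=%d Q=%.3f (p=%.3g)", len(kept), q, q_p)
    return _build_result(beta, se, "ivw", len(kept), alpha, exposure_id, outcome_id, q, q_p)


def mr_estimate(
    pairs: Sequence[HarmonizedPair],
    alpha: float = 0.05,
    random_effects: bool = False,
    exposure_id: str = "",
    outcome_id: str = "",
) -> MRResult:
    """Dispatch: Wald ratio for one usable instrument, IVW for two or more."""
    kept = [p for p in usable_pairs(pairs) if p.beta_exp != 0]
    if not kept:
        raise ValueError("mr_estimate: no usable instruments")
    if len(kept) == 1:
        return wald_ratio(kept[0], alpha, exposure_id, outcome_id)
    return ivw(kept, alpha, random_effects, exposure_id, outcome_id)
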