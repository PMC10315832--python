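"""Bayesian colocalization under a single-causal-variant model.

Each variant's evidence of association with a trait is summarized by the
Wakefield approximate Bayes factor: with V = se², W = prior_sd² and
z = beta/se,

    log ABF = 1/2 [ log(V / (V + W)) + z² · W / (V + W) ].

For a region of m variants and two traits, the five hypotheses are
enumerated exactly as in the standard single-causal-variant scheme:

* H0 — no association with either trait (mass 1)
* H1 / H2 — association with one trait only (mass p1·ΣABF₁ᵢ, p2·ΣABF₂ⱼ)
* H3 — two distinct causal variants (mass p1·p2·Σ_{i≠j} ABF₁ᵢ·ABF₂ⱼ)
* H4 — one shared causal variant (mass p12·Σᵢ ABF₁ᵢ·ABF₂ᵢ)

All sums run in log space (log-sum-exp); posteriors are the normalized
masses.  Defaults: per-variant priors p1 = p2 = 1e-4, p12 = 1e-5; effect
prior sd 0.15 for a quantitative trait (per-SD scale) and 0.2 for a binary
trait (log-odds scale); a region colocalizes when PPH4 > 0.8 (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .gwas_io import VariantAssociation

__all__ = ["ColocPriors", "ColocResult", "wakefield_labf", "coloc_abf"]


@dataclass(frozen=True, slots=True)
class ColocPriors:
    """Per-variant prior probabilities of association.

    ``p1``/``p2`` — causal for trait 1/2 only; ``p12`` — causal for both.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("priors must satisfy 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("per-variant priors sum to >= 1")

    def check_region(self, n_variants: int) -> None:
        if n_variants * (self.p1 + self.p2 + self.p12) >= 1:
            raise ValueError(
                f"priors too large for a {n_variants}-variant region: "
                "n * (p1 + p2 + p12) must stay below 1"
            )


@dataclass(frozen=True, slots=True)
class ColocResult:
    """Posterior probabilities over the five colocalization hypotheses."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    colocalized: bool

    def posteriors(self) -> tuple[float, float, float, float, float]:
        return (self.pph0, self.pph1, self.pph2, self.pph3, self.pph4)


def wakefield_labf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for one variant/trait association."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if prior_sd <= 0:
        raise ValueError(f"prior_sd must be positive, got {prior_sd}")
    v = se * se
    w = prior_sd * prior_sd
    z = beta / se
    shrink = w / (v + w)
    return 0.5 * (math.log(v / (v + w)) + z * z * shrink)


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for b <= a; -inf when the difference vanishes."""
    if b >= a:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(
    region_exp: Sequence[VariantAssociation],
    region_out: Sequence[VariantAssociation],
    priors: ColocPriors = ColocPriors(),
    pph4_threshold: float = 0.8,
    prior_sd_exp: float = 0.15,
    prior_sd_out: float = 0.2,
) -> ColocResult:
    """Colocalize two traits over a shared (harmonized) variant region.

    Variants are matched by id, in the exposure's order; at least one shared
    variant is required.  Note H3 is impossible (mass 0) for a single-variant
    region.
    """
    out_by_id = {v.variant_id: v for v in region_out}
    shared = [(e, out_by_id[e.variant_id]) for e in region_exp if e.variant_id in out_by_id]
    if not shared:
        raise ValueError("coloc_abf: no shared variants between the two regions")
    m = len(shared)
    priors.check_region(m)

    labf1 = np.array([wakefield_labf(e.beta, e.se, prior_sd_exp) for e, _ in shared])
    labf2 = np.array([wakefield_labf(o.beta, o.se, prior_sd_out) for _, o in shared])

    l1 = float(logsumexp(labf1))
    l2 = float(logsumexp(labf2))
    l12_same = float(logsumexp(labf1 + labf2))
    l12_diff = _logdiffexp(l1 + l2, l12_same)

    log_masses = np.array(
        [
            0.0,
            math.log(priors.p1) + l1,
            math.log(priors.p2) + l2,
            math.log(priors.p1) + math.log(priors.p2) + l12_diff,
            math.log(priors.p12) + l12_same,
        ]
    )
    post = np.exp(log_masses - logsumexp(log_masses))
    post = np.clip(post, 0.0, 1.0)
    pph0, pph1, pph2, pph3, pph4 = (float(x) for x in post)
    return ColocResult(
        pph0=pph0,
        pph1=pph1,
        pph2=pph2,
        pph3=pph3,
        pph4=pph4,
        n_snps=m,
        colocalized=pph4 > pph4_threshold,
    )
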