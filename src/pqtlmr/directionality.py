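"""Reverse-causality checks: Steiger directionality test and bidirectional MR.

The Steiger test asks whether the instruments explain more variance in the
exposure than in the outcome: per-trait PVE is summed over the (clumped,
hence approximately independent) instruments, converted to a correlation
r = sqrt(PVE), Fisher z-transformed, and the difference tested with a
two-sided normal statistic

    z = (z_exp - z_out) / sqrt(1/(n_exp - 3) + 1/(n_out - 3)).

The test passes when the direction is correct (PVE_exp > PVE_out) and
p < 0.05; otherwise it fails.

Bidirectional MR swaps the roles: instruments are selected from the outcome
GWAS (same significance/strength/clumping criteria, no cis restriction) and
the outcome's effect on the exposure is estimated with the same Wald/IVW
machinery.  Reverse causality is confirmed when the reverse estimate is
significant (p < 0.05) or the forward Steiger test failed; an outcome with
no eligible instruments yields an explicit not-testable result that counts
as non-significant.

For a binary outcome the PVE uses the same observed-scale formula
beta^2/(beta^2 + N*se^2) with total N — an approximation (no liability-scale
conversion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from scipy import stats as sps

from .gwas_io import HarmonizedPair, LDMatrix, SummaryStats, harmonize, usable_pairs
from .instruments import GeneAnnotation, compute_pve, select_instruments
from .mr import MRResult, mr_estimate

__all__ = [
    "SteigerResult",
    "NotTestable",
    "steiger_test",
    "bidirectional_mr",
    "reverse_causality_verdict",
]


@dataclass(frozen=True, slots=True)
class SteigerResult:
    """Outcome of the directionality test.

    ``verdict`` is "passed" iff the direction is correct and p < 0.05.
    """

    pve_exposure: float
    pve_outcome: float
    correct_direction: bool
    zscore: float
    pvalue: float
    verdict: str


@dataclass(frozen=True, slots=True)
class NotTestable:
    """Explicit marker for a reverse MR that could not be run."""

    reason: str


def steiger_test(pairs: Sequence[HarmonizedPair], alpha: float = 0.05) -> SteigerResult:
    """Directionality test on the harmonized instrument pairs.

    Sample sizes per trait are taken as the minimum across instruments
    (conservative when they differ).  Requires n > 3 on both sides.
    """
    kept = usable_pairs(pairs)
    if not kept:
        raise ValueError("steiger_test: no usable pairs")
    n_exp = min(p.n_exp for p in kept)
    n_out = min(p.n_out for p in kept)
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("steiger_test: sample size must exceed 3 for both traits")

    pve_exp = sum(compute_pve(p.beta_exp, p.se_exp, p.n_exp) for p in kept)
    pve_out = sum(compute_pve(p.beta_out, p.se_out, p.n_out) for p in kept)
    # summed PVE can exceed 1 only in pathological inputs; keep atanh in range
    r_exp = math.sqrt(min(pve_exp, 1.0 - 1e-12))
    r_out = math.sqrt(min(pve_out, 1.0 - 1e-12))
    z_exp = math.atanh(r_exp)
    z_out = math.atanh(r_out)
    denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (z_exp - z_out) / denom
    p = max(2.0 * sps.norm.sf(abs(z)), 1e-300)
    correct = pve_exp > pve_out
    verdict = "passed" if (correct and p < alpha) else "failed"
    return SteigerResult(
        pve_exposure=pve_exp,
        pve_outcome=pve_out,
        correct_direction=correct,
        zscore=z,
        pvalue=p,
        verdict=verdict,
    )


def bidirectional_mr(
    outcome_stats: SummaryStats,
    protein_stats: SummaryStats,
    outcome_ld: LDMatrix,
    p_threshold: float = 5e-8,
    f_threshold: float = 10.0,
    r2_threshold: float = 0.001,
    alpha: float = 0.05,
    palindrome_eaf_window: float = 0.08,
    exclude_gene: Optional[GeneAnnotation] = None,
    exclude_window_bp: int = 1_000_000,
) -> Union[MRResult, NotTestable]:
    """Estimate the outcome→protein effect with outcome instruments.

    Instruments for the (disease) outcome are selected with the same
    inclusion criteria as pQTL instruments, minus the cis restriction
    (``gene=None``).  When ``exclude_gene`` is given, outcome instruments
    inside that gene's cis window are discarded first: a disease instrument
    at the protein's own locus can act on the protein directly rather than
    through the disease, which would contaminate the reverse test with the
    forward (mediated) pathway.  Returns :class:`NotTestable` when no
    instrument survives selection or harmonization.
    """
    if exclude_gene is not None:
        kept = {
            vid: v
            for vid, v in outcome_stats.records.items()
            if not (
                v.chrom == exclude_gene.chrom
                and v.pos is not None
                and abs(v.pos - exclude_gene.tss) <= exclude_window_bp
            )
        }
        outcome_stats = SummaryStats(
            trait_id=outcome_stats.trait_id,
            trait_type=outcome_stats.trait_type,
            records=kept,
            genome_build=outcome_stats.genome_build,
        )
        if not kept:
            return NotTestable("no outcome variants outside the excluded cis window")
    inst = select_instruments(
        outcome_stats,
        gene=None,
        ld=outcome_ld,
        p_threshold=p_threshold,
        f_threshold=f_threshold,
        r2_threshold=r2_threshold,
    )
    if len(inst) == 0:
        return NotTestable("no genome-wide-significant outcome instruments")
    try:
        pairs = harmonize(inst.variants(), protein_stats, palindrome_eaf_window)
    except ValueError:
        return NotTestable("outcome instruments absent from protein summary statistics")
    if not usable_pairs(pairs):
        return NotTestable("all outcome instruments dropped during harmonization")
    return mr_estimate(
        pairs,
        alpha=alpha,
        exposure_id=outcome_stats.trait_id,
        outcome_id=protein_stats.trait_id,
    )


def reverse_causality_verdict(
    forward_steiger: Optional[SteigerResult],
    reverse_mr: Union[MRResult, NotTestable, None],
    alpha: float = 0.05,
) -> str:
    """Combined rule: reverse causation is confirmed when the reverse MR is
    significant or the forward Steiger test failed.

    A not-testable (or absent) reverse MR counts as non-significant; an
    absent Steiger result (e.g. forward model not instrumentable) does not
    by itself confirm reverse causation.
    """
    reverse_sig = isinstance(reverse_mr, MRResult) and reverse_mr.pvalue < alpha
    steiger_failed = forward_steiger is not None and forward_steiger.verdict == "failed"
    return "confirmed_reverse" if (reverse_sig or steiger_failed) else "no_reverse_evidence"
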