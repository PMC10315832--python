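"""Phenome-wide MR screening of a prioritized protein across disease traits.

Each prioritized protein is tested (with its primary-analysis instruments)
against a battery of disease GWASs.  Per-SD MR estimates are then rescaled
to the protein change whose genetically predicted effect on the index
disease equals a 10% risk reduction:

    scaling_factor = ln(0.90) / beta_protein_on_index_disease   (in SD)

so a protective protein (negative beta on the index disease) gets a positive
factor (an increase toward the therapeutic direction) and a harmful protein
a negative one (a reduction).  Scaled betas, odds ratios and CIs transform
by the same factor, with CI bounds swapped when the factor is negative.
Multiple testing across the battery is controlled per protein by
Benjamini–Hochberg FDR (a Bonferroni toggle is available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from statsmodels.stats.multitest import multipletests

from .gwas_io import SummaryStats, harmonize, usable_pairs
from .instruments import InstrumentSet
from .mr import MRResult, Z95, mr_estimate

logger = logging.getLogger(__name__)

__all__ = ["PhewasRecord", "scaling_to_target", "phewas_screen"]


@dataclass(frozen=True, slots=True)
class PhewasRecord:
    """One protein × disease PheW-MR result.

    ``raw`` is the per-SD estimate; the ``scaled_*`` fields express the same
    effect per ``scaling_factor`` SD of protein (the 10%-risk-reduction
    standardization).  ``untested`` marks diseases where harmonization left
    no usable instrument; such records carry no estimates.
    """

    protein_id: str
    disease_id: str
    raw: Optional[MRResult]
    scaling_factor: float
    scaled_beta: Optional[float] = None
    scaled_or: Optional[float] = None
    scaled_ci_low: Optional[float] = None
    scaled_ci_high: Optional[float] = None
    pvalue: Optional[float] = None
    adjusted_q: Optional[float] = None
    untested: bool = False


def scaling_to_target(beta_protein_on_vv: float, target_rr: float = 0.90) -> float:
    """Signed SD change in protein whose predicted effect on the index
    disease's log-odds equals ln(target_rr)."""
    if beta_protein_on_vv == 0:
        raise ValueError("protein effect on the index disease is zero; cannot standardize")
    if not (0 < target_rr < 1):
        raise ValueError(f"target_rr must lie in (0, 1), got {target_rr}")
    return math.log(target_rr) / beta_protein_on_vv


def _scale(raw: MRResult, factor: float) -> tuple[float, float, float, float]:
    beta = raw.beta * factor
    lo_log = factor * (raw.beta - Z95 * raw.se)
    hi_log = factor * (raw.beta + Z95 * raw.se)
    if factor < 0:
        lo_log, hi_log = hi_log, lo_log
    return beta, math.exp(beta), math.exp(lo_log), math.exp(hi_log)


def phewas_screen(
    protein_instruments: InstrumentSet,
    disease_battery: Sequence[SummaryStats],
    beta_protein_on_vv: float,
    target_rr: float = 0.90,
    alpha: float = 0.05,
    multitest_method: str = "fdr_bh",
    palindrome_eaf_window: float = 0.08,
) -> list[PhewasRecord]:
    """Screen one protein against a battery of disease GWASs.

    ``multitest_method`` is "fdr_bh" (default) or "bonferroni".  Raises when
    the battery is empty or every disease ends up untested.
    """
    if not disease_battery:
        raise ValueError("phewas_screen: empty disease battery")
    if multitest_method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown multiple-testing method {multitest_method!r}")
    factor = scaling_to_target(beta_protein_on_vv, target_rr)

    records: list[PhewasRecord] = []
    tested_idx: list[int] = []
    for disease in disease_battery:
        try:
            pairs = harmonize(
                protein_instruments.variants(), disease, palindrome_eaf_window
            )
            kept = [p for p in usable_pairs(pairs) if p.beta_exp != 0]
        except ValueError:
            kept = []
        if not kept:
            records.append(
                PhewasRecord(
                    protein_id=protein_instruments.exposure_id,
                    disease_id=disease.trait_id,
                    raw=None,
                    scaling_factor=factor,
                    untested=True,
                )
            )
            continue
        raw = mr_estimate(
            kept,
            alpha=alpha,
            exposure_id=protein_instruments.exposure_id,
            outcome_id=disease.trait_id,
        )
        beta, or_, lo, hi = _scale(raw, factor)
        tested_idx.append(len(records))
        records.append(
            PhewasRecord(
                protein_id=protein_instruments.exposure_id,
                disease_id=disease.trait_id,
                raw=raw,
                scaling_factor=factor,
                scaled_beta=beta,
                scaled_or=or_,
                scaled_ci_low=lo,
                scaled_ci_high=hi,
                pvalue=raw.pvalue,
            )
        )

    if not tested_idx:
        raise ValueError("phewas_screen: every disease in the battery was untested")

    pvals = [records[i].pvalue for i in tested_idx]
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method=multitest_method)
    for i, q in zip(tested_idx, qvals):
        r = records[i]
        records[i] = PhewasRecord(
            protein_id=r.protein_id,
            disease_id=r.disease_id,
            raw=r.raw,
            scaling_factor=r.scaling_factor,
            scaled_beta=r.scaled_beta,
            scaled_or=r.scaled_or,
            scaled_ci_low=r.scaled_ci_low,
            scaled_ci_high=r.scaled_ci_high,
            pvalue=r.pvalue,
            adjusted_q=float(q),
        )
    n_untested = len(records) - len(tested_idx)
    if n_untested:
        logger.info(
            "phewas %s: %d of %d diseases untested",
            protein_instruments.exposure_id,
            n_untested,
            len(records),
        )
    return records
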