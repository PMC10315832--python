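"""Genetic-instrument selection for cis-pQTL Mendelian randomization.

Instruments for a protein are its cis variants (within a configurable window
of the encoding gene's TSS) that are genome-wide significant, strong
(F statistic above threshold) and mutually independent (greedy LD clumping).
Per-instrument strength is quantified by the proportion of variance
explained, PVE = beta^2 / (beta^2 + N * se^2), and the single-instrument
F approximation F = PVE * (N - k - 1) / (k * (1 - PVE)) with k = 1.

A local SNP→trait catalog stands in for a phenome-scanner lookup: an
instrument is flagged pleiotropic when the catalog reports a genome-wide
significant association with any other trait; the protein-level verdict is
advisory (annotates, never drops).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .gwas_io import LDMatrix, SummaryStats, VariantAssociation

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "Instrument",
    "InstrumentSet",
    "TraitCatalog",
    "compute_pve",
    "compute_f_stat",
    "clump",
    "select_instruments",
    "flag_pleiotropy",
    "read_gene_annotations",
    "read_trait_catalog",
]


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """A gene's transcription start site, defining its cis window."""

    gene_id: str
    chrom: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"{self.gene_id}: tss must be >= 1 (1-based)")


@dataclass(frozen=True, slots=True)
class Instrument:
    """A retained instrument with its strength statistics."""

    variant: VariantAssociation
    pve: float
    f_stat: float
    is_cis: bool = True
    pleiotropy_flags: tuple[str, ...] = ()


@dataclass
class InstrumentSet:
    """Instruments retained for one exposure after all filters.

    ``stage_counts`` records how many candidates survived each filter
    (candidates → cis → pvalue → f_stat → clump) for reproducible logging.
    """

    exposure_id: str
    instruments: list[Instrument] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.instruments)

    def variants(self) -> list[VariantAssociation]:
        return [inst.variant for inst in self.instruments]

    @property
    def pleiotropic(self) -> bool:
        return any(inst.pleiotropy_flags for inst in self.instruments)


@dataclass
class TraitCatalog:
    """Local SNP→trait association catalog (variant id, trait, p-value)."""

    records: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for vid, trait, p in self.records:
            if not (0 < p <= 1):
                raise ValueError(f"catalog p-value out of (0,1] for {vid}/{trait}: {p}")

    def traits_for(self, variant_id: str, p_threshold: float) -> list[str]:
        return [t for vid, t, p in self.records if vid == variant_id and p < p_threshold]


def compute_pve(beta: float, se: float, n: int) -> float:
    """Proportion of trait variance explained: beta^2 / (beta^2 + n * se^2)."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    b2 = beta * beta
    return b2 / (b2 + n * se * se)


def compute_f_stat(pve: float, n: int, k: int = 1) -> float:
    """Instrument-strength F statistic, F = pve*(n-k-1) / (k*(1-pve))."""
    if not (0 <= pve < 1):
        raise ValueError(f"pve must lie in [0, 1), got {pve}")
    if n <= k + 1:
        raise ValueError(f"n must exceed k+1 = {k + 1}, got {n}")
    return pve * (n - k - 1) / (k * (1.0 - pve))


def _clump_order_key(v: VariantAssociation):
    # ties in p (including floored/underflowed p-values, where |z| still
    # ranks) broken by |z|, then deterministically by coordinate and id
    return (v.pvalue, -abs(v.beta) / v.se, v.chrom or "", v.pos or 0, v.variant_id)


def clump(
    candidates: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
) -> list[VariantAssociation]:
    """Greedy LD clumping: keep the most significant variant, drop everything
    in LD with it (r² ≥ threshold), repeat.  The retained set is pairwise
    independent at the threshold."""
    for v in candidates:
        if v.variant_id not in ld:
            raise ValueError(f"candidate {v.variant_id} missing from LD matrix")
    remaining = sorted(candidates, key=_clump_order_key)
    kept: list[VariantAssociation] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            v for v in remaining if ld.r2(best.variant_id, v.variant_id) < r2_threshold
        ]
    return kept


def select_instruments(
    stats: SummaryStats,
    gene: Optional[GeneAnnotation],
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    f_threshold: float = 10.0,
    r2_threshold: float = 0.001,
    cis_window_bp: int = 1_000_000,
) -> InstrumentSet:
    """Select instruments: cis filter → significance → strength → clumping.

    With ``gene=None`` the cis restriction is skipped (appropriate for a
    disease trait when extracting instruments for bidirectional MR).
    An empty result is legal: the exposure is simply not instrumentable.
    """
    candidates = stats.variants()
    counts = {"candidates": len(candidates)}

    if gene is not None:
        cis = [
            v
            for v in candidates
            if v.chrom == gene.chrom and v.pos is not None and abs(v.pos - gene.tss) <= cis_window_bp
        ]
    else:
        cis = candidates
    counts["cis"] = len(cis)

    sig = [v for v in cis if v.pvalue < p_threshold]
    counts["pvalue"] = len(sig)

    strength: dict[str, tuple[float, float]] = {}
    strong = []
    for v in sig:
        pve = compute_pve(v.beta, v.se, v.n)
        f = compute_f_stat(pve, v.n, k=1)
        if f > f_threshold:
            strength[v.variant_id] = (pve, f)
            strong.append(v)
    counts["f_stat"] = len(strong)

    clumped = clump(strong, ld, r2_threshold)
    counts["clump"] = len(clumped)

    instruments = [
        Instrument(
            variant=v,
            pve=strength[v.variant_id][0],
            f_stat=strength[v.variant_id][1],
            is_cis=gene is not None,
        )
        for v in clumped
    ]
    logger.debug("%s: instrument selection counts %s", stats.trait_id, counts)
    return InstrumentSet(exposure_id=stats.trait_id, instruments=instruments, stage_counts=counts)


def flag_pleiotropy(
    inst: InstrumentSet,
    catalog: TraitCatalog,
    gw_threshold: float = 5e-8,
) -> InstrumentSet:
    """Annotate each instrument with catalog traits it is genome-wide
    significantly associated with.  Advisory: instruments are never dropped."""
    flagged = [
        replace(i, pleiotropy_flags=tuple(catalog.traits_for(i.variant.variant_id, gw_threshold)))
        for i in inst.instruments
    ]
    return InstrumentSet(
        exposure_id=inst.exposure_id, instruments=flagged, stage_counts=dict(inst.stage_counts)
    )


def read_gene_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a tab-delimited gene annotation table (GENE, CHR, TSS)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.upper(): c for c in df.columns}
    for needed in ("GENE", "CHR", "TSS"):
        if needed not in cols:
            raise ValueError(f"{path}: missing column {needed}")
    return {
        str(row[cols["GENE"]]): GeneAnnotation(
            gene_id=str(row[cols["GENE"]]), chrom=str(row[cols["CHR"]]), tss=int(row[cols["TSS"]])
        )
        for _, row in df.iterrows()
    }


def read_trait_catalog(path: str | Path) -> TraitCatalog:
    """Read a tab-delimited SNP→trait catalog (SNP, TRAIT, P)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.upper(): c for c in df.columns}
    for needed in ("SNP", "TRAIT", "P"):
        if needed not in cols:
            raise ValueError(f"{path}: missing column {needed}")
    records = [
        (str(r[cols["SNP"]]), str(r[cols["TRAIT"]]), float(r[cols["P"]]))
        for _, r in df.iterrows()
    ]
    return TraitCatalog(records)
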