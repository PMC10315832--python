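"""End-to-end proteome-wide MR screen.

Per protein the stages run in a fixed order:

1. cis-pQTL instrument selection (significance, strength, clumping);
2. harmonization of the instruments to the outcome GWAS and Wald/IVW
   estimation;
3. Bonferroni prioritization at alpha / n_tests;
4. for prioritized proteins: pleiotropy scan against a local trait catalog,
   Steiger directionality + bidirectional MR, Bayesian colocalization of the
   cis region, and replication in an alternative pQTL source (p < 0.05 with
   a direction concordant with the primary estimate).

Final status per protein:

* ``not_instrumentable`` — no instrument survived selection/harmonization;
* ``not_significant`` — estimate above the Bonferroni threshold;
* ``prioritized`` — significant but not (yet) confirmed on every axis;
* ``validated_target`` — prioritized, no reverse-causality evidence, not
  flagged pleiotropic, colocalized (PPH4 above threshold) and externally
  replicated.  Stages that could not run (no catalog, no replication
  source) never silently pass: a protein missing its replication source
  stays ``prioritized``/``not_replicable``.

The pleiotropy verdict demotes a protein from ``validated_target`` but the
protein is still reported with all its flags, so users can apply their own
judgment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .coloc import ColocPriors, ColocResult, coloc_abf
from .directionality import (
    NotTestable,
    SteigerResult,
    bidirectional_mr,
    reverse_causality_verdict,
    steiger_test,
)
from .gwas_io import (
    LDMatrix,
    SummaryStats,
    harmonize,
    read_ld_matrix,
    read_summary_stats,
    usable_pairs,
)
from .instruments import (
    GeneAnnotation,
    InstrumentSet,
    TraitCatalog,
    flag_pleiotropy,
    read_trait_catalog,
    select_instruments,
)
from .mr import MRResult, bonferroni_threshold, mr_estimate
from .phewas import PhewasRecord, phewas_screen
from .simulate import SimulatedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "ProteinInput",
    "ScreenRow",
    "ScreenReport",
    "screen_proteins",
    "screen_simulated",
    "run_screen",
    "write_report",
]


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds of the screen, with their standard defaults."""

    p_threshold: float = 5e-8
    f_threshold: float = 10.0
    clump_r2: float = 0.001
    cis_window_bp: int = 1_000_000
    alpha: float = 0.05
    n_tests: Optional[int] = None  # default: number of proteins screened
    palindrome_eaf_window: float = 0.08
    pleiotropy_gw_threshold: float = 5e-8
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    pph4_threshold: float = 0.8
    coloc_prior_sd_exp: float = 0.15
    coloc_prior_sd_out: float = 0.2
    replication_alpha: float = 0.05
    require_direction_concordance: bool = True
    random_effects: bool = False


@dataclass
class ProteinInput:
    """Everything the screen needs for one protein."""

    protein_id: str
    stats: SummaryStats
    ld: LDMatrix
    gene: GeneAnnotation
    replication_stats: Optional[SummaryStats] = None


@dataclass
class ScreenRow:
    """Per-protein results across all stages."""

    protein_id: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    instruments: Optional[InstrumentSet] = None
    n_instruments_harmonized: int = 0
    mr: Optional[MRResult] = None
    pleiotropy_flags: tuple[str, ...] = ()
    pleiotropy_verdict: Optional[str] = None  # "pleiotropic" / "clean" / None (skipped)
    steiger: Optional[SteigerResult] = None
    bidirectional: Union[MRResult, NotTestable, None] = None
    reverse_verdict: Optional[str] = None
    coloc: Optional[ColocResult] = None
    replication: Optional[MRResult] = None
    replication_status: Optional[str] = None  # replicated/not_replicated/not_replicable
    status: str = "not_instrumentable"


@dataclass
class ScreenReport:
    """The screen's full output: one row per protein."""

    outcome_id: str
    n_tests: int
    mr_threshold: float
    rows: list[ScreenRow] = field(default_factory=list)

    def status_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for row in self.rows:
            counts[row.status] = counts.get(row.status, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec: dict = {
                "protein": r.protein_id,
                "status": r.status,
                "n_instruments": len(r.instruments) if r.instruments else 0,
                "n_harmonized": r.n_instruments_harmonized,
            }
            if r.mr:
                rec.update(
                    method=r.mr.method,
                    beta=r.mr.beta,
                    se=r.mr.se,
                    or_=r.mr.odds_ratio,
                    ci_low=r.mr.ci_low,
                    ci_high=r.mr.ci_high,
                    p=r.mr.pvalue,
                )
            rec["pleiotropy"] = r.pleiotropy_verdict
            rec["pleiotropy_traits"] = ";".join(r.pleiotropy_flags) or None
            if r.steiger:
                rec["steiger"] = r.steiger.verdict
                rec["steiger_p"] = r.steiger.pvalue
            if isinstance(r.bidirectional, MRResult):
                rec["bidir_or"] = r.bidirectional.odds_ratio
                rec["bidir_ci_low"] = r.bidirectional.ci_low
                rec["bidir_ci_high"] = r.bidirectional.ci_high
                rec["bidir_p"] = r.bidirectional.pvalue
            elif isinstance(r.bidirectional, NotTestable):
                rec["bidir_or"] = None
                rec["bidir_p"] = None
            rec["reverse_verdict"] = r.reverse_verdict
            if r.coloc:
                rec["pph4"] = r.coloc.pph4
                rec["colocalized"] = r.coloc.colocalized
            if r.replication:
                rec["replication_or"] = r.replication.odds_ratio
                rec["replication_p"] = r.replication.pvalue
            rec["replication_status"] = r.replication_status
            records.append(rec)
        return pd.DataFrame(records)


def _mr_for_protein(
    instruments: InstrumentSet,
    outcome: SummaryStats,
    cfg: ScreenConfig,
    threshold: float,
):
    pairs = harmonize(instruments.variants(), outcome, cfg.palindrome_eaf_window)
    kept = [p for p in usable_pairs(pairs) if p.beta_exp != 0]
    if not kept:
        return None, []
    result = mr_estimate(
        kept,
        alpha=threshold,
        random_effects=cfg.random_effects,
        exposure_id=instruments.exposure_id,
        outcome_id=outcome.trait_id,
    )
    return result, kept


def _replicate_one(
    protein: ProteinInput,
    outcome: SummaryStats,
    primary: MRResult,
    cfg: ScreenConfig,
) -> tuple[Optional[MRResult], str]:
    """Re-run selection + MR with the alternative pQTL source."""
    if protein.replication_stats is None:
        return None, "not_replicable"
    inst = select_instruments(
        protein.replication_stats,
        protein.gene,
        protein.ld,
        cfg.p_threshold,
        cfg.f_threshold,
        cfg.clump_r2,
        cfg.cis_window_bp,
    )
    if len(inst) == 0:
        return None, "not_replicable"
    try:
        result, kept = _mr_for_protein(inst, outcome, cfg, cfg.replication_alpha)
    except ValueError:
        return None, "not_replicable"
    if result is None:
        return None, "not_replicable"
    concordant = (result.beta > 0) == (primary.beta > 0)
    replicated = result.pvalue < cfg.replication_alpha and (
        concordant or not cfg.require_direction_concordance
    )
    return result, "replicated" if replicated else "not_replicated"


def screen_proteins(
    proteins: Sequence[ProteinInput],
    outcome: Union[SummaryStats, Mapping[str, SummaryStats]],
    config: ScreenConfig = ScreenConfig(),
    catalog: Optional[TraitCatalog] = None,
) -> ScreenReport:
    """Run the full screen over a set of proteins.

    ``outcome`` is either one genome-wide outcome GWAS shared by all
    proteins or a mapping from protein id to the outcome's summary
    statistics near that protein's region (the natural form for simulated
    or pre-windowed data).  The same per-region outcome statistics also
    drive bidirectional MR and colocalization.
    """
    n_tests = config.n_tests or len(proteins)
    threshold = bonferroni_threshold(config.alpha, n_tests)
    outcome_for = (
        (lambda pid: outcome) if isinstance(outcome, SummaryStats) else (lambda pid: outcome[pid])
    )
    report = ScreenReport(
        outcome_id=outcome_for(proteins[0].protein_id).trait_id if proteins else "",
        n_tests=n_tests,
        mr_threshold=threshold,
    )

    for protein in proteins:
        out_stats = outcome_for(protein.protein_id)
        if protein.stats.genome_build != out_stats.genome_build:
            raise ValueError(
                f"{protein.protein_id}: genome build mismatch "
                f"({protein.stats.genome_build} vs {out_stats.genome_build})"
            )
        row = ScreenRow(protein_id=protein.protein_id)
        report.rows.append(row)

        inst = select_instruments(
            protein.stats,
            protein.gene,
            protein.ld,
            config.p_threshold,
            config.f_threshold,
            config.clump_r2,
            config.cis_window_bp,
        )
        row.instruments = inst
        row.stage_counts = dict(inst.stage_counts)
        if len(inst) == 0:
            row.status = "not_instrumentable"
            continue

        try:
            result, kept = _mr_for_protein(inst, out_stats, config, threshold)
        except ValueError:
            result, kept = None, []
        row.n_instruments_harmonized = len(kept)
        row.stage_counts["harmonized"] = len(kept)
        if result is None:
            row.status = "not_instrumentable"
            continue
        row.mr = result
        if not result.significant:
            row.status = "not_significant"
            continue
        row.status = "prioritized"

        # --- confirmation stages (prioritized proteins only) ---
        if catalog is not None:
            flagged = flag_pleiotropy(inst, catalog, config.pleiotropy_gw_threshold)
            row.instruments = flagged
            row.pleiotropy_flags = tuple(
                t for i in flagged.instruments for t in i.pleiotropy_flags
            )
            row.pleiotropy_verdict = "pleiotropic" if flagged.pleiotropic else "clean"

        row.steiger = steiger_test(kept, alpha=0.05)
        row.bidirectional = bidirectional_mr(
            out_stats,
            protein.stats,
            protein.ld,
            config.p_threshold,
            config.f_threshold,
            config.clump_r2,
            palindrome_eaf_window=config.palindrome_eaf_window,
            exclude_gene=protein.gene,
            exclude_window_bp=config.cis_window_bp,
        )
        row.reverse_verdict = reverse_causality_verdict(row.steiger, row.bidirectional)

        region_ids = [
            v.variant_id
            for v in protein.stats.variants()
            if v.chrom == protein.gene.chrom
            and v.pos is not None
            and abs(v.pos - protein.gene.tss) <= config.cis_window_bp
        ]
        region_exp = [protein.stats.records[i] for i in region_ids]
        region_out = [out_stats.records[i] for i in region_ids if i in out_stats]
        row.coloc = coloc_abf(
            region_exp,
            region_out,
            config.coloc_priors,
            config.pph4_threshold,
            config.coloc_prior_sd_exp,
            config.coloc_prior_sd_out,
        )

        row.replication, row.replication_status = _replicate_one(
            protein, out_stats, result, config
        )

        validated = (
            row.reverse_verdict == "no_reverse_evidence"
            and row.pleiotropy_verdict != "pleiotropic"
            and row.coloc.colocalized
            and row.replication_status == "replicated"
        )
        if validated:
            row.status = "validated_target"

    logger.info("screen: %s", report.status_counts())
    return report


def screen_simulated(
    datasets: Sequence[SimulatedDataset],
    config: ScreenConfig = ScreenConfig(),
    catalog: Optional[TraitCatalog] = None,
    replication: Optional[Mapping[str, SummaryStats]] = None,
) -> ScreenReport:
    """Convenience wrapper running the screen on simulated regions."""
    proteins = [
        ProteinInput(
            protein_id=d.protein_stats.trait_id,
            stats=d.protein_stats,
            ld=d.ld,
            gene=d.gene,
            replication_stats=(replication or {}).get(d.protein_stats.trait_id),
        )
        for d in datasets
    ]
    outcome = {d.protein_stats.trait_id: d.disease_stats for d in datasets}
    return screen_proteins(proteins, outcome, config, catalog)


# ---------------------------------------------------------------------------
# File-driven entry point


def _load_config_thresholds(raw: dict) -> ScreenConfig:
    th = dict(raw.get("thresholds", {}))
    priors = th.pop("coloc_priors", None)
    kwargs = {k: v for k, v in th.items()}
    if priors:
        kwargs["coloc_priors"] = ColocPriors(**priors)
    return ScreenConfig(**kwargs)


def run_screen(config: Union[str, Path, dict], out_dir: Union[str, Path, None] = None) -> ScreenReport:
    """Run the screen from a YAML configuration.

    Expected keys::

        outcome: {path, trait_id, trait_type}
        proteins:
          - {id, pgwas, ld, gene: {chrom, tss}, replication: optional path}
        catalog: optional path (SNP, TRAIT, P)
        thresholds: optional overrides of ScreenConfig fields

    Writes ``report.tsv``, ``mr_results.tsv`` and ``coloc.tsv`` to
    ``out_dir`` when given.  Deterministic for fixed inputs.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    out_cfg = config["outcome"]
    outcome = read_summary_stats(
        out_cfg["path"],
        out_cfg.get("trait_id", "outcome"),
        out_cfg.get("trait_type", "binary"),
        out_cfg.get("genome_build", "GRCh37"),
    )
    proteins = []
    for p in config["proteins"]:
        gene = GeneAnnotation(gene_id=p["id"], chrom=str(p["gene"]["chrom"]), tss=int(p["gene"]["tss"]))
        stats = read_summary_stats(
            p["pgwas"], p["id"], "quantitative", p.get("genome_build", "GRCh37")
        )
        rep = (
            read_summary_stats(p["replication"], p["id"], "quantitative",
                               p.get("genome_build", "GRCh37"))
            if p.get("replication")
            else None
        )
        proteins.append(
            ProteinInput(
                protein_id=p["id"],
                stats=stats,
                ld=read_ld_matrix(p["ld"]),
                gene=gene,
                replication_stats=rep,
            )
        )
    catalog = read_trait_catalog(config["catalog"]) if config.get("catalog") else None
    screen_cfg = _load_config_thresholds(config)
    report = screen_proteins(proteins, outcome, screen_cfg, catalog)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: ScreenReport, out_dir: Union[str, Path]) -> None:
    """Write the report tables (report.tsv, mr_results.tsv, coloc.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    frame.to_csv(out / "report.tsv", sep="\t", index=False, na_rep="NA")
    mr_cols = [
        c
        for c in ("protein", "status", "method", "n_harmonized", "beta", "se", "or_",
                  "ci_low", "ci_high", "p")
        if c in frame.columns
    ]
    frame[mr_cols].to_csv(out / "mr_results.tsv", sep="\t", index=False, na_rep="NA")
    coloc_rows = [
        {
            "protein": r.protein_id,
            "n_snps": r.coloc.n_snps,
            "PPH0": r.coloc.pph0,
            "PPH1": r.coloc.pph1,
            "PPH2": r.coloc.pph2,
            "PPH3": r.coloc.pph3,
            "PPH4": r.coloc.pph4,
            "colocalized": r.coloc.colocalized,
        }
        for r in report.rows
        if r.coloc is not None
    ]
    pd.DataFrame(coloc_rows).to_csv(out / "coloc.tsv", sep="\t", index=False, na_rep="NA")
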