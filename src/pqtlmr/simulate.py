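"""Synthetic GWAS summary statistics with known ground truth.

The generator works directly on the marginal (LD-convolved) scale the
pipeline consumes.  A region of m variants gets an AR-1 signed LD matrix
r_ij = ld_decay^|i-j|.  Direct (joint) effects are placed at chosen indices;
the true marginal effect at every variant i is the LD convolution
sum_c r(i, c) * effect(c).  Observed betas are the true marginals plus
Gaussian sampling noise with the standard GWAS-scale standard error
se = 1 / sqrt(2 * maf * (1 - maf) * N); the noise is correlated across
variants with the same AR-1 structure as the LD (as the z-scores of a real
GWAS are, which is what makes colocalization behave), drawn in O(m) by the
AR-1 recursion.  The same formulas are used on the log-odds scale for the
binary disease trait (an approximation — the case fraction enters only
through the reported case/control counts).

Each simulated dataset has two unlinked blocks: the protein's cis region
(chromosome 1, around the gene TSS) and a disease background region
(chromosome 2) carrying the disease's own loci — the polygenic signal a
real disease GWAS has outside any one protein's locus, which is what
bidirectional MR draws its instruments from.  Effect pathways (all
scenarios are parameterizations of the same model):

    cis block:        protein = conv(causal_variants) + reverse_effect * conv(pleiotropy)
                      disease = theta * conv(causal_variants) + conv(pleiotropy)
    background block: disease = conv(disease_loci)
                      protein = reverse_effect * conv(disease_loci)

so ``theta`` is the protein→disease causal effect, ``pleiotropy`` holds
direct (horizontal) disease effects inside the cis region, and
``reverse_effect`` routes the disease's genetic signal back into the
protein (reverse causation: the protein tracks disease liability wherever
the disease has genetics).

Default study conditions mirror the screen the package implements: a plasma
pGWAS of n_exp = 7,213 (the discovery proteomics cohort; 35,559 for the
replication cohort), a disease GWAS of n_out = 459,702 with 22,037 cases,
cis regions of 200 variants with adjacent-variant LD 0.95, common variants
(MAF 0.05–0.5), and strong cis-pQTLs of 0.3 SD per allele.

Everything is deterministic given the seed; per-protein seeds in
:func:`simulate_screen` are derived from the master seed by index offset
(``master_seed + index``) so any single protein can be regenerated alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import lfilter

from .gwas_io import LDMatrix, SummaryStats, VariantAssociation
from .instruments import GeneAnnotation

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "scenario_config",
    "simulate_region",
    "simulate_replication",
    "simulate_screen",
    "SCENARIOS",
]

SCENARIOS = ("null", "causal", "shared_coloc", "distinct_coloc", "reverse")

#: Discovery / replication pGWAS and disease-GWAS sample sizes (study conditions).
N_EXPOSURE_DISCOVERY = 7_213
N_EXPOSURE_REPLICATION = 35_559
N_OUTCOME = 459_702
N_OUTCOME_CASES = 22_037


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated cis region."""

    seed: int = 0
    n_variants: int = 200
    ld_decay: float = 0.95
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = N_EXPOSURE_DISCOVERY
    n_out: int = N_OUTCOME
    #: direct effects on the protein, (variant index, effect in SD per allele)
    causal_variants: tuple[tuple[int, float], ...] = ((100, 0.3),)
    #: protein→disease causal effect, log-odds per SD
    theta: float = -0.2
    #: direct (horizontal) effects on the disease, (index, log-odds per allele)
    pleiotropy: tuple[tuple[int, float], ...] = ()
    #: disease→protein effect routing the disease's genetic signal backwards
    reverse_effect: float = 0.0
    scenario: str = "causal"
    case_fraction: float = N_OUTCOME_CASES / N_OUTCOME
    #: unlinked disease background region (chromosome 2)
    n_background_variants: int = 200
    #: disease loci in the background region, (index, log-odds per allele)
    disease_loci: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must satisfy 0 < low <= high < 1")
        if self.n_exp < 2 or self.n_out < 2:
            raise ValueError("sample sizes must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        for idx, _ in (*self.causal_variants, *self.pleiotropy):
            if not (0 <= idx < self.n_variants):
                raise ValueError(f"causal index {idx} outside region of {self.n_variants}")
        for idx, _ in self.disease_loci:
            if not (0 <= idx < self.n_background_variants):
                raise ValueError(
                    f"disease locus {idx} outside background of {self.n_background_variants}"
                )


@dataclass
class SimulatedDataset:
    """Simulated protein + disease summary statistics for one region."""

    protein_stats: SummaryStats
    disease_stats: SummaryStats
    ld: LDMatrix
    gene: GeneAnnotation
    truth: SimulationConfig


def scenario_config(scenario: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Canonical configuration for each study scenario.

    * ``null`` — instrumentable protein, no effect on disease (theta = 0).
    * ``causal`` — three independent cis-pQTLs, theta = -0.2 (protective).
    * ``shared_coloc`` — a single causal variant driving both traits.
    * ``distinct_coloc`` — separate causal variants (r² ≈ 0.002), no
      protein→disease effect.
    * ``reverse`` — the disease (n = 100,000) causally raises the protein
      (effect 0.3 SD per log-odds); the protein has no cis genetics of its
      own, only the backdoor signal at the disease's locus.  The disease's
      causal variant carries a large effect (0.5 log-odds per allele) so
      the backdoor signal is resolvable at the protein GWAS's modest
      sample size.

    All scenarios except ``reverse`` give the disease two background loci
    of 0.05 log-odds each on the unlinked block, so bidirectional MR has
    genuine disease instruments to draw on.

    Keyword overrides are applied on top of the preset.
    """
    background = ((50, 0.05), (150, 0.05))  # the disease's own (non-protein) loci
    presets: dict[str, dict] = {
        "null": dict(
            causal_variants=((20, 0.3), (100, 0.3), (180, 0.3)),
            theta=0.0,
            disease_loci=background,
        ),
        "causal": dict(
            causal_variants=((20, 0.3), (100, 0.3), (180, 0.3)),
            theta=-0.2,
            disease_loci=background,
        ),
        "shared_coloc": dict(
            causal_variants=((100, 0.3),), theta=-0.2, disease_loci=background
        ),
        "distinct_coloc": dict(
            causal_variants=((70, 0.3),),
            pleiotropy=((130, 0.05),),
            theta=0.0,
            disease_loci=background,
        ),
        "reverse": dict(
            causal_variants=(),
            theta=0.0,
            reverse_effect=0.3,
            disease_loci=((100, 0.5),),
            n_out=100_000,
        ),
    }
    if scenario not in presets:
        raise ValueError(f"unknown scenario {scenario!r}")
    kwargs = {"scenario": scenario, "seed": seed, **presets[scenario]}
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def _convolve(r: np.ndarray, effects: Sequence[tuple[int, float]], m: int) -> np.ndarray:
    true = np.zeros(m)
    for idx, eff in effects:
        true += r[:, idx] * eff
    return true


def _marginal_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _ar1_noise(rng: np.random.Generator, rho: float, m: int) -> np.ndarray:
    """Standard-normal margins with corr(x_i, x_j) = rho^|i-j| (AR-1)."""
    eta = rng.standard_normal(m)
    if rho == 0.0 or m == 1:
        return eta
    u = eta * np.sqrt(1.0 - rho * rho)
    u[0] = eta[0]
    return lfilter([1.0], [1.0, -rho], u)


def _records(
    variant_ids: Sequence[str],
    chrom: str,
    positions: np.ndarray,
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    n_cases: Optional[int] = None,
) -> list[VariantAssociation]:
    z = beta / se
    pvals = np.maximum(2.0 * sps.norm.sf(np.abs(z)), 1e-300)
    n_controls = None if n_cases is None else n - n_cases
    return [
        VariantAssociation(
            variant_id=variant_ids[i],
            chrom=chrom,
            pos=int(positions[i]),
            effect_allele="A",
            other_allele="G",
            eaf=float(maf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(pvals[i]),
            n=n,
            n_cases=n_cases,
            n_controls=n_controls,
        )
        for i in range(len(variant_ids))
    ]


def _simulate_block(
    rng: np.random.Generator,
    config: SimulationConfig,
    m: int,
    protein_true: np.ndarray,
    disease_true: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw maf and noisy marginals for one LD block (fixed rng draw order:
    maf, protein noise, disease noise)."""
    maf = rng.uniform(*config.maf_range, size=m)
    se_exp = _marginal_se(maf, config.n_exp)
    se_out = _marginal_se(maf, config.n_out)
    beta_exp = protein_true + se_exp * _ar1_noise(rng, config.ld_decay, m)
    beta_out = disease_true + se_out * _ar1_noise(rng, config.ld_decay, m)
    return maf, beta_exp, se_exp, beta_out, se_out


def simulate_region(
    config: SimulationConfig,
    protein_id: str = "PROT",
    disease_id: str = "DISEASE",
    start_pos: int = 1_000_000,
    pos_step: int = 2_000,
) -> SimulatedDataset:
    """Simulate one protein's dataset: cis block plus disease background.

    The cis block sits on chromosome 1 with the gene's TSS at its central
    variant (so the whole block is cis); the disease background block sits
    on chromosome 2, unlinked.  Identical configs (same seed) yield
    identical data.
    """
    rng = np.random.default_rng(config.seed)
    n_cases = int(round(config.case_fraction * config.n_out))
    protein = SummaryStats(trait_id=protein_id, trait_type="quantitative")
    disease = SummaryStats(trait_id=disease_id, trait_type="binary")

    # --- cis block (chromosome 1) ---
    m = config.n_variants
    idx = np.arange(m)
    r_cis = config.ld_decay ** np.abs(idx[:, None] - idx[None, :])
    protein_direct = _convolve(r_cis, config.causal_variants, m)
    disease_direct = _convolve(r_cis, config.pleiotropy, m)
    disease_true = config.theta * protein_direct + disease_direct
    protein_true = protein_direct + config.reverse_effect * disease_direct
    maf, beta_exp, se_exp, beta_out, se_out = _simulate_block(
        rng, config, m, protein_true, disease_true
    )
    positions = start_pos + pos_step * idx
    cis_ids = [f"rs{1000 + i}" for i in range(m)]
    for rec in _records(cis_ids, "1", positions, maf, beta_exp, se_exp, config.n_exp):
        protein.add(rec)
    for rec in _records(cis_ids, "1", positions, maf, beta_out, se_out, config.n_out, n_cases):
        disease.add(rec)

    # --- disease background block (chromosome 2) ---
    b = config.n_background_variants
    if b > 0:
        bidx = np.arange(b)
        r_bg = config.ld_decay ** np.abs(bidx[:, None] - bidx[None, :])
        disease_bg = _convolve(r_bg, config.disease_loci, b)
        protein_bg = config.reverse_effect * disease_bg
        maf_b, be_b, se_b, bo_b, so_b = _simulate_block(rng, config, b, protein_bg, disease_bg)
        positions_b = start_pos + pos_step * bidx
        bg_ids = [f"rs{9000 + i}" for i in range(b)]
        for rec in _records(bg_ids, "2", positions_b, maf_b, be_b, se_b, config.n_exp):
            protein.add(rec)
        for rec in _records(bg_ids, "2", positions_b, maf_b, bo_b, so_b, config.n_out, n_cases):
            disease.add(rec)
        ids = cis_ids + bg_ids
        r_full = np.zeros((m + b, m + b))
        r_full[:m, :m] = r_cis
        r_full[m:, m:] = r_bg
        np.fill_diagonal(r_full, 1.0)
    else:
        ids = cis_ids
        r_full = r_cis

    gene = GeneAnnotation(gene_id=protein_id, chrom="1", tss=int(positions[m // 2]))
    return SimulatedDataset(
        protein_stats=protein,
        disease_stats=disease,
        ld=LDMatrix(ids, r_full),
        gene=gene,
        truth=config,
    )


def simulate_replication(
    dataset: SimulatedDataset,
    n_exp: int = N_EXPOSURE_REPLICATION,
    seed_offset: int = 10_007,
) -> SummaryStats:
    """Re-measure a region's protein in an independent (replication) cohort.

    Same ground truth, new sampling noise and allele frequencies, a
    different (larger by default) sample size.
    """
    cfg = replace(
        dataset.truth,
        seed=(dataset.truth.seed + seed_offset) % 2**31,
        n_exp=n_exp,
    )
    return simulate_region(
        cfg,
        protein_id=dataset.protein_stats.trait_id,
        disease_id=dataset.disease_stats.trait_id,
    ).protein_stats


def simulate_screen(
    n_proteins: int,
    base_config: Optional[SimulationConfig] = None,
    per_protein_overrides: Optional[dict[int, dict]] = None,
    seed: int = 0,
) -> tuple[list[SimulatedDataset], pd.DataFrame]:
    """Simulate independent regions, one per protein, with a truth table.

    Per-protein seeds are ``(seed + index) % 2**31``.  ``per_protein_overrides``
    maps a protein index to ``SimulationConfig`` field overrides (e.g. to make
    a subset of proteins causal).  Returns the datasets and a truth table with
    one row per protein (protein_id, theta, scenario).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    base = base_config or scenario_config("null")
    overrides = per_protein_overrides or {}
    datasets: list[SimulatedDataset] = []
    rows = []
    for i in range(n_proteins):
        cfg = replace(base, seed=(seed + i) % 2**31, **overrides.get(i, {}))
        pid = f"P{i + 1:04d}"
        datasets.append(simulate_region(cfg, protein_id=pid))
        rows.append({"protein_id": pid, "theta": cfg.theta, "scenario": cfg.scenario})
    return datasets, pd.DataFrame(rows)
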