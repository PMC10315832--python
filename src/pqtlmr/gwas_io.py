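"""Reading, writing and harmonizing GWAS summary statistics and LD matrices.

This module owns the shared variant/allele data model used throughout the
package:

* :class:`VariantAssociation` — one variant's marginal association with one
  trait (effect and other allele, effect-allele frequency, beta, se, p, N).
* :class:`SummaryStats` — a validated collection of associations for a trait.
* :class:`HarmonizedPair` — an exposure/outcome pair aligned to a common
  effect allele, the unit consumed by the MR estimators.
* :class:`LDMatrix` — signed pairwise correlations (r) over region variants.

File conventions
----------------
Summary statistics are tab- (or comma-) delimited with a header.  Canonical
column names are ``SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N, N_CASES,
N_CONTROLS``; common synonyms are resolved case-insensitively through
:data:`COLUMN_SYNONYMS`.  Files may be gzip-compressed.  Betas are per SD of
a quantitative trait or log-odds for a binary trait.  Positions are 1-based.
LD matrices are delimited square matrices whose first row and column carry
the variant ids.

Rows that violate the record invariants (non-positive se, identical alleles,
p outside (0, 1], ...) are dropped on read and counted in the module log;
structural problems (missing mandatory columns, zero valid rows) raise.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantAssociation",
    "SummaryStats",
    "HarmonizedPair",
    "LDMatrix",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "usable_pairs",
    "read_ld_matrix",
    "write_ld_matrix",
    "COLUMN_SYNONYMS",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Header synonyms accepted on read, matched case-insensitively.  The first
#: canonical name in each list is what :func:`write_summary_stats` emits.
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "variant_id": ("SNP", "RSID", "VARIANT_ID", "MARKERNAME", "ID"),
    "chrom": ("CHR", "CHROM", "CHROMOSOME"),
    "pos": ("POS", "BP", "POSITION", "BASE_PAIR_LOCATION"),
    "effect_allele": ("EA", "EFFECT_ALLELE", "A1", "ALT"),
    "other_allele": ("OA", "OTHER_ALLELE", "A2", "REF"),
    "eaf": ("EAF", "EFFECT_ALLELE_FREQUENCY", "AF", "FREQ"),
    "beta": ("BETA", "B", "EFFECT"),
    "se": ("SE", "STANDARD_ERROR", "STDERR"),
    "pvalue": ("P", "PVALUE", "PVAL", "P_VALUE"),
    "n": ("N", "SAMPLE_SIZE", "N_TOTAL"),
    "n_cases": ("N_CASES", "NCASE", "NCASES"),
    "n_controls": ("N_CONTROLS", "NCONTROL", "NCONTROLS"),
}

_MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue", "n")


def _complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def _is_palindromic(a: str, b: str) -> bool:
    """A/T or C/G single-base pairs; indels are never palindromic."""
    return len(a) == 1 and len(b) == 1 and _complement(a) == b


def _valid_allele(a: str) -> bool:
    return len(a) >= 1 and all(c in "ACGT" for c in a)


@dataclass(frozen=True, slots=True)
class VariantAssociation:
    """One variant's marginal association with one trait.

    ``beta`` is per SD for quantitative traits and log-odds for binary
    traits; ``eaf`` is the effect-allele frequency (``None`` when the source
    does not report it); ``n`` is the total sample size.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: int
    chrom: Optional[str] = None
    pos: Optional[int] = None
    eaf: Optional[float] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def __post_init__(self) -> None:
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.variant_id}: pvalue must lie in (0, 1], got {self.pvalue}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not (_valid_allele(self.effect_allele) and _valid_allele(self.other_allele)):
            raise ValueError(f"{self.variant_id}: alleles must be non-empty ACGT strings")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1 (1-based)")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf must lie in [0, 1]")
        if self.n < 1:
            raise ValueError(f"{self.variant_id}: n must be >= 1")
        if (
            self.n_cases is not None
            and self.n_controls is not None
            and self.n_cases + self.n_controls != self.n
        ):
            raise ValueError(f"{self.variant_id}: n_cases + n_controls must equal n")

    @property
    def is_palindromic(self) -> bool:
        return _is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class SummaryStats:
    """GWAS summary statistics for one trait, keyed by variant id."""

    trait_id: str
    trait_type: str  # "quantitative" or "binary"
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    genome_build: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"trait_type must be quantitative or binary, got {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def add(self, rec: VariantAssociation) -> None:
        if rec.variant_id in self.records:
            raise ValueError(f"duplicate variant id {rec.variant_id} in trait {self.trait_id}")
        self.records[rec.variant_id] = rec

    def variants(self) -> list[VariantAssociation]:
        return list(self.records.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.records.values():
            rows.append(
                {
                    "SNP": v.variant_id,
                    "CHR": v.chrom,
                    "POS": v.pos,
                    "EA": v.effect_allele,
                    "OA": v.other_allele,
                    "EAF": v.eaf,
                    "BETA": v.beta,
                    "SE": v.se,
                    "P": v.pvalue,
                    "N": v.n,
                    "N_CASES": v.n_cases,
                    "N_CONTROLS": v.n_controls,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True, slots=True)
class HarmonizedPair:
    """Exposure/outcome effects for one variant expressed on a common effect allele.

    ``status`` is one of ``ok`` (already aligned), ``flipped`` (the outcome
    beta was negated to align alleles), ``dropped_palindromic`` (A/T or C/G
    with ambiguous strand) or ``dropped_mismatch`` (incompatible alleles).
    Only ``ok``/``flipped`` pairs enter MR.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    n_exp: int
    beta_out: float
    se_out: float
    n_out: int
    status: str
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None

    @property
    def usable(self) -> bool:
        return self.status in ("ok", "flipped")


def usable_pairs(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if p.usable]


@dataclass
class LDMatrix:
    """Signed LD correlations (r) over an ordered set of variants."""

    variant_ids: list[str]
    r: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {m} variant ids")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD matrix has |r| > 1")
        if np.any(np.abs(np.diag(self.r) - 1.0) > 1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        asym = float(np.max(np.abs(self.r - self.r.T))) if m else 0.0
        if asym >= 1e-8:
            raise ValueError(f"LD matrix asymmetry {asym:g} exceeds tolerance 1e-8")
        self.r = np.clip((self.r + self.r.T) / 2.0, -1.0, 1.0)
        self._index = {vid: i for i, vid in enumerate(self.variant_ids)}
        if len(self._index) != m:
            raise ValueError("duplicate variant ids in LD matrix")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r_value(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r_value(a, b) ** 2

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[i] for i in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Summary-statistics I/O


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map canonical field names to actual header names, case-insensitively."""
    upper = {c.upper(): c for c in columns}
    out: dict[str, str] = {}
    for canon, names in COLUMN_SYNONYMS.items():
        for name in names:
            if name in upper:
                out[canon] = upper[name]
                break
    return out


def _sniff_sep(path: str | Path) -> str:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_stats(
    path: str | Path,
    trait_id: str,
    trait_type: str = "quantitative",
    genome_build: str = "GRCh37",
) -> SummaryStats:
    """Read and validate a summary-statistics table.

    Rows failing record invariants are dropped (and counted in the log);
    a missing mandatory column or zero valid rows is a hard error.
    Allele strings are upper-cased on read.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    cols = _resolve_columns(df.columns)
    for canon in _MANDATORY:
        if canon not in cols:
            raise ValueError(f"{path}: missing mandatory column for '{canon}' "
                             f"(accepted names: {', '.join(COLUMN_SYNONYMS[canon])})")

    stats = SummaryStats(trait_id=trait_id, trait_type=trait_type, genome_build=genome_build)
    n_dropped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()

        def get(canon: str):
            if canon not in cols:
                return None
            val = d[cols[canon]]
            return None if pd.isna(val) else val

        try:
            rec = VariantAssociation(
                variant_id=str(get("variant_id")),
                chrom=None if get("chrom") is None else str(get("chrom")),
                pos=None if get("pos") is None else int(get("pos")),
                effect_allele=str(get("effect_allele")).upper(),
                other_allele=str(get("other_allele")).upper(),
                eaf=None if get("eaf") is None else float(get("eaf")),
                beta=float(get("beta")),
                se=float(get("se")),
                pvalue=float(get("pvalue")),
                n=int(get("n")),
                n_cases=None if get("n_cases") is None else int(get("n_cases")),
                n_controls=None if get("n_controls") is None else int(get("n_controls")),
            )
            stats.add(rec)
        except (ValueError, TypeError) as exc:
            n_dropped += 1
            logger.warning("%s: dropped row (%s)", path, exc)
    if n_dropped:
        logger.info("%s: dropped %d invalid rows, kept %d", path, n_dropped, len(stats))
    if len(stats) == 0:
        raise ValueError(f"{path}: no valid summary-statistic rows")
    return stats


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    """Write a tab-delimited table such that a read reproduces the records.

    Binary traits always carry the N_CASES/N_CONTROLS columns; for
    quantitative traits they are emitted only if any record has them.
    """
    if len(stats) == 0:
        raise ValueError("refusing to write SummaryStats with no records")
    df = stats.to_frame()
    if stats.trait_type != "binary" and df["N_CASES"].isna().all() and df["N_CONTROLS"].isna().all():
        df = df.drop(columns=["N_CASES", "N_CONTROLS"])
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Harmonization


def _pair(exp: VariantAssociation, out: VariantAssociation, status: str,
          flipped: bool = False, eaf_out: Optional[float] = None) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exp.variant_id,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        beta_exp=exp.beta,
        se_exp=exp.se,
        n_exp=exp.n,
        eaf_exp=exp.eaf,
        beta_out=-out.beta if flipped else out.beta,
        se_out=out.se,
        n_out=out.n,
        eaf_out=eaf_out if eaf_out is not None else out.eaf,
        status=status,
    )


def _harmonize_one(exp: VariantAssociation, out: VariantAssociation,
                   window: float) -> HarmonizedPair:
    ea_e, oa_e = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele

    if _is_palindromic(ea_e, oa_e):
        # A/T and C/G pairs are their own strand complement: alleles can only
        # match as a set, and orientation must be inferred from frequency.
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return _pair(exp, out, "dropped_mismatch")
        if exp.eaf is None or out.eaf is None:
            return _pair(exp, out, "dropped_palindromic")
        if abs(exp.eaf - 0.5) < window or abs(out.eaf - 0.5) < window:
            return _pair(exp, out, "dropped_palindromic")
        flipped = ea_o != ea_e
        eaf_out = 1.0 - out.eaf if flipped else out.eaf
        if (exp.eaf < 0.5) != (eaf_out < 0.5):  # frequencies disagree: other strand
            flipped = not flipped
            eaf_out = 1.0 - eaf_out
        return _pair(exp, out, "flipped" if flipped else "ok", flipped, eaf_out)

    if (ea_o, oa_o) == (ea_e, oa_e):
        return _pair(exp, out, "ok")
    if (ea_o, oa_o) == (oa_e, ea_e):
        eaf_out = None if out.eaf is None else 1.0 - out.eaf
        return _pair(exp, out, "flipped", True, eaf_out)
    # strand complement (base-wise)
    if (_complement(ea_o), _complement(oa_o)) == (ea_e, oa_e):
        return _pair(exp, out, "ok")
    if (_complement(ea_o), _complement(oa_o)) == (oa_e, ea_e):
        eaf_out = None if out.eaf is None else 1.0 - out.eaf
        return _pair(exp, out, "flipped", True, eaf_out)
    return _pair(exp, out, "dropped_mismatch")


def harmonize(
    exposure_subset: Iterable[VariantAssociation],
    outcome: SummaryStats,
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonizedPair]:
    """Align exposure and outcome effects to a common effect allele.

    Same alleles in the same order pass through (``ok``); swapped alleles
    negate the outcome beta and reflect its frequency (``flipped``); strand
    complements are resolved by complementing; palindromic variants whose
    frequency on either side lies within ``palindrome_eaf_window`` of 0.5
    (or is missing) are dropped; anything else is a mismatch.

    Raises ``ValueError`` when no exposure variant is present in the outcome.
    """
    pairs: list[HarmonizedPair] = []
    for exp in exposure_subset:
        out = outcome.records.get(exp.variant_id)
        if out is None:
            continue
        pairs.append(_harmonize_one(exp, out, palindrome_eaf_window))
    if not pairs:
        raise ValueError("no overlapping variants between exposure and outcome")
    n_drop = sum(not p.usable for p in pairs)
    if n_drop:
        logger.info("harmonize: %d of %d shared variants dropped", n_drop, len(pairs))
    return pairs


# ---------------------------------------------------------------------------
# LD matrix I/O


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a delimited square LD matrix with variant-id header row/column.

    Near-symmetric input (max asymmetry < 1e-8) is symmetrized by averaging;
    larger asymmetry, |r| > 1, a non-unit diagonal or a non-square table is
    a hard error.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: LD matrix is not square ({df.shape[0]}x{df.shape[1]})")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise ValueError(f"{path}: LD matrix row and column variant ids differ")
    return LDMatrix(row_ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")
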