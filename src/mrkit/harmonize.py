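"""Instrument selection and exposure/outcome harmonization.

Selection follows the usual two-sample MR pipeline: keep genome-wide
significant SNPs (p < 5e-8, strict), prune linkage disequilibrium against a
caller-supplied r-squared matrix (r2 < 0.01, keeping the smaller p), and
align outcome associations to the exposure effect allele.  Palindromic (A/T
or C/G) variants cannot be strand-resolved from allele labels; they are
oriented by allele-frequency agreement when the minor-allele frequency is
at most 0.42 and dropped as not inferable above that.

Every exclusion is recorded in the instrument set's ``dropped`` audit list
with a machine-readable reason, so the exclusion-restriction bookkeeping is
inspectable rather than implicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CoverageError, EmptyInstrumentError, MRKitError, ValidationError
from .gwas_io import AssociationTable, VariantRecord

__all__ = [
    "HarmonizedPair",
    "InstrumentSet",
    "DROP_REASONS",
    "GWAS_SIGNIFICANCE",
    "DEFAULT_R2_THRESHOLD",
    "DEFAULT_MAF_THRESHOLD",
    "significance_filter",
    "ld_clump",
    "read_ld_matrix",
    "classify_palindrome",
    "harmonize",
    "build_instrument_set",
    "f_statistic",
]

GWAS_SIGNIFICANCE = 5e-8
DEFAULT_R2_THRESHOLD = 0.01
DEFAULT_MAF_THRESHOLD = 0.42
#: Ambiguity margin for palindrome orientation by frequency agreement.
PALINDROME_FREQ_MARGIN = 0.01

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DROP_REASONS = frozenset(
    {
        "not_significant",
        "clumped",
        "unmatched_in_outcome",
        "allele_mismatch",
        "palindromic_maf_gt_threshold",
        "palindromic_ambiguous_freq",
        "palindromic_no_freq",
    }
)


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a common effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.se_exp > 0:
            raise ValidationError(f"{self.snp_id}: se_exp must be > 0")
        if not self.se_out > 0:
            raise ValidationError(f"{self.snp_id}: se_out must be > 0")


@dataclass(frozen=True)
class InstrumentSet:
    """Harmonized instruments for one exposure-outcome analysis.

    ``dropped`` is the audit trail: (snp_id, reason) for every SNP excluded
    on the way from the raw tables to the final pairs.
    """

    exposure: str
    outcome: str
    pairs: tuple[HarmonizedPair, ...]
    dropped: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if len(self.pairs) < 1:
            raise EmptyInstrumentError(
                f"no instruments for {self.exposure} -> {self.outcome}"
            )
        bad = {reason for _, reason in self.dropped} - DROP_REASONS
        if bad:
            raise ValidationError(f"unknown drop reasons: {sorted(bad)}")

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(p.snp_id for p in self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        return (
            np.array([p.beta_exp for p in self.pairs], dtype=float),
            np.array([p.se_exp for p in self.pairs], dtype=float),
            np.array([p.beta_out for p in self.pairs], dtype=float),
            np.array([p.se_out for p in self.pairs], dtype=float),
        )

    def subset(self, keep) -> "InstrumentSet":
        """Restrict to SNP ids in ``keep`` (order preserved)."""
        keep = set(keep)
        return InstrumentSet(
            exposure=self.exposure,
            outcome=self.outcome,
            pairs=tuple(p for p in self.pairs if p.snp_id in keep),
            dropped=self.dropped,
        )

    def drop_snp(self, snp_id: str) -> "InstrumentSet":
        return self.subset(set(self.snp_ids) - {snp_id})

    @classmethod
    def from_summary(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids=None,
        exposure: str = "exposure",
        outcome: str = "outcome",
    ) -> "InstrumentSet":
        """Build an instrument set straight from aligned summary arrays."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(len(beta_exp))]
        pairs = tuple(
            HarmonizedPair(str(s), float(bx), float(sx), float(by), float(sy))
            for s, bx, sx, by, sy in zip(snp_ids, beta_exp, se_exp, beta_out, se_out)
        )
        return cls(exposure=exposure, outcome=outcome, pairs=pairs)


def significance_filter(
    table: AssociationTable, threshold: float = GWAS_SIGNIFICANCE
) -> AssociationTable:
    """Keep records with pval strictly below ``threshold`` (order preserved)."""
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    return table.with_records(r for r in table.records if r.pval < threshold)


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a square SNP-by-SNP r-squared matrix from TSV (ids on both axes)."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    return ld


def _check_ld(ld: pd.DataFrame, snp_ids) -> None:
    missing = [s for s in snp_ids if s not in ld.index or s not in ld.columns]
    if missing:
        raise CoverageError(f"LD matrix does not cover SNPs: {missing}")
    vals = ld.loc[list(snp_ids), list(snp_ids)].to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValidationError("LD r2 values must lie in [0, 1]")
    if not np.allclose(np.diag(vals), 1.0):
        raise ValidationError("LD matrix diagonal must be 1")


def ld_clump(
    table: AssociationTable,
    ld: pd.DataFrame,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> AssociationTable:
    """Greedy LD pruning: scan SNPs in ascending p (ties by input order) and
    retain a SNP iff its r2 with every already-retained SNP is strictly below
    ``r2_threshold``.  Returns retained records in their original input order.
    """
    ids = table.snp_ids
    _check_ld(ld, ids)
    order = sorted(range(len(ids)), key=lambda i: (table.records[i].pval, i))
    retained: list[int] = []
    for i in order:
        if all(float(ld.at[ids[i], ids[j]]) < r2_threshold for j in retained):
            retained.append(i)
    keep = sorted(retained)
    return table.with_records(table.records[i] for i in keep)


def classify_palindrome(
    effect_allele: str,
    other_allele: str,
    eaf: float | None,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> str:
    """Classify a variant's strand-resolvability.

    Returns ``"not_palindromic"`` for non-complementary allele pairs,
    ``"drop"`` for palindromes whose minor-allele frequency exceeds
    ``maf_threshold`` (or is unknown), and ``"alignable"`` otherwise.
    """
    if COMPLEMENT.get(effect_allele) != other_allele:
        return "not_palindromic"
    if eaf is None:
        return "drop"
    maf = min(eaf, 1.0 - eaf)
    return "drop" if maf > maf_threshold else "alignable"


def _orient_palindrome(exp: VariantRecord, out: VariantRecord):
    """Orient an alignable palindrome by allele-frequency agreement.

    Returns ``("same", ...)``, ``("flip", ...)`` or ``("ambiguous", None)``
    when the same-strand and flipped-strand frequency distances are within
    ``PALINDROME_FREQ_MARGIN`` of each other.
    """
    if out.eaf is None:
        return "no_freq", None
    d_same = abs(exp.eaf - out.eaf)
    d_flip = abs(exp.eaf + out.eaf - 1.0)
    if abs(d_same - d_flip) < PALINDROME_FREQ_MARGIN:
        return "ambiguous", None
    return ("same" if d_same < d_flip else "flip"), None


def harmonize(
    exposure: AssociationTable,
    outcome: AssociationTable,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> InstrumentSet:
    """Align outcome associations to the exposure effect alleles.

    SNPs are matched by rsID.  A non-palindromic outcome record reported on
    the opposite allele has its beta negated and frequency complemented
    (flag ``flipped_outcome``).  Palindromic SNPs are dropped when their MAF
    exceeds ``maf_threshold`` and otherwise oriented by frequency agreement
    (flag ``palindromic_aligned``); conflicting or missing frequency signals
    drop the SNP with an explicit audit reason.
    """
    out_by_id = {r.snp_id: r for r in outcome.records}
    pairs: list[HarmonizedPair] = []
    dropped: list[tuple[str, str]] = []

    for exp in exposure.records:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            dropped.append((exp.snp_id, "unmatched_in_outcome"))
            continue
        ea, oa = exp.effect_allele, exp.other_allele
        cls = classify_palindrome(ea, oa, exp.eaf, maf_threshold)
        flags: set[str] = set()
        if cls == "not_palindromic":
            if (out.effect_allele, out.other_allele) == (ea, oa):
                aligned = out
            elif (out.effect_allele, out.other_allele) == (oa, ea):
                aligned = out.flip_alleles()
                flags.add("flipped_outcome")
            else:
                dropped.append((exp.snp_id, "allele_mismatch"))
                continue
        elif cls == "drop":
            dropped.append((exp.snp_id, "palindromic_maf_gt_threshold"))
            continue
        else:  # alignable palindrome: allele labels cannot settle strand
            if {out.effect_allele, out.other_allele} != {ea, oa}:
                dropped.append((exp.snp_id, "allele_mismatch"))
                continue
            orientation, _ = _orient_palindrome(exp, out)
            if orientation == "no_freq":
                dropped.append((exp.snp_id, "palindromic_no_freq"))
                continue
            if orientation == "ambiguous":
                dropped.append((exp.snp_id, "palindromic_ambiguous_freq"))
                continue
            flags.add("palindromic_aligned")
            if orientation == "flip":
                aligned = out.flip_alleles()
                flags.add("flipped_outcome")
            else:
                aligned = out
        pairs.append(
            HarmonizedPair(
                snp_id=exp.snp_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=aligned.beta,
                se_out=aligned.se,
                eaf_exp=exp.eaf,
                eaf_out=aligned.eaf,
                flags=frozenset(flags),
            )
        )

    if not pairs:
        raise EmptyInstrumentError(
            f"harmonization matched zero usable SNPs between {exposure.trait!r} "
            f"and {outcome.trait!r} (dropped: {dropped})"
        )
    return InstrumentSet(
        exposure=exposure.trait,
        outcome=outcome.trait,
        pairs=tuple(pairs),
        dropped=tuple(dropped),
    )


def build_instrument_set(
    exposure: AssociationTable,
    outcome: AssociationTable,
    ld: pd.DataFrame | None = None,
    p_threshold: float = GWAS_SIGNIFICANCE,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> InstrumentSet:
    """Full selection pipeline: significance filter, optional LD clumping,
    then harmonization, with a merged audit trail."""
    audit: list[tuple[str, str]] = []
    sig = significance_filter(exposure, p_threshold)
    audit += [(s, "not_significant") for s in exposure.snp_ids if s not in set(sig.snp_ids)]
    if ld is not None:
        clumped = ld_clump(sig, ld, r2_threshold)
        audit += [(s, "clumped") for s in sig.snp_ids if s not in set(clumped.snp_ids)]
        sig = clumped
    if len(sig) == 0:
        raise EmptyInstrumentError(
            f"no SNPs in {exposure.trait!r} survive selection (dropped: {audit})"
        )
    instruments = harmonize(sig, outcome, maf_threshold)
    return InstrumentSet(
        exposure=instruments.exposure,
        outcome=instruments.outcome,
        pairs=instruments.pairs,
        dropped=tuple(audit) + instruments.dropped,
    )


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, (beta/se)^2; values above 10 are the
    conventional adequacy threshold."""
    if not se > 0 or not math.isfinite(se):
        raise MRKitError(f"se must be > 0, got {se}")
    return (beta / se) ** 2
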