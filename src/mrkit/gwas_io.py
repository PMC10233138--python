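"""Domain types and tabular I/O for GWAS summary statistics.

The unit of I/O is one trait's per-SNP association table: rsID, alleles,
effect-allele frequency, additive effect (beta), its standard error, and the
association p-value.  Betas are in trait units for continuous exposures and
log-odds for binary outcomes.

Packaged fixtures transcribe the published per-SNP associations for six serum
micronutrients (phosphorus, magnesium, selenium, iron, zinc, copper) together
with the matched outcome associations for coronary artery disease in diabetic
patients, exactly as printed — including one outcome beta (selenium
rs6586282, −0.046) whose sign is inconsistent with the downstream selenium
result; an opt-in ``selenium_patched`` fixture flips that single sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping, NamedTuple

import pandas as pd

from .exceptions import FixtureLookupError, FormatError, ValidationError

__all__ = [
    "VariantRecord",
    "AssociationTable",
    "FixtureStudy",
    "DEFAULT_DIALECT",
    "FIXTURE_NAMES",
    "read_association_table",
    "write_association_table",
    "load_fixture",
    "printed_f_statistics",
]

VALID_ALLELES = frozenset("ACGT")

#: Canonical field name -> default column name in TSV files.
DEFAULT_DIALECT: Mapping[str, str] = {
    "snp_id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
}

#: Exposure labels with packaged fixtures (``selenium_patched`` is the
#: clearly-labelled opt-in variant with the rs6586282 outcome sign flipped).
FIXTURE_NAMES = (
    "phosphorus",
    "magnesium",
    "selenium",
    "iron",
    "zinc",
    "copper",
    "selenium_patched",
)

OUTCOME_TRAIT = "cad_diabetes"


def _normalize_token(raw: str) -> str:
    # The source table mixes unicode minus signs (U+2212), en-dashes and
    # thousands separators into numeric cells; normalize before parsing.
    return raw.strip().replace("−", "-").replace("–", "-").replace(",", "")


def _parse_float(raw: str, what: str) -> float:
    token = _normalize_token(raw)
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"unparseable {what}: {raw!r}") from exc


@dataclass(frozen=True)
class VariantRecord:
    """One SNP's summary association with a single trait.

    ``eaf`` may be ``None`` when the source study did not report allele
    frequencies; all other numeric fields are mandatory.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} not in A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: other allele {self.other_allele!r} not in A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0 or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValidationError(f"{self.snp_id}: eaf must lie in (0, 1), got {self.eaf}")
        if not 0 < self.pval <= 1:
            raise ValidationError(f"{self.snp_id}: pval must lie in (0, 1], got {self.pval}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta must be finite")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos must be a 1-based position")

    def flip_alleles(self) -> "VariantRecord":
        """Re-express the record on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass(frozen=True)
class AssociationTable:
    """Ordered per-SNP summary statistics for one trait."""

    trait: str
    trait_type: str  # "continuous" | "binary"
    records: tuple[VariantRecord, ...]

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )
        seen: set[str] = set()
        for rec in self.records:
            if rec.snp_id in seen:
                raise ValidationError(f"duplicate snp_id {rec.snp_id!r} in table {self.trait!r}")
            seen.add(rec.snp_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def get(self, snp_id: str) -> VariantRecord:
        for rec in self.records:
            if rec.snp_id == snp_id:
                return rec
        raise KeyError(snp_id)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(rec.snp_id for rec in self.records)

    def with_records(self, records) -> "AssociationTable":
        return AssociationTable(self.trait, self.trait_type, tuple(records))

    def to_dataframe(self) -> pd.DataFrame:
        cols = list(DEFAULT_DIALECT)
        return pd.DataFrame(
            [[getattr(rec, c) for c in cols] for rec in self.records],
            columns=[DEFAULT_DIALECT[c] for c in cols],
        )


class FixtureStudy(NamedTuple):
    """A packaged exposure table with its matched outcome associations."""

    name: str
    exposure: AssociationTable
    outcome: AssociationTable


def read_association_table(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    trait: str | None = None,
    trait_type: str = "continuous",
) -> AssociationTable:
    """Read one trait's summary statistics from a TSV file.

    ``dialect`` maps canonical field names (the keys of ``DEFAULT_DIALECT``)
    to the column names actually present in the file; omitted keys fall back
    to the defaults.  Extra columns are ignored.  Unicode minus signs and
    scientific-notation p-values are normalized on read.  Rows violating the
    record invariants raise :class:`ValidationError` naming the row index —
    they are never silently dropped.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(cols)
        if unknown:
            raise FormatError(f"unknown dialect keys: {sorted(unknown)}")
        cols.update(dialect)

    frame = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    for fieldname, colname in cols.items():
        if colname not in frame.columns and fieldname != "eaf":
            raise FormatError(f"missing required column {colname!r} in {path}")
    has_eaf = cols["eaf"] in frame.columns

    records = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        try:
            eaf_raw = row[cols["eaf"]] if has_eaf else None
            eaf = (
                None
                if eaf_raw is None or pd.isna(eaf_raw) or _normalize_token(str(eaf_raw)) == ""
                else _parse_float(str(eaf_raw), "eaf")
            )
            records.append(
                VariantRecord(
                    snp_id=str(row[cols["snp_id"]]).strip(),
                    chrom=str(row[cols["chrom"]]).strip(),
                    pos=int(_parse_float(str(row[cols["pos"]]), "pos")),
                    effect_allele=str(row[cols["effect_allele"]]).strip().upper(),
                    other_allele=str(row[cols["other_allele"]]).strip().upper(),
                    eaf=eaf,
                    beta=_parse_float(str(row[cols["beta"]]), "beta"),
                    se=_parse_float(str(row[cols["se"]]), "se"),
                    pval=_parse_float(str(row[cols["pval"]]), "pval"),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(str(exc), row=idx) from exc

    name = trait if trait is not None else str(path)
    return AssociationTable(trait=name, trait_type=trait_type, records=tuple(records))


def write_association_table(table: AssociationTable, path, dialect: Mapping[str, str] | None = None) -> None:
    """Write a table as TSV using the (possibly remapped) default columns."""
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    frame = table.to_dataframe().rename(
        columns={DEFAULT_DIALECT[k]: v for k, v in cols.items()}
    )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def _fixture_path(filename: str):
    return resources.files("mrkit.fixtures").joinpath(filename)


def load_fixture(name: str) -> FixtureStudy:
    """Load one micronutrient's packaged exposure and matched outcome tables.

    Valid names are the six micronutrients plus ``selenium_patched``, the
    opt-in variant whose rs6586282 outcome beta is +0.046 instead of the
    printed −0.046 (the sign under which the published selenium result is
    reproducible).
    """
    if name not in FIXTURE_NAMES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    exposure_file = "selenium_exposure.tsv" if name == "selenium_patched" else f"{name}_exposure.tsv"
    with resources.as_file(_fixture_path(exposure_file)) as p:
        exposure = read_association_table(p, trait=name, trait_type="continuous")
    with resources.as_file(_fixture_path(f"{name}_outcome.tsv")) as p:
        outcome = read_association_table(p, trait=OUTCOME_TRAIT, trait_type="binary")
    return FixtureStudy(name=name, exposure=exposure, outcome=outcome)


def printed_f_statistics(name: str) -> dict[str, float]:
    """Per-SNP F statistics as printed in the source table (display only).

    For some exposures the printed values are not exactly (beta/se)^2 of the
    printed betas — the source GWASs evidently supplied unrounded effects —
    so these are stored for display and never recomputed from them.
    """
    if name not in FIXTURE_NAMES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    exposure_file = "selenium_exposure.tsv" if name == "selenium_patched" else f"{name}_exposure.tsv"
    with resources.as_file(_fixture_path(exposure_file)) as p:
        frame = pd.read_csv(p, sep="\t", dtype=str, encoding="utf-8")
    return {
        str(row["snp"]): float(_normalize_token(str(row["f"])))
        for _, row in frame.iterrows()
    }
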