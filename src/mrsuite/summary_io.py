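"""Reading, validating and writing GWAS summary-statistic tables.

The on-disk dialect is the most common GWAS summary format: UTF-8,
tab-separated, ``.`` decimal separator, one header row.  Column naming
varies wildly between consortia, so every reader takes a ``column_map``
translating canonical field names to the source file's headers.

Only single-base biallelic variants are accepted: indels and
multi-allelic records are rejected at parse time with a per-row reason.
Positions are 1-based base-pair coordinates, the dbSNP/GWAS-catalog
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "SummaryDataset",
    "HarmonizedInstrument",
    "ConfigurationError",
    "ValidationError",
    "DEFAULT_COLUMN_MAP",
    "HARMONIZED_COLUMNS",
    "read_summary",
    "parse_summary_frame",
    "write_summary",
    "write_harmonized",
    "read_harmonized",
    "instruments_to_frame",
    "frame_to_instruments",
]

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical field -> conventional GWAS header
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
}

REQUIRED_FIELDS = ("rsid", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "se", "pval")

ALLOWED_FLAGS = frozenset({"flipped", "palindromic", "frequency_aligned"})

HARMONIZED_COLUMNS = ["rsid", "beta_exp", "se_exp", "beta_out", "se_out",
                      "eaf_exp", "eaf_out", "flags"]


class ConfigurationError(Exception):
    """A reader was configured inconsistently with the input file."""


class ValidationError(ValueError):
    """An input table violates a dataset-level invariant."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association summary in a single GWAS.

    ``beta`` is the additive effect per copy of ``effect_allele`` on the
    log-odds scale; ``eaf`` is the effect-allele frequency and may be
    missing (``None``).
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float

    def __post_init__(self) -> None:
        reason = _invalid_reason(self)
        if reason is not None:
            raise ValueError(f"{self.rsid}: {reason}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G variants, whose strand is ambiguous."""
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


def _invalid_reason(v: VariantAssociation) -> str | None:
    """Reason a record violates the row invariants, or None if valid."""
    for allele in (v.effect_allele, v.other_allele):
        if allele not in VALID_BASES:
            return f"invalid allele '{allele}'"
    if v.effect_allele == v.other_allele:
        return "identical alleles"
    if not (isinstance(v.pos, (int, np.integer)) and v.pos >= 1):
        return "invalid position"
    if not np.isfinite(v.beta):
        return "malformed effect size"
    if not (np.isfinite(v.se) and v.se > 0):
        return "non-positive SE"
    if not (np.isfinite(v.pval) and 0.0 < v.pval <= 1.0):
        return "p-value outside (0,1]"
    if v.eaf is not None and not (np.isfinite(v.eaf) and 0.0 <= v.eaf <= 1.0):
        return "allele frequency outside [0,1]"
    return None


@dataclass
class SummaryDataset:
    """An ordered collection of per-SNP associations for one trait."""

    records: list[VariantAssociation]
    trait: str = ""
    ancestry: str = ""
    n_cases: int = 0
    n_controls: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise ValidationError(f"duplicate rsid '{rec.rsid}'")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def get(self, rsid: str) -> VariantAssociation | None:
        for r in self.records:
            if r.rsid == rsid:
                return r
        return None

    def subset(self, rsids: Iterable[str]) -> "SummaryDataset":
        keep = set(rsids)
        return replace(self, records=[r for r in self.records if r.rsid in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [np.nan if r.eaf is None else r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pval": [r.pval for r in self.records],
            }
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP with exposure and outcome effects on the same effect allele."""

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.rsid}: non-positive SE")
        unknown = set(self.flags) - ALLOWED_FLAGS
        if unknown:
            raise ValueError(f"{self.rsid}: unknown flags {sorted(unknown)}")


def _coerce_float(value, allow_missing: bool = False) -> float | None:
    if value is None:
        if allow_missing:
            return None
        raise ValueError("missing value")
    if isinstance(value, str):
        value = value.strip()
        if value in ("", ".", "NA", "NaN", "nan"):
            if allow_missing:
                return None
            raise ValueError("missing value")
    out = float(value)
    if np.isnan(out) and allow_missing:
        return None
    return out


def parse_summary_frame(
    frame: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[VariantAssociation], list[tuple[int, str]]]:
    """Parse a raw summary table into validated records.

    Returns ``(records, rejections)`` where each rejection is a
    ``(row_index, reason)`` pair; accepted + rejected always equals the
    number of input rows.

    Raises
    ------
    ConfigurationError
        if a required mapped column is absent from the table.
    ValidationError
        if two accepted rows share an rsid.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    for fieldname in REQUIRED_FIELDS:
        col = cmap.get(fieldname)
        if col is None or col not in frame.columns:
            raise ConfigurationError(
                f"required column for '{fieldname}' "
                f"({col!r}) not found in input"
            )
    has_eaf = "eaf" in cmap and cmap["eaf"] in frame.columns

    records: list[VariantAssociation] = []
    rejections: list[tuple[int, str]] = []
    seen: dict[str, int] = {}
    for idx, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        try:
            rsid = str(row[cmap["rsid"]]).strip()
            rec = VariantAssociation(
                rsid=rsid,
                chrom=str(row[cmap["chrom"]]).strip(),
                pos=int(float(row[cmap["pos"]])),
                effect_allele=str(row[cmap["effect_allele"]]).strip().upper(),
                other_allele=str(row[cmap["other_allele"]]).strip().upper(),
                eaf=_coerce_float(row[cmap["eaf"]], allow_missing=True)
                if has_eaf else None,
                beta=_coerce_float(row[cmap["beta"]]),
                se=_coerce_float(row[cmap["se"]]),
                pval=_coerce_float(row[cmap["pval"]]),
            )
        except (ValueError, TypeError) as exc:
            reason = str(exc)
            # strip the "rsid: " prefix the record constructor adds
            reason = reason.split(": ", 1)[-1] if ": " in reason else reason
            rejections.append((idx, reason or "malformed row"))
            continue
        if rec.rsid in seen:
            raise ValidationError(f"duplicate rsid '{rec.rsid}'")
        seen[rec.rsid] = idx
        records.append(rec)
    return records, rejections


def read_summary(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait: str = "",
    ancestry: str = "",
    n_cases: int = 0,
    n_controls: int = 0,
) -> SummaryDataset:
    """Read a tab-separated GWAS summary table into a SummaryDataset.

    Rows violating the record invariants are rejected; the count of
    accepted and rejected rows (with per-row reasons) is logged.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    records, rejections = parse_summary_frame(frame, column_map)
    for idx, reason in rejections:
        logger.warning("rejected row %d of %s: %s", idx, path, reason)
    logger.info(
        "read %s: %d accepted, %d rejected", path, len(records), len(rejections)
    )
    return SummaryDataset(
        records=records,
        trait=trait,
        ancestry=ancestry,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def write_summary(dataset: SummaryDataset, path,
                  column_map: Mapping[str, str] | None = None) -> None:
    """Write a SummaryDataset in the tab-separated GWAS dialect."""
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    frame = dataset.to_frame().rename(columns=cmap)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def instruments_to_frame(
    instruments: Sequence[HarmonizedInstrument],
) -> pd.DataFrame:
    """Tabulate harmonized instruments (flags serialized ';'-joined sorted)."""
    return pd.DataFrame(
        {
            "rsid": [i.rsid for i in instruments],
            "beta_exp": [i.beta_exp for i in instruments],
            "se_exp": [i.se_exp for i in instruments],
            "beta_out": [i.beta_out for i in instruments],
            "se_out": [i.se_out for i in instruments],
            "eaf_exp": [np.nan if i.eaf_exp is None else i.eaf_exp
                        for i in instruments],
            "eaf_out": [np.nan if i.eaf_out is None else i.eaf_out
                        for i in instruments],
            "flags": [";".join(sorted(i.flags)) for i in instruments],
        }
    )


def frame_to_instruments(frame: pd.DataFrame) -> list[HarmonizedInstrument]:
    out = []
    for row in frame.itertuples(index=False):
        flags = getattr(row, "flags", "")
        if isinstance(flags, float) and np.isnan(flags):
            flags = ""
        out.append(
            HarmonizedInstrument(
                rsid=str(row.rsid),
                beta_exp=float(row.beta_exp),
                se_exp=float(row.se_exp),
                beta_out=float(row.beta_out),
                se_out=float(row.se_out),
                eaf_exp=None if pd.isna(row.eaf_exp) else float(row.eaf_exp),
                eaf_out=None if pd.isna(row.eaf_out) else float(row.eaf_out),
                flags=frozenset(f for f in str(flags).split(";") if f),
            )
        )
    return out


def write_harmonized(instruments: Sequence[HarmonizedInstrument], path) -> None:
    """Write harmonized instruments as TSV; read-back is the identity."""
    if len(instruments) == 0:
        raise ValueError("refusing to write an empty instrument collection")
    frame = instruments_to_frame(instruments)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_harmonized(path) -> list[HarmonizedInstrument]:
    frame = pd.read_csv(path, sep="\t")
    return frame_to_instruments(frame)
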