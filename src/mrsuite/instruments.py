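"""Selection of independent, exposure-specific genetic instruments.

Three stages: genome-wide significance filtering, greedy LD clumping
against an abstract pairwise-r2 source, and exclusion of variants
associated with potential confounder traits in a local SNP->trait
catalog (a stand-in for a Phenoscanner query).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .summary_io import SummaryDataset

__all__ = [
    "LDSourceError",
    "TabularLDSource",
    "TraitCatalog",
    "read_ld_tsv",
    "read_trait_catalog",
    "filter_significant",
    "clump",
    "exclude_pleiotropic_traits",
]


class LDSourceError(RuntimeError):
    """The LD source failed for a named variant pair."""


class TabularLDSource:
    """Pairwise r2 lookups backed by an in-memory table.

    ``r2(a, b)`` is symmetric, ``r2(x, x) == 1`` and pairs absent from
    the table return ``None`` (unknown LD).
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._table: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), value in pairs.items():
                self.add(a, b, value)

    def add(self, rsid_a: str, rsid_b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of range for ({rsid_a}, {rsid_b}): {r2}")
        key = (rsid_a, rsid_b) if rsid_a <= rsid_b else (rsid_b, rsid_a)
        self._table[key] = float(r2)

    def r2(self, rsid_a: str, rsid_b: str) -> float | None:
        if rsid_a == rsid_b:
            return 1.0
        key = (rsid_a, rsid_b) if rsid_a <= rsid_b else (rsid_b, rsid_a)
        return self._table.get(key)

    def __len__(self) -> int:
        return len(self._table)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, v) for (a, b), v in sorted(self._table.items())]
        return pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"])


def read_ld_tsv(path) -> TabularLDSource:
    """Read a 3-column TSV (rsid_a, rsid_b, r2) into an LD source."""
    frame = pd.read_csv(path, sep="\t")
    source = TabularLDSource()
    for row in frame.itertuples(index=False):
        source.add(str(row.rsid_a), str(row.rsid_b), float(row.r2))
    return source


@dataclass
class TraitCatalog:
    """Local SNP -> (trait, p) association catalog with an exclusion list."""

    associations: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    excluded_traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rsid, entries in self.associations.items():
            for trait, pval in entries:
                if not 0.0 < pval <= 1.0:
                    raise ValueError(
                        f"{rsid}/{trait}: p-value outside (0,1]: {pval}"
                    )

    def lookup(self, rsid: str) -> list[tuple[str, float]]:
        return self.associations.get(rsid, [])

    @property
    def flagged_rsids(self) -> set[str]:
        """rsids carrying at least one excluded-trait association."""
        excluded = set(self.excluded_traits)
        return {
            rsid
            for rsid, entries in self.associations.items()
            if any(trait in excluded for trait, _ in entries)
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (rsid, trait, pval)
            for rsid, entries in sorted(self.associations.items())
            for trait, pval in entries
        ]
        return pd.DataFrame(rows, columns=["rsid", "trait", "pval"])


def read_trait_catalog(path, excluded_traits: Iterable[str]) -> TraitCatalog:
    frame = pd.read_csv(path, sep="\t")
    associations: dict[str, list[tuple[str, float]]] = {}
    for row in frame.itertuples(index=False):
        associations.setdefault(str(row.rsid), []).append(
            (str(row.trait), float(row.pval))
        )
    return TraitCatalog(associations=associations,
                        excluded_traits=list(excluded_traits))


def filter_significant(dataset: SummaryDataset,
                       p_threshold: float = 5e-8) -> SummaryDataset:
    """Keep records with ``pval < p_threshold``, preserving input order."""
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError(f"p_threshold outside (0,1]: {p_threshold}")
    kept = [r for r in dataset.records if r.pval < p_threshold]
    return replace(dataset, records=kept)


def clump(
    dataset: SummaryDataset,
    ld_source,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000,
    missing_ld: str = "remove",
) -> SummaryDataset:
    """Greedy LD clumping: keep index SNPs, prune their LD neighbours.

    Repeatedly takes the remaining record with the smallest p-value as an
    index SNP (ties broken by chrom, pos, rsid ascending) and removes all
    remaining same-chromosome records within ``window_bp`` whose r2 with
    the index is >= ``r2_threshold``.  Unknown LD within the window is
    treated as r2 = 1 when ``missing_ld="remove"`` (conservative), or
    retained when ``missing_ld="keep"``.

    The output is ordered by (chrom, pos, rsid) so it is invariant to the
    input row order.
    """
    if r2_threshold <= 0 or window_bp <= 0:
        raise ValueError("r2_threshold and window_bp must be positive")
    if missing_ld not in ("remove", "keep"):
        raise ValueError(f"unknown missing_ld policy: {missing_ld!r}")

    remaining = sorted(
        dataset.records, key=lambda r: (r.pval, r.chrom, r.pos, r.rsid)
    )
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for cand in remaining:
            if cand.chrom == index.chrom and abs(cand.pos - index.pos) <= window_bp:
                try:
                    r2 = ld_source.r2(index.rsid, cand.rsid)
                except Exception as exc:  # noqa: BLE001 - propagate with context
                    raise LDSourceError(
                        f"LD lookup failed for ({index.rsid}, {cand.rsid})"
                    ) from exc
                if r2 is None:
                    if missing_ld == "remove":
                        continue  # prune: assume correlated
                elif r2 >= r2_threshold:
                    continue  # prune
            survivors.append(cand)
        remaining = survivors
    kept.sort(key=lambda r: (r.chrom, r.pos, r.rsid))
    return replace(dataset, records=kept)


def exclude_pleiotropic_traits(
    dataset: SummaryDataset,
    catalog: TraitCatalog,
    p_threshold: float = 5e-8,
) -> tuple[SummaryDataset, list[tuple[str, str, float]]]:
    """Drop instruments associated with an excluded trait below p_threshold.

    Returns the filtered dataset and an exclusion log of
    ``(rsid, trait, pval)`` triples, one per excluded-trait association
    that triggered a removal.
    """
    excluded = set(catalog.excluded_traits)
    kept = []
    log: list[tuple[str, str, float]] = []
    for rec in dataset.records:
        hits = [
            (trait, pval)
            for trait, pval in catalog.lookup(rec.rsid)
            if trait in excluded and pval < p_threshold
        ]
        if hits:
            log.extend((rec.rsid, trait, pval) for trait, pval in hits)
        else:
            kept.append(rec)
    return replace(dataset, records=kept), log
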