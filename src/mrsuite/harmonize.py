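"""Alignment of exposure and outcome effects to a common effect allele.

Two GWAS may report the same SNP on different strands or with the
effect/other allele labels swapped.  Harmonization rewrites the outcome
association so its effect refers to the exposure's effect allele:

* swapped labels: negate the outcome beta, reflect its frequency;
* strand complement (non-palindromic): translate alleles A<->T, C<->G
  and retry;
* palindromic (A/T or C/G): allele labels cannot resolve the strand, so
  orientation is inferred from allele frequencies when the exposure MAF
  is below a threshold (default 0.3) and the variant is dropped as
  ambiguous otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .summary_io import HarmonizedInstrument, SummaryDataset, VariantAssociation

__all__ = ["Dropped", "harmonize_pair", "harmonize_datasets"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Dropped:
    """A variant excluded during harmonization, with the reason."""

    rsid: str
    reason: str


def _flip(out: VariantAssociation) -> tuple[float, float | None]:
    """Outcome effect re-expressed on the opposite allele."""
    eaf = None if out.eaf is None else 1.0 - out.eaf
    return -out.beta, eaf


def harmonize_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    maf_threshold: float = 0.3,
    palindromic_action: str = "align",
) -> HarmonizedInstrument | Dropped:
    """Harmonize one exposure/outcome record pair (same rsid).

    ``palindromic_action`` is ``"align"`` (frequency-align palindromes
    with exposure MAF below ``maf_threshold``, drop the rest) or
    ``"drop"`` (drop all palindromes).
    """
    if exp.rsid != out.rsid:
        raise ValueError(f"rsid mismatch: {exp.rsid} vs {out.rsid}")
    if palindromic_action not in ("align", "drop"):
        raise ValueError(f"unknown palindromic_action: {palindromic_action!r}")

    exp_alleles = (exp.effect_allele, exp.other_allele)
    out_alleles = (out.effect_allele, out.other_allele)

    def build(beta_out: float, eaf_out: float | None,
              flags: set[str]) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            rsid=exp.rsid,
            beta_exp=exp.beta,
            se_exp=exp.se,
            beta_out=beta_out,
            se_out=out.se,
            eaf_exp=exp.eaf,
            eaf_out=eaf_out,
            flags=frozenset(flags),
        )

    if exp.is_palindromic:
        if set(out_alleles) != set(exp_alleles):
            return Dropped(exp.rsid, "allele mismatch")
        if palindromic_action == "drop":
            return Dropped(exp.rsid, "palindromic variant")
        if exp.eaf is None or out.eaf is None:
            return Dropped(exp.rsid, "missing frequency for palindromic variant")
        maf = min(exp.eaf, 1.0 - exp.eaf)
        if maf >= maf_threshold:
            return Dropped(exp.rsid, "ambiguous palindrome")
        # Orient so both frequencies fall on the same side of 0.5.
        flags = {"palindromic", "frequency_aligned"}
        if (exp.eaf - 0.5) * (out.eaf - 0.5) >= 0:
            return build(out.beta, out.eaf, flags)
        beta, eaf = _flip(out)
        return build(beta, eaf, flags | {"flipped"})

    comp = tuple(COMPLEMENT[a] for a in out_alleles)
    if out_alleles == exp_alleles or comp == exp_alleles:
        return build(out.beta, out.eaf, set())
    if out_alleles == exp_alleles[::-1] or comp == exp_alleles[::-1]:
        beta, eaf = _flip(out)
        return build(beta, eaf, {"flipped"})
    return Dropped(exp.rsid, "allele mismatch")


def harmonize_datasets(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    maf_threshold: float = 0.3,
    palindromic_action: str = "align",
) -> tuple[list[HarmonizedInstrument], list[Dropped]]:
    """Harmonize every exposure instrument against the outcome dataset.

    Every exposure rsid is accounted for: it appears either in the
    returned instrument list or in the drop log (reason
    ``"not in outcome"``, a palindrome reason, or ``"allele mismatch"``).
    """
    outcome_by_rsid = {r.rsid: r for r in outcome.records}
    instruments: list[HarmonizedInstrument] = []
    drop_log: list[Dropped] = []
    for exp in exposure.records:
        out = outcome_by_rsid.get(exp.rsid)
        if out is None:
            drop_log.append(Dropped(exp.rsid, "not in outcome"))
            continue
        result = harmonize_pair(exp, out, maf_threshold, palindromic_action)
        if isinstance(result, Dropped):
            drop_log.append(result)
        else:
            instruments.append(result)
    return instruments, drop_log
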