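"""Cross-platform concordance with explicit missing-call bookkeeping.

Cells are compared as unordered allele pairs. Any cell without a passing call
on either platform is excluded from the denominator and counted separately
(a strict mode counting such cells as discordant exists for sensitivity
analysis). Copy-number comparisons list inconclusive-vs-integer pairs
separately: an inconclusive call resolved by the other platform is not a
discordance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .cnv import INCONCLUSIVE, CopyNumberCall
from .genotypes import PASS, GenotypeMatrix
from .phenotype import INDETERMINATE, PhenotypeRecord
from .util import pct


@dataclass(frozen=True)
class ConcordanceReport:
    platform_pair: tuple[str, str]
    n_comparable: int
    n_concordant: int
    n_discordant: int
    discordant_list: tuple[tuple, ...]
    n_excluded_missing: int
    concordance_pct: float | None  # None when nothing is comparable

    def as_dict(self) -> dict:
        return {
            "platform_pair": list(self.platform_pair),
            "n_comparable": self.n_comparable,
            "n_concordant": self.n_concordant,
            "n_discordant": self.n_discordant,
            "n_excluded_missing": self.n_excluded_missing,
            "concordance_pct": self.concordance_pct,
            "discordant": [list(d) for d in self.discordant_list],
        }


def _report(pair, concordant, discordant, excluded, ndigits=1):
    comparable = concordant + len(discordant)
    return ConcordanceReport(
        platform_pair=pair, n_comparable=comparable, n_concordant=concordant,
        n_discordant=len(discordant), discordant_list=tuple(discordant),
        n_excluded_missing=excluded,
        concordance_pct=pct(concordant, comparable, ndigits))


def genotype_concordance(matrix: GenotypeMatrix,
                         pair: tuple[str, str],
                         strict_missing: bool = False) -> ConcordanceReport:
    """Compare genotype calls between two platforms over shared samples."""
    a, b = pair
    platforms = matrix.platforms()
    for p in pair:
        if p not in platforms:
            raise ValueError(f"platform {p!r} not present in matrix")
    concordant, excluded = 0, 0
    discordant: list[tuple] = []
    for sample in matrix.samples:
        for loc in matrix.panel:
            ca = matrix.get(sample, loc.rsid, a)
            cb = matrix.get(sample, loc.rsid, b)
            ca_pass = ca is not None and ca.status == PASS
            cb_pass = cb is not None and cb.status == PASS
            if not (ca_pass and cb_pass):
                if strict_missing and (ca is not None or cb is not None):
                    discordant.append((sample, loc.rsid,
                                       ca.alleles if ca_pass else None,
                                       cb.alleles if cb_pass else None))
                else:
                    excluded += 1
                continue
            if ca.alleles == cb.alleles:
                concordant += 1
            else:
                discordant.append((sample, loc.rsid, ca.alleles, cb.alleles))
    return _report(pair, concordant, discordant, excluded)


@dataclass(frozen=True)
class CnvConcordanceReport:
    n_comparable: int
    n_concordant: int
    n_discordant: int
    discordant_list: tuple[tuple, ...]
    resolved_by_other: tuple[tuple, ...]  # inconclusive on one side only
    n_both_inconclusive: int
    concordance_pct: float | None


def cnv_concordance(calls_a: Sequence[CopyNumberCall],
                    calls_b: Sequence[CopyNumberCall]) -> CnvConcordanceReport:
    """Compare copy-number calls over the shared sample set."""
    by_a = {c.sample_id: c for c in calls_a}
    by_b = {c.sample_id: c for c in calls_b}
    shared = [s for s in by_a if s in by_b]
    concordant = 0
    discordant: list[tuple] = []
    resolved: list[tuple] = []
    both_inconclusive = 0
    for s in shared:
        ca, cb = by_a[s].copy_number, by_b[s].copy_number
        a_inc, b_inc = ca == INCONCLUSIVE, cb == INCONCLUSIVE
        if a_inc and b_inc:
            both_inconclusive += 1
        elif a_inc or b_inc:
            resolved.append((s, ca, cb))
        elif ca == cb:
            concordant += 1
        else:
            discordant.append((s, ca, cb))
    comparable = concordant + len(discordant)
    return CnvConcordanceReport(
        n_comparable=comparable, n_concordant=concordant,
        n_discordant=len(discordant), discordant_list=tuple(discordant),
        resolved_by_other=tuple(resolved),
        n_both_inconclusive=both_inconclusive,
        concordance_pct=pct(concordant, comparable, 1))


def phenotype_concordance(records_a: Sequence[PhenotypeRecord],
                          records_b: Sequence[PhenotypeRecord],
                          gene: str) -> ConcordanceReport:
    """Compare phenotype classes for one gene; indeterminate on either side is
    excluded and counted."""
    by_a = {r.sample_id: r for r in records_a if r.gene == gene}
    by_b = {r.sample_id: r for r in records_b if r.gene == gene}
    shared = [s for s in by_a if s in by_b]
    concordant, excluded = 0, 0
    discordant: list[tuple] = []
    for s in shared:
        pa, pb = by_a[s].phenotype_class, by_b[s].phenotype_class
        if INDETERMINATE in (pa, pb):
            excluded += 1
        elif pa == pb:
            concordant += 1
        else:
            discordant.append((s, gene, pa, pb))
    return _report(("a", "b"), concordant, discordant, excluded)


def write_discordance_tsv(report: ConcordanceReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\trsid\tcall_a\tcall_b\n")
        for sample, rsid, ca, cb in report.discordant_list:
            fa = "/".join(ca) if ca else "."
            fb = "/".join(cb) if cb else "."
            fh.write(f"{sample}\t{rsid}\t{fa}\t{fb}\n")
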