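"""Star-allele diplotype inference from unphased genotypes.

A star pair (a, b) is consistent with the observed genotypes when, at every
pass-status locus of the gene, the unordered pair {allele required by a,
allele required by b} (reference where the star imposes nothing) equals the
observed allele pair. Loci with missing or failed calls impose no constraint
(wildcards), so ambiguity can only grow as calls drop out.

The "most likely" pick among several consistent pairs formalizes a manual
clinical judgement: highest product of population star frequencies when
frequencies are supplied, then the pair with fewest non-*1 haplotypes, then
canonical (lexical star-number) order. A sample is demoted from ambiguous to
no_call when missing calls leave the candidate set spanning more than
``key_span`` distinct activity scores, the operational meaning of a missing
"key position".
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement
from typing import Iterable, Mapping

from .errors import GenotypeDataError
from .genotypes import FAIL, MISSING, PASS, GenotypeCall, GenotypeMatrix
from .panel import PanelDefinition, StarAlleleTable
from .util import canonical_pair, star_sort_key

RESOLVED = "resolved"
AMBIGUOUS = "ambiguous"
NO_CALL = "no_call"


@dataclass(frozen=True)
class DiplotypeCall:
    """A star-allele pair with its resolution state and copy-number annotation.

    ``mult1``/``mult2`` are haplotype copy multiplicities (e.g. *1x2/*4 has
    mult1=2); ``dup_unassigned`` marks a gain whose duplicated haplotype could
    not be phased. ``reflex`` flags samples where follow-up targeted testing
    is recommended (inconclusive copy number, or CN conflicting with genotype).
    """

    sample_id: str
    gene: str
    platform: str
    hap1: str | None
    hap2: str | None
    state: str
    candidates: tuple[tuple[str, str], ...] = ()
    missing_loci: tuple[str, ...] = ()
    reason: str = ""
    copy_number: int | str | None = None
    mult1: int = 1
    mult2: int = 1
    dup_unassigned: bool = False
    reflex: bool = False

    @property
    def notation(self) -> str | None:
        if self.hap1 is None or self.hap2 is None:
            return None

        def part(hap, mult):
            return f"{hap}x{mult}" if mult > 1 else hap

        return f"{part(self.hap1, self.mult1)}/{part(self.hap2, self.mult2)}"

    @property
    def is_het(self) -> bool:
        return (self.hap1 is not None and self.hap2 is not None
                and self.hap1 != self.hap2)


def enumerate_candidates(gene_calls: Mapping[str, GenotypeCall],
                         stars: StarAlleleTable, gene: str,
                         panel: PanelDefinition) -> list[tuple[str, str]]:
    """All star pairs consistent with the pass-status genotypes at a gene.

    Output is deduplicated and canonically ordered. An observed allele outside
    the locus's {ref, alt} raises :class:`GenotypeDataError`.
    """
    defs = {name: s for name, s in stars.stars_for(gene).items() if s.enumerable}
    observed: dict[str, tuple[str, str]] = {}
    for rsid, call in gene_calls.items():
        loc = panel.locus(rsid)
        if call.status != PASS:
            continue
        for a in call.alleles:
            if a not in (loc.ref, loc.alt):
                raise GenotypeDataError(
                    f"{call.sample_id} {rsid}: observed allele {a!r} is neither "
                    f"ref {loc.ref!r} nor alt {loc.alt!r}")
        observed[rsid] = call.alleles

    names = sorted(defs, key=star_sort_key)
    out = []
    for a, b in combinations_with_replacement(names, 2):
        da, db = defs[a].defining, defs[b].defining
        ok = True
        for rsid, obs in observed.items():
            ref = panel.locus(rsid).ref
            expected = tuple(sorted((da.get(rsid, ref), db.get(rsid, ref))))
            if expected != obs:
                ok = False
                break
        if ok:
            out.append(canonical_pair(a, b))
    return sorted(set(out), key=lambda p: (star_sort_key(p[0]), star_sort_key(p[1])))


def resolve_diplotype(candidates: list[tuple[str, str]], *, sample_id: str,
                      gene: str, platform: str,
                      missing_loci: Iterable[str] = (),
                      freqs: Mapping[str, float] | None = None,
                      stars: StarAlleleTable | None = None,
                      key_span: int = 3) -> DiplotypeCall:
    """Pick the most likely pair (or report ambiguity / no-call)."""
    missing = tuple(sorted(missing_loci))
    cands = tuple(candidates)
    if not cands:
        return DiplotypeCall(sample_id, gene, platform, None, None, NO_CALL,
                             candidates=(), missing_loci=missing,
                             reason="no star pair consistent with genotypes")
    if len(cands) == 1:
        h1, h2 = cands[0]
        return DiplotypeCall(sample_id, gene, platform, h1, h2, RESOLVED,
                             candidates=cands, missing_loci=missing)

    # missing "key position" rule: too wide a spread of possible activity
    # scores means no single diplotype can be responsibly assigned
    if missing and stars is not None and stars.has_activity_scale(gene):
        scores = set()
        unknown_activity = False
        for a, b in cands:
            va, vb = stars.activity(gene, a), stars.activity(gene, b)
            if va is None or vb is None:
                unknown_activity = True
                break
            scores.add(va + vb)
        if unknown_activity or len(scores) > key_span:
            return DiplotypeCall(
                sample_id, gene, platform, None, None, NO_CALL,
                candidates=cands, missing_loci=missing,
                reason="missing calls at key positions "
                       f"(candidates span {len(scores)} activity scores)")

    def rank(pair):
        a, b = pair
        if freqs is not None:
            prod = freqs.get(a, 0.0) * freqs.get(b, 0.0)
        else:
            prod = 0.0
        n_non_ref = (a != "*1") + (b != "*1")
        return (-prod, n_non_ref, star_sort_key(a), star_sort_key(b))

    best = min(cands, key=rank)
    return DiplotypeCall(sample_id, gene, platform, best[0], best[1], AMBIGUOUS,
                         candidates=cands, missing_loci=missing)


def diplotype_sample(matrix: GenotypeMatrix, stars: StarAlleleTable,
                     sample: str, gene: str, platform: str,
                     freqs: Mapping[str, float] | None = None,
                     key_span: int = 3) -> DiplotypeCall:
    calls = matrix.gene_calls(sample, gene, platform)
    missing = [rsid for rsid, c in calls.items() if c.status in (MISSING, FAIL)]
    try:
        cands = enumerate_candidates(calls, stars, gene, matrix.panel)
    except GenotypeDataError as exc:
        return DiplotypeCall(sample, gene, platform, None, None, NO_CALL,
                             missing_loci=tuple(sorted(missing)),
                             reason=str(exc))
    return resolve_diplotype(cands, sample_id=sample, gene=gene,
                             platform=platform, missing_loci=missing,
                             freqs=(freqs or {}).get(gene) if freqs else None,
                             stars=stars, key_span=key_span)


def diplotype_cohort(matrix: GenotypeMatrix, stars: StarAlleleTable,
                     genes: Iterable[str] | None = None,
                     platforms: Iterable[str] | None = None,
                     freqs: Mapping[str, Mapping[str, float]] | None = None,
                     key_span: int = 3) -> list[DiplotypeCall]:
    """One DiplotypeCall per (sample, gene, platform); per-sample failures
    become no_call records, never abort the cohort."""
    genes = list(genes) if genes is not None else stars.genes
    platforms = list(platforms) if platforms is not None else matrix.platforms()
    out = []
    for platform in platforms:
        for sample in matrix.samples:
            for gene in genes:
                out.append(diplotype_sample(matrix, stars, sample, gene,
                                            platform, freqs=freqs,
                                            key_span=key_span))
    return out


def write_diplotypes_tsv(calls: Iterable[DiplotypeCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\tplatform\thap1\thap2\tstate\tnotation\t"
                 "candidates\tmissing_loci\treason\n")
        for c in calls:
            cands = ";".join(f"{a}/{b}" for a, b in c.candidates)
            fh.write("\t".join([
                c.sample_id, c.gene, c.platform, c.hap1 or ".", c.hap2 or ".",
                c.state, c.notation or ".", cands or ".",
                ",".join(c.missing_loci) or ".", c.reason or "."]) + "\n")
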