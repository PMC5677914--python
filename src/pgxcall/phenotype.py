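"""Diplotype-to-phenotype translation and clinical actionability.

CYP2D6 uses the activity-score system: each haplotype contributes its allele
activity value (1 for normal-function alleles, 0.5 for decreased, 0 for
non-functional and for the deletion *5) times its copy multiplicity, and the
sum maps onto metabolizer classes (0 -> poor, (0,1) -> intermediate,
[1,2] -> extensive, >2 -> ultrarapid). Other metabolizer genes are classified
from the function classes of their two alleles; single-tag genes (SLCO1B1,
VKORC1, IFNL3 and the HLA proxies) are looked up in a bundled genotype table.

Actionability: every rule whose phenotype trigger matches contributes; a
sample's category is the maximum over triggered rules (3 > 2 > 1) and
category 1 means nothing triggered. Indeterminate phenotypes never trigger
rules; they are surfaced as reflex-testing recommendations instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cnv import INCONCLUSIVE
from .diplotype import NO_CALL, DiplotypeCall
from .genotypes import PASS, GenotypeMatrix
from .panel import (ActionabilityRule, PanelDefinition, StarAlleleTable,
                    load_genotype_phenotypes)
from .util import pct

INDETERMINATE = "indeterminate"

#: Default activity-score cutpoints: class -> (low, high], except poor == 0.
DEFAULT_CUTPOINTS = {"intermediate": (0.0, 1.0), "extensive": (1.0, 2.0)}


@dataclass(frozen=True)
class PhenotypeRecord:
    sample_id: str
    gene: str
    phenotype_class: str
    activity_score: float | None = None
    diplotype: DiplotypeCall | None = None
    genotype: tuple[str, str] | None = None
    basis: str = "CPIC"


@dataclass(frozen=True)
class SampleActionability:
    sample_id: str
    category: int
    triggering_genes: tuple[str, ...]
    specialty_flags: frozenset[str]
    reflex_genes: tuple[str, ...] = ()


def activity_score(diplotype: DiplotypeCall, stars: StarAlleleTable) -> float | None:
    """Sum of per-haplotype activity values times copy multiplicity.

    None when the diplotype is unresolved, an activity value is unknown, or
    the amplified haplotype of a gain is unassigned and the two possible
    assignments disagree.
    """
    if diplotype.hap1 is None or diplotype.hap2 is None:
        return None
    v1 = stars.activity(diplotype.gene, diplotype.hap1)
    v2 = stars.activity(diplotype.gene, diplotype.hap2)
    if v1 is None or v2 is None:
        return None
    if diplotype.dup_unassigned and diplotype.copy_number not in (None, 2):
        k = int(diplotype.copy_number)
        a = v1 * (k - 1) + v2
        b = v1 + v2 * (k - 1)
        return a if a == b else None
    return v1 * diplotype.mult1 + v2 * diplotype.mult2


def score_to_phenotype(score: float,
                       cutpoints: Mapping[str, tuple[float, float]] = DEFAULT_CUTPOINTS,
                       ) -> str:
    """Map an activity score to a metabolizer class."""
    if score < 0:
        raise ValueError("activity score cannot be negative")
    if score == 0:
        return "poor"
    lo_i, hi_i = cutpoints["intermediate"]
    lo_e, hi_e = cutpoints["extensive"]
    if lo_i < score < hi_i:
        return "intermediate"
    if lo_e <= score <= hi_e:
        return "extensive"
    return "ultrarapid"


def phenotype_activity_gene(diplotype: DiplotypeCall, stars: StarAlleleTable,
                            cutpoints=DEFAULT_CUTPOINTS) -> PhenotypeRecord:
    """Phenotype an activity-score gene (CYP2D6) from a CN-annotated diplotype."""
    sample, gene = diplotype.sample_id, diplotype.gene
    if diplotype.state == NO_CALL or diplotype.copy_number == INCONCLUSIVE:
        return PhenotypeRecord(sample, gene, INDETERMINATE, diplotype=diplotype)
    score = activity_score(diplotype, stars)
    if score is not None:
        return PhenotypeRecord(sample, gene, score_to_phenotype(score, cutpoints),
                               activity_score=score, diplotype=diplotype)
    # unassigned duplication: accept the class only if both possible
    # assignments of the extra copies agree
    if diplotype.dup_unassigned and diplotype.copy_number not in (None, 2):
        k = int(diplotype.copy_number)
        v1 = stars.activity(gene, diplotype.hap1)
        v2 = stars.activity(gene, diplotype.hap2)
        if v1 is not None and v2 is not None:
            cls_a = score_to_phenotype(v1 * (k - 1) + v2, cutpoints)
            cls_b = score_to_phenotype(v1 + v2 * (k - 1), cutpoints)
            if cls_a == cls_b:
                return PhenotypeRecord(sample, gene, cls_a, diplotype=diplotype)
    return PhenotypeRecord(sample, gene, INDETERMINATE, diplotype=diplotype)


def _function_counts(stars: StarAlleleTable, gene: str, h1: str, h2: str):
    f1 = stars.get(gene, h1).function
    f2 = stars.get(gene, h2).function
    counts = {"no_function": 0, "decreased": 0, "increased": 0, "normal": 0}
    for f in (f1, f2):
        counts[f] = counts.get(f, 0) + 1
    return counts


def phenotype_metabolizer_gene(diplotype: DiplotypeCall,
                               stars: StarAlleleTable) -> PhenotypeRecord:
    """Classify a metabolizer gene from its two alleles' function classes."""
    sample, gene = diplotype.sample_id, diplotype.gene
    if diplotype.state == NO_CALL or diplotype.hap1 is None:
        return PhenotypeRecord(sample, gene, INDETERMINATE, diplotype=diplotype)
    c = _function_counts(stars, gene, diplotype.hap1, diplotype.hap2)
    if c["no_function"] == 2:
        cls = "poor"
    elif c["no_function"] == 1 or c["decreased"] >= 1:
        cls = "intermediate"
    elif c["increased"] >= 1:
        cls = "ultrarapid"
    else:
        cls = "extensive"
    return PhenotypeRecord(sample, gene, cls, diplotype=diplotype)


def phenotype_single_locus_genes(matrix: GenotypeMatrix, sample: str,
                                 platform: str,
                                 table=None) -> list[PhenotypeRecord]:
    """Phenotype genes typed through one tag variant (bundled lookup table)."""
    table = table if table is not None else load_genotype_phenotypes()
    out = []
    for row in table.itertuples(index=False):
        loc = matrix.panel.locus(row.rsid)
        call = matrix.get(sample, row.rsid, platform)
        if call is None or call.status != PASS:
            out.append(PhenotypeRecord(sample, row.phenotype_gene, INDETERMINATE,
                                       basis=row.basis))
            continue
        n_alt = sum(1 for a in call.alleles if a == loc.alt)
        cls = (row.ref_hom, row.het, row.alt_hom)[n_alt]
        out.append(PhenotypeRecord(sample, row.phenotype_gene, cls,
                                   genotype=call.alleles, basis=row.basis))
    return out


def categorize_sample(records: Sequence[PhenotypeRecord],
                      rules: Sequence[ActionabilityRule]) -> SampleActionability:
    """Evaluate every rule against a sample's phenotype records."""
    sample = records[0].sample_id if records else ""
    by_gene = {r.gene: r for r in records}
    category = 1
    triggering: list[str] = []
    specialties: set[str] = set()
    for rule in rules:
        rec = by_gene.get(rule.gene)
        if rec is None or rec.phenotype_class == INDETERMINATE:
            continue
        if rule.triggers(rec.phenotype_class):
            category = max(category, rule.category)
            if rule.gene not in triggering:
                triggering.append(rule.gene)
            specialties |= set(rule.specialties)
    reflex = tuple(r.gene for r in records if r.phenotype_class == INDETERMINATE)
    return SampleActionability(sample, category, tuple(triggering),
                               frozenset(specialties), reflex)


def cohort_summary(actionability: Sequence[SampleActionability],
                   ndigits: int = 0) -> dict:
    """Per-category counts and per-specialty percentages over the full cohort."""
    n = len(actionability)
    categories = {1: 0, 2: 0, 3: 0}
    specialty_counts: dict[str, int] = {}
    for a in actionability:
        categories[a.category] += 1
        for s in a.specialty_flags:
            specialty_counts[s] = specialty_counts.get(s, 0) + 1
    specialty_pct = {s: pct(c, n, ndigits)
                     for s, c in sorted(specialty_counts.items())}
    actionable = categories[2] + categories[3]
    return {"n_samples": n, "categories": categories,
            "n_actionable": actionable,
            "actionable_pct": pct(actionable, n, ndigits),
            "specialty_pct": specialty_pct}


def write_phenotypes_tsv(records: Iterable[PhenotypeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\tdiplotype\tactivity_score\tphenotype_class\tbasis\n")
        for r in records:
            dip = r.diplotype.notation if r.diplotype else (
                "/".join(r.genotype) if r.genotype else ".")
            score = "." if r.activity_score is None else f"{r.activity_score:g}"
            fh.write("\t".join([r.sample_id, r.gene, dip or ".", score,
                                r.phenotype_class, r.basis]) + "\n")


def write_actionability_tsv(acts: Iterable[SampleActionability], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcategory\ttriggering_genes\tspecialties\treflex_genes\n")
        for a in acts:
            fh.write("\t".join([
                a.sample_id, str(a.category), ",".join(a.triggering_genes) or ".",
                ",".join(sorted(a.specialty_flags)) or ".",
                ",".join(a.reflex_genes) or "."]) + "\n")
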