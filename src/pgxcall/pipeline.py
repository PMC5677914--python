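"""End-to-end orchestration: genotype matrix + coverage -> diplotypes,
copy-number calls, phenotypes and actionability for one platform."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .cnv import (CopyNumberCall, CoverageProfile, DEFAULT_BANDS,
                  DEFAULT_MIN_DEPTH, DEFAULT_SKEW, DuplicationPhase,
                  classify_copy_number, integrate_cn_into_diplotype,
                  phase_duplication)
from .diplotype import DiplotypeCall, diplotype_sample
from .genotypes import GenotypeMatrix
from .panel import (StarAlleleTable, default_star_table,
                    load_actionability_rules, load_genotype_phenotypes)
from .phenotype import (PhenotypeRecord, SampleActionability, categorize_sample,
                        cohort_summary, phenotype_activity_gene,
                        phenotype_metabolizer_gene,
                        phenotype_single_locus_genes)

ACTIVITY_GENES = ("CYP2D6",)


@dataclass
class PipelineResult:
    platform: str
    diplotypes: dict  # sample -> gene -> DiplotypeCall (CN-annotated)
    cn_calls: dict  # sample -> CopyNumberCall
    phases: dict  # sample -> DuplicationPhase (only CN >= 3 heterozygotes)
    phenotypes: dict  # sample -> list[PhenotypeRecord]
    actionability: dict  # sample -> SampleActionability
    summary: dict


def run_pipeline(matrix: GenotypeMatrix,
                 profiles: Sequence[CoverageProfile] = (),
                 stars: StarAlleleTable | None = None,
                 rules=None,
                 platform: str | None = None,
                 star_freqs: Mapping[str, Mapping[str, float]] | None = None,
                 bands=DEFAULT_BANDS,
                 min_depth: int = DEFAULT_MIN_DEPTH,
                 skew_threshold: float = DEFAULT_SKEW,
                 key_span: int = 3) -> PipelineResult:
    """Run diplotyping, CYP2D6 CNV integration, phenotyping and actionability.

    ``profiles`` supply CYP2D6 relative coverage; without them every sample is
    treated as two-copy. Population ``star_freqs`` are optional priors for
    ambiguity resolution.
    """
    panel = matrix.panel
    stars = stars or default_star_table(panel)
    rules = rules if rules is not None else load_actionability_rules()
    geno_table = load_genotype_phenotypes()
    if platform is None:
        platform = matrix.platforms()[0]

    cn_by_sample = {p.sample_id: classify_copy_number(
        p.mean_relative_coverage, bands, p.sample_id) for p in profiles}

    star_genes = [g for g in stars.genes]
    diplotypes: dict = {}
    phases: dict = {}
    phenotypes: dict = {}
    actionability: dict = {}
    for sample in matrix.samples:
        dips: dict[str, DiplotypeCall] = {}
        for gene in star_genes:
            dip = diplotype_sample(matrix, stars, sample, gene, platform,
                                   freqs=star_freqs, key_span=key_span)
            if gene in ACTIVITY_GENES:
                cn = cn_by_sample.get(sample,
                                      CopyNumberCall(sample, 2, 1.0))
                phase = None
                if (isinstance(cn.copy_number, int) and cn.copy_number >= 3
                        and dip.is_het):
                    phase = phase_duplication(
                        dip, matrix.gene_calls(sample, gene, platform),
                        stars, panel, copy_number=cn.copy_number,
                        min_depth=min_depth, skew_threshold=skew_threshold)
                    phases[sample] = phase
                dip = integrate_cn_into_diplotype(dip, cn, phase)
            dips[gene] = dip
        diplotypes[sample] = dips

        records: list[PhenotypeRecord] = []
        for gene in star_genes:
            if gene in ACTIVITY_GENES:
                records.append(phenotype_activity_gene(dips[gene], stars))
            else:
                records.append(phenotype_metabolizer_gene(dips[gene], stars))
        records.extend(phenotype_single_locus_genes(matrix, sample, platform,
                                                    table=geno_table))
        phenotypes[sample] = records
        actionability[sample] = categorize_sample(records, rules)

    summary = cohort_summary(list(actionability.values()))
    return PipelineResult(platform=platform, diplotypes=diplotypes,
                          cn_calls=cn_by_sample, phases=phases,
                          phenotypes=phenotypes, actionability=actionability,
                          summary=summary)
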