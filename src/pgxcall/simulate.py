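"""Synthetic cohort generator: ground truth plus platform-realistic call sets.

Emulates the structure of a 98-child sequencing cohort typed on three
platforms: star-allele haplotypes drawn per gene from population frequencies,
a CYP2D6 copy-number distribution with ~17% CNV carriers (7:81:9:1 over copy
numbers 1-4), relative coverage proportional to copy number with Gaussian
window noise, allelic read depths drawn binomially from the copy composition,
and platform-specific no-call patterns: heavy rs16947 dropout on WGS, extra
CYP2D6 ambiguity when a *4 haplotype is present, two upstream CYP2D6 loci
absent from the exome capture, and near-complete targeted genotyping.

Low-confidence WGS cells are emitted as half-called genotypes (one allele
missing), which the reader classifies as fail_quality, mirroring ambiguous
calling; outright no-calls are fully missing genotypes.

Everything is driven by one integer seed; identical (config, seed) produce
byte-identical fixture files.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .cnv import CoverageProfile
from .diplotype import RESOLVED, DiplotypeCall
from .errors import ValidationError
from .genotypes import (FAIL, MISSING, PASS, GenotypeCall, GenotypeMatrix)
from .panel import (PanelDefinition, StarAlleleTable, default_panel,
                    default_star_table, load_actionability_rules,
                    load_genotype_phenotypes)
from .phenotype import (categorize_sample, phenotype_activity_gene,
                        phenotype_metabolizer_gene, PhenotypeRecord)
from .util import canonical_pair

PLATFORM_ORDER = ("WGS", "WES", "TARGETED")

#: Cohort-calibrated star-allele frequencies (per gene, summing to 1).
DEFAULT_STAR_FREQS: dict[str, dict[str, float]] = {
    "CYP2D6": {"*1": 0.40, "*2": 0.27, "*4": 0.18, "*10": 0.06, "*17": 0.03,
               "*9": 0.02, "*35": 0.02, "*3": 0.01, "*6": 0.005, "*29": 0.005},
    "CYP2C19": {"*1": 0.62, "*2": 0.15, "*17": 0.21, "*3": 0.01,
                "*8": 0.005, "*9": 0.005},
    "CYP2C9": {"*1": 0.79, "*2": 0.13, "*3": 0.07, "*5": 0.005, "*6": 0.005},
    "CYP3A5": {"*3": 0.85, "*1": 0.15},
    "TPMT": {"*1": 0.95, "*3A": 0.035, "*3C": 0.01, "*2": 0.005},
    "DPYD": {"*1": 0.985, "*2A": 0.01, "c.2846A>T": 0.005},
}

#: Alt-allele frequencies for loci not covered by star definitions.
DEFAULT_ALT_FREQS: dict[str, float] = {
    "rs1801131": 0.30, "rs1801133": 0.33,
    "rs1800497": 0.20, "rs1954787": 0.35,
    "rs2306283": 0.40, "rs4149056": 0.15,
    "rs9923231": 0.40, "rs2108622": 0.23, "rs12979860": 0.35,
    "rs1051266": 0.45, "rs4633": 0.47, "rs4818": 0.42, "rs4680": 0.48,
    "rs2228001": 0.37, "rs2231142": 0.11, "rs2231137": 0.06,
    "rs1061235": 0.04, "rs2395029": 0.03,
    "rs1128503": 0.42, "rs2032582": 0.43, "rs1045642": 0.48,
}

#: Cohort copy-number distribution over CYP2D6 copies 1-4.
DEFAULT_CNV_PROBS: dict[int, float] = {1: 7 / 98, 2: 81 / 98, 3: 9 / 98,
                                       4: 1 / 98}

#: Per-(platform, rsid) no-call probabilities; "_cyp2d6" and "_default" are
#: gene-level and global fallbacks.
DEFAULT_MISSINGNESS: dict[str, dict[str, float]] = {
    "WGS": {"rs16947": 60 / 98, "_cyp2d6": 0.02, "_default": 0.003},
    "WES": {"_default": 0.0},
    "TARGETED": {"_cyp2d6": 0.0025, "_default": 0.0003},
}

DEFAULT_FAIL_RATES: dict[str, float] = {"WGS": 0.002, "WES": 0.0,
                                        "TARGETED": 0.0}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    ``depth_mean`` is the mean sequencing depth at a diploid locus; depth at
    CYP2D6 loci scales with copy number. Its default is set so the
    fixed-threshold read-ratio phasing rule (major fraction >= 0.6 at >= 75
    reads) operates with <= 5% false assignments on balanced reads and
    >= 95% recovery on a 2:1 skew (binomial analysis; see methods).
    """

    n_samples: int = 98
    seed: int = 0
    star_freqs: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_STAR_FREQS.items()})
    alt_freqs: dict = field(default_factory=lambda: dict(DEFAULT_ALT_FREQS))
    cnv_probs: dict = field(default_factory=lambda: dict(DEFAULT_CNV_PROBS))
    missingness: dict = field(default_factory=lambda: {
        p: dict(v) for p, v in DEFAULT_MISSINGNESS.items()})
    fail_rates: dict = field(default_factory=lambda: dict(DEFAULT_FAIL_RATES))
    ambiguity_given_star4: float = 0.05
    coverage_noise_sd: float = 0.05
    depth_mean: float = 150.0
    exact_depths: bool = False
    platforms: tuple = PLATFORM_ORDER

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        for gene, freqs in self.star_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{gene}: star frequencies sum to {total}")
            if any(f < 0 for f in freqs.values()):
                raise ValidationError(f"{gene}: negative star frequency")
        if abs(sum(self.cnv_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("cnv_probs must sum to 1")
        probs = ([self.ambiguity_given_star4]
                 + list(self.alt_freqs.values())
                 + list(self.fail_rates.values())
                 + [v for d in self.missingness.values() for v in d.values()])
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.coverage_noise_sd < 0 or self.depth_mean <= 0:
            raise ValidationError("coverage_noise_sd >= 0 and depth_mean > 0 required")

    def missing_prob(self, platform: str, rsid: str, gene: str) -> float:
        table = self.missingness.get(platform, {})
        if rsid in table:
            return table[rsid]
        if gene == "CYP2D6" and "_cyp2d6" in table:
            return table["_cyp2d6"]
        return table.get("_default", 0.0)

    @classmethod
    def noise_free(cls, n_samples: int = 98, seed: int = 0) -> "SimulationConfig":
        """All call dropout and noise switched off; depths exact."""
        return cls(
            n_samples=n_samples, seed=seed,
            missingness={p: {"_default": 0.0} for p in PLATFORM_ORDER},
            fail_rates={p: 0.0 for p in PLATFORM_ORDER},
            ambiguity_given_star4=0.0, coverage_noise_sd=0.0,
            exact_depths=True)


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    panel: PanelDefinition
    manifest: dict
    truth_diplotypes: dict  # sample -> gene -> DiplotypeCall (CN-annotated)
    truth_genotypes: dict  # sample -> rsid -> (allele, allele)
    truth_cn: dict  # sample -> int
    matrices: dict  # platform -> GenotypeMatrix
    profiles: list


def _draw_star(rng: np.random.Generator, freqs: Mapping[str, float]) -> str:
    names = sorted(freqs)
    p = np.array([freqs[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=p / p.sum())]


def simulate_cohort(config: SimulationConfig,
                    panel: PanelDefinition | None = None,
                    stars: StarAlleleTable | None = None,
                    rules=None) -> SimulatedCohort:
    """Draw a cohort and derive every platform's call set from the ground truth."""
    config.validate()
    panel = panel or default_panel()
    stars = stars or default_star_table(panel)
    rules = rules if rules is not None else load_actionability_rules()
    geno_table = load_genotype_phenotypes()
    rng = np.random.default_rng(config.seed)

    star_genes = [g for g in sorted(config.star_freqs) if g in stars.genes]
    cn_values = sorted(config.cnv_probs)
    cn_p = np.array([config.cnv_probs[k] for k in cn_values], dtype=float)

    samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    truth_diplotypes: dict = {}
    truth_genotypes: dict = {}
    truth_cn: dict = {}
    manifest_samples: dict = {}

    for sample in samples:
        dips: dict[str, DiplotypeCall] = {}
        genos: dict[str, tuple[str, str]] = {}
        # haplotypes per star gene
        for gene in star_genes:
            h1 = _draw_star(rng, config.star_freqs[gene])
            h2 = _draw_star(rng, config.star_freqs[gene])
            h1, h2 = canonical_pair(h1, h2)
            dips[gene] = DiplotypeCall(sample, gene, "truth", h1, h2, RESOLVED,
                                       candidates=((h1, h2),), copy_number=2)
        # CYP2D6 copy number and phase
        cn = int(cn_values[rng.choice(len(cn_values), p=cn_p / cn_p.sum())])
        truth_cn[sample] = cn
        d6 = dips["CYP2D6"]
        if cn == 1:
            survivor = (d6.hap1, d6.hap2)[int(rng.integers(2))]
            dips["CYP2D6"] = replace(d6, hap1=survivor, hap2="*5",
                                     copy_number=1)
        elif cn >= 3:
            which = int(rng.integers(2))
            dips["CYP2D6"] = replace(
                d6, copy_number=cn,
                mult1=cn - 1 if which == 0 else 1,
                mult2=cn - 1 if which == 1 else 1)
        # genotypes: star-gene loci from haplotypes, remaining loci from
        # Hardy-Weinberg alt frequencies
        for loc in panel:
            if loc.gene in star_genes:
                d = dips[loc.gene]
                defs = stars.stars_for(loc.gene)
                if loc.gene == "CYP2D6" and cn == 1:
                    a = defs[d.hap1].defining.get(loc.rsid, loc.ref)
                    genos[loc.rsid] = (a, a)
                else:
                    a1 = defs[d.hap1].defining.get(loc.rsid, loc.ref)
                    a2 = defs[d.hap2].defining.get(loc.rsid, loc.ref)
                    genos[loc.rsid] = tuple(sorted((a1, a2)))
            else:
                f = config.alt_freqs.get(loc.rsid, 0.0)
                pair = tuple(sorted(
                    loc.alt if rng.random() < f else loc.ref for _ in range(2)))
                genos[loc.rsid] = pair
        truth_diplotypes[sample] = dips
        truth_genotypes[sample] = genos

    # truth phenotypes + actionability via the phenotyper's own tables
    for sample in samples:
        records = []
        for gene in star_genes:
            d = truth_diplotypes[sample][gene]
            if gene == "CYP2D6":
                records.append(phenotype_activity_gene(d, stars))
            else:
                records.append(phenotype_metabolizer_gene(d, stars))
        for row in geno_table.itertuples(index=False):
            loc = panel.locus(row.rsid)
            pair = truth_genotypes[sample][loc.rsid]
            n_alt = sum(1 for a in pair if a == loc.alt)
            cls = (row.ref_hom, row.het, row.alt_hom)[n_alt]
            records.append(PhenotypeRecord(sample, row.phenotype_gene, cls,
                                           genotype=pair, basis=row.basis))
        act = categorize_sample(records, rules)
        d6 = truth_diplotypes[sample]["CYP2D6"]
        dup = None
        if truth_cn[sample] >= 3:
            dup = d6.hap1 if d6.mult1 > 1 else d6.hap2
        manifest_samples[sample] = {
            "diplotypes": {g: {"hap1": d.hap1, "hap2": d.hap2,
                               "mult1": d.mult1, "mult2": d.mult2,
                               "notation": d.notation}
                           for g, d in truth_diplotypes[sample].items()},
            "cyp2d6_cn": truth_cn[sample],
            "duplicated_star": dup,
            "phenotypes": {r.gene: r.phenotype_class for r in records},
            "activity_score": next(
                (r.activity_score for r in records if r.gene == "CYP2D6"), None),
            "category": act.category,
            "specialties": sorted(act.specialty_flags),
        }

    # platform call sets
    matrices: dict[str, GenotypeMatrix] = {}
    for platform in config.platforms:
        matrix = GenotypeMatrix(panel, samples)
        for sample in samples:
            cn = truth_cn[sample]
            d6 = truth_diplotypes[sample]["CYP2D6"]
            has_star4 = "*4" in (d6.hap1, d6.hap2)
            for loc in panel:
                if (platform == "WES" and loc.gene == "CYP2D6"
                        and loc.region_class == "upstream"):
                    # not covered by the exome capture: cell stays absent
                    # and reads back as missing
                    matrix.calls[(sample, loc.rsid, platform)] = GenotypeCall(
                        sample, loc.rsid, platform, None, MISSING)
                    continue
                pair = truth_genotypes[sample][loc.rsid]
                p_miss = config.missing_prob(platform, loc.rsid, loc.gene)
                if (platform == "WGS" and loc.gene == "CYP2D6" and has_star4):
                    p_miss = min(1.0, p_miss + config.ambiguity_given_star4)
                status = PASS
                if rng.random() < p_miss:
                    status = MISSING
                elif rng.random() < config.fail_rates.get(platform, 0.0):
                    status = FAIL
                depth = ref_reads = alt_reads = None
                if platform in ("WGS", "WES") and status == PASS:
                    copies = cn if loc.gene == "CYP2D6" else 2
                    base = config.depth_mean * copies / 2.0
                    if loc.gene == "CYP2D6":
                        d = truth_diplotypes[sample]["CYP2D6"]
                        defs = stars.stars_for("CYP2D6")
                        m_alt = sum(
                            mult
                            for hap, mult in ((d.hap1, d.mult1), (d.hap2, d.mult2))
                            if hap != "*5"
                            and defs[hap].defining.get(loc.rsid, loc.ref) == loc.alt)
                    else:
                        m_alt = sum(1 for a in pair if a == loc.alt)
                    frac = m_alt / copies
                    if config.exact_depths:
                        depth = int(round(base))
                        alt_reads = int(round(depth * frac))
                    else:
                        depth = int(rng.poisson(base))
                        alt_reads = int(rng.binomial(depth, frac)) if depth else 0
                    ref_reads = depth - alt_reads
                alleles = pair if status == PASS else None
                matrix.calls[(sample, loc.rsid, platform)] = GenotypeCall(
                    sample, loc.rsid, platform, alleles, status,
                    depth=depth, ref_reads=ref_reads, alt_reads=alt_reads)
        matrices[platform] = matrix

    # coverage profiles (WGS relative coverage, 3 x 2 kb windows)
    profiles = []
    for sample in samples:
        mean = truth_cn[sample] / 2.0
        vals = tuple(
            max(0.0, float(rng.normal(mean, config.coverage_noise_sd)))
            for _ in range(3))
        profiles.append(CoverageProfile(sample_id=sample, window_values=vals))

    manifest = {"n_samples": config.n_samples, "seed": config.seed,
                "samples": manifest_samples}
    return SimulatedCohort(config=config, panel=panel, manifest=manifest,
                           truth_diplotypes=truth_diplotypes,
                           truth_genotypes=truth_genotypes, truth_cn=truth_cn,
                           matrices=matrices, profiles=profiles)


# ---------------------------------------------------------------------------
# fixture writing


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def _write_vcf(matrix: GenotypeMatrix, panel: PanelDefinition, path: Path,
               with_depth: bool) -> None:
    samples = matrix.samples
    platform = matrix.platforms()[0]
    loci = sorted(panel, key=lambda l: (_chrom_key(l.chrom), l.pos))
    fmt = "GT:DP:AD" if with_depth else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##reference=GRCh37\n")
        for chrom in sorted({l.chrom for l in loci}, key=_chrom_key):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FILTER=<ID=LowQual,Description="Low confidence call">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for loc in loci:
            cells = []
            any_call = False
            for sample in samples:
                call = matrix.calls.get((sample, loc.rsid, platform))
                if call is None:
                    cells.append("./.:.:.,." if with_depth else "./.")
                    continue
                any_call = True
                if call.status == MISSING:
                    gt = "./."
                elif call.status == FAIL:
                    gt = "0/."  # one allele confidently called
                else:
                    idx = sorted("01"[a == loc.alt] for a in call.alleles)
                    gt = "/".join(idx)
                if with_depth:
                    if call.depth is None:
                        cells.append(f"{gt}:.:.,.")
                    else:
                        cells.append(f"{gt}:{call.depth}:"
                                     f"{call.ref_reads},{call.alt_reads}")
                else:
                    cells.append(gt)
            if not any_call:
                continue  # locus absent from this platform's output
            fh.write("\t".join([
                loc.chrom, str(loc.pos), loc.rsid, loc.ref, loc.alt, ".",
                "PASS", ".", fmt] + cells) + "\n")


def write_fixture_set(sim: SimulatedCohort, directory: str | Path) -> dict:
    """Write VCF (WGS/WES), wide targeted TSV, coverage TSV, targeted copy
    numbers and the ground-truth manifest; returns the file paths.

    Re-reading the files with the genotype readers reproduces the in-memory
    matrices exactly; identical (config, seed) produce byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    panel = sim.panel
    paths = {}

    for platform, fname in (("WGS", "wgs.vcf"), ("WES", "wes.vcf")):
        if platform not in sim.matrices:
            continue
        path = directory / fname
        matrix = sim.matrices[platform]
        if platform == "WES":
            # drop uncovered upstream CYP2D6 loci from the exome VCF entirely
            matrix = _without_wes_uncovered(matrix)
        _write_vcf(matrix, panel, path, with_depth=True)
        paths[platform.lower()] = path

    if "TARGETED" in sim.matrices:
        path = directory / "targeted.tsv"
        matrix = sim.matrices["TARGETED"]
        rsids = [l.rsid for l in panel]
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(rsids) + "\n")
            for sample in matrix.samples:
                cells = []
                for rsid in rsids:
                    call = matrix.calls.get((sample, rsid, "TARGETED"))
                    if call is None or call.status != PASS:
                        cells.append(".")
                    else:
                        cells.append("/".join(call.alleles))
                fh.write(sample + "\t" + "\t".join(cells) + "\n")
        paths["targeted"] = path

    path = directory / "coverage.tsv"
    with open(path, "w") as fh:
        fh.write("# relative coverage, 1 = diploid; 2 kb windows, GRCh37\n")
        fh.write("sample_id\tchrom\twindow_start\twindow_end\trelative_coverage\n")
        for prof in sim.profiles:
            chrom, start, _ = prof.region
            for i, v in enumerate(prof.window_values):
                ws = start + 2000 * i
                fh.write(f"{prof.sample_id}\t{chrom}\t{ws}\t{ws + 2000}\t{v:.6f}\n")
    paths["coverage"] = path

    path = directory / "targeted_cn.tsv"
    with open(path, "w") as fh:
        fh.write("sample_id\tcopy_number\n")
        for sample in sorted(sim.truth_cn):
            fh.write(f"{sample}\t{sim.truth_cn[sample]}\n")
    paths["targeted_cn"] = path

    path = directory / "manifest.json"
    with open(path, "w") as fh:
        json.dump(sim.manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    paths["manifest"] = path
    return paths


def _without_wes_uncovered(matrix: GenotypeMatrix) -> GenotypeMatrix:
    out = GenotypeMatrix(matrix.panel, matrix.samples)
    for key, call in matrix.calls.items():
        loc = matrix.panel.locus(call.rsid)
        if loc.gene == "CYP2D6" and loc.region_class == "upstream":
            continue
        out.calls[key] = call
    return out
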