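"""CYP2D6 copy-number classification and duplication phasing.

Copy number is classified from mean relative coverage over three 2 kb windows
spanning chr22:42,522,000-42,528,000 (GRCh37), where relative coverage is
normalized so a diploid state equals 1. Band edges codify the qualitative
"close to k/2" reading of coverage: values between bands are inconclusive and
routed to reflex testing rather than forced into a class.

For samples with a copy-number gain and a heterozygous diplotype, the
amplified haplotype is deduced from reference/alternative read counts at
informative positions (het sites whose alleles distinguish the two
haplotypes): with one haplotype present in k-1 of k copies, its allele is
expected in (k-1)/k of reads, so a site whose major-allele fraction clears a
skew threshold votes for the haplotype carrying that allele. Sites below a
read-depth floor abstain, and conflicting votes yield "indeterminate".
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binomtest

from .diplotype import NO_CALL, DiplotypeCall
from .errors import FormatError, PgxError, ValidationError
from .genotypes import PASS, GenotypeCall
from .panel import PanelDefinition

INCONCLUSIVE = "inconclusive"
INDETERMINATE = "indeterminate"

#: Default classification bands: copy number -> [low, high] of mean relative
#: coverage (inclusive). Gaps between bands are inconclusive.
DEFAULT_BANDS: tuple[tuple[int, float, float], ...] = (
    (0, 0.0, 0.1),
    (1, 0.4, 0.6),
    (2, 0.8, 1.2),
    (3, 1.4, 1.6),
    (4, 1.8, math.inf),
)

DEFAULT_REGION = ("22", 42_522_000, 42_528_000)
DEFAULT_MIN_DEPTH = 75
DEFAULT_SKEW = 0.6


@dataclass(frozen=True)
class CoverageProfile:
    sample_id: str
    window_values: tuple[float, ...]
    region: tuple[str, int, int] = DEFAULT_REGION

    def __post_init__(self):
        if any(v < 0 for v in self.window_values):
            raise ValidationError(f"{self.sample_id}: negative relative coverage")

    @property
    def mean_relative_coverage(self) -> float:
        return sum(self.window_values) / len(self.window_values)


@dataclass(frozen=True)
class CopyNumberCall:
    sample_id: str
    copy_number: int | str  # integer or "inconclusive"
    evidence: float  # mean relative coverage
    band: tuple[float, float] | None = None


@dataclass(frozen=True)
class DuplicationPhase:
    sample_id: str
    duplicated_star: str  # star name or "indeterminate"
    informative_positions: tuple[tuple[str, int, int], ...]
    min_depth_used: int


def validate_bands(bands: Sequence[tuple[int, float, float]]) -> None:
    ordered = sorted(bands, key=lambda b: b[1])
    for cn, lo, hi in ordered:
        if lo > hi or lo < 0:
            raise ValidationError(f"band for CN {cn} is malformed: [{lo}, {hi}]")
    for (cn_a, _, hi_a), (cn_b, lo_b, _) in zip(ordered, ordered[1:]):
        if hi_a >= lo_b:
            raise ValidationError(f"bands for CN {cn_a} and CN {cn_b} overlap")
    cns = sorted(b[0] for b in ordered)
    if [b[0] for b in ordered] != cns:
        raise ValidationError("bands are not monotone in copy number")


def classify_copy_number(mean_rel_cov: float,
                         bands: Sequence[tuple[int, float, float]] = DEFAULT_BANDS,
                         sample_id: str = "") -> CopyNumberCall:
    """Map mean relative coverage to an integer copy number or inconclusive."""
    if mean_rel_cov < 0:
        raise ValidationError("relative coverage cannot be negative")
    for cn, lo, hi in bands:
        if lo <= mean_rel_cov <= hi:
            return CopyNumberCall(sample_id, cn, mean_rel_cov, (lo, hi))
    return CopyNumberCall(sample_id, INCONCLUSIVE, mean_rel_cov, None)


def call_cohort_cnv(profiles: Iterable[CoverageProfile],
                    bands: Sequence[tuple[int, float, float]] = DEFAULT_BANDS,
                    ) -> tuple[list[CopyNumberCall], dict]:
    """Classify every profile; summary histogram includes inconclusive."""
    calls = [classify_copy_number(p.mean_relative_coverage, bands, p.sample_id)
             for p in profiles]
    histogram: dict = {}
    for c in calls:
        histogram[c.copy_number] = histogram.get(c.copy_number, 0) + 1
    return calls, histogram


def load_coverage_tsv(path: str | Path) -> list[CoverageProfile]:
    """Coverage TSV: sample_id, chrom, window_start, window_end,
    relative_coverage (one row per window; 1-based GRCh37)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"sample_id": str, "chrom": str})
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse coverage TSV ({exc})") from exc
    profiles = []
    for sample, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("window_start")
        region = (str(grp["chrom"].iloc[0]),
                  int(grp["window_start"].min()), int(grp["window_end"].max()))
        profiles.append(CoverageProfile(
            sample_id=str(sample),
            window_values=tuple(float(v) for v in grp["relative_coverage"]),
            region=region))
    return profiles


def phase_duplication(diplotype: DiplotypeCall,
                      gene_calls: Mapping[str, GenotypeCall],
                      stars, panel: PanelDefinition,
                      copy_number: int = 3,
                      min_depth: int = DEFAULT_MIN_DEPTH,
                      skew_threshold: float = DEFAULT_SKEW,
                      use_pvalue: bool = False,
                      alpha: float = 0.05) -> DuplicationPhase:
    """Deduce the amplified haplotype of a heterozygous copy-number gain.

    ``use_pvalue`` additionally requires a one-sided binomial test of the
    observed major-allele count against an even split to reach ``alpha``
    (off by default; the plain fraction threshold mirrors visual inspection
    of read counts).
    """
    if copy_number < 3:
        raise PgxError("duplication phasing requires copy number >= 3")
    if not diplotype.is_het:
        raise PgxError("duplication phasing requires a heterozygous diplotype")
    defs = stars.stars_for(diplotype.gene)
    da = defs[diplotype.hap1].defining
    db = defs[diplotype.hap2].defining

    votes: set[str] = set()
    informative: list[tuple[str, int, int]] = []
    for rsid, call in gene_calls.items():
        if call.status != PASS or not call.is_het:
            continue
        loc = panel.locus(rsid)
        allele_a = da.get(rsid, loc.ref)
        allele_b = db.get(rsid, loc.ref)
        if allele_a == allele_b:
            continue
        if call.ref_reads is None or call.alt_reads is None:
            continue
        informative.append((rsid, call.ref_reads, call.alt_reads))
        total = call.ref_reads + call.alt_reads
        if total < min_depth:
            continue
        major_reads = max(call.ref_reads, call.alt_reads)
        if major_reads / total < skew_threshold:
            continue
        if use_pvalue:
            p = binomtest(major_reads, total, 0.5, alternative="greater").pvalue
            if p >= alpha:
                continue
        major_allele = loc.ref if call.ref_reads >= call.alt_reads else loc.alt
        if major_allele == allele_a:
            votes.add(diplotype.hap1)
        elif major_allele == allele_b:
            votes.add(diplotype.hap2)
    duplicated = votes.pop() if len(votes) == 1 else INDETERMINATE
    return DuplicationPhase(diplotype.sample_id, duplicated,
                            tuple(informative), min_depth)


def integrate_cn_into_diplotype(diplotype: DiplotypeCall, cn: CopyNumberCall,
                                phase: DuplicationPhase | None = None,
                                ) -> DiplotypeCall:
    """Fold a copy-number call (and optional duplication phase) into a diplotype.

    CN 2 leaves the call unchanged; CN 1 replaces the second haplotype with the
    deletion allele *5 (the SNP data of a hemizygote look homozygous, so the
    resolved pair is (h, h) and becomes (h, *5)); CN 0 is a homozygous
    deletion; CN >= 3 annotates the amplified haplotype with its multiplicity
    when phased, or flags the gain as unassigned; an inconclusive CN flags the
    sample for reflex testing.
    """
    if cn.sample_id and diplotype.sample_id and cn.sample_id != diplotype.sample_id:
        raise ValidationError("copy-number call is for a different sample")
    if cn.copy_number == INCONCLUSIVE:
        return replace(diplotype, copy_number=INCONCLUSIVE, reflex=True)
    k = int(cn.copy_number)
    if diplotype.state == NO_CALL:
        return replace(diplotype, copy_number=k)
    if k == 2:
        return replace(diplotype, copy_number=2)
    if k == 0:
        return replace(diplotype, hap1="*5", hap2="*5", copy_number=0,
                       mult1=1, mult2=1)
    if k == 1:
        if diplotype.is_het:
            # a heterozygous genotype cannot come from a single copy
            return replace(diplotype, copy_number=1, reflex=True,
                           reason="heterozygous calls conflict with CN 1")
        return replace(diplotype, hap2="*5", copy_number=1)
    # k >= 3
    if not diplotype.is_het:
        return replace(diplotype, copy_number=k, mult1=k - 1, mult2=1)
    if phase is not None and phase.duplicated_star in (diplotype.hap1,
                                                       diplotype.hap2):
        if phase.duplicated_star == diplotype.hap1:
            return replace(diplotype, copy_number=k, mult1=k - 1, mult2=1)
        return replace(diplotype, copy_number=k, mult1=1, mult2=k - 1)
    return replace(diplotype, copy_number=k, dup_unassigned=True)


def write_cnv_tsv(calls: Iterable[CopyNumberCall], path,
                  phases: Mapping[str, DuplicationPhase] | None = None) -> None:
    phases = phases or {}
    with open(path, "w") as fh:
        fh.write("sample_id\tmean_rel_cov\tcopy_number\tband\tduplicated_star\n")
        for c in calls:
            band = "." if c.band is None else f"[{c.band[0]},{c.band[1]}]"
            ph = phases.get(c.sample_id)
            fh.write("\t".join([
                c.sample_id, f"{c.evidence:.4f}", str(c.copy_number), band,
                ph.duplicated_star if ph else "."]) + "\n")
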