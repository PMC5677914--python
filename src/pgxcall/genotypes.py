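"""Genotype input: VCF (sequencing platforms) and wide TSV (targeted genotyping).

Calls are unphased everywhere: VCF phase separators are accepted and discarded.
Every (sample, panel locus) cell gets exactly one call per platform; loci absent
from the input are explicit ``missing`` calls so that accounting categories
partition the full sample x locus grid.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
from cyvcf2 import VCF

from .errors import FormatError, ValidationError
from .panel import PanelDefinition, _norm_chrom
from .util import pct

PLATFORMS = ("WGS", "WES", "TARGETED")

PASS = "pass"
FAIL = "fail_quality"
MISSING = "missing"
STATUSES = (PASS, FAIL, MISSING)


@dataclass(frozen=True)
class GenotypeCall:
    """One platform's call at one locus for one sample.

    ``alleles`` is the unordered genotype stored as a sorted pair of allele
    strings; half-missing genotypes (only one allele confidently called) are
    recorded as ``fail_quality`` with alleles absent. ``ref_reads``/``alt_reads``
    hold allelic depths when the source provides them (used for read-ratio
    phasing of CYP2D6 duplications).
    """

    sample_id: str
    rsid: str
    platform: str
    alleles: tuple[str, str] | None
    status: str
    depth: int | None = None
    ref_reads: int | None = None
    alt_reads: int | None = None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")
        if self.status == PASS and self.alleles is None:
            raise ValidationError("pass call must carry alleles")
        if (self.depth is not None and self.ref_reads is not None
                and self.alt_reads is not None
                and self.ref_reads + self.alt_reads > self.depth):
            raise ValidationError("ref_reads + alt_reads exceeds depth")

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]


class GenotypeMatrix:
    """Per-sample, per-locus calls with platform provenance."""

    def __init__(self, panel: PanelDefinition, samples: Iterable[str] = ()):
        self.panel = panel
        self.samples: list[str] = list(samples)
        self.calls: dict[tuple[str, str, str], GenotypeCall] = {}

    def add(self, call: GenotypeCall) -> None:
        if call.rsid not in self.panel:
            raise ValidationError(f"rsid not in panel: {call.rsid}")
        rsid = self.panel.locus(call.rsid).rsid
        if rsid != call.rsid:
            call = replace(call, rsid=rsid)
        key = (call.sample_id, rsid, call.platform)
        if key in self.calls:
            raise ValidationError(f"duplicate call for {key}")
        self.calls[key] = call
        if call.sample_id not in self.samples:
            self.samples.append(call.sample_id)

    def get(self, sample: str, rsid: str, platform: str) -> GenotypeCall | None:
        rsid = self.panel.locus(rsid).rsid
        return self.calls.get((sample, rsid, platform))

    def platforms(self) -> list[str]:
        seen: dict[str, None] = {}
        for (_, _, p) in self.calls:
            seen.setdefault(p, None)
        return list(seen)

    def gene_calls(self, sample: str, gene: str, platform: str) -> dict[str, GenotypeCall]:
        """Calls at every panel locus of ``gene`` (missing cells filled in)."""
        out = {}
        for loc in self.panel.loci_for_gene(gene):
            call = self.calls.get((sample, loc.rsid, platform))
            if call is None:
                call = GenotypeCall(sample, loc.rsid, platform, None, MISSING)
            out[loc.rsid] = call
        return out

    def restricted(self, genes: Iterable[str]) -> "GenotypeMatrix":
        genes = set(genes)
        out = GenotypeMatrix(self.panel, self.samples)
        for key, call in self.calls.items():
            if self.panel.locus(call.rsid).gene in genes:
                out.calls[key] = call
        return out

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.calls == other.calls
                and self.samples == other.samples)


def _complete(matrix: GenotypeMatrix, samples: list[str], platform: str,
              exclude_rsids: set[str] | None = None) -> None:
    """Fill absent (sample, locus) cells with explicit missing calls."""
    exclude = exclude_rsids or set()
    for sample in samples:
        for loc in matrix.panel:
            if loc.rsid in exclude:
                continue
            key = (sample, loc.rsid, platform)
            if key not in matrix.calls:
                matrix.calls[key] = GenotypeCall(sample, loc.rsid, platform,
                                                 None, MISSING)


def read_vcf_calls(path: str | Path, panel: PanelDefinition,
                   platform: str) -> GenotypeMatrix:
    """Read a (multi-sample) GRCh37 VCF into a genotype matrix.

    Records are matched to panel loci by normalized (chrom, pos, ref, alt) or,
    failing that, by the ID column rsid. FILTER other than PASS gives
    ``fail_quality`` (alleles retained but not used downstream); a fully
    missing genotype at a present record, or a record absent entirely, gives
    ``missing``; a half-missing genotype gives ``fail_quality``.
    """
    if platform not in PLATFORMS:
        raise ValidationError(f"unknown platform {platform!r}")
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot open VCF ({exc})") from exc
    samples = list(vcf.samples)
    matrix = GenotypeMatrix(panel, samples)
    for v in vcf:
        alt = v.ALT[0] if v.ALT else "."
        loc = panel.locus_at(v.CHROM, v.POS, v.REF, alt)
        if loc is None and v.ID and v.ID in panel:
            loc = panel.locus(v.ID)
        if loc is None:
            continue
        filt = v.FILTER  # None means PASS in cyvcf2
        alleles_by_index = {0: v.REF}
        for i, a in enumerate(v.ALT or [], start=1):
            alleles_by_index[i] = a
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        for si, sample in enumerate(samples):
            gt = v.genotypes[si][:-1]  # drop phasedness flag
            depth = int(dp[si][0]) if dp is not None and dp[si][0] >= 0 else None
            ref_reads = alt_reads = None
            if ad is not None and len(ad[si]) >= 2 and ad[si][0] >= 0:
                ref_reads, alt_reads = int(ad[si][0]), int(ad[si][1])
            n_missing = sum(1 for a in gt if a < 0)
            if n_missing == len(gt):
                status, alleles = MISSING, None
            elif n_missing > 0:
                # ambiguous calling: only one allele confidently called
                status, alleles = FAIL, None
            else:
                alleles = tuple(sorted(alleles_by_index[a] for a in gt))
                status = PASS if filt is None else FAIL
            key = (sample, loc.rsid, platform)
            if key in matrix.calls:
                raise FormatError(f"{path}: duplicate record for {loc.rsid}")
            matrix.calls[key] = GenotypeCall(
                sample, loc.rsid, platform, alleles, status,
                depth=depth, ref_reads=ref_reads, alt_reads=alt_reads)
    _complete(matrix, samples, platform)
    return matrix


def read_targeted_calls(path: str | Path, panel: PanelDefinition) -> GenotypeMatrix:
    """Read a wide targeted-genotyping TSV: one row per sample, one column per
    rsid, cells like ``A/G`` or ``.`` for a no-call."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse targeted TSV ({exc})") from exc
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be sample_id")
    unknown = [c for c in df.columns[1:] if c not in panel]
    if unknown:
        raise ValidationError(f"{path}: columns not in panel: {unknown}")
    samples = df["sample_id"].tolist()
    matrix = GenotypeMatrix(panel, samples)
    for row in df.itertuples(index=False):
        sample = row.sample_id
        for rsid, cell in zip(df.columns[1:], row[1:]):
            cell = "" if not isinstance(cell, str) else cell.strip()
            if cell in (".", ""):
                call = GenotypeCall(sample, rsid, "TARGETED", None, MISSING)
            else:
                parts = cell.split("/")
                if len(parts) != 2 or not all(parts):
                    raise FormatError(
                        f"{path}: malformed cell {cell!r} for sample {sample} "
                        f"at {rsid}")
                call = GenotypeCall(sample, rsid, "TARGETED",
                                    tuple(sorted(parts)), PASS)
            matrix.add(call)
    _complete(matrix, samples, "TARGETED")
    return matrix


def call_accounting(matrix: GenotypeMatrix, ndigits: int = 0) -> dict:
    """Per-platform counts of pass / fail_quality / missing cells.

    The three categories partition samples x loci exactly; ``pass_pct`` is
    half-up rounded to ``ndigits`` decimals.
    """
    out: dict[str, dict] = {}
    for platform in matrix.platforms():
        counts = {PASS: 0, FAIL: 0, MISSING: 0}
        for (_, _, p), call in matrix.calls.items():
            if p == platform:
                counts[call.status] += 1
        total = sum(counts.values())
        counts["total"] = total
        counts["pass_pct"] = pct(counts[PASS], total, ndigits)
        out[platform] = counts
    return out


_LONG_COLUMNS = ["sample_id", "rsid", "platform", "allele1", "allele2",
                 "status", "depth", "ref_reads", "alt_reads"]


def write_matrix_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Long-format export: one row per (sample, rsid, platform)."""
    def fmt(x):
        return "." if x is None else str(x)

    rows = sorted(matrix.calls.values(),
                  key=lambda c: (c.platform, c.sample_id,
                                 matrix.panel.locus(c.rsid).chrom,
                                 matrix.panel.locus(c.rsid).pos))
    with open(path, "w") as fh:
        fh.write("\t".join(_LONG_COLUMNS) + "\n")
        for c in rows:
            a1, a2 = c.alleles if c.alleles else (None, None)
            fh.write("\t".join([c.sample_id, c.rsid, c.platform, fmt(a1),
                                fmt(a2), c.status, fmt(c.depth),
                                fmt(c.ref_reads), fmt(c.alt_reads)]) + "\n")


def read_matrix_tsv(path: str | Path, panel: PanelDefinition) -> GenotypeMatrix:
    """Inverse of :func:`write_matrix_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    matrix = GenotypeMatrix(panel)
    for row in df.itertuples(index=False):
        alleles = None
        if row.allele1 != "." and row.allele2 != ".":
            alleles = tuple(sorted((row.allele1, row.allele2)))

        def num(x):
            return None if x == "." else int(x)

        matrix.add(GenotypeCall(row.sample_id, row.rsid, row.platform, alleles,
                                row.status, depth=num(row.depth),
                                ref_reads=num(row.ref_reads),
                                alt_reads=num(row.alt_reads)))
    return matrix
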