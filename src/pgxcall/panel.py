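"""Panel catalogue, star-allele definition tables and actionability rules.

The bundled panel covers 67 SNP/indel loci in 19 pharmacogenes on GRCh37
(1-based coordinates, as in VCF). Star-allele definitions are shipped as data
files transcribed from the public nomenclature resources (PharmVar / CPIC
allele tables), pre-collapsed to the resolution the panel's tag variants can
discriminate. HLA alleles are represented by tag-SNP proxies
(rs1061235 <-> HLA-A*31:01, rs2395029 <-> HLA-B*57:01); no HLA typing is done.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files as _pkg_files
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import FormatError, ValidationError

REGION_CLASSES = ("exonic", "intronic", "upstream")

#: Closed vocabulary of medical-specialty tags used by actionability rules.
SPECIALTIES = frozenset(
    {"cardiology", "psychiatry", "infectious_diseases", "neurology",
     "gastroenterology", "transplant", "pain", "oncology"}
)

PHENOTYPE_CLASSES = frozenset(
    {"poor", "intermediate", "extensive", "ultrarapid", "carrier",
     "non_carrier", "decreased_function", "normal_function", "indeterminate"}
)


def _data_path(name: str) -> Path:
    return Path(str(_pkg_files("pgxcall.data") / name))


@dataclass(frozen=True)
class VariantLocus:
    """One panel locus with its GRCh37 coordinate and ref/alt representation."""

    rsid: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    region_class: str
    aliases: tuple[str, ...] = ()
    label: str | None = None

    def __post_init__(self):
        if self.pos <= 0:
            raise ValidationError(f"{self.rsid}: pos must be positive")
        if self.ref == self.alt:
            raise ValidationError(f"{self.rsid}: ref and alt alleles are equal")
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(
                f"{self.rsid}: unknown region_class {self.region_class!r}")


class PanelDefinition:
    """Ordered catalogue of :class:`VariantLocus`, keyed by rsid (aliases resolve)."""

    def __init__(self, loci: Iterable[VariantLocus], name: str = "panel"):
        self.loci: list[VariantLocus] = list(loci)
        self.name = name
        self._by_rsid: dict[str, VariantLocus] = {}
        for loc in self.loci:
            for key in (loc.rsid, *loc.aliases):
                if key in self._by_rsid:
                    raise ValidationError(f"duplicate rsid in panel: {key}")
                self._by_rsid[key] = loc
        self._by_coord = {
            (_norm_chrom(l.chrom), l.pos, l.ref, l.alt): l for l in self.loci
        }

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def locus(self, rsid: str) -> VariantLocus:
        try:
            return self._by_rsid[rsid]
        except KeyError:
            raise KeyError(f"rsid not in panel: {rsid}") from None

    def locus_at(self, chrom: str, pos: int, ref: str, alt: str) -> VariantLocus | None:
        return self._by_coord.get((_norm_chrom(chrom), pos, ref, alt))

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for loc in self.loci:
            seen.setdefault(loc.gene, None)
        return list(seen)

    def loci_for_gene(self, gene: str) -> list[VariantLocus]:
        return [l for l in self.loci if l.gene == gene]


def _norm_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def load_panel(path: str | Path, name: str | None = None) -> PanelDefinition:
    """Load a panel TSV (columns rsid, aliases, gene, chrom, pos, ref, alt,
    region_class[, label]); '#' lines are comments."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # noqa: BLE001 - reported as a format error
        raise FormatError(f"{path}: cannot parse panel TSV ({exc})") from exc
    required = {"rsid", "gene", "chrom", "pos", "ref", "alt", "region_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    loci = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            aliases = ()
            raw_alias = getattr(row, "aliases", None)
            if isinstance(raw_alias, str) and raw_alias not in (".", ""):
                aliases = tuple(raw_alias.split(";"))
            label = getattr(row, "label", None)
            if not isinstance(label, str) or label == ".":
                label = None
            loci.append(VariantLocus(
                rsid=row.rsid, gene=row.gene, chrom=_norm_chrom(row.chrom),
                pos=int(row.pos), ref=row.ref, alt=row.alt,
                region_class=row.region_class, aliases=aliases, label=label))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return PanelDefinition(loci, name=name or path.stem)


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Inverse of :func:`load_panel` (1-based GRCh37 coordinates, stated in the header)."""
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based GRCh37 (hg19)\n")
        fh.write("rsid\taliases\tgene\tchrom\tpos\tref\talt\tregion_class\tlabel\n")
        for l in panel:
            fh.write("\t".join([
                l.rsid, ";".join(l.aliases) or ".", l.gene, l.chrom, str(l.pos),
                l.ref, l.alt, l.region_class, l.label or "."]) + "\n")


def count_panel(panel: PanelDefinition) -> dict:
    """Per-gene locus counts plus total; the counts always sum to the total."""
    per_gene: dict[str, int] = {}
    for loc in panel:
        per_gene[loc.gene] = per_gene.get(loc.gene, 0) + 1
    return {"total": len(panel), "n_genes": len(per_gene), "per_gene": per_gene}


def default_panel() -> PanelDefinition:
    return load_panel(_data_path("panel_grch37.tsv"), name="default-67")


# ---------------------------------------------------------------------------
# star-allele definitions


@dataclass(frozen=True)
class StarAllele:
    """A named haplotype: the alleles that define it plus its functional annotation.

    ``defining`` is empty for the reference star (*1) and for structural
    alleles such as the CYP2D6 deletion *5, which is never matched from SNP
    data (``enumerable`` False) and only attached by copy-number integration.
    """

    gene: str
    name: str
    defining: Mapping[str, str]
    activity: float | None  # None = unknown / not using the activity scale
    function: str
    enumerable: bool = True


class StarAlleleTable:
    """Definitions indexed by (gene, star_name)."""

    def __init__(self, stars: Iterable[StarAllele]):
        self._by_gene: dict[str, dict[str, StarAllele]] = {}
        for s in stars:
            self._by_gene.setdefault(s.gene, {})[s.name] = s
        for gene, defs in self._by_gene.items():
            if "*1" not in defs:
                raise ValidationError(f"{gene}: reference star *1 missing")

    @property
    def genes(self) -> list[str]:
        return list(self._by_gene)

    def stars_for(self, gene: str) -> dict[str, StarAllele]:
        return self._by_gene[gene]

    def get(self, gene: str, name: str) -> StarAllele:
        return self._by_gene[gene][name]

    def activity(self, gene: str, name: str) -> float | None:
        return self._by_gene[gene][name].activity

    def has_activity_scale(self, gene: str) -> bool:
        return any(s.activity is not None
                   for s in self._by_gene.get(gene, {}).values())

    def defining_rsids(self, gene: str) -> set[str]:
        out: set[str] = set()
        for s in self._by_gene[gene].values():
            out.update(s.defining)
        return out


def load_star_definitions(path: str | Path, panel: PanelDefinition) -> StarAlleleTable:
    """Load star definitions TSV and validate every defining rsid against the panel."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse star-definition TSV ({exc})") from exc
    required = {"gene", "star_name", "rsid", "required_allele", "activity_value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")

    unknown: list[str] = []
    grouped: dict[tuple[str, str], dict] = {}
    for row in df.itertuples(index=False):
        key = (row.gene, row.star_name)
        entry = grouped.setdefault(
            key, {"defining": {}, "activity": row.activity_value,
                  "function": getattr(row, "function", "normal")})
        if row.rsid != ".":
            if row.rsid not in panel:
                unknown.append(f"{row.gene} {row.star_name}: {row.rsid}")
                continue
            canonical = panel.locus(row.rsid).rsid
            entry["defining"][canonical] = row.required_allele
    if unknown:
        raise ValidationError(
            "star definitions reference rsids absent from panel: "
            + "; ".join(unknown))

    stars = []
    for (gene, name), entry in grouped.items():
        raw = entry["activity"]
        activity = None if raw in (None, "NA", ".", "") else float(raw)
        for rsid, allele in entry["defining"].items():
            loc = panel.locus(rsid)
            if loc.gene != gene:
                raise ValidationError(
                    f"{gene} {name}: defining rsid {rsid} belongs to {loc.gene}")
            if allele not in (loc.ref, loc.alt):
                raise ValidationError(
                    f"{gene} {name}: required allele {allele!r} at {rsid} is "
                    f"neither ref nor alt")
        enumerable = bool(entry["defining"]) or name == "*1"
        stars.append(StarAllele(gene=gene, name=name, defining=entry["defining"],
                                activity=activity, function=entry["function"],
                                enumerable=enumerable))
    return StarAlleleTable(stars)


def default_star_table(panel: PanelDefinition | None = None) -> StarAlleleTable:
    return load_star_definitions(_data_path("star_alleles.tsv"),
                                 panel or default_panel())


# ---------------------------------------------------------------------------
# genotype-level phenotype tables and actionability rules


def load_genotype_phenotypes(path: str | Path | None = None) -> pd.DataFrame:
    """Single-locus genotype -> phenotype translation table (HLA tags, SLCO1B1,
    VKORC1, IFNL3)."""
    path = Path(path) if path else _data_path("genotype_phenotypes.tsv")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    bad = set(df["ref_hom"]) | set(df["het"]) | set(df["alt_hom"])
    bad -= PHENOTYPE_CLASSES
    if bad:
        raise ValidationError(f"{path}: unknown phenotype classes {sorted(bad)}")
    return df


@dataclass(frozen=True)
class ActionabilityRule:
    gene: str
    phenotypes: tuple[str, ...]
    category: int
    drugs: tuple[str, ...]
    specialties: tuple[str, ...]
    source: str

    def __post_init__(self):
        if self.category not in (1, 2, 3):
            raise ValidationError(f"{self.gene}: category must be 1, 2 or 3")
        if self.category == 3 and not self.drugs:
            raise ValidationError(f"{self.gene}: category-3 rule needs >= 1 drug")
        bad = set(self.specialties) - SPECIALTIES
        if bad:
            raise ValidationError(f"{self.gene}: unknown specialties {sorted(bad)}")
        bad = set(self.phenotypes) - PHENOTYPE_CLASSES
        if bad:
            raise ValidationError(f"{self.gene}: unknown phenotypes {sorted(bad)}")

    def triggers(self, phenotype_class: str) -> bool:
        return phenotype_class in self.phenotypes


def load_actionability_rules(path: str | Path | None = None) -> list[ActionabilityRule]:
    path = Path(path) if path else _data_path("actionability_rules.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for gene, entries in raw.items():
        for e in entries:
            rules.append(ActionabilityRule(
                gene=gene, phenotypes=tuple(e["phenotypes"]),
                category=int(e["category"]), drugs=tuple(e.get("drugs", ())),
                specialties=tuple(e.get("specialties", ())),
                source=e.get("source", "CPIC")))
    return rules
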