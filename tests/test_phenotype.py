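"""Activity scores, phenotype translation and actionability categories."""
import pytest

from pgxcall.diplotype import DiplotypeCall, NO_CALL, RESOLVED
from pgxcall.genotypes import PASS, GenotypeCall, GenotypeMatrix
from pgxcall.phenotype import (INDETERMINATE, PhenotypeRecord, activity_score,
                               categorize_sample, cohort_summary,
                               phenotype_activity_gene,
                               phenotype_metabolizer_gene,
                               phenotype_single_locus_genes,
                               score_to_phenotype)


def _dip(gene, h1, h2, cn=2, mult1=1, mult2=1, state=RESOLVED, **kw):
    return DiplotypeCall("s", gene, "WGS", h1, h2, state,
                         candidates=((h1, h2),) if h1 else (),
                         copy_number=cn, mult1=mult1, mult2=mult2, **kw)


@pytest.mark.parametrize("dip,expected", [
    (_dip("CYP2D6", "*1", "*1"), 2.0),
    (_dip("CYP2D6", "*4", "*5", cn=1), 0.0),
    (_dip("CYP2D6", "*1", "*4", cn=3, mult1=2), 2.0),   # *1x2/*4
    (_dip("CYP2D6", "*1", "*4", cn=3, mult2=2), 1.0),   # *1/*4x2
    (_dip("CYP2D6", "*1", "*2", cn=3, mult1=2), 3.0),   # *1x2/*2
    (_dip("CYP2D6", "*10", "*10"), 1.0),
])
def test_activity_score_multiplicity(stars, dip, expected):
    assert activity_score(dip, stars) == expected


def test_activity_score_additivity(stars):
    # score(a, b) == score(a, *5) + value(b) * multiplicity(b)
    full = activity_score(_dip("CYP2D6", "*2", "*10"), stars)
    hemi = activity_score(_dip("CYP2D6", "*2", "*5", cn=1), stars)
    assert full == hemi + stars.activity("CYP2D6", "*10") * 1


@pytest.mark.parametrize("score,cls", [
    (0.0, "poor"), (0.5, "intermediate"), (1.0, "extensive"),
    (2.0, "extensive"), (2.5, "ultrarapid"), (3.0, "ultrarapid"),
])
def test_score_to_phenotype_cutpoints(score, cls):
    assert score_to_phenotype(score) == cls


def test_duplication_phenotype_changes_with_assignment(stars):
    """A *1x2/*4 carrier scores 2 (extensive) while *1/*4 without the gain
    scores 1; an unassigned duplication whose two readings disagree is
    indeterminate, but one whose readings agree keeps its class."""
    assert phenotype_activity_gene(_dip("CYP2D6", "*1", "*4", cn=3, mult1=2),
                                   stars).phenotype_class == "extensive"
    disagree = phenotype_activity_gene(
        _dip("CYP2D6", "*1", "*2", cn=3, dup_unassigned=True), stars)
    assert disagree.phenotype_class == "ultrarapid"  # 3.0 either way
    agree = phenotype_activity_gene(
        _dip("CYP2D6", "*2", "*4", cn=3, dup_unassigned=True), stars)
    assert agree.phenotype_class == "extensive"  # 2.0 vs 1.0, same class
    differ = phenotype_activity_gene(
        _dip("CYP2D6", "*2", "*10", cn=3, dup_unassigned=True), stars)
    assert differ.phenotype_class == INDETERMINATE  # 2.5 vs 2.0 split classes


def test_no_call_and_inconclusive_are_indeterminate(stars):
    nc = DiplotypeCall("s", "CYP2D6", "WGS", None, None, NO_CALL)
    assert phenotype_activity_gene(nc, stars).phenotype_class == INDETERMINATE
    inc = _dip("CYP2D6", "*1", "*4", cn="inconclusive", reflex=True)
    assert phenotype_activity_gene(inc, stars).phenotype_class == INDETERMINATE


@pytest.mark.parametrize("gene,h1,h2,cls", [
    ("CYP2C19", "*1", "*1", "extensive"),
    ("CYP2C19", "*1", "*2", "intermediate"),
    ("CYP2C19", "*2", "*2", "poor"),
    ("CYP2C19", "*1", "*17", "ultrarapid"),
    ("CYP2C19", "*2", "*17", "intermediate"),
    ("TPMT", "*1", "*3A", "intermediate"),
    ("TPMT", "*3A", "*3C", "poor"),
    ("CYP2C9", "*1", "*2", "intermediate"),
    ("CYP3A5", "*1", "*3", "intermediate"),
    ("CYP3A5", "*3", "*3", "poor"),
])
def test_metabolizer_translation(stars, gene, h1, h2, cls):
    assert phenotype_metabolizer_gene(_dip(gene, h1, h2),
                                      stars).phenotype_class == cls


def test_single_locus_genes(panel, geno_table):
    m = GenotypeMatrix(panel)
    het = {"rs2395029", "rs4149056"}
    for row in geno_table.itertuples(index=False):
        loc = panel.locus(row.rsid)
        alleles = (tuple(sorted((loc.ref, loc.alt))) if row.rsid in het
                   else (loc.ref, loc.ref))
        m.add(GenotypeCall("s", row.rsid, "WGS", alleles, PASS))
    by_gene = {r.gene: r.phenotype_class
               for r in phenotype_single_locus_genes(m, "s", "WGS", geno_table)}
    assert by_gene["HLA-B"] == "carrier"       # rs2395029 het
    assert by_gene["HLA-A"] == "non_carrier"
    assert by_gene["SLCO1B1"] == "decreased_function"
    assert by_gene["VKORC1"] == "normal_function"


def _rec(gene, cls):
    return PhenotypeRecord("s", gene, cls)


def test_categorization(rules):
    benign = categorize_sample(
        [_rec("CYP2D6", "extensive"), _rec("HLA-B", "non_carrier"),
         _rec("CYP2C19", "extensive")], rules)
    assert benign.category == 1 and not benign.triggering_genes

    abacavir = categorize_sample([_rec("HLA-B", "carrier")], rules)
    assert abacavir.category == 3
    assert "HLA-B" in abacavir.triggering_genes
    assert "infectious_diseases" in abacavir.specialty_flags

    dosing = categorize_sample([_rec("CYP2C19", "intermediate")], rules)
    assert dosing.category == 2

    # adding a triggered rule never lowers the category
    both = categorize_sample(
        [_rec("CYP2C19", "intermediate"), _rec("HLA-B", "carrier")], rules)
    assert both.category == 3

    # indeterminate phenotypes never trigger, they route to reflex testing
    reflex = categorize_sample([_rec("CYP2D6", INDETERMINATE)], rules)
    assert reflex.category == 1 and reflex.reflex_genes == ("CYP2D6",)


def test_cohort_summary_tallies(rules):
    acts = [categorize_sample([_rec("CYP2D6", "extensive")], rules),
            categorize_sample([_rec("CYP2C19", "intermediate")], rules),
            categorize_sample([_rec("CYP2C9", "poor")], rules),
            categorize_sample([_rec("HLA-B", "carrier")], rules)]
    summary = cohort_summary(acts)
    assert summary["categories"] == {1: 1, 2: 2, 3: 1}
    assert summary["n_actionable"] == 3
    assert summary["actionable_pct"] == 75
    assert summary["specialty_pct"]["infectious_diseases"] == 25

    empty = cohort_summary([])
    assert empty["categories"] == {1: 0, 2: 0, 3: 0}
    assert empty["actionable_pct"] is None
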