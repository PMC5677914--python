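"""Diplotype enumeration and resolution, checked against a brute-force oracle."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgxcall.diplotype import (AMBIGUOUS, NO_CALL, RESOLVED,
                               diplotype_cohort, diplotype_sample,
                               enumerate_candidates, resolve_diplotype)
from pgxcall.genotypes import (FAIL, MISSING, PASS, GenotypeCall,
                               GenotypeMatrix)
from pgxcall.util import star_sort_key


def _calls(panel, gene, genotypes, missing=(), failed=()):
    """Build gene_calls: alt-carrying loci from `genotypes` (rsid -> n_alt),
    everything else ref/ref; loci in `missing`/`failed` are dropped out."""
    out = {}
    for loc in panel.loci_for_gene(gene):
        if loc.rsid in missing:
            out[loc.rsid] = GenotypeCall("s", loc.rsid, "WGS", None, MISSING)
        elif loc.rsid in failed:
            out[loc.rsid] = GenotypeCall("s", loc.rsid, "WGS", None, FAIL)
        else:
            n_alt = genotypes.get(loc.rsid, 0)
            alleles = tuple(sorted([loc.alt] * n_alt + [loc.ref] * (2 - n_alt)))
            out[loc.rsid] = GenotypeCall("s", loc.rsid, "WGS", alleles, PASS)
    return out


def oracle_pairs(gene_calls, stars, gene, panel):
    """Independent all-pairs check: iterate the full cartesian product and
    compare sorted allele lists locus by locus."""
    defs = stars.stars_for(gene)
    names = [n for n, s in defs.items() if s.enumerable]
    found = set()
    for a, b in itertools.product(names, names):
        consistent = True
        for rsid, call in gene_calls.items():
            if call.status != "pass":
                continue
            ref = panel.locus(rsid).ref
            expect = sorted([defs[a].defining.get(rsid, ref),
                             defs[b].defining.get(rsid, ref)])
            if expect != sorted(call.alleles):
                consistent = False
                break
        if consistent:
            found.add(tuple(sorted((a, b), key=star_sort_key)))
    return sorted(found, key=lambda p: (star_sort_key(p[0]), star_sort_key(p[1])))


def test_all_reference_gives_star1_homozygote(panel, stars):
    calls = _calls(panel, "CYP2D6", {})
    assert enumerate_candidates(calls, stars, "CYP2D6", panel) == [("*1", "*1")]


def test_star4_het_detected(panel, stars):
    calls = _calls(panel, "CYP2D6", {"rs3892097": 1})
    cands = enumerate_candidates(calls, stars, "CYP2D6", panel)
    assert cands == [("*1", "*4")]


def test_missing_locus_is_wildcard(panel, stars):
    calls = _calls(panel, "CYP2D6", {}, missing={"rs16947"})
    cands = enumerate_candidates(calls, stars, "CYP2D6", panel)
    # *2 is defined only by the missing rs16947, so it re-enters the candidate set
    assert ("*1", "*1") in cands
    assert ("*1", "*2") in cands
    assert ("*2", "*2") in cands
    assert cands == oracle_pairs(calls, stars, "CYP2D6", panel)


@pytest.mark.parametrize("gene", ["CYP2D6", "CYP2C19", "CYP2C9", "TPMT",
                                  "DPYD", "CYP3A5"])
def test_enumeration_matches_oracle_on_random_genotypes(panel, stars, gene):
    """Draw genotypes from random true star pairs, with random dropout, and
    compare against the independent all-pairs oracle."""
    rng = np.random.default_rng(20260925)
    defs = stars.stars_for(gene)
    names = [n for n, s in defs.items() if s.enumerable]
    loci = [l.rsid for l in panel.loci_for_gene(gene)]
    for _ in range(40):
        a, b = rng.choice(names, 2)
        genotypes = {}
        for rsid in set(defs[a].defining) | set(defs[b].defining):
            alt = panel.locus(rsid).alt
            genotypes[rsid] = ((defs[a].defining.get(rsid) == alt)
                               + (defs[b].defining.get(rsid) == alt))
        missing = {r for r in loci if rng.random() < 0.15}
        calls = _calls(panel, gene, genotypes, missing=missing)
        got = enumerate_candidates(calls, stars, gene, panel)
        assert got == oracle_pairs(calls, stars, gene, panel)
        if not (set(defs[a].defining) | set(defs[b].defining)) & missing:
            assert tuple(sorted((a, b), key=star_sort_key)) in got


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_enumeration_invariant_under_locus_order_and_allele_swap(panel, stars, seed):
    rng = np.random.default_rng(seed)
    loci = panel.loci_for_gene("CYP2D6")
    calls = {}
    for loc in loci:
        n_alt = int(rng.integers(0, 3))
        pair = [loc.alt] * n_alt + [loc.ref] * (2 - n_alt)
        calls[loc.rsid] = GenotypeCall("s", loc.rsid, "WGS",
                                       tuple(sorted(pair)), PASS)
    base = enumerate_candidates(calls, stars, "CYP2D6", panel)
    # permute locus order
    order = list(calls)
    rng.shuffle(order)
    shuffled = {r: calls[r] for r in order}
    assert enumerate_candidates(shuffled, stars, "CYP2D6", panel) == base


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_extra_missing_locus_never_removes_candidates(panel, stars, seed):
    rng = np.random.default_rng(seed)
    defs = stars.stars_for("CYP2D6")
    names = [n for n, s in defs.items() if s.enumerable]
    a, b = rng.choice(names, 2)
    genotypes = {}
    for rsid in set(defs[a].defining) | set(defs[b].defining):
        alt = panel.locus(rsid).alt
        genotypes[rsid] = ((defs[a].defining.get(rsid) == alt)
                           + (defs[b].defining.get(rsid) == alt))
    calls = _calls(panel, "CYP2D6", genotypes)
    before = set(enumerate_candidates(calls, stars, "CYP2D6", panel))
    drop = str(rng.choice([l.rsid for l in panel.loci_for_gene("CYP2D6")]))
    masked = dict(calls)
    masked[drop] = GenotypeCall("s", drop, "WGS", None, MISSING)
    after = set(enumerate_candidates(masked, stars, "CYP2D6", panel))
    assert before <= after


def test_resolution_rules(stars):
    one = resolve_diplotype([("*1", "*4")], sample_id="s", gene="CYP2D6",
                            platform="WGS")
    assert one.state == RESOLVED and (one.hap1, one.hap2) == ("*1", "*4")

    none = resolve_diplotype([], sample_id="s", gene="CYP2D6", platform="WGS")
    assert none.state == NO_CALL

    # parsimony tie-break without frequencies
    amb = resolve_diplotype([("*1", "*1"), ("*1", "*2")], sample_id="s",
                            gene="CYP2D6", platform="WGS")
    assert amb.state == AMBIGUOUS
    assert (amb.hap1, amb.hap2) == ("*1", "*1")
    assert set(amb.candidates) == {("*1", "*1"), ("*1", "*2")}

    # frequency product overrides parsimony
    freq = resolve_diplotype([("*1", "*1"), ("*1", "*2")], sample_id="s",
                             gene="CYP2D6", platform="WGS",
                             freqs={"*1": 0.2, "*2": 0.8})
    assert (freq.hap1, freq.hap2) == ("*1", "*2")


def test_missing_key_position_forces_no_call(panel, stars):
    """Losing the *4-discriminating site plus enough other sites spreads the
    candidate activity scores too widely for a responsible assignment."""
    missing = {"rs3892097", "rs16947", "rs1065852", "rs35742686", "rs5030655"}
    calls = _calls(panel, "CYP2D6", {}, missing=missing)
    cands = enumerate_candidates(calls, stars, "CYP2D6", panel)
    dip = resolve_diplotype(cands, sample_id="s", gene="CYP2D6", platform="WGS",
                            missing_loci=missing, stars=stars)
    assert dip.state == NO_CALL
    assert dip.missing_loci == tuple(sorted(missing))


def test_contradictory_genotype_is_no_call(panel, stars):
    # an alt allele belonging to no star definition (intronic tag locus)
    calls = _calls(panel, "CYP2D6", {"rs2837172": 1})
    assert enumerate_candidates(calls, stars, "CYP2D6", panel) == []


def test_cohort_cardinality_and_recovery(panel, stars):
    m = GenotypeMatrix(panel)
    for loc in panel.loci_for_gene("CYP2C19"):
        n_alt = 1 if loc.rsid == "rs4244285" else 0
        alleles = tuple(sorted([loc.alt] * n_alt + [loc.ref] * (2 - n_alt)))
        m.add(GenotypeCall("only", loc.rsid, "WGS", alleles, PASS))
    calls = diplotype_cohort(m, stars, genes=["CYP2C19"], platforms=["WGS"])
    assert len(calls) == 1
    assert calls[0].state == RESOLVED
    assert (calls[0].hap1, calls[0].hap2) == ("*1", "*2")
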