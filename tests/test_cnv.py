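"""Copy-number classification bands, duplication phasing, CN integration."""
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binomtest

from pgxcall.cnv import (DEFAULT_BANDS, INCONCLUSIVE, CopyNumberCall,
                         CoverageProfile, call_cohort_cnv,
                         classify_copy_number, integrate_cn_into_diplotype,
                         phase_duplication, validate_bands)
from pgxcall.diplotype import DiplotypeCall, RESOLVED
from pgxcall.errors import PgxError, ValidationError
from pgxcall.genotypes import PASS, GenotypeCall


@pytest.mark.parametrize("cov,expected", [
    (1.96, 4),   # high-gain sample
    (1.5, 3),    # duplication
    (1.0, 2),    # diploid reference point
    (0.5, 1),    # heterozygous deletion
    (0.75, INCONCLUSIVE),  # between deletion and diploid bands
    (1.3, INCONCLUSIVE),   # between diploid and duplication bands
    (0.05, 0),   # homozygous deletion
])
def test_classification_worked_examples(cov, expected):
    assert classify_copy_number(cov).copy_number == expected


def test_negative_coverage_rejected():
    with pytest.raises(ValidationError):
        classify_copy_number(-0.1)
    with pytest.raises(ValidationError):
        CoverageProfile("s", (-0.2, 0.5, 0.5))


def test_default_bands_disjoint_and_monotone():
    validate_bands(DEFAULT_BANDS)


@given(st.floats(min_value=0.0, max_value=5.0, allow_nan=False))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_every_coverage_maps_to_exactly_one_outcome(cov):
    hits = [cn for cn, lo, hi in DEFAULT_BANDS if lo <= cov <= hi]
    call = classify_copy_number(cov)
    if hits:
        assert call.copy_number == hits[0] and len(hits) == 1
    else:
        assert call.copy_number == INCONCLUSIVE


@given(st.floats(min_value=0.0, max_value=5.0), st.floats(min_value=0.0, max_value=5.0))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_integer_cn_monotone_in_coverage(a, b):
    ca, cb = classify_copy_number(min(a, b)), classify_copy_number(max(a, b))
    if isinstance(ca.copy_number, int) and isinstance(cb.copy_number, int):
        assert ca.copy_number <= cb.copy_number


def test_cohort_histogram_counts():
    profiles = [CoverageProfile("a", (0.5, 0.5, 0.5)),
                CoverageProfile("b", (1.0, 1.0, 1.0)),
                CoverageProfile("c", (0.75, 0.75, 0.75))]
    calls, hist = call_cohort_cnv(profiles)
    assert len(calls) == 3
    assert hist == {1: 1, 2: 1, INCONCLUSIVE: 1}
    assert calls[0].copy_number == 1  # mean 0.5 -> heterozygous deletion


def _dip(h1, h2, state=RESOLVED, **kw):
    return DiplotypeCall("s", "CYP2D6", "WGS", h1, h2, state,
                         candidates=((h1, h2),), **kw)


def _het_call(rsid, ref_reads, alt_reads, panel):
    loc = panel.locus(rsid)
    return GenotypeCall("s", rsid, "WGS", tuple(sorted((loc.ref, loc.alt))),
                        PASS, depth=ref_reads + alt_reads,
                        ref_reads=ref_reads, alt_reads=alt_reads)


def test_phasing_skewed_reads_pick_ref_haplotype(panel, stars):
    # *1/*4 het at rs3892097; 60 ref vs 30 alt reads favors the *1 copy,
    # and a binomial test agrees the skew is real
    calls = {"rs3892097": _het_call("rs3892097", 60, 30, panel)}
    ph = phase_duplication(_dip("*1", "*4"), calls, stars, panel)
    assert ph.duplicated_star == "*1"
    assert binomtest(60, 90, 0.5, alternative="greater").pvalue < 0.05


def test_phasing_balanced_or_shallow_reads_indeterminate(panel, stars):
    balanced = {"rs3892097": _het_call("rs3892097", 45, 45, panel)}
    assert phase_duplication(_dip("*1", "*4"), balanced, stars,
                             panel).duplicated_star == "indeterminate"
    shallow = {"rs3892097": _het_call("rs3892097", 26, 14, panel)}
    assert phase_duplication(_dip("*1", "*4"), shallow, stars,
                             panel).duplicated_star == "indeterminate"


def test_phasing_conflicting_positions_indeterminate(panel, stars):
    # *2/*4 het at both tag sites with skews pointing at different haplotypes
    calls = {"rs3892097": _het_call("rs3892097", 60, 30, panel),   # favors *2
             "rs16947": _het_call("rs16947", 60, 30, panel)}       # favors *4
    ph = phase_duplication(_dip("*2", "*4"), calls, stars, panel)
    assert ph.duplicated_star == "indeterminate"


def test_phasing_preconditions(panel, stars):
    with pytest.raises(PgxError):
        phase_duplication(_dip("*1", "*4"), {}, stars, panel, copy_number=2)
    with pytest.raises(PgxError):
        phase_duplication(_dip("*1", "*1"), {}, stars, panel)


def test_integration_rules():
    unchanged = integrate_cn_into_diplotype(_dip("*1", "*4"),
                                            CopyNumberCall("s", 2, 1.0))
    assert (unchanged.hap1, unchanged.hap2) == ("*1", "*4")
    assert unchanged.copy_number == 2

    hemi = integrate_cn_into_diplotype(_dip("*1", "*1"),
                                       CopyNumberCall("s", 1, 0.5))
    assert (hemi.hap1, hemi.hap2) == ("*1", "*5")
    assert hemi.notation == "*1/*5"

    from pgxcall.cnv import DuplicationPhase
    phased = integrate_cn_into_diplotype(
        _dip("*1", "*4"), CopyNumberCall("s", 3, 1.5),
        DuplicationPhase("s", "*1", (("rs3892097", 60, 30),), 75))
    assert phased.notation == "*1x2/*4"

    unphased = integrate_cn_into_diplotype(_dip("*1", "*4"),
                                           CopyNumberCall("s", 3, 1.5))
    assert unphased.dup_unassigned

    inconclusive = integrate_cn_into_diplotype(
        _dip("*1", "*4"), CopyNumberCall("s", INCONCLUSIVE, 0.75))
    assert inconclusive.reflex and inconclusive.copy_number == INCONCLUSIVE

    conflict = integrate_cn_into_diplotype(_dip("*1", "*4"),
                                           CopyNumberCall("s", 1, 0.5))
    assert conflict.reflex  # het genotypes cannot come from one copy
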