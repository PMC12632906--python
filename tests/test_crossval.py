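"""Candidate merging and long-read validation rules."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicbench.core import CallRecord, CallSet, VariantKey
from mosaicbench.crossval import (
    ValidationStatus,
    binomial_het_pvalue,
    classify_indel_reads,
    merge_candidates,
    resolve_multiallelic,
    validate_indel,
    validate_snv,
)
from tests.conftest import make_pileup


def _key(pos, ref="A", alt="G"):
    return VariantKey("chr1", pos, ref, alt)


def _callset(caller, positions):
    return CallSet(
        caller=caller,
        dataset="d",
        records=[CallRecord(_key(p)) for p in positions],
    )


# ---------------------------------------------------------------------------
# merging


def test_merge_disjoint_and_shared():
    merged = merge_candidates([_callset("a", [1, 2, 3]), _callset("b", [4, 5, 6])])
    assert len(merged) == 6
    assert (merged["caller_count"] == 1).all()

    four = [_callset(c, [10]) for c in "abcd"]
    merged = merge_candidates(four)
    assert len(merged) == 1
    assert merged["caller_count"].item() == 4


def test_merge_matches_set_union_oracle():
    rng = np.random.default_rng(11)
    callsets = [
        _callset(f"c{i}", sorted(rng.choice(500, size=80, replace=False) + 1))
        for i in range(4)
    ]
    merged = merge_candidates(callsets)
    union = set().union(*(cs.keys() for cs in callsets))
    assert set(merged.index) == union
    for cs in callsets:
        for key in cs.keys():
            assert merged.loc[key, cs.caller]


def test_merge_filters_nonpass_and_long_indels():
    records = [
        CallRecord(_key(1)),
        CallRecord(_key(2), filters=frozenset({"LowQual"})),
        CallRecord(VariantKey("chr1", 3, "A", "A" + "G" * 60)),  # 60 bp insertion
    ]
    merged = merge_candidates([CallSet("a", "d", records)])
    assert list(merged.index) == [_key(1)]


def test_duplicate_keys_rejected_at_construction():
    with pytest.raises(ValueError, match="duplicate"):
        CallSet("a", "d", [CallRecord(_key(1)), CallRecord(_key(1))])


# ---------------------------------------------------------------------------
# multi-allelic resolution


def test_resolve_multiallelic_examples():
    assert resolve_multiallelic(make_pileup(ref="C", A=5, T=2)) == "A"
    assert resolve_multiallelic(make_pileup(ref="C", A=3, T=3)) == "A"  # tie: lexicographic
    assert resolve_multiallelic(make_pileup(ref="C", C=10)) is None


@given(counts=st.dictionaries(st.sampled_from("AGT"), st.integers(1, 50), min_size=1))
@settings(max_examples=200, deadline=None)
def test_resolve_multiallelic_argmax_oracle(counts):
    got = resolve_multiallelic(make_pileup(ref="C", **counts))
    best = max(counts.values())
    assert got == min(a for a, c in counts.items() if c == best)


# ---------------------------------------------------------------------------
# SNV validation


def test_validate_snv_rules():
    key = _key(100)
    ok = validate_snv(key, make_pileup(G=2, depth=300), make_pileup(depth=300))
    assert ok.status is ValidationStatus.VALIDATED

    weak = validate_snv(key, make_pileup(G=1, depth=300), make_pileup(depth=300))
    assert weak.status is ValidationStatus.NO_TUMOR_SUPPORT

    leaky = validate_snv(key, make_pileup(G=10, depth=300), make_pileup(G=1, depth=300))
    assert leaky.status is ValidationStatus.NORMAL_SUPPORT

    competing = validate_snv(
        key, make_pileup(G=3, T=9, depth=300), make_pileup(depth=300)
    )
    assert competing.status is ValidationStatus.SUPERSEDED_MULTIALLELIC

    missing = validate_snv(key, None, make_pileup(depth=300))
    assert missing.status is ValidationStatus.EVIDENCE_MISSING


@given(
    tumor_alt=st.integers(0, 20),
    normal_alt=st.integers(0, 5),
    extra_tumor=st.integers(1, 10),
    extra_normal=st.integers(1, 5),
)
@settings(max_examples=200, deadline=None)
def test_validate_snv_monotonicity(tumor_alt, normal_alt, extra_tumor, extra_normal):
    """More tumor support never revokes validation; more normal support
    never creates it."""
    key = _key(100)

    def verdict(t_alt, n_alt):
        return validate_snv(
            key,
            make_pileup(G=t_alt, depth=500) if t_alt else make_pileup(depth=500),
            make_pileup(G=n_alt, depth=500) if n_alt else make_pileup(depth=500),
        ).validated

    base = verdict(tumor_alt, normal_alt)
    if base:
        assert verdict(tumor_alt + extra_tumor, normal_alt)
    else:
        assert not verdict(tumor_alt, normal_alt + extra_normal)


def test_validation_sensitivity_matches_binomial_closed_form():
    """Planted tumor-only variants with Binomial(D, f) support validate at
    the closed-form rate P(X >= 2), within Monte-Carlo error."""
    from scipy import stats

    rng = np.random.default_rng(5)
    depth, f, n = 300, 0.01, 4000
    validated = 0
    for _ in range(n):
        alt = int(rng.binomial(depth, f))
        v = validate_snv(
            _key(100),
            make_pileup(G=alt, depth=depth) if alt else make_pileup(depth=depth),
            make_pileup(depth=depth),
        )
        validated += v.validated
    expected = stats.binom.sf(1, depth, f)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(validated / n - expected) < 4 * se


# ---------------------------------------------------------------------------
# binomial heterozygous test


def test_binomial_het_pvalue_examples():
    assert binomial_het_pvalue(1, 0) == pytest.approx(1.0)
    assert binomial_het_pvalue(10, 5) == pytest.approx(1.0)
    assert binomial_het_pvalue(100, 10) < 0.05
    with pytest.raises(ValueError):
        binomial_het_pvalue(0, 0)


def exact_two_sided_pvalue(n, k):
    """Exact-rational enumeration oracle: sum of C(n,i)/2^n over outcomes no
    more likely than the observed one."""
    coeffs = [comb(n, i) for i in range(n + 1)]
    return float(Fraction(sum(c for c in coeffs if c <= coeffs[k]), 2**n))


@pytest.mark.parametrize("n", [1, 2, 5, 17, 40, 60])
def test_binomial_pvalue_against_enumeration(n):
    for k in range(n + 1):
        assert binomial_het_pvalue(n, k) == pytest.approx(
            exact_two_sided_pvalue(n, k), abs=1e-12
        )


# ---------------------------------------------------------------------------
# indel read classification


def test_classify_indel_reads_examples():
    key = VariantKey("chr1", 100, "CA", "C")
    reads = [(60, "CA")] * 8 + [(60, "C")] * 2
    cls = classify_indel_reads(reads, key)
    assert (cls.ref_support, cls.target_alt_support, cls.af) == (8, 2, 0.2)

    other = classify_indel_reads([(60, "CTT")], key)
    assert other.target_alt_support == 0
    assert other.other_alt == {"CTT": 1}

    empty = classify_indel_reads([], key)
    assert empty.depth == 0 and empty.af is None


def test_classify_indel_reads_mapq_filter():
    key = VariantKey("chr1", 100, "CA", "C")
    cls = classify_indel_reads([(0, "C"), (1, "C")], key, min_mapq=1)
    assert cls.depth == 1 and cls.target_alt_support == 1


@given(
    seqs=st.lists(
        st.tuples(st.integers(0, 60), st.sampled_from(["CA", "C", "CTT", "CAG"])),
        max_size=40,
    )
)
@settings(max_examples=100, deadline=None)
def test_classify_indel_reads_string_oracle(seqs):
    key = VariantKey("chr1", 100, "CA", "C")
    cls = classify_indel_reads(seqs, key, min_mapq=20)
    kept = [s for q, s in seqs if q >= 20]
    assert cls.depth == len(kept)
    assert cls.ref_support == kept.count("CA")
    assert cls.target_alt_support == kept.count("C")
    assert sum(cls.other_alt.values()) == len(kept) - kept.count("CA") - kept.count("C")


# ---------------------------------------------------------------------------
# indel validation


def _cls(depth, dtv):
    from mosaicbench.core import IndelReadClassification

    return IndelReadClassification(
        depth=depth, ref_support=depth - dtv, target_alt_support=dtv
    )


def test_validate_indel_rules():
    key = VariantKey("chr1", 100, "CA", "C")
    ok = validate_indel(key, _cls(100, 45), _cls(100, 40), _cls(100, 0))
    assert ok.status is ValidationStatus.VALIDATED

    long_key = VariantKey("chr1", 100, "C" + "A" * 60, "C")
    assert (
        validate_indel(long_key, _cls(100, 45), _cls(100, 40), _cls(100, 0)).status
        is ValidationStatus.LENGTH_FAIL
    )

    assert (
        validate_indel(key, _cls(100, 45), _cls(100, 40), _cls(100, 10)).status
        is ValidationStatus.NORMAL_VAF_FAIL
    )

    # 80/100 alt reads: rejects the heterozygous hypothesis
    assert (
        validate_indel(key, _cls(100, 80), _cls(100, 40), _cls(100, 0)).status
        is ValidationStatus.ALLELIC_IMBALANCE_FAIL
    )

    # long-read AF at the 0.2 boundary fails (strict inequality)
    assert (
        validate_indel(key, _cls(100, 45), _cls(100, 20), _cls(100, 0)).status
        is ValidationStatus.TUMOR_VAF_FAIL
    )

    assert (
        validate_indel(key, _cls(100, 1), _cls(100, 40), _cls(100, 0)).status
        is ValidationStatus.NO_TUMOR_SUPPORT
    )

    missing = validate_indel(key, _cls(0, 0), _cls(100, 40), _cls(100, 0))
    assert missing.status is ValidationStatus.EVIDENCE_MISSING
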