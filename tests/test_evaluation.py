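"""Call classification, stratified metrics, and VAF concordance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicbench.core import CallRecord, CallSet, VafBinning, VariantKey
from mosaicbench.evaluation import (
    assemble_truth,
    classify_call,
    compute_metrics,
    eval_vaf,
    stratify_position,
    vaf_concordance,
)
from mosaicbench.mixture import colo829blt50_design
from mosaicbench.regions import GenomeRegions
from mosaicbench.simulate import gen_genotypes, gen_masks, simulate_callset, simulate_pileup
from tests.conftest import make_pileup


def _key(pos, alt="G"):
    return VariantKey("chr1", pos, "A", alt)


def _truth(positive_positions, negative_intervals):
    return assemble_truth(
        [_key(p) for p in positive_positions],
        negative_regions=GenomeRegions.from_intervals(negative_intervals),
    )


def test_assemble_counts_and_conflicts():
    truth = assemble_truth(
        [_key(p) for p in range(1, 11)],
        culture_set=[_key(20), _key(21)],
        negative_regions=GenomeRegions.from_intervals([("chr1", 100, 200)]),
    )
    assert len(truth.positives) == 12
    assert truth.positives[_key(20)] == "culture"

    with pytest.raises(ValueError, match="overlap the negative set"):
        assemble_truth(
            [_key(150)],
            negative_regions=GenomeRegions.from_intervals([("chr1", 100, 200)]),
        )


def test_classify_call_three_way():
    truth = _truth([5], [("chr1", 100, 200)])
    assert classify_call(CallRecord(_key(5)), truth) == "TP"
    assert classify_call(CallRecord(_key(150)), truth) == "FP"
    assert classify_call(CallRecord(_key(5000)), truth) == "masked"
    # negatives match by position, any allele
    assert classify_call(CallRecord(_key(150, alt="T")), truth) == "FP"


def test_eval_vaf_conventions():
    pileups = {("chr1", 5): make_pileup(pos=5, G=3, depth=300)}
    assert eval_vaf(_key(5), True, pileups, caller_vaf=0.5) == pytest.approx(0.01)
    # truth variant without pileup row: unsampled -> 0 (first bin)
    assert eval_vaf(_key(6), True, pileups, caller_vaf=0.5) == 0.0
    # non-truth call: caller VAF
    assert eval_vaf(_key(7), False, pileups, caller_vaf=0.004) == 0.004
    assert eval_vaf(_key(7), False, pileups, caller_vaf=None) is None


@given(
    positives=st.sets(st.integers(1, 80), min_size=1, max_size=30),
    negatives=st.sets(st.integers(101, 180), max_size=30),
    called=st.sets(st.integers(1, 260), max_size=60),
)
@settings(max_examples=100, deadline=None)
def test_classification_conservation(positives, negatives, called):
    """TP + FP + masked = total calls, for any call set."""
    truth = _truth(positives, [("chr1", p - 1, p) for p in negatives])
    calls = [CallRecord(_key(p), caller_vaf=0.01) for p in called]
    counts = {"TP": 0, "FP": 0, "masked": 0}
    for c in calls:
        counts[classify_call(c, truth)] += 1
    assert sum(counts.values()) == len(calls)

    metrics = compute_metrics(calls, truth)
    assert (
        metrics["TP"].sum() + metrics["FP"].sum() + metrics.attrs["unbinned_masked"]
        == len(calls)
    )


def test_metrics_against_confusion_matrix_oracle():
    """With negatives covering the whole non-positive contig and no masking,
    the per-bin tallies reduce to a textbook confusion matrix."""
    positives = [1, 2, 3, 4, 5]
    truth = _truth(positives, [("chr1", 5, 1000)])
    pileups = {
        ("chr1", p): make_pileup(pos=p, G=2, depth=100) for p in positives  # VAF 2%
    }
    calls = [CallRecord(_key(p), caller_vaf=0.02) for p in [1, 2, 3]] + [
        CallRecord(_key(500), caller_vaf=0.025),
        CallRecord(_key(600), caller_vaf=0.025),
    ]
    metrics = compute_metrics(calls, truth, mixture_pileups=pileups)
    row = metrics.loc[("2-3%", "all")]
    assert (row.TP, row.FP, row.FN) == (3, 2, 2)
    assert row.sensitivity == pytest.approx(3 / 5)
    assert row.precision == pytest.approx(3 / 5)
    assert row.f1 == pytest.approx(0.6)


def test_perfect_and_degenerate_callers():
    design = colo829blt50_design()
    _, truth_table = gen_genotypes(300, design, {(0.5,): 0.5, (1.0,): 0.5}, seed=1)
    truth = assemble_truth(
        [VariantKey(r.chrom, r.pos, r.ref, r.alt) for r in truth_table.itertuples(index=False)],
        negative_regions=GenomeRegions(),
    )
    pileups = simulate_pileup(truth_table, depth=400, seed=2)

    perfect = simulate_callset(truth_table, sens_curve=lambda f: 1.0, seed=3)
    m = compute_metrics(perfect, truth, mixture_pileups=pileups)
    populated = m[m.TP + m.FN > 0]
    assert (populated.sensitivity == 1.0).all()
    assert (populated.precision == 1.0).all()

    silent = simulate_callset(truth_table, sens_curve=lambda f: 0.0, seed=3)
    assert len(silent) == 0


def test_fp_only_caller_has_zero_precision_and_f1():
    truth = _truth([1], [("chr1", 99, 300)])
    calls = [CallRecord(_key(p), caller_vaf=0.01) for p in (150, 200, 250)]
    m = compute_metrics(calls, truth)
    row = m.loc[("1-1.5%", "all")]
    assert row.FP == 3 and row.precision == 0.0 and row.f1 == 0.0


def test_planted_sensitivity_recovered_within_binomial_ci():
    """Evaluating a synthetic caller with planted per-bin sensitivity
    recovers the sensitivity curve within 95% binomial CIs."""
    design = colo829blt50_design()
    _, truth_table = gen_genotypes(
        4000, design, {(0.5,): 0.5, (1.0,): 0.5}, seed=7
    )
    sens = {"0.5-1%": 0.35, "1-1.5%": 0.6, "1.5-2%": 0.75, "2-3%": 0.9}
    callset = simulate_callset(truth_table, sens_curve=sens, seed=12)
    truth = assemble_truth(
        [VariantKey(r.chrom, r.pos, r.ref, r.alt) for r in truth_table.itertuples(index=False)],
        negative_regions=GenomeRegions(),
    )
    # bin truth variants by their designed VAF: use a pileup dict reproducing
    # exactly the expected VAF (depth 10000 keeps binning deterministic)
    pileups = {
        ("chr1", r.pos): make_pileup(
            pos=r.pos, ref=r.ref, depth=10000,
            **{r.alt: int(r.expected_vaf * 10000)},
        )
        for r in truth_table.itertuples(index=False)
    }
    metrics = compute_metrics(callset, truth, mixture_pileups=pileups)
    for bin_label, s in [("1-1.5%", 0.6), ("2-3%", 0.9)]:
        row = metrics.loc[(bin_label, "all")]
        n = row.TP + row.FN
        assert n > 300
        half_width = 1.96 * np.sqrt(s * (1 - s) / n)
        assert abs(row.sensitivity - s) < half_width + 1e-9


# ---------------------------------------------------------------------------
# stratification


def test_stratify_position_definitions():
    primary = GenomeRegions.from_intervals([("chr1", 0, 100)])
    secondary = GenomeRegions.from_intervals([("chr1", 0, 200)])
    assert stratify_position("chr1", 50, primary, secondary) == "easy"
    assert stratify_position("chr1", 150, primary, secondary) == "difficult"
    assert stratify_position("chr1", 250, primary, secondary) == "extreme"


def test_stratify_warns_on_nesting_violation():
    primary = GenomeRegions.from_intervals([("chr1", 0, 100)])
    secondary = GenomeRegions.from_intervals([("chr1", 50, 100)])
    with pytest.warns(UserWarning, match="nest"):
        assert stratify_position("chr1", 10, primary, secondary) == "easy"


def test_mask_fractions_drive_stratum_proportions():
    """Masks at the published genome composition (74/10/16%) classify
    uniform positions in those proportions."""
    rng = np.random.default_rng(5)
    length = 1_000_000
    primary, secondary = gen_masks(length, 0.74, 0.10, seed=6)
    positions = rng.integers(1, length + 1, size=20_000)
    strata = [stratify_position("chr1", int(p), primary, secondary) for p in positions]
    frac = {s: strata.count(s) / len(strata) for s in ("easy", "difficult", "extreme")}
    assert frac["easy"] == pytest.approx(0.74, abs=0.02)
    assert frac["difficult"] == pytest.approx(0.10, abs=0.02)
    assert frac["extreme"] == pytest.approx(0.16, abs=0.02)


# ---------------------------------------------------------------------------
# VAF concordance


def test_vaf_concordance_rules():
    out = vaf_concordance([0.01, 0.01, 0.02], [0.01, 0.05, 0.02])
    assert out.loc["overall", "concordant"] == pytest.approx(2 / 3)
    # expected 0.01 observed 0.05: outside the half-distance window to 0.02
    assert out.loc[0.01, "concordant"] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        vaf_concordance([], [])


def test_concordance_decreases_with_shallower_depth():
    """Binomial sampling noise inflates reported VAFs more at lower depth,
    so concordance with the designed VAF drops as depth drops."""
    rng = np.random.default_rng(11)
    levels = [0.0025, 0.01, 0.02, 0.05]
    expected = np.array(rng.choice(levels, size=4000))
    fractions = {}
    for depth in (100, 500):
        observed = rng.binomial(depth, expected) / depth
        out = vaf_concordance(expected, observed, levels=levels)
        fractions[depth] = out.loc["overall", "concordant"]
    assert fractions[100] < fractions[500]
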