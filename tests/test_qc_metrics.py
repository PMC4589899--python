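"""Mendelian checks, concordance classification, INFO scoring and
masked-imputation accuracy against hand enumerations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txdesign import (
    MISSING,
    GenotypeMatrix,
    PedigreeTable,
    concordance_classify,
    concordance_report,
    info_score,
    masked_imputation_eval,
    mendelian_errors,
    ppc_heritability,
    simulate_posteriors,
    trio_report,
)
from txdesign.qc_metrics import round_half_up

from conftest import toy_manifest

GT = st.integers(0, 2)


# ---------------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "gf, gm, gc, expected",
    [
        (0, 0, 1, 1),  # hom-ref x hom-ref -> het child is an error
        (0, 0, 0, 0),
        (0, 0, 2, 1),
        (0, 2, 0, 1),  # hom-ref x hom-alt child must be het
        (0, 2, 1, 0),
        (1, 1, 0, 0),  # het x het: every child genotype compatible
        (1, 1, 1, 0),
        (1, 1, 2, 0),
        (2, 2, 1, 1),
        (2, 0, 2, 1),
        (1, 0, 2, 1),
        (1, 2, 0, 1),
    ],
)
def test_mendelian_error_classification(gf, gm, gc, expected):
    assert mendelian_errors(gf, gm, gc) == expected


def test_mendelian_requires_non_missing():
    with pytest.raises(ValueError):
        mendelian_errors(MISSING, 0, 0)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(GT, GT, GT)
def test_mendelian_matches_allele_enumeration(gf, gm, gc):
    """Error iff no pair of transmitted alleles reproduces the child."""
    transmissible = {0: (0,), 1: (0, 1), 2: (1,)}
    compatible = {a + b for a in transmissible[gf] for b in transmissible[gm]}
    assert mendelian_errors(gf, gm, gc) == int(gc not in compatible)


# ---------------------------------------------------------------------------
# Trio reports / P-P-C heritability
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "errors, total, expected",
    [
        (3757, 767_203, 99.51),
        (264, 767_203, 99.97),
        (4672, 767_203, 99.39),
        (0, 767_203, 100.00),
    ],
)
def test_ppc_heritability_display(errors, total, expected):
    assert round_half_up(ppc_heritability(errors, total), 2) == expected


def test_trio_report_counts_and_missing_handling():
    man = toy_manifest(5)
    # markers: 0 ok, 1 error (0x0 -> 1), 2 missing father, 3 error (2x2 -> 1), 4 ok
    genotypes = np.array(
        [
            [0, 0, 0],
            [0, 0, 1],
            [MISSING, 1, 1],
            [2, 2, 1],
            [1, 1, 2],
        ],
        dtype=np.int8,
    )
    matrix = GenotypeMatrix(genotypes, ["dad", "mom", "kid"], man)
    ped = PedigreeTable(
        pd.DataFrame(
            [
                ("f1", "dad", "0", "0", "1", "-9"),
                ("f1", "mom", "0", "0", "2", "-9"),
                ("f1", "kid", "dad", "mom", "0", "-9"),
            ],
            columns=PedigreeTable.COLUMNS,
        )
    )
    (rep,) = trio_report(matrix, ped, total_snps=5)
    assert rep.snps_compared == 4 and rep.skipped_missing == 1
    assert rep.error_count == 2
    assert rep.ppc_heritability == pytest.approx(100 * 3 / 5)
    assert rep.ppc_heritability_nonmissing == pytest.approx(100 * 2 / 4)
    # exact identity: error_rate + heritability/100 = 1 on unrounded values
    assert rep.error_count / rep.total_snps + rep.ppc_heritability / 100 == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a, b, expected",
    [(1, 1, "full"), (0, 0, "full"), (0, 1, "half"), (2, 1, "half"), (0, 2, "discordant")],
)
def test_concordance_classification(a, b, expected):
    assert concordance_classify(a, b) == expected


@settings(deadline=None, max_examples=50, derandomize=True)
@given(GT, GT)
def test_concordance_classification_symmetric(a, b):
    assert concordance_classify(a, b) == concordance_classify(b, a)


def test_concordance_report_hand_enumeration():
    """3 samples x 4 markers with one half and one discordant mismatch and
    two missing-excluded pairs: 10 full of 12 tested."""
    man = toy_manifest(4)
    a = GenotypeMatrix(
        np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 1]], dtype=np.int8),
        ["s1", "s2", "s3"],
        man,
    )
    b_geno = a.genotypes.copy()
    b_geno[0, 0] = 1  # half (0 vs 1)
    b_geno[1, 1] = MISSING  # excluded
    b_geno[2, 2] = MISSING  # excluded
    b_geno[3, 1] = 0  # discordant (2 vs 0)
    b = GenotypeMatrix(b_geno, ["s1", "s2", "s3"], man)
    rep = concordance_report(a, b)["ALL"]
    assert rep.tested == 10
    assert (rep.full, rep.half, rep.discordant) == (8, 1, 1)
    assert rep.full + rep.half + rep.discordant == rep.tested
    assert rep.concordance_pct == 80.0


def test_concordance_identical_matrices(two_pop_panel):
    matrix = two_pop_panel.to_genotypes()
    rep = concordance_report(matrix, matrix)["ALL"]
    assert rep.half == rep.discordant == 0
    assert rep.concordance_pct == 100.0
    assert rep.tested == matrix.n_markers * matrix.n_samples


def test_concordance_strata_conserve_counts(two_pop_panel):
    matrix = two_pop_panel.to_genotypes()
    other = GenotypeMatrix(matrix.genotypes.copy(), matrix.samples, matrix.manifest)
    other.genotypes[0, :] = 0
    n = matrix.n_markers
    strata = {"first_half": np.arange(n) < n // 2, "second_half": np.arange(n) >= n // 2}
    reps = concordance_report(matrix, other, strata=strata)
    for rep in reps.values():
        assert rep.full + rep.half + rep.discordant == rep.tested
    assert reps["first_half"].tested + reps["second_half"].tested == reps["ALL"].tested
    assert reps["first_half"].full + reps["second_half"].full == reps["ALL"].full


def test_rounding_is_half_up():
    assert round_half_up(99.565, 2) == 99.57
    assert round_half_up(99.5649, 2) == 99.56
    assert round_half_up(0.125, 2) == 0.13  # bankers' rounding would give 0.12


# ---------------------------------------------------------------------------
# INFO score
# ---------------------------------------------------------------------------

def test_info_degenerate_posteriors_score_one():
    p = np.zeros((6, 3))
    p[:3, 1] = 1.0
    p[3:, 2] = 1.0
    score = info_score(p)
    assert score.raw == pytest.approx(1.0)
    assert not score.monomorphic


def test_info_uniform_posteriors():
    """Uniform (1/3,1/3,1/3) posteriors: theta=0.5, raw INFO = -1/3."""
    score = info_score(np.full((50, 3), 1 / 3))
    assert score.theta == pytest.approx(0.5)
    assert score.raw == pytest.approx(-1 / 3)
    assert score.clipped == 0.0


def test_info_monomorphic_flag():
    p = np.zeros((4, 3))
    p[:, 0] = 1.0
    score = info_score(p)
    assert score.monomorphic and np.isnan(score.raw)


def test_info_rejects_unnormalized():
    with pytest.raises(ValueError, match="sum to 1"):
        info_score(np.array([[0.5, 0.2, 0.2]]))


def test_info_decreases_under_posterior_flattening(two_pop_panel):
    matrix = two_pop_panel.to_genotypes()
    prev = None
    for noise in (0.0, 0.3, 0.6, 0.9):
        post = simulate_posteriors(matrix, noise=noise, seed=12)
        scores = [
            info_score(post[i]).raw
            for i in range(matrix.n_markers)
            if not info_score(post[i]).monomorphic
        ]
        mean_info = float(np.mean(scores))
        if prev is not None:
            assert mean_info < prev
        prev = mean_info


# ---------------------------------------------------------------------------
# Masked imputation
# ---------------------------------------------------------------------------

def test_masked_eval_perfect_posteriors(two_pop_panel):
    matrix = two_pop_panel.to_genotypes()
    post = simulate_posteriors(matrix, noise=0.0, seed=1)
    rep = masked_imputation_eval(matrix, post, mask_fraction=0.2, seed=3)
    assert rep.overall_accuracy_pct == 100.0
    assert (rep.bin_table["accuracy_pct"] == 100.0).all()
    assert rep.overall_accuracy_pct_info_filtered == 100.0


def test_masked_eval_flip_construction_oracle(two_pop_panel):
    """Flipping the best guess for every sample at k of m masked markers
    gives accuracy exactly 100 (m - k) / m."""
    matrix = two_pop_panel.to_genotypes()
    post = simulate_posteriors(matrix, noise=0.0, seed=1)
    rep0 = masked_imputation_eval(matrix, post, mask_fraction=0.2, seed=3)
    masked = rep0.masked_markers
    m, k = len(masked), 3
    flipped = post.copy()
    ids = list(matrix.manifest.marker_ids)
    for mid in masked[:k]:
        i = ids.index(mid)
        truth_row = matrix.genotypes[i]
        wrong = (truth_row + 1) % 3
        flipped[i] = 0.0
        flipped[i, np.arange(matrix.n_samples), wrong] = 1.0
    rep = masked_imputation_eval(matrix, flipped, mask_fraction=0.2, seed=3)
    assert rep.masked_markers == masked  # same seed -> identical mask set
    assert rep.overall_accuracy_pct == pytest.approx(100.0 * (m - k) / m)


def test_masked_eval_deterministic_mask(two_pop_panel):
    matrix = two_pop_panel.to_genotypes()
    post = simulate_posteriors(matrix, noise=0.3, seed=4)
    a = masked_imputation_eval(matrix, post, 0.1, seed=9)
    b = masked_imputation_eval(matrix, post, 0.1, seed=9)
    assert a.masked_markers == b.masked_markers
    assert a.overall_accuracy_pct == b.overall_accuracy_pct


def test_masked_eval_bins_partition_maf_range(two_pop_panel):
    matrix = two_pop_panel.to_genotypes()
    post = simulate_posteriors(matrix, noise=0.2, seed=4)
    rep = masked_imputation_eval(matrix, post, mask_fraction=0.5, seed=5)
    bt = rep.bin_table
    assert (bt["maf_bin_low"] >= 0.0).all() and (bt["maf_bin_high"] <= 0.5).all()
    assert ((bt["maf_bin_high"] - bt["maf_bin_low"]).round(6) == 0.01).all()
    assert ((bt["accuracy_pct"] >= 0) & (bt["accuracy_pct"] <= 100)).all()
    polymorphic_masked = rep.per_marker[rep.per_marker["maf"] > 0]
    assert bt["n_markers"].sum() == len(polymorphic_masked)
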