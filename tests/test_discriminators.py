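"""Discrimination numbers, the decision rule, grid-search fitting, ensembles.

Brute-force oracles (explicit Python loops over frames and over the full
threshold lattice, with confusion counts assembled by hand) provide the
independent route against which the vectorized implementation is checked.
"""

import numpy as np
import pytest

from opnote import (
    DiscriminatorSpec,
    Family,
    FittedDiscriminator,
    binarize,
    discrimination_number,
    ensemble_predict,
    fit_threshold,
    integer_grid_max,
    predict,
    threshold_stability,
    weighted_f1,
)

ALL_FAMILIES = list(Family)


# ---------------------------------------------------------------- oracles


def oracle_longest_run(bits):
    best = run = 0
    for b in bits:
        run = run + 1 if b else 0
        best = max(best, run)
    return best


def oracle_delta(family, probs):
    bits = [1 if p >= 0.5 else 0 for p in probs]
    n = len(probs)
    return {
        Family.BINARY_INTEGER: float(sum(bits)),
        Family.BINARY_FRACTION: sum(bits) / n,
        Family.PROBABILITY_INTEGER: float(sum(probs)),
        Family.PROBABILITY_FRACTION: sum(probs) / n,
        Family.CHAIN_INTEGER: float(oracle_longest_run(bits)),
        Family.CHAIN_FRACTION: oracle_longest_run(bits) / n,
    }[family]


def oracle_weighted_f1(y_true, y_pred):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t and p)
    fp = sum(1 for t, p in zip(y_true, y_pred) if not t and p)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t and not p)
    tn = sum(1 for t, p in zip(y_true, y_pred) if not t and not p)
    f1_pos = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    f1_neg = 2 * tn / (2 * tn + fn + fp) if 2 * tn + fn + fp else 0.0
    n = len(y_true)
    return ((tp + fn) * f1_pos + (tn + fp) * f1_neg) / n


def oracle_fit(spec, deltas, truth):
    best_tau, best_score = None, -1.0
    for tau in spec.grid():
        preds = [d >= tau for d in deltas]
        score = oracle_weighted_f1(truth, preds)
        if score > best_score:  # strict: keeps the smallest maximizing tau
            best_tau, best_score = float(tau), score
    return best_tau, best_score


# ------------------------------------------------- discrimination numbers


def test_discrimination_number_worked_examples():
    binary = np.array([1.0, 1.0, 0.0, 1.0])
    assert discrimination_number(DiscriminatorSpec(Family.BINARY_INTEGER), binary) == 3
    assert discrimination_number(DiscriminatorSpec(Family.CHAIN_INTEGER), binary) == 2
    assert discrimination_number(DiscriminatorSpec(Family.BINARY_FRACTION), binary) == 0.75
    assert discrimination_number(DiscriminatorSpec(Family.CHAIN_FRACTION), binary) == 0.5
    mixed = np.array([0.5, 1.0, 0.0, 0.5])
    assert discrimination_number(DiscriminatorSpec(Family.PROBABILITY_INTEGER), mixed) == 2.0
    assert discrimination_number(DiscriminatorSpec(Family.PROBABILITY_FRACTION), mixed) == 0.5


@pytest.mark.parametrize("family", ALL_FAMILIES)
def test_discrimination_number_matches_bruteforce(family):
    rng = np.random.default_rng(0)
    spec = DiscriminatorSpec(family)
    for _ in range(300):
        probs = rng.random(int(rng.integers(1, 200)))
        assert discrimination_number(spec, probs) == pytest.approx(
            oracle_delta(family, probs.tolist()), abs=1e-12
        )


def test_empty_sequence_rejected():
    with pytest.raises(ValueError, match="empty"):
        discrimination_number(DiscriminatorSpec(Family.BINARY_INTEGER), np.array([]))


def test_family_bounds_hold():
    rng = np.random.default_rng(1)
    for _ in range(100):
        probs = rng.random(int(rng.integers(1, 150)))
        for family in (Family.BINARY_FRACTION, Family.PROBABILITY_FRACTION,
                       Family.CHAIN_FRACTION):
            assert 0.0 <= discrimination_number(DiscriminatorSpec(family), probs) <= 1.0
        chain = discrimination_number(DiscriminatorSpec(Family.CHAIN_INTEGER), probs)
        count = discrimination_number(DiscriminatorSpec(Family.BINARY_INTEGER), probs)
        assert chain <= count


# --------------------------------------------------------- decision rule


def test_delta_equal_to_tau_predicts_positive():
    spec = DiscriminatorSpec(Family.BINARY_INTEGER)
    fitted = FittedDiscriminator(spec, tau=3.0, fit_score=1.0)
    assert predict(fitted, np.array([1.0, 1.0, 1.0, 0.0])) is True


def test_tau_zero_always_positive():
    for family in ALL_FAMILIES:
        fitted = FittedDiscriminator(DiscriminatorSpec(family), tau=0.0, fit_score=1.0)
        assert predict(fitted, np.zeros(5)) is True


def test_fraction_grid_max_with_one_negative_frame_predicts_negative():
    fitted = FittedDiscriminator(
        DiscriminatorSpec(Family.BINARY_FRACTION), tau=1.0, fit_score=1.0
    )
    assert predict(fitted, np.array([1.0, 1.0, 0.0, 1.0])) is False


def test_positive_set_shrinks_as_tau_rises():
    rng = np.random.default_rng(2)
    spec = DiscriminatorSpec(Family.BINARY_FRACTION)
    seqs = [rng.random(50) for _ in range(20)]
    previous = None
    for tau in spec.grid()[::10]:
        fitted = FittedDiscriminator(spec, tau=float(tau), fit_score=0.0)
        current = {i for i, s in enumerate(seqs) if predict(fitted, s)}
        if previous is not None:
            assert current <= previous
        previous = current


# ---------------------------------------------------------------- grids


def test_grid_lattice_includes_both_endpoints_exactly():
    for family, (stride, gmax) in (
        (Family.BINARY_FRACTION, (0.01, 1.0)),
        (Family.CHAIN_FRACTION, (0.001, 1.0)),
        (Family.BINARY_INTEGER, (100.0, 16200.0)),
        (Family.CHAIN_INTEGER, (1.0, 16200.0)),
    ):
        grid = DiscriminatorSpec(family).grid()
        assert grid[0] == 0.0 and grid[-1] == gmax
        assert len(grid) == round(gmax / stride) + 1
        # lattice points are exact stride multiples (0.03 == 3/100 etc.)
        assert 3 * stride in grid


def test_integer_grid_max_covers_longest_video():
    assert integer_grid_max(16103, 100) == 16200
    assert integer_grid_max(16200, 100) == 16200
    assert integer_grid_max(1, 100) == 100


# -------------------------------------------------------------- fitting


def _chain_seq(run_length, total=20):
    p = np.zeros(total)
    p[:run_length] = 1.0
    return p


def test_perfect_separation_takes_smallest_lattice_point_above_negatives():
    spec = DiscriminatorSpec(Family.CHAIN_INTEGER)
    training = [(_chain_seq(10), True)] * 3 + [(_chain_seq(2), False)] * 3
    fitted = fit_threshold(spec, training)
    assert fitted.tau == 3.0
    assert fitted.fit_score == 1.0


def test_all_positive_training_yields_tau_zero():
    spec = DiscriminatorSpec(Family.BINARY_FRACTION)
    fitted = fit_threshold(spec, [(_chain_seq(5), True), (_chain_seq(9), True)])
    assert fitted.tau == 0.0
    assert fitted.fit_score == 1.0


@pytest.mark.parametrize(
    "family",
    [Family.BINARY_INTEGER, Family.BINARY_FRACTION, Family.PROBABILITY_FRACTION,
     Family.CHAIN_INTEGER, Family.CHAIN_FRACTION],
)
def test_fit_matches_exhaustive_grid_argmax(family):
    rng = np.random.default_rng(3)
    # small custom grids keep the Python-loop oracle exhaustive yet fast
    stride, gmax = ((1.0, 40.0) if "integer" in family.value else (0.02, 1.0))
    spec = DiscriminatorSpec(family, grid_stride=stride, grid_max=gmax)
    for _ in range(25):
        n_videos = int(rng.integers(2, 10))
        training = [
            (rng.random(int(rng.integers(5, 40))), bool(rng.random() < 0.6))
            for _ in range(n_videos)
        ]
        fitted = fit_threshold(spec, training)
        deltas = [discrimination_number(spec, s) for s, _ in training]
        truth = [t for _, t in training]
        tau, score = oracle_fit(spec, deltas, truth)
        assert fitted.tau == pytest.approx(tau, abs=1e-12)
        assert fitted.fit_score == pytest.approx(score, abs=1e-12)


def test_fit_curve_agrees_with_weighted_f1_implementation():
    """The vectorized fitting curve and the evaluation metric are distinct
    code paths; they must agree pointwise."""
    from opnote.discriminators import _weighted_f1_curve

    rng = np.random.default_rng(4)
    for _ in range(20):
        deltas = rng.random(15)
        truth = rng.random(15) < 0.5
        taus = np.linspace(0, 1, 11)
        curve = _weighted_f1_curve(deltas, truth, taus)
        for tau, score in zip(taus, curve):
            preds = (deltas >= tau).astype(int)
            assert score == pytest.approx(weighted_f1(truth.astype(int), preds))


def test_fit_rejects_empty_training_set():
    with pytest.raises(ValueError, match="empty"):
        fit_threshold(DiscriminatorSpec(Family.BINARY_INTEGER), [])


def test_threshold_stability_probes_neighbouring_lattice_points():
    spec = DiscriminatorSpec(Family.CHAIN_INTEGER)
    training = [(_chain_seq(10), True)] * 3 + [(_chain_seq(2), False)] * 3
    fitted = fit_threshold(spec, training)
    probe = threshold_stability(fitted, training, k=2)
    taus = [t for t, _ in probe]
    assert taus == [1.0, 2.0, 3.0, 4.0, 5.0]
    assert all(s == 1.0 for t, s in probe if 3.0 <= t <= 5.0)


# ------------------------------------------------------------- ensembles


def test_ensemble_operators():
    a, b = [True, False], [True, True]
    assert ensemble_predict(a, b, "intersection").tolist() == [True, False]
    assert ensemble_predict(a, b, "union").tolist() == [True, True]
    assert ensemble_predict(a, a, "intersection").tolist() == a
    assert ensemble_predict(a, a, "union").tolist() == a
    assert ensemble_predict(a, [True, True], "union").tolist() == [True, True]


def test_ensemble_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        ensemble_predict([True], [True, False], "union")
    with pytest.raises(ValueError, match="operator"):
        ensemble_predict([True], [False], "xor")
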