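import numpy as np
import pytest

from helpers import oracle_iterated_integrals, random_path, shoelace_levy_area
from trajsig.errors import ContractError, InvalidInputError
from trajsig.sigcore import (
    LabeledPath,
    chen_concat,
    compute_log_signature,
    compute_signature,
    identity_signature,
    log_signature_to_named_features,
    segment_signature,
    signature_to_named_features,
)

ATOL = 1e-10


def make_path(times, values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or tuple(f"X{i + 1}" for i in range(values.shape[1]))
    return LabeledPath(times=np.asarray(times, float), values=values, channel_names=names)


class TestLabeledPath:
    def test_rejects_unsorted_times(self):
        with pytest.raises(InvalidInputError):
            make_path([0.0, 0.0, 1.0], np.zeros((3, 2)))

    def test_rejects_nan(self):
        with pytest.raises(InvalidInputError):
            make_path([0.0, 1.0], [[np.nan, 0.0], [1.0, 1.0]])

    def test_rejects_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            LabeledPath(times=np.array([0.0, 1.0]), values=np.zeros((2, 2)), channel_names=("a",))

    def test_single_sample_allowed(self):
        path = make_path([3.0], [[1.0, 2.0]])
        assert path.n_samples == 1 and path.dim == 2


class TestSegmentSignature:
    def test_two_channel_example(self):
        sig = segment_signature([8.0, 9.0], degree=2)
        assert sig.level(0)[0] == 1.0
        np.testing.assert_allclose(sig.level(1), [8.0, 9.0])
        np.testing.assert_allclose(sig.level(2), [32.0, 36.0, 36.0, 40.5])

    def test_zero_segment(self):
        sig = segment_signature([0.0, 0.0], degree=2)
        assert sig.level(0)[0] == 1.0
        assert np.all(sig.level(1) == 0) and np.all(sig.level(2) == 0)

    def test_degree_three_repeated_index(self):
        sig = segment_signature([2.0, 1.0], degree=3)
        assert sig.coeff((1, 1, 1)) == pytest.approx(8.0 / 6.0, abs=1e-14)

    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidInputError):
            segment_signature([np.inf, 0.0], degree=2)

    def test_rejects_zero_degree(self):
        with pytest.raises(InvalidInputError):
            segment_signature([1.0], degree=0)


class TestChenConcat:
    def test_identity_is_neutral(self, rng):
        sig = segment_signature(rng.normal(size=3), degree=2)
        ident = identity_signature(3, 2)
        assert chen_concat(ident, sig).allclose(sig, atol=1e-14)
        assert chen_concat(sig, ident).allclose(sig, atol=1e-14)

    def test_two_segments_match_quadrature_oracle(self):
        # first two segments of the worked-example path
        a = segment_signature([2.0, 1.0], degree=2)
        b = segment_signature([2.0, 6.0], degree=2)
        combined = chen_concat(a, b)
        np.testing.assert_allclose(combined.level(1), [4.0, 7.0], atol=1e-12)
        # frozen from the quadrature oracle: 1 + 18 = 19
        times = [0.0, 1.0, 2.0]
        values = [[2.0, 1.0], [4.0, 2.0], [6.0, 8.0]]
        _, level2 = oracle_iterated_integrals(times, values)
        assert level2[0, 1] == pytest.approx(19.0, abs=1e-9)
        assert combined.coeff((1, 2)) == pytest.approx(19.0, abs=1e-12)

    def test_associativity(self, rng):
        for _ in range(20):
            s1, s2, s3 = (
                segment_signature(rng.uniform(-3, 3, 3), degree=3) for _ in range(3)
            )
            left = chen_concat(chen_concat(s1, s2), s3)
            right = chen_concat(s1, chen_concat(s2, s3))
            assert left.allclose(right, atol=1e-12)

    def test_mismatch_rejected(self):
        with pytest.raises(ContractError):
            chen_concat(identity_signature(2, 2), identity_signature(3, 2))
        with pytest.raises(ContractError):
            chen_concat(identity_signature(2, 2), identity_signature(2, 3))


class TestComputeSignature:
    def test_worked_example(self, fig_path):
        sig = compute_signature(fig_path, degree=2)
        flat = sig.flatten()
        np.testing.assert_allclose(
            flat, [1.0, 8.0, 9.0, 32.0, 31.0, 41.0, 40.5], atol=1e-12
        )

    def test_single_point_path(self):
        sig = compute_signature(make_path([0.0], [[5.0, -1.0]]), degree=2)
        np.testing.assert_allclose(sig.flatten(), [1, 0, 0, 0, 0, 0, 0], atol=0)

    def test_matches_quadrature_oracle(self, rng):
        for _ in range(5):
            times, values = random_path(rng, n_points=6, dim=3)
            sig = compute_signature(make_path(times, values), degree=2)
            level1, level2 = oracle_iterated_integrals(times, values)
            np.testing.assert_allclose(sig.level(1), level1, rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(
                sig.level(2).reshape(3, 3), level2, rtol=1e-6, atol=1e-8
            )


class TestLogSignature:
    def test_worked_example(self, fig_path):
        logsig = compute_log_signature(fig_path)
        np.testing.assert_allclose(logsig.increments, [8.0, 9.0], atol=1e-12)
        assert logsig.area(1, 2) == pytest.approx(-5.0, abs=1e-12)

    def test_consistent_with_signature_cross_terms(self, fig_path):
        sig = compute_signature(fig_path, degree=2)
        logsig = compute_log_signature(fig_path)
        assert logsig.area(1, 2) == pytest.approx(
            (sig.coeff((1, 2)) - sig.coeff((2, 1))) / 2.0, abs=1e-12
        )

    def test_straight_line_has_zero_area(self):
        path = make_path([0.0, 7.0], [[0.0, 1.0], [3.0, 5.0]])
        logsig = compute_log_signature(path)
        np.testing.assert_allclose(logsig.areas, 0.0, atol=1e-14)

    def test_matches_shoelace_oracle(self, rng):
        for _ in range(10):
            times, values = random_path(rng, n_points=7, dim=2)
            logsig = compute_log_signature(make_path(times, values))
            oracle = shoelace_levy_area(values[:, 0], values[:, 1])
            assert logsig.area(1, 2) == pytest.approx(oracle, abs=1e-9)

    def test_unsupported_degree(self, fig_path):
        with pytest.raises(InvalidInputError):
            compute_log_signature(fig_path, degree=3)


class TestNamedFeatures:
    def test_four_channel_count_and_order(self, rng):
        times, values = random_path(rng, n_points=5, dim=4)
        names = ("Wholebrain", "Hippocampus", "Ventricles", "Time")
        sig = compute_signature(make_path(times, values, names), degree=2)
        named = signature_to_named_features(sig, names)
        assert len(named) == 20
        assert [n for n, _ in named[:4]] == [
            "(Wholebrain)",
            "(Hippocampus)",
            "(Ventricles)",
            "(Time)",
        ]
        assert named[4][0] == "(Wholebrain, Wholebrain)"
        assert "(Hippocampus, Time)" in dict(named)
        assert named[-1][0] == "(Time, Time)"

    def test_worked_example_values(self, fig_path):
        sig = compute_signature(fig_path, degree=2)
        named = signature_to_named_features(sig, fig_path.channel_names)
        assert named == [
            ("(X1)", 8.0),
            ("(X2)", 9.0),
            ("(X1, X1)", 32.0),
            ("(X1, X2)", 31.0),
            ("(X2, X1)", 41.0),
            ("(X2, X2)", 40.5),
        ]

    def test_log_variant_count(self, rng):
        times, values = random_path(rng, n_points=5, dim=4)
        names = ("Wholebrain", "Hippocampus", "Ventricles", "Time")
        logsig = compute_log_signature(make_path(times, values, names))
        named = log_signature_to_named_features(logsig, names)
        assert len(named) == 10
        assert [n for n, _ in named[4:]] == [
            "[Wholebrain, Hippocampus]",
            "[Wholebrain, Ventricles]",
            "[Wholebrain, Time]",
            "[Hippocampus, Ventricles]",
            "[Hippocampus, Time]",
            "[Ventricles, Time]",
        ]

    def test_name_count_mismatch(self, fig_path):
        sig = compute_signature(fig_path, degree=2)
        with pytest.raises(ContractError):
            signature_to_named_features(sig, ("only_one",))


class TestAlgebraicProperties:
    """Invariant suites on random paths (tolerance 1e-10)."""

    def test_shuffle_relation(self, rng):
        for _ in range(100):
            d = int(rng.integers(2, 5))
            times, values = random_path(rng, n_points=int(rng.integers(2, 11)), dim=d)
            sig = compute_signature(make_path(times, values), degree=2)
            level2 = sig.level(2).reshape(d, d)
            s1 = sig.level(1)
            for i in range(d):
                for j in range(d):
                    assert level2[i, j] + level2[j, i] == pytest.approx(
                        s1[i] * s1[j], abs=ATOL
                    )

    def test_chen_prefix_suffix_split(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            times, values = random_path(rng, n_points=n, dim=3)
            cut = int(rng.integers(1, n - 1))
            whole = compute_signature(make_path(times, values), degree=2)
            prefix = compute_signature(
                make_path(times[: cut + 1], values[: cut + 1]), degree=2
            )
            suffix = compute_signature(make_path(times[cut:], values[cut:]), degree=2)
            assert chen_concat(prefix, suffix).allclose(whole, atol=ATOL)

    def test_reparameterisation_invariance(self, rng):
        for _ in range(100):
            times, values = random_path(rng, n_points=5, dim=3)
            base = compute_signature(make_path(times, values), degree=2)
            # insert collinear points into a random segment
            seg = int(rng.integers(0, len(times) - 1))
            fracs = np.sort(rng.uniform(0.1, 0.9, int(rng.integers(1, 4))))
            new_times = np.concatenate(
                [times[: seg + 1], times[seg] + fracs * (times[seg + 1] - times[seg]), times[seg + 1 :]]
            )
            new_values = np.vstack(
                [
                    values[: seg + 1],
                    values[seg] + fracs[:, None] * (values[seg + 1] - values[seg]),
                    values[seg + 1 :],
                ]
            )
            refined = compute_signature(make_path(new_times, new_values), degree=2)
            assert refined.allclose(base, atol=ATOL)

    def test_translation_invariance(self, rng):
        for _ in range(100):
            times, values = random_path(rng, n_points=6, dim=3)
            base = compute_signature(make_path(times, values), degree=2)
            shifted = compute_signature(
                make_path(times, values + rng.uniform(-50, 50, 3)), degree=2
            )
            assert shifted.allclose(base, atol=ATOL)

    def test_exp_log_consistency(self, rng):
        for _ in range(100):
            d = int(rng.integers(2, 5))
            times, values = random_path(rng, n_points=6, dim=d)
            path = make_path(times, values)
            sig = compute_signature(path, degree=2)
            logsig = compute_log_signature(path)
            level2 = sig.level(2).reshape(d, d)
            incr = logsig.increments
            for i in range(d):
                for j in range(d):
                    if i == j:
                        signed_area = 0.0
                    elif i < j:
                        signed_area = logsig.area(i + 1, j + 1)
                    else:
                        signed_area = -logsig.area(j + 1, i + 1)
                    rebuilt = incr[i] * incr[j] / 2.0 + signed_area
                    assert rebuilt == pytest.approx(level2[i, j], abs=ATOL)
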