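import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irnet import (
    EmbeddingSpec,
    ami_profile,
    auto_recurrence,
    delay_embed,
    first_minimum_lag,
    fnn_profile,
    select_dim,
    standardize,
)


class TestStandardize:
    def test_simple_example(self):
        assert np.allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = standardize(rng.normal(2.0, 3.0, size=500))
        assert np.allclose(standardize(x), x, atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize([5.0, 5.0, 5.0])

    @given(
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-50.0, 50.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_recurrence_invariant_to_affine_rescaling(self, scale, shift):
        """Standardization makes the recurrence structure independent of the
        raw series' units and offset."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=80)
        spec = EmbeddingSpec(lag=2, dim=2)
        base = auto_recurrence(delay_embed(x, spec), target_rr=0.1)
        scaled = auto_recurrence(delay_embed(scale * x + shift, spec), target_rr=0.1)
        assert np.array_equal(base.matrix, scaled.matrix)


class TestDelayEmbed:
    def test_small_example(self):
        spec = EmbeddingSpec(lag=2, dim=3, standardized=False)
        traj = delay_embed(np.arange(1.0, 11.0), spec)
        assert traj.points.shape == (6, 3)
        assert list(traj.points[0]) == [1, 3, 5]
        assert list(traj.points[-1]) == [6, 8, 10]

    def test_dim_one_is_identity(self):
        x = np.arange(5.0)
        traj = delay_embed(x, EmbeddingSpec(lag=3, dim=1, standardized=False))
        assert np.array_equal(traj.points.ravel(), x)

    def test_pipeline_dimensions(self):
        x = np.sin(np.arange(2100) / 50)
        traj = delay_embed(x, EmbeddingSpec(lag=100, dim=5))
        assert len(traj) == 1700

    def test_too_short_series_reports_minimum(self):
        with pytest.raises(ValueError, match="minimum length"):
            delay_embed(np.arange(10.0), EmbeddingSpec(lag=5, dim=3))


def ami_bruteforce(x, max_lag, n_bins=32):
    """Independent mutual-information oracle: explicit probability tables."""
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    edges[-1] += 1e-12
    out = []
    for k in range(max_lag + 1):
        a = np.digitize(x[: len(x) - k] if k else x, edges) - 1
        b = np.digitize(x[k:] if k else x, edges) - 1
        mi = 0.0
        n = len(a)
        for i in range(n_bins):
            for j in range(n_bins):
                pij = np.sum((a == i) & (b == j)) / n
                if pij > 0:
                    pi = np.sum(a == i) / n
                    pj = np.sum(b == j) / n
                    mi += pij * np.log(pij / (pi * pj))
        out.append(mi)
    return np.asarray(out)


class TestAMI:
    def test_iid_noise_has_negligible_information(self):
        rng = np.random.default_rng(1)
        prof = ami_profile(rng.normal(size=10_000), max_lag=20)
        assert prof[1:].max() < 0.05

    def test_lag_zero_is_marginal_entropy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        prof = ami_profile(x, max_lag=3)
        h, _ = np.histogram(x, bins=np.linspace(x.min(), x.max() + 1e-12, 33))
        p = h / h.sum()
        entropy = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert prof[0] == pytest.approx(entropy, rel=1e-6)

    def test_sinusoid_first_minimum_near_quarter_period(self):
        """A touch of noise regularizes the histogram estimator, whose MI for
        a perfectly deterministic signal saturates into a flat plateau."""
        period = 40
        rng = np.random.default_rng(6)
        x = np.sin(2 * np.pi * np.arange(2000) / period)
        x = x + 0.05 * rng.normal(size=len(x))
        prof = ami_profile(x, max_lag=period)
        assert abs(first_minimum_lag(prof) - period // 4) <= 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        x = np.sin(np.arange(300) / 5) + 0.2 * rng.normal(size=300)
        fast = ami_profile(x, max_lag=8, n_bins=8)
        slow = ami_bruteforce(x, max_lag=8, n_bins=8)
        assert np.allclose(fast, slow, atol=1e-10)

    def test_monotone_profile_warns_and_falls_back(self):
        prof = np.linspace(1.0, 0.1, 10)  # strictly decreasing
        with pytest.warns(UserWarning, match="global minimum"):
            assert first_minimum_lag(prof) == 9


def fnn_bruteforce(x, lag, max_dim, r_tol=10.0, a_tol=2.0):
    """Exhaustive-pair FNN oracle (no spatial index)."""
    x = standardize(np.asarray(x, dtype=float))
    sd = x.std(ddof=1)
    fractions = []
    for m in range(1, max_dim + 1):
        n = len(x) - m * lag
        if n < 2:
            break
        emb = np.column_stack([x[i * lag : i * lag + n] for i in range(m)])
        extra = x[m * lag : m * lag + n]
        false = 0
        for i in range(n):
            dists = np.sqrt(((emb - emb[i]) ** 2).sum(axis=1))
            dists[i] = np.inf
            j = int(np.argmin(dists))
            d = dists[j]
            gap = abs(extra[i] - extra[j])
            if (gap > r_tol * d and gap > 1e-10 * sd) or np.hypot(d, gap) > a_tol * sd:
                false += 1
        fractions.append(false / n)
    return np.asarray(fractions)


class TestFNN:
    def test_noiseless_sinusoid_unfolds_in_two_dimensions(self):
        x = np.sin(2 * np.pi * np.arange(1200) / 60)
        prof = fnn_profile(x, lag=15, max_dim=4)
        assert prof[1] < 0.01
        assert select_dim(prof, threshold=0.01) <= 2

    def test_iid_noise_never_settles(self):
        rng = np.random.default_rng(4)
        prof = fnn_profile(rng.normal(size=1500), lag=1, max_dim=5)
        assert prof.min() > 0.05
        with pytest.raises(ValueError, match="no dimension"):
            select_dim(prof, threshold=0.01)

    def test_select_dim_on_exactly_zero_profile(self):
        assert select_dim(np.array([0.4, 0.0, 0.0]), threshold=0.01) == 2

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        x = np.sin(np.arange(400) / 7) + 0.1 * rng.normal(size=400)
        fast = fnn_profile(x, lag=5, max_dim=4)
        slow = fnn_bruteforce(x, lag=5, max_dim=4)
        assert np.allclose(fast, slow, atol=1e-12)

    def test_truncated_profile_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            prof = fnn_profile(np.sin(np.arange(40.0)), lag=10, max_dim=6)
        assert len(prof) < 6
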