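"""Unit and property tests for the Student-t slice-attention chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import t as scipy_t

from tdslice.attention import (
    AttentionWeights,
    FeatureMap,
    PooledDescriptors,
    SimilarityPair,
    TFitConfig,
    TParams,
    apply_weights,
    attend,
    fit_t_params,
    initial_weights,
    pool_slice_features,
    similarity_pair,
    slice_weights,
    t_pdf,
)

# ---------------------------------------------------------------------------
# independent straight-loop reference implementation (kept deliberately naive)
# ---------------------------------------------------------------------------


def _loop_attention_chain(m: np.ndarray, nu_min=2.05, nu_max=200.0):
    """Plain-Python re-derivation of the whole chain; no shared code paths."""
    import math

    S, C = m.shape[0], m.shape[1]
    avg = np.zeros((S, C))
    mx = np.zeros((S, C))
    for s in range(S):
        for c in range(C):
            vals = [m[s, c, i, j] for i in range(m.shape[2]) for j in range(m.shape[3])]
            avg[s, c] = sum(vals) / len(vals)
            mx[s, c] = max(vals)

    def rowsoftmax(logits):
        out = np.zeros_like(logits)
        for i in range(logits.shape[0]):
            row = logits[i] - max(logits[i])
            e = [math.exp(v) for v in row]
            out[i] = [v / sum(e) for v in e]
        return out

    s1 = rowsoftmax(avg @ mx.T)
    s2 = rowsoftmax(mx @ avg.T)
    d = (s1 + s2) / 2.0
    t_s = [sum(d[k, s] for k in range(S)) / S for s in range(S)]
    omega = [t / sum(t_s) for t in t_s]
    mu = sum(omega[s] * (s + 1) for s in range(S))
    v = sum(omega[s] * ((s + 1) - mu) ** 2 for s in range(S))
    if v <= 1.0:
        nu = nu_max
    else:
        nu = min(max(2.0 * v / (v - 1.0), nu_min), nu_max)

    def tden(x):
        return (
            math.gamma((nu + 1) / 2)
            / (math.gamma(nu / 2) * math.sqrt(nu * math.pi))
            * (1 + (x - mu) ** 2 / nu) ** (-(nu + 1) / 2)
        )

    dens = [tden(s + 1) for s in range(S)]
    w = np.array([d_ / sum(dens) for d_ in dens])
    out = np.zeros_like(m)
    for s in range(S):
        out[s] = w[s] * m[s]
    return np.array(omega), mu, nu, w, out


# ------------------------------------------------------------------- pooling


def test_pooling_constant_map_gives_constant_descriptors():
    m = FeatureMap(np.full((2, 1, 3, 3), 3.5))
    p = pool_slice_features(m)
    assert np.allclose(p.avg, 3.5) and np.allclose(p.max, 3.5)


def test_pooling_single_hot_entry():
    v = np.zeros((1, 1, 2, 2))
    v[0, 0, 1, 0] = 8.0
    p = pool_slice_features(FeatureMap(v))
    assert p.avg[0, 0] == pytest.approx(2.0)
    assert p.max[0, 0] == pytest.approx(8.0)


def test_pooling_matches_loop_oracle(rng):
    v = rng.normal(size=(4, 3, 5, 5))
    p = pool_slice_features(FeatureMap(v))
    avg = np.array([[v[s, c].mean() for c in range(3)] for s in range(4)])
    mx = np.array([[v[s, c].max() for c in range(3)] for s in range(4)])
    assert np.max(np.abs(p.avg - avg)) < 1e-10
    assert np.max(np.abs(p.max - mx)) < 1e-10


def test_pooling_rejects_non_finite():
    v = np.ones((2, 1, 2, 2))
    v[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        pool_slice_features(FeatureMap(v))


# ---------------------------------------------------------------- similarity


def test_similarity_single_slice_is_identity():
    p = PooledDescriptors(avg=[[1.0, 2.0]], max=[[3.0, 4.0]])
    sp = similarity_pair(p)
    assert np.allclose(sp.s1, [[1.0]]) and np.allclose(sp.s2, [[1.0]])


def test_similarity_identical_slices_uniform():
    p = PooledDescriptors(avg=np.tile([1.0, -2.0], (4, 1)), max=np.tile([3.0, 0.5], (4, 1)))
    sp = similarity_pair(p)
    assert np.allclose(sp.s1, 0.25) and np.allclose(sp.s2, 0.25)


def test_similarity_matches_exp_normalise_loop(rng):
    avg = rng.normal(size=(3, 2))
    mx = avg + rng.exponential(size=(3, 2))
    sp = similarity_pair(PooledDescriptors(avg=avg, max=mx))
    for mat, logits in ((sp.s1, avg @ mx.T), (sp.s2, mx @ avg.T)):
        ref = np.array([np.exp(r) / np.exp(r).sum() for r in logits])
        assert np.max(np.abs(mat - ref)) < 1e-10


def test_similarity_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        PooledDescriptors(avg=np.ones((3, 2)), max=np.ones((2, 2)))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(2, 6), st.integers(1, 4), st.integers(0, 2**31 - 1))
def test_similarity_rows_stochastic_property(s, c, seed):
    r = np.random.default_rng(seed)
    sp = similarity_pair(
        PooledDescriptors(avg=r.normal(size=(s, c)), max=r.normal(size=(s, c)))
    )
    assert np.allclose(sp.s1.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(sp.s2.sum(axis=1), 1.0, atol=1e-9)
    assert (sp.s1 > 0).all() and (sp.s2 > 0).all()


# ------------------------------------------------------------ initial weights


def test_initial_weights_uniform_for_identical_slices():
    d = np.full((4, 4), 0.25)
    iw = initial_weights(SimilarityPair(s1=d * 2 - d, s2=d))  # both uniform
    assert np.allclose(iw.omega, 0.25)


def test_initial_weights_column_sum_hand_example():
    d = np.array([[0.9, 0.1], [0.9, 0.1]])
    iw = initial_weights(SimilarityPair(s1=d, s2=d))
    assert np.allclose(iw.omega, [0.9, 0.1])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(2, 7), st.integers(0, 2**31 - 1))
def test_initial_weights_on_simplex_property(s, seed):
    r = np.random.default_rng(seed)
    p = PooledDescriptors(avg=r.normal(size=(s, 3)), max=r.normal(size=(s, 3)))
    iw = initial_weights(similarity_pair(p))
    assert np.isclose(iw.omega.sum(), 1.0, atol=1e-9)
    assert (iw.omega >= 0).all()


def test_row_index_sum_reading_is_degenerate(rng):
    """Summing D over its column index (per-row) is identically 1 for any
    input, so that reading would always produce uniform weights — the
    column-index sum is the only informative reading."""
    for _ in range(10):
        p = PooledDescriptors(avg=rng.normal(size=(5, 3)), max=rng.normal(size=(5, 3)))
        iw = initial_weights(similarity_pair(p))
        row_sums = iw.d.sum(axis=1)  # degenerate variant
        assert np.allclose(row_sums, 1.0, atol=1e-9)
        degenerate_omega = row_sums / row_sums.sum()
        assert np.allclose(degenerate_omega, 1.0 / 5, atol=1e-9)


def test_permutation_covariance_of_omega(rng):
    v = rng.normal(size=(6, 3, 4, 4))
    perm = rng.permutation(6)
    om = initial_weights(similarity_pair(pool_slice_features(FeatureMap(v)))).omega
    om_p = initial_weights(
        similarity_pair(pool_slice_features(FeatureMap(v[perm])))
    ).omega
    assert np.allclose(om_p, om[perm], atol=1e-10)


# --------------------------------------------------------------------- t fit


def test_fit_uniform_omega_centres_mu():
    iw = initial_weights(SimilarityPair(s1=np.full((5, 5), 0.2), s2=np.full((5, 5), 0.2)))
    tp = fit_t_params(iw)
    assert tp.mu == pytest.approx(3.0)


def test_fit_one_hot_degenerates_to_nu_max():
    d = np.zeros((5, 5))
    d[:, 2] = 1.0
    iw = InitialWeightsFactory(d)
    tp = fit_t_params(iw)
    assert tp.mu == pytest.approx(3.0)
    assert tp.nu == pytest.approx(TFitConfig().nu_max)


def InitialWeightsFactory(d):
    from tdslice.attention import InitialWeights

    t = d.mean(axis=0)
    return InitialWeights(d=d, omega=t / t.sum())


def test_fit_moment_matching_hand_example():
    from tdslice.attention import InitialWeights

    omega = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
    iw = InitialWeights(d=np.tile(omega, (5, 1)), omega=omega)
    tp = fit_t_params(iw)
    # weighted mean 3.0, weighted variance 1.2 -> nu = 2*1.2/0.2 = 12
    assert tp.mu == pytest.approx(3.0)
    assert tp.nu == pytest.approx(12.0)


def test_fit_fixed_nu_used_verbatim():
    from tdslice.attention import InitialWeights

    omega = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
    iw = InitialWeights(d=np.tile(omega, (5, 1)), omega=omega)
    tp = fit_t_params(iw, TFitConfig(nu=1.0))
    assert tp.nu == 1.0


# --------------------------------------------------------------------- t pdf


def test_t_pdf_nu_one_is_cauchy():
    tp = TParams(mu=2.0, nu=1.0)
    xs = np.linspace(-10, 14, 97)
    cauchy = 1.0 / (np.pi * (1.0 + (xs - 2.0) ** 2))
    assert np.max(np.abs(t_pdf(xs, tp) - cauchy)) < 1e-12


def test_t_pdf_symmetry():
    tp = TParams(mu=5.0, nu=3.7)
    for d in (0.1, 1.0, 2.5, 7.0):
        assert t_pdf(5.0 + d, tp) == pytest.approx(t_pdf(5.0 - d, tp), abs=1e-15)


@pytest.mark.parametrize("nu", [2.5, 5.0, 30.0])
def test_t_pdf_integrates_to_one(nu):
    # full-support quadrature: heavy tails (nu=2.5) hold ~8e-5 of mass
    # beyond +/-50, so a finite window cannot reach 1e-6 accuracy
    tp = TParams(mu=3.0, nu=nu)
    total, _ = quad(lambda x: t_pdf(x, tp), -np.inf, np.inf, limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_t_pdf_matches_scipy_reference(rng):
    """Independent cross-check against the library Student-t density."""
    for _ in range(20):
        mu, nu = rng.uniform(-5, 5), rng.uniform(0.5, 100)
        xs = rng.uniform(-20, 20, size=7)
        ours = t_pdf(xs, TParams(mu=mu, nu=nu))
        ref = scipy_t.pdf(xs, df=nu, loc=mu)
        assert np.max(np.abs(ours - ref)) < 1e-12


def test_t_pdf_rejects_nonpositive_nu():
    with pytest.raises(ValueError):
        TParams(mu=1.0, nu=0.0)


# ------------------------------------------------------------- slice weights


def test_slice_weights_single_slice():
    assert slice_weights(1, TParams(mu=1.0, nu=5.0)).w == pytest.approx([1.0])


@pytest.mark.parametrize("s", [3, 5, 9, 14])
@pytest.mark.parametrize("nu", [2.5, 5.0, 30.0])
def test_slice_weights_centered_symmetric_unimodal(s, nu):
    tp = TParams(mu=(s + 1) / 2.0, nu=nu)
    w = slice_weights(s, tp).w
    assert np.isclose(w.sum(), 1.0, atol=1e-9)
    assert np.allclose(w, w[::-1], atol=1e-12)  # symmetric about the middle
    mode = (s - 1) // 2
    assert w[mode] >= w[0] and w[mode] >= w[-1]
    # strictly decreasing away from the mode (even S: central pair ties)
    assert all(w[i] > w[i + 1] for i in range(s // 2, s - 1))


def test_slice_weights_five_point_oracle():
    tp = TParams(mu=3.0, nu=4.2)
    dens = np.array([t_pdf(float(x), tp) for x in range(1, 6)])
    assert np.max(np.abs(slice_weights(5, tp).w - dens / dens.sum())) < 1e-12


# ------------------------------------------------------------- apply weights


def test_apply_uniform_weights_scales_by_inverse_s(rng):
    v = rng.normal(size=(4, 2, 3, 3))
    out = apply_weights(FeatureMap(v), AttentionWeights(np.full(4, 0.25)))
    assert np.allclose(out.values, v * 0.25)


def test_apply_zero_weight_annihilates_slice(rng):
    v = rng.normal(size=(3, 2, 2, 2))
    w = np.array([0.0, 0.5, 0.5])
    out = apply_weights(FeatureMap(v), AttentionWeights(w))
    assert np.all(out.values[0] == 0.0)
    assert np.allclose(np.sign(out.values[1:]), np.sign(v[1:]) * (np.abs(v[1:]) > 0))


def test_apply_weights_length_mismatch():
    with pytest.raises(ValueError):
        apply_weights(FeatureMap(np.ones((3, 1, 2, 2))), AttentionWeights([0.5, 0.5]))


def test_apply_weights_matches_loop(rng):
    v = rng.normal(size=(5, 3, 4, 4))
    w = rng.dirichlet(np.ones(5))
    out = apply_weights(FeatureMap(v), AttentionWeights(w))
    ref = np.stack([w[s] * v[s] for s in range(5)])
    assert np.max(np.abs(out.values - ref)) < 1e-12


# ------------------------------------------------------------- whole chain


def test_full_chain_matches_straight_loop_reference(rng):
    worst = 0.0
    for _ in range(50):
        s = int(rng.integers(1, 7))
        c = int(rng.integers(1, 5))
        h = int(rng.integers(1, 5))
        v = rng.normal(size=(s, c, h, h))
        weighted, state = attend(FeatureMap(v))
        omega, mu, nu, w, out = _loop_attention_chain(v)
        worst = max(
            worst,
            np.max(np.abs(state.initial.omega - omega)),
            abs(state.tparams.mu - mu),
            np.max(np.abs(state.weights.w - w)),
            np.max(np.abs(weighted.values - out)),
        )
    assert worst < 1e-8


def test_centrality_with_uniform_omega():
    """Centered fit gives the middle slice strictly more weight than the ends."""
    for s in range(3, 20):
        tp = TParams(mu=(s + 1) / 2.0, nu=2.5)
        w = slice_weights(s, tp).w
        mid = w[(s - 1) // 2]
        assert mid > w[0] and mid > w[-1]
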