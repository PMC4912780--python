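"""Summarization, design extension, fitting, moderation and combination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import splicevents as sv
from splicevents.splice_stats import (
    DesignSpec, Q, combine_pvalues, extend_contrast, extend_design,
    fit_events, median_polish, moderate_variances, PathSignals,
)

# the extended design printed for the two-sample (normal/tumor) example
EQ6_MATRIX = np.array([
    [1, 0, 0, 0, 0, 0],
    [1, 1, 0, 0, 0, 0],
    [1, 1, 1, 0, 0, 0],
    [1, 0, 0, 1, 0, 0],
    [1, 1, 0, 1, 1, 0],
    [1, 1, 1, 1, 1, 1],
], dtype=float)


# ---------------------------------------------------------------------------
# median polish

def median_polish_oracle(block, n_sweeps=200):
    """Independently coded sweep loop (plain Python, statistics.median)."""
    from statistics import median
    z = [list(map(float, row)) for row in block]
    nr, nc = len(z), len(z[0])
    row = [0.0] * nr
    col = [0.0] * nc
    overall = 0.0
    for _ in range(n_sweeps):
        for i in range(nr):
            m = median(z[i])
            row[i] += m
            for j in range(nc):
                z[i][j] -= m
        d = median(col)
        overall += d
        col = [c - d for c in col]
        for j in range(nc):
            m = median(z[i][j] for i in range(nr))
            col[j] += m
            for i in range(nr):
                z[i][j] -= m
        d = median(row)
        overall += d
        row = [r - d for r in row]
    return [overall + c for c in col]


def test_median_polish_additive_matrix_exact():
    rng = np.random.default_rng(0)
    a = rng.normal(size=6)
    b = rng.normal(size=4)
    block = a[:, None] + b[None, :]
    got = median_polish(block)
    # per-sample values recover b up to a common constant; residuals vanish
    assert np.allclose(np.diff(got), np.diff(b), atol=1e-12)
    fitted = (got[None, :] + (block - got[None, :]).mean(axis=1,
                                                         keepdims=True))
    assert np.allclose(fitted, block, atol=1e-9)


def test_median_polish_single_probe_returns_row():
    row = np.array([1.5, -2.0, 3.25])
    assert np.allclose(median_polish(row[None, :]), row, atol=1e-12)


def test_median_polish_matches_oracle_with_outlier():
    rng = np.random.default_rng(1)
    block = rng.normal(size=(3, 3))
    block[1, 2] += 10.0  # single outlier cell
    got = median_polish(block, max_iter=500)
    want = median_polish_oracle(block)
    assert np.allclose(got, want, atol=1e-12)


# odd extents keep every sweep median unique, so the fit is unambiguous
# and two independent implementations must agree exactly
@pytest.mark.parametrize("shape", [(3, 5), (5, 3), (5, 7), (7, 3)])
def test_median_polish_matches_oracle_random(shape):
    rng = np.random.default_rng(hash(shape) % 2**31)
    block = rng.normal(size=shape)
    assert np.allclose(median_polish(block, max_iter=500),
                       median_polish_oracle(block), atol=1e-10)


def test_median_polish_rejects_empty_and_nonfinite():
    with pytest.raises(ValueError):
        median_polish(np.empty((0, 3)))
    with pytest.raises(ValueError):
        median_polish(np.array([[1.0, np.nan]]))


# ---------------------------------------------------------------------------
# design / contrast extension

def test_extend_design_two_sample_example():
    assert np.array_equal(extend_design([[1, 0], [1, 1]]), EQ6_MATRIX)


def test_extend_design_identity_is_q():
    assert np.array_equal(extend_design([[1]]), Q)


def test_extend_design_blocks_match_kronecker_definition():
    rng = np.random.default_rng(2)
    D = rng.normal(size=(5, 3))
    ext = extend_design(D)
    assert ext.shape == (15, 9)
    for i in range(5):
        for j in range(3):
            block = ext[3 * i:3 * i + 3, 3 * j:3 * j + 3]
            assert np.allclose(block, D[i, j] * Q)


def test_extend_design_rank_deficient_rejected():
    with pytest.raises(ValueError, match="rank"):
        extend_design([[1, 1], [1, 1]])


def test_extend_contrast_two_sample_rows():
    C = np.array([[0.0, 1.0]])
    ext = extend_contrast(C)
    # rows select b3+b4 (isoform 1) then b3+b4+b5 (isoform 2)
    assert np.array_equal(ext, [[0, 0, 0, 1, 1, 0],
                                [0, 0, 0, 1, 1, 1]])


def test_extend_contrast_identity_gives_2k_rows():
    k = 4
    ext = extend_contrast(np.eye(k))
    assert ext.shape == (2 * k, 3 * k)


def test_extend_contrast_paired_design_hand_expansion():
    _, C = sv.paired_design(3)
    ext = extend_contrast(C)
    # hand expansion: condition coefficient block gets [1 1 0] / [1 1 1]
    want = np.zeros((2, 12))
    want[0, 0:3] = [1, 1, 0]
    want[1, 0:3] = [1, 1, 1]
    assert np.array_equal(ext, want)


def test_contrast_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="columns"):
        DesignSpec(D=[[1, 0], [1, 1]], C=[[0, 1, 0]])


def test_all_zero_contrast_rejected():
    with pytest.raises(ValueError, match="zero"):
        DesignSpec(D=[[1, 0], [1, 1]], C=[[0, 0]])


# ---------------------------------------------------------------------------
# fitting

def noise_free_signals(t_n, t_t, n=3, affinities=(1.0, 1.0, 1.0)):
    """Exact path signals for a two-condition event, no noise."""
    conc = np.array([
        [t_n[0] + t_n[1], t_t[0] + t_t[1]],
        [t_n[0], t_t[0]],
        [t_n[1], t_t[1]],
    ])
    aff = np.log2(np.asarray(affinities))[:, None]
    y = np.log2(conc) + aff            # (3 paths, 2 conditions)
    values = np.empty((1, 2 * n, 3))
    values[0, :n, :] = y[:, 0]
    values[0, n:, :] = y[:, 1]
    return PathSignals(["EV1"], [f"s{i}" for i in range(2 * n)], values)


def table4_identities(t_n, t_t):
    b3 = np.log2((t_t[0] + t_t[1]) / (t_n[0] + t_n[1]))
    b4 = np.log2(t_t[0] / (t_t[0] + t_t[1])) - \
        np.log2(t_n[0] / (t_n[0] + t_n[1]))
    b5 = np.log2(t_t[1] / t_t[0]) - np.log2(t_n[1] / t_n[0])
    return b3, b4, b5


def test_noise_free_coefficients_match_concentration_formulas():
    t_n, t_t = (4.0, 4.0), (8.0, 2.0)
    ps = noise_free_signals(t_n, t_t)
    spec = DesignSpec(*sv.two_group_design(3, 3))
    fits = fit_events(ps, spec)
    b3, b4, b5 = table4_identities(t_n, t_t)
    coef = fits.coef[0]
    assert abs(coef[3] - b3) < 1e-10
    assert abs(coef[4] - b4) < 1e-10
    assert abs(coef[5] - b5) < 1e-10
    assert abs(fits.contrast_est[0, 0] - (b3 + b4)) < 1e-10      # iso 1 FC
    assert abs(fits.contrast_est[0, 1] - (b3 + b4 + b5)) < 1e-10  # iso 2 FC
    assert fits.s2[0] < 1e-20


def test_null_event_has_zero_splicing_coefficients():
    ps = noise_free_signals((4.0, 4.0), (4.0, 4.0))
    fits = fit_events(ps, DesignSpec(*sv.two_group_design(3, 3)))
    assert np.allclose(fits.coef[0, 3:], 0.0, atol=1e-12)


def test_affinity_invariance_of_splicing_coefficients():
    t_n, t_t = (6.0, 2.0), (3.0, 4.0)
    base = fit_events(noise_free_signals(t_n, t_t),
                      DesignSpec(*sv.two_group_design(3, 3)))
    scaled = fit_events(
        noise_free_signals(t_n, t_t, affinities=(5.0, 0.25, 3.0)),
        DesignSpec(*sv.two_group_design(3, 3)))
    assert np.allclose(base.coef[0, 3:], scaled.coef[0, 3:], atol=1e-10)
    assert not np.allclose(base.coef[0, :3], scaled.coef[0, :3])


def test_contrast_sampling_variance_matches_closed_form():
    """Monte-Carlo variance of contrast estimates vs sigma^2 c'(X'X)^-1 c."""
    rng = np.random.default_rng(3)
    spec = DesignSpec(*sv.two_group_design(3, 3))
    sigma = 0.4
    n_rep = 5000
    X = spec.D_DRS
    Y = rng.normal(0.0, sigma, size=(n_rep, X.shape[0]))
    ps = PathSignals([f"E{i}" for i in range(n_rep)],
                     [f"s{j}" for j in range(6)],
                     Y.reshape(n_rep, 6, 3))
    fits = fit_events(ps, spec)
    mc_var = fits.contrast_est.var(axis=0, ddof=1)
    expected = sigma ** 2 * fits.contrast_var_factor
    assert np.allclose(mc_var, expected, rtol=0.10)


def test_too_few_samples_rejected():
    ps = noise_free_signals((4, 4), (4, 4), n=1)
    with pytest.raises(ValueError, match="3n"):
        fit_events(ps, DesignSpec(*sv.two_group_design(1, 1)))


# ---------------------------------------------------------------------------
# moderation

def test_identical_variances_fully_shrunk():
    s2 = np.full(100, 0.3)
    post, d0, s02 = moderate_variances(s2, df=6.0)
    assert np.isinf(d0)
    assert np.allclose(post, 0.3, atol=1e-12)
    assert abs(s02 - 0.3) < 1e-12


def test_hyperparameter_recovery_from_known_hierarchy():
    rng = np.random.default_rng(4)
    d0_true, s02_true, df = 4.0, 0.05, 6.0
    n = 10000
    sigma2 = s02_true * d0_true / rng.chisquare(d0_true, size=n)
    s2 = sigma2 * rng.chisquare(df, size=n) / df
    post, d0, s02 = moderate_variances(s2, df=df)
    assert abs(d0 - d0_true) / d0_true < 0.10
    assert abs(s02 - s02_true) / s02_true < 0.10


def test_extreme_variance_is_shrunk_towards_prior():
    rng = np.random.default_rng(5)
    sigma2 = 4.0 * 1.0 / rng.chisquare(4.0, size=500)  # real heterogeneity
    s2 = np.r_[sigma2 * rng.chisquare(6, size=500) / 6, 50.0]
    post, d0, s02 = moderate_variances(s2, df=6.0)
    assert np.isfinite(d0)
    assert s02 < post[-1] < 50.0
    # monotone shrinkage: order preserved
    assert np.all(np.argsort(post) == np.argsort(s2))


# ---------------------------------------------------------------------------
# combination, filter, SI, FDR

def test_combine_pvalues_reference_points():
    assert combine_pvalues(0.0, 0.0) == 0.0
    assert combine_pvalues(0.5, 0.5) == 1.0
    assert combine_pvalues(1.0, 1.0) == 0.0
    # frozen from the triangular tail: P(|S - 1| >= 0.8) with S = U1 + U2
    assert np.isclose(combine_pvalues(0.1, 0.1), 0.04)


def test_combine_pvalues_matches_monte_carlo_tail():
    rng = np.random.default_rng(6)
    s_obs = 0.2
    draws = rng.uniform(size=(10 ** 6, 2)).sum(axis=1)
    mc = (np.abs(draws - 1.0) >= abs(s_obs - 1.0)).mean()
    assert np.isclose(combine_pvalues(0.1, 0.1), mc, atol=3e-3)


def test_combine_pvalues_rejects_out_of_range():
    with pytest.raises(ValueError):
        combine_pvalues(-0.1, 0.5)
    with pytest.raises(ValueError):
        combine_pvalues(0.5, 1.2)


@given(st.floats(0, 1), st.floats(0, 1))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_combine_pvalues_bounds_property(pa, pb):
    s = pa + pb
    p = float(combine_pvalues(pa, pb))
    assert 0.0 <= p <= 1.0
    assert (p == 1.0) == (s == 1.0)


def _path_signals_from_maxima(ref, p1, p2):
    n_events = len(ref)
    values = np.zeros((n_events, 2, 3))
    values[:, 0, 0] = ref
    values[:, 0, 1] = p1
    values[:, 0, 2] = p2
    values[:, 1, :] = values[:, 0, :] - 1.0  # second sample always lower
    return PathSignals([f"E{i}" for i in range(n_events)], ["a", "b"],
                       values)


def test_expression_filter_hand_enumerated_fixture():
    ref = np.array([10, 9, 8, 7, 6, 5, 4, 3, 2, 1], dtype=float)
    p1 = np.array([9, 9, 9, 9, 1, 9, 9, 9, 9, 9], dtype=float)
    p2 = np.array([9, 9, 9, 2, 9, 9, 9, 9, 9, 9], dtype=float)
    ps = _path_signals_from_maxima(ref, p1, p2)
    expressed, thr = sv.expression_filter(ps, 0.5)
    # type-7 median of 1..10 = 5.5; events pass iff all maxima > 5.5
    assert thr == 5.5
    want = (ref > 5.5) & (p1 > 5.5) & (p2 > 5.5)
    assert np.array_equal(expressed, want)


def test_expression_filter_boundary_quantiles():
    ref = np.array([3.0, 2.0, 1.0])
    ps = _path_signals_from_maxima(ref, ref, ref)
    exp0, thr0 = sv.expression_filter(ps, 0.0)
    assert thr0 == 1.0 and list(exp0) == [True, True, False]
    exp1, thr1 = sv.expression_filter(ps, 1.0)
    assert thr1 == 3.0 and not exp1.any()
    with pytest.raises(ValueError):
        sv.expression_filter(ps, 1.5)


def test_splicing_index_reference_cases():
    cond1 = np.array([True, True, False, False])
    cond2 = ~cond1
    gene = np.array([5.0, 5.0, 5.0, 5.0])
    si, log_si = sv.splicing_index(gene, gene, cond1, cond2)
    assert np.isclose(si, 1.0) and np.isclose(log_si, 0.0)
    probeset = gene + np.array([1.0, 1.0, 0.0, 0.0])  # x2 in condition 1
    si2, _ = sv.splicing_index(probeset, gene, cond1, cond2)
    assert np.isclose(si2, 2.0)


def test_splicing_index_matches_direct_formula():
    rng = np.random.default_rng(7)
    probeset = rng.uniform(1, 10, size=6)
    gene = rng.uniform(1, 10, size=6)
    cond1 = np.array([True] * 3 + [False] * 3)
    si, _ = sv.splicing_index(probeset, gene, cond1, ~cond1,
                              log2_input=False)
    want = (probeset[:3].mean() / gene[:3].mean()) / \
           (probeset[3:].mean() / gene[3:].mean())
    assert np.isclose(si, want)


def bh_oracle(pvals):
    """Hand-coded step-up: p_(i) * m / i, cumulative min from the right."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def test_adjust_fdr_matches_hand_computation():
    p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.36]
    assert np.allclose(sv.adjust_fdr(p), bh_oracle(p), atol=1e-12)
    assert np.allclose(sv.adjust_fdr([1.0] * 5), 1.0)
    assert np.allclose(sv.adjust_fdr([0.37]), [0.37])


# ---------------------------------------------------------------------------
# table-level behavior

def test_results_table_paired_design_runs():
    """The same machinery accepts a blocked (paired) design unchanged."""
    rng = np.random.default_rng(8)
    n_pairs = 4
    D, C = sv.paired_design(n_pairs)
    signals, pmap, _, _ = sv.simulate_event_blocks(
        50, rng, n_per_cond=(n_pairs, n_pairs), t_tumor=(8.0, 2.0))
    res = sv.stats_pipeline(signals, pmap, D, C)
    assert len(res) == 50
    assert (res.pvalue < 1e-3).mean() > 0.9


def test_results_sorted_by_combined_pvalue(small_dataset):
    ds = small_dataset
    _, pmap, _, _ = sv.build_events_pipeline(ds.genes, ds.probes, ds.genome)
    res = sv.stats_pipeline(ds.signals, pmap, ds.design, ds.contrast)
    assert res.pvalue.is_monotonic_increasing
    assert set(res.columns) >= {
        "event_id", "logFC_path1", "logFC_path2", "p_path1", "p_path2",
        "pvalue_sum", "pvalue", "padj", "expressed"}
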