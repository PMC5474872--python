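"""Statistics layer: oracles, calibration and invariants."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import integrate, stats as sps
from scipy.special import betainc

from wmlquant import stats as st


# -- gaussianity gate ------------------------------------------------------

def test_gate_normal_data_mostly_passes():
    rng = np.random.default_rng(0)
    dec = [st.gaussianity_gate(rng.normal(size=50)) for _ in range(200)]
    assert dec.count("none") >= 180       # Shapiro at alpha=0.05 rejects ~5%


def test_gate_lognormal_goes_log10():
    rng = np.random.default_rng(1)
    dec = [st.gaussianity_gate(10 ** rng.normal(size=50)) for _ in range(200)]
    assert dec.count("log10") > 100


def test_gate_zero_blocks_log10():
    rng = np.random.default_rng(2)
    for _ in range(20):
        y = np.concatenate([[0.0], 10 ** rng.normal(size=49)])
        assert st.gaussianity_gate(y) != "log10"


def test_gate_small_n_forces_permutation():
    with pytest.warns(UserWarning):
        assert st.gaussianity_gate(np.arange(5.0)) == "permutation"


# -- ANCOVA ----------------------------------------------------------------

def _null_df(rng, n=50, covs=True):
    d = {"y": rng.normal(size=n), "g": ["a"] * (n // 2) + ["b"] * (n - n // 2)}
    if covs:
        d["age"] = rng.normal(60, 8, n)
        d["gender"] = rng.integers(0, 2, n)
    return pd.DataFrame(d)


def test_ancova_f_equals_squared_pooled_t():
    rng = np.random.default_rng(3)
    df = _null_df(rng, 24, covs=False)
    res = st.ancova(df, "y", "g")
    t, p = sps.ttest_ind(df.y[df.g == "a"], df.y[df.g == "b"])
    assert res.statistic == pytest.approx(t ** 2, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)


def test_ancova_null_p_uniform():
    rng = np.random.default_rng(4)
    ps = [st.ancova(_null_df(rng), "y", "g", ["age", "gender"]).p
          for _ in range(2000)]
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_ancova_log10_transform():
    rng = np.random.default_rng(5)
    df = _null_df(rng, 40)
    df["y"] = 10 ** df["y"]
    res = st.ancova(df, "y", "g", ["age"], transform="log10")
    assert res.method == "ancova_log10"
    df.loc[0, "y"] = 0.0
    with pytest.raises(ValueError):
        st.ancova(df, "y", "g", ["age"], transform="log10")


def test_ancova_degenerate_and_collinear():
    df = pd.DataFrame({"y": [1.0] * 10, "g": ["a"] * 5 + ["b"] * 5,
                       "age": np.arange(10.0)})
    with pytest.raises(ValueError, match="variance"):
        st.ancova(df, "y", "g", ["age"])
    df2 = pd.DataFrame({"y": np.random.default_rng(0).normal(size=10),
                        "g": ["a"] * 5 + ["b"] * 5, "age": np.arange(10.0)})
    df2["age2"] = df2["age"]
    with pytest.raises(ValueError, match="age"):
        st.ancova(df2, "y", "g", ["age", "age2"])


# -- permutation GLM -------------------------------------------------------

def test_permutation_exhaustive_matches_enumeration_oracle():
    """For n=6 the auto-exhaustive Freedman-Lane p equals a brute-force
    enumeration over all residual orderings, computed independently."""
    rng = np.random.default_rng(6)
    n = 6
    df = pd.DataFrame({"y": rng.normal(size=n), "g": ["a"] * 3 + ["b"] * 3,
                       "age": rng.normal(60, 5, n)})
    res = st.permutation_glm(df, "y", "g", ["age"], seed=0)
    assert res.extras["exhaustive"]

    X = np.column_stack([np.ones(n), (df.g == "b").astype(float), df.age])
    Z = X[:, [0, 2]]
    y = df.y.to_numpy()
    fit = Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = y - fit
    cov = np.linalg.inv(X.T @ X)

    def tstat(yy):
        b = np.linalg.lstsq(X, yy, rcond=None)[0]
        e = yy - X @ b
        return b[1] / math.sqrt((e @ e) / (n - 3) * cov[1, 1])

    tobs = abs(tstat(y))
    ts = [abs(tstat(fit + r[list(p)]))
          for p in itertools.permutations(range(n))]
    assert res.p == pytest.approx(np.mean(np.array(ts) >= tobs - 1e-12), abs=1e-12)


def test_permutation_seeded_determinism_and_floor():
    rng = np.random.default_rng(7)
    df = _null_df(rng, 30)
    a = st.permutation_glm(df, "y", "g", ["age"], n_permutations=500, seed=42,
                           exhaustive=False)
    b = st.permutation_glm(df, "y", "g", ["age"], n_permutations=500, seed=42,
                           exhaustive=False)
    assert a.p == b.p
    assert a.p >= 1.0 / 501


def test_permutation_null_calibration():
    """Empirical type-I error of the Freedman-Lane test at alpha=0.05
    stays within the binomial 99% band under a seeded null (1000 reps)."""
    rng = np.random.default_rng(8)
    rej = 0
    reps = 1000
    for i in range(reps):
        df = _null_df(rng, 30)
        p = st.permutation_glm(df, "y", "g", ["age", "gender"],
                               n_permutations=1000, seed=i, exhaustive=False).p
        rej += p <= 0.05
    band = 2.576 * math.sqrt(0.05 * 0.95 / reps)
    assert 0.05 - band <= rej / reps <= 0.05 + band


def test_ancova_and_permutation_agree_on_gaussian_data():
    rng = np.random.default_rng(9)
    agree = 0
    for i in range(30):
        df = _null_df(rng, 60)
        df["y"] += (df.g == "b") * 0.3
        pa = st.ancova(df, "y", "g", ["age"]).p
        pp = st.permutation_glm(df, "y", "g", ["age"], n_permutations=10_000,
                                seed=i, exhaustive=False).p
        agree += abs(pa - pp) <= 0.02
    assert agree >= 27       # >= 90% of replicates


# -- Bonferroni ------------------------------------------------------------

@settings(max_examples=50, deadline=None, derandomize=True)
@given(hst.lists(hst.floats(min_value=1e-12, max_value=1.0), min_size=1,
                 max_size=8))
def test_bonferroni_properties(ps):
    adj = st.bonferroni(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(adj <= 1.0)
    assert np.allclose(st.bonferroni(ps, m=1), ps)


def test_bonferroni_examples():
    assert st.bonferroni([0.01], m=4)[0] == pytest.approx(0.04)
    assert st.bonferroni([0.5], m=5)[0] == 1.0


# -- partial Spearman ------------------------------------------------------

def test_partial_spearman_no_covariates_is_classical():
    rng = np.random.default_rng(10)
    x = rng.normal(size=40)
    y = x + rng.normal(size=40)
    df = pd.DataFrame({"x": x, "y": y})
    res = st.partial_spearman(df, "x", "y")
    rho, p = sps.spearmanr(x, y)
    assert res.statistic == pytest.approx(rho, abs=1e-12)
    assert res.p == pytest.approx(p, rel=1e-6)


def test_partial_spearman_monotone_is_one():
    x = np.arange(20.0)
    df = pd.DataFrame({"x": x, "y": np.exp(x / 5)})
    assert st.partial_spearman(df, "x", "y").statistic == pytest.approx(1.0)


def test_partial_spearman_null_with_confounder():
    """x tracks the covariate and y is independent: the partial
    correlation is null-calibrated (~5% rejections)."""
    rng = np.random.default_rng(11)
    rej = 0
    for _ in range(500):
        z = rng.normal(size=40)
        df = pd.DataFrame({"x": z + 0.1 * rng.normal(size=40),
                           "y": rng.normal(size=40), "z": z})
        rej += st.partial_spearman(df, "x", "y", ["z"]).p <= 0.05
    assert 0.02 <= rej / 500 <= 0.08


def test_partial_spearman_constant_is_missing():
    df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
    res = st.partial_spearman(df, "x", "y")
    assert np.isnan(res.statistic)


# -- repeated measures -----------------------------------------------------

def test_rm_ancova_constant_shift_construction():
    rng = np.random.default_rng(12)
    n = 20
    left = rng.normal(10, 2, n)
    df = pd.DataFrame({"left": left, "right": left + 3.0,
                       "g": ["a"] * 10 + ["b"] * 10})
    out = st.rm_ancova(df, "left", "right", "g")
    assert out["interaction"].statistic == pytest.approx(0.0, abs=1e-12)
    assert out["hemisphere"].p < 1e-12   # the shift is exactly captured


def test_rm_ancova_matches_mixed_anova_oracle():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(13)
    n = 24
    g = np.repeat(["a", "b"], n // 2)
    left = rng.normal(10, 2, n) + (g == "b") * 1.0
    right = left + rng.normal(0.5, 1, n)
    df = pd.DataFrame({"left": left, "right": right, "g": g})
    out = st.rm_ancova(df, "left", "right", "g")
    long = pd.DataFrame({"subj": np.tile(np.arange(n), 2),
                         "hemi": np.repeat(["L", "R"], n),
                         "grp": np.tile(g, 2),
                         "y": np.concatenate([left, right])})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=long, dv="y", within="hemi", subject="subj",
                             between="grp").set_index("Source")
    assert out["group"].statistic == pytest.approx(aov.loc["grp", "F"], rel=1e-9)
    assert out["hemisphere"].statistic == pytest.approx(aov.loc["hemi", "F"], rel=1e-9)
    assert out["interaction"].statistic == pytest.approx(
        aov.loc["Interaction", "F"], rel=1e-9)


def test_rm_ancova_null_ps_uniform():
    rng = np.random.default_rng(14)
    ps = {"group": [], "hemisphere": [], "interaction": []}
    for _ in range(1000):
        n = 30
        df = pd.DataFrame({"left": rng.normal(size=n), "right": rng.normal(size=n),
                           "g": ["a"] * 15 + ["b"] * 15,
                           "age": rng.normal(60, 8, n)})
        out = st.rm_ancova(df, "left", "right", "g", ["age"])
        for k in ps:
            ps[k].append(out[k].p)
    for k, v in ps.items():
        assert sps.kstest(v, "uniform").pvalue > 0.01, k


# -- Liebermeister ---------------------------------------------------------

def _beta_oracle(a, b, c, d):
    f = lambda x: betainc(a + 1, b + 1, x) * sps.beta.pdf(x, c + 1, d + 1)
    v, _ = integrate.quad(f, 0, 1, epsabs=1e-12, epsrel=1e-12, limit=200)
    return v


def test_liebermeister_symmetry_and_extreme():
    assert st.liebermeister(3, 4, 3, 4)[0] == pytest.approx(0.5, abs=1e-12)
    assert st.liebermeister(0, 0, 0, 0)[0] == pytest.approx(0.5, abs=1e-12)
    one, two = st.liebermeister(10, 0, 0, 10)
    assert one < 1e-4
    assert two == pytest.approx(2 * one)


def test_liebermeister_closed_form_matches_beta_integration():
    """Closed-form hypergeometric tail equals numeric integration of the
    Beta posterior comparison, over a grid of small tables."""
    for a in range(0, 7):
        for b in range(0, 7 - a):
            for c in range(0, 7):
                for d in range(0, 7 - c):
                    p1 = st.liebermeister(a, b, c, d)[0]
                    assert p1 == pytest.approx(_beta_oracle(a, b, c, d), abs=1e-8)


def test_liebermeister_rejects_bad_cells():
    with pytest.raises(ValueError):
        st.liebermeister(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        st.liebermeister(0.5, 2, 3, 4)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(hst.integers(0, 12), hst.integers(0, 12), hst.integers(0, 12),
       hst.integers(0, 12))
def test_liebermeister_p_bounds_and_complement(a, b, c, d):
    one, two = st.liebermeister(a, b, c, d)
    assert 0.0 < one < 1.0
    assert one + st.liebermeister(c, d, a, b)[0] == pytest.approx(1.0, abs=1e-12)
    assert two <= 1.0


# -- voxel-wise ------------------------------------------------------------

def _random_maps(rng, n, shape, p):
    return list((rng.random((n,) + shape) < p).astype(np.uint8))


def test_voxelwise_presence_threshold_is_ceiling():
    rng = np.random.default_rng(15)
    maps = _random_maps(rng, 55, (4, 4, 2), 0.3)
    res = st.voxelwise_lesion_test(maps, ["a"] * 27 + ["b"] * 28,
                                   presence_min=0.10, n_permutations=50, seed=0)
    assert res.presence_threshold == 6          # ceil(0.10 * 55)
    stack = np.stack([m for m in maps]).sum(axis=0)
    assert ((stack >= 6) == res.mask).all()


def test_voxelwise_seeded_determinism():
    rng = np.random.default_rng(16)
    maps = _random_maps(rng, 20, (5, 5, 3), 0.3)
    groups = ["a"] * 10 + ["b"] * 10
    r1 = st.voxelwise_lesion_test(maps, groups, n_permutations=200, seed=3)
    r2 = st.voxelwise_lesion_test(maps, groups, n_permutations=200, seed=3)
    assert np.array_equal(r1.p_fwe_map, r2.p_fwe_map)


def test_voxelwise_corrected_never_below_raw():
    rng = np.random.default_rng(17)
    maps = _random_maps(rng, 30, (6, 6, 3), 0.25)
    res = st.voxelwise_lesion_test(maps, ["a"] * 15 + ["b"] * 15,
                                   n_permutations=300, seed=1)
    m = res.mask
    assert np.all(res.p_fwe_map[m] >= res.p_map[m] - 1e-12)


def test_voxelwise_empty_mask_reported():
    maps = [np.zeros((3, 3, 3), np.uint8) for _ in range(10)]
    res = st.voxelwise_lesion_test(maps, ["a"] * 5 + ["b"] * 5,
                                   n_permutations=50, seed=0)
    assert res.n_in_mask == 0
    assert (res.p_fwe_map == 1).all()


def test_voxelwise_detects_planted_focal_difference():
    """A strong focal group difference at 20 voxels is detected with
    FWE-corrected p <= 0.05 in most seeded replicates."""
    detected = 0
    for i in range(20):
        rng = np.random.default_rng(100 + i)
        maps = np.stack(_random_maps(rng, 30, (10, 10, 4), 0.15))
        flat = maps.reshape(30, -1)
        flat[15:, :20] |= (rng.random((15, 20)) < 0.6)
        res = st.voxelwise_lesion_test(list(maps), ["a"] * 15 + ["b"] * 15,
                                       n_permutations=300, seed=i)
        detected += (res.p_fwe_map.reshape(-1)[:20] <= 0.05).any()
    assert detected / 20 > 0.5
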