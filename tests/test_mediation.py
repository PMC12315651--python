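"""Simple and serial mediation: path algebra, bootstrap behavior, recovery."""

import numpy as np
import pytest

from scnmorph.mediation import mediate_serial, mediate_simple


def _chain_data(rng, n=300, a=0.5, b=0.4, cprime=0.2, noise=1.0):
    x = rng.normal(size=n)
    m = a * x + noise * rng.normal(size=n)
    y = b * m + cprime * x + noise * rng.normal(size=n)
    return x, m, y


def test_simple_near_deterministic_chain(rng):
    """M ~ 2X, Y ~ 3M in the vanishing-noise limit: a=2, b=3, indirect=6, c'=0.

    The exactly-deterministic chain is rank deficient (M is collinear with X
    in the outcome model), so a hierarchy of tiny noise scales is used: each
    downstream residual is far smaller than the identifying variation above it.
    """
    n = 200
    x = rng.normal(size=n)
    m = 2 * x + 1e-4 * rng.normal(size=n)
    y = 3 * m + 1e-8 * rng.normal(size=n)
    res = mediate_simple(x, m, y, n_boot=100, seed=0)
    assert res.paths["a"] == pytest.approx(2.0, abs=1e-4)
    assert res.paths["b"] == pytest.approx(3.0, abs=1e-4)
    assert res.indirect["a*b"] == pytest.approx(6.0, abs=1e-3)
    assert res.paths["c_prime"] == pytest.approx(0.0, abs=1e-3)


def test_serial_near_identity_chain(rng):
    """M1 ~ X, M2 ~ M1, Y ~ M2 in the vanishing-noise limit: a1=d21=b2=1,
    chained indirect=1, c'=0 (hierarchical noise scales for identifiability)."""
    n = 200
    x = rng.normal(size=n)
    m1 = x + 1e-2 * rng.normal(size=n)
    m2 = m1 + 1e-4 * rng.normal(size=n)
    y = m2 + 1e-8 * rng.normal(size=n)
    res = mediate_serial(x, m1, m2, y, n_boot=100, seed=0)
    for path in ("a1", "d21", "b2"):
        assert res.paths[path] == pytest.approx(1.0, abs=1e-2)
    assert res.indirect["a1*d21*b2"] == pytest.approx(1.0, abs=2e-2)
    assert res.paths["c_prime"] == pytest.approx(0.0, abs=2e-2)


@pytest.mark.parametrize("seed", range(5))
def test_decomposition_identity_exact(seed):
    """c = c' + total indirect to 1e-10 for every OLS fit, simple and serial."""
    rng = np.random.default_rng(seed)
    n = 120
    cov = rng.normal(size=(n, 3))
    x = rng.normal(size=n) + cov @ [0.2, 0, 0.1]
    m1 = 0.4 * x + rng.normal(size=n)
    m2 = 0.3 * x + 0.5 * m1 + rng.normal(size=n)
    y = 0.2 * x + 0.3 * m1 + 0.4 * m2 + cov @ [0.1, -0.2, 0] + rng.normal(size=n)
    rs = mediate_simple(x, m1, y, cov, n_boot=100, seed=seed)
    assert rs.paths["c"] == pytest.approx(rs.paths["c_prime"] + rs.indirect["a*b"], abs=1e-10)
    rr = mediate_serial(x, m1, m2, y, cov, n_boot=100, seed=seed)
    assert rr.paths["c"] == pytest.approx(
        rr.paths["c_prime"] + rr.indirect["total_indirect"], abs=1e-10
    )


def test_null_indirect_coverage():
    """b = 0 by construction: indirect CI covers 0 in >=90% of 50 simulations."""
    covered = 0
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        n = 150
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)  # independent of M given X
        res = mediate_simple(x, m, y, n_boot=200, seed=seed)
        lo, hi = res.ci["a*b"]
        covered += lo <= 0 <= hi
    assert covered >= 45


def test_serial_null_chained_indirect_coverage():
    """d21 = a2 = 0: chained indirect CI covers 0 in >=90% of 50 simulations."""
    covered = 0
    for seed in range(50):
        rng = np.random.default_rng(2000 + seed)
        n = 150
        x = rng.normal(size=n)
        m1 = 0.5 * x + rng.normal(size=n)
        m2 = rng.normal(size=n)  # no dependence on X or M1
        y = 0.3 * x + 0.2 * m1 + 0.4 * m2 + rng.normal(size=n)
        res = mediate_serial(x, m1, m2, y, n_boot=200, seed=seed)
        lo, hi = res.ci["a1*d21*b2"]
        covered += lo <= 0 <= hi
    assert covered >= 45


def test_point_estimate_recovery_within_mc_error():
    """a=0.5, b=0.4: mean point estimates across replicates near truth."""
    ests = []
    for seed in range(40):
        rng = np.random.default_rng(3000 + seed)
        x, m, y = _chain_data(rng, n=500)
        res = mediate_simple(x, m, y, n_boot=100, seed=seed)
        ests.append((res.paths["a"], res.paths["b"], res.indirect["a*b"]))
    mean = np.mean(ests, axis=0)
    se = np.std(ests, axis=0, ddof=1) / np.sqrt(len(ests))
    for got, truth, s in zip(mean, (0.5, 0.4, 0.2), se):
        assert abs(got - truth) < 3 * max(s, 1e-3)


def test_bootstrap_determinism_and_seed_sensitivity(rng):
    x, m, y = _chain_data(rng, n=200)
    r1 = mediate_simple(x, m, y, n_boot=200, seed=7)
    r2 = mediate_simple(x, m, y, n_boot=200, seed=7)
    assert r1.ci == r2.ci
    r3 = mediate_simple(x, m, y, n_boot=200, seed=8)
    assert r1.ci != r3.ci


def test_ci_width_shrinks_with_sample_size():
    """CI width ~ 1/sqrt(n): quadrupling n roughly halves the width."""
    widths = []
    for n in (200, 800, 3200):
        rng = np.random.default_rng(99)
        x, m, y = _chain_data(rng, n=n)
        res = mediate_simple(x, m, y, n_boot=400, seed=5)
        lo, hi = res.ci["a*b"]
        widths.append(hi - lo)
    for w_large_n, w_small_n in zip(widths[1:], widths[:-1]):
        ratio = w_large_n / w_small_n
        assert 0.3 < ratio < 0.75  # ~0.5 expected


def test_serial_mediator_order_matters(rng):
    """Relabeling M1/M2 on an asymmetric chain changes the chained indirect."""
    n = 400
    x = rng.normal(size=n)
    m1 = 0.8 * x + 0.3 * rng.normal(size=n)
    m2 = 0.9 * m1 + 0.3 * rng.normal(size=n)  # chain runs X -> M1 -> M2
    y = 0.7 * m2 + 0.3 * rng.normal(size=n)
    fwd = mediate_serial(x, m1, m2, y, n_boot=100, seed=1)
    rev = mediate_serial(x, m2, m1, y, n_boot=100, seed=1)
    assert abs(fwd.indirect["a1*d21*b2"] - rev.indirect["a1*d21*b2"]) > 0.05


def test_proportion_mediated_signed(rng):
    """Suppression yields proportions outside [0, 1], reported as-is."""
    n = 500
    x = rng.normal(size=n)
    m = 0.8 * x + 0.3 * rng.normal(size=n)
    y = -1.0 * m + 0.9 * x + 0.2 * rng.normal(size=n)  # opposing direct/indirect
    res = mediate_simple(x, m, y, n_boot=100, seed=3)
    assert res.proportion_mediated["a*b"] > 1 or res.proportion_mediated["a*b"] < 0


def test_bc_ci_and_standardize_options(rng):
    x, m, y = _chain_data(rng, n=300)
    res_bc = mediate_simple(x, m, y, n_boot=300, seed=2, ci_method="bc")
    for lo, hi in res_bc.ci.values():
        assert lo <= hi
    res_std = mediate_simple(x, m, y, n_boot=100, seed=2, standardize=True)
    # standardized a equals the Pearson correlation of x and m
    assert res_std.paths["a"] == pytest.approx(np.corrcoef(x, m)[0, 1], abs=1e-10)
    with pytest.raises(ValueError):
        mediate_simple(x, m, y, n_boot=100, ci_method="bogus")


def test_mediation_input_validation(rng):
    x = rng.normal(size=10)
    with pytest.raises(ValueError):
        mediate_simple(x, x[:5], x, n_boot=100)
    xs = rng.normal(size=6)
    with pytest.raises(ValueError):
        mediate_simple(xs, xs, xs, covariates=rng.normal(size=(6, 3)), n_boot=100)
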