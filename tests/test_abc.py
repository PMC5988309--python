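import numpy as np
import pandas as pd
import pytest

from sticklescan import abc as abcmod
from sticklescan import winstats
from sticklescan.abc import (
    SUMMARY_NAMES,
    ModelSpec,
    PriorSpec,
    ReferenceTable,
    build_reference_table,
    estimate_parameters,
    locus_summaries,
    pod_validate,
    sample_abc_loci,
    scaled_migration,
    select_model,
    simulate_summaries,
)
from sticklescan.gio import MISSING
from sticklescan.simdata import LocusSpec

from conftest import make_haps


# ---------------------------------------------------------------------------
# scaled migration
# ---------------------------------------------------------------------------

def test_scaled_migration_bottleneck_worked_value():
    # bottleneck-era Japan Sea size and the posterior-median migration
    # rate give ~0.03 expected migrants per generation
    val = scaled_migration(1.22e4, 1.3e-6)
    assert val == pytest.approx(2 * 1.22e4 * 1.3e-6, abs=1e-15)
    assert abs(val - 0.031) < 1e-3


@pytest.mark.parametrize("N,m,expected", [
    (5e5, 1e-6, 1.0),
    (1e4, 0.0, 0.0),
])
def test_scaled_migration_arithmetic(N, m, expected):
    assert scaled_migration(N, m) == pytest.approx(expected)


def test_scaled_migration_domain():
    with pytest.raises(ValueError):
        scaled_migration(-1, 1e-6)
    with pytest.raises(ValueError):
        scaled_migration(1e4, 1.0)


# ---------------------------------------------------------------------------
# locus sampling
# ---------------------------------------------------------------------------

def _sparse_haps():
    """5 grid loci on a 520-kb chromosome; loci 2 and 4 under-called.

    The bad loci carry 1,100 variant sites called in fewer than 14
    individuals, leaving only 900 callable bp (< the 1,000-bp floor).
    """
    rng = np.random.default_rng(0)
    n_haps = 40  # 20 single-haplotype samples per population
    sites, alleles = [], []
    for k in range(5):
        start = k * 125_000
        if k in (2, 4):
            pos = np.sort(rng.choice(np.arange(1, 2_000), 1_100,
                                     replace=False))
            block = rng.integers(0, 2, size=(1_100, n_haps)).astype(np.int8)
            block[:, :28] = MISSING  # only 12 of 40 samples called
        else:
            pos = np.sort(rng.choice(np.arange(1, 2_000), 10,
                                     replace=False))
            block = rng.integers(0, 2, size=(10, n_haps)).astype(np.int8)
        sites.append(pos + start)
        alleles.append(block)
    pops = ["JS"] * 20 + ["PO"] * 20
    return make_haps(np.vstack(alleles), pops, length=520_000,
                     positions=np.concatenate(sites))


def test_locus_filters_match_enumeration():
    haps = _sparse_haps()
    loci = sample_abc_loci(haps, locus_length=2_000, spacing=125_000,
                           min_length=1_000, min_samples=14, seed=0)
    assert len(loci) == 3


def test_locus_min_length_boundary_excludes_999bp():
    rng = np.random.default_rng(1)
    n_haps = 40
    # 1,001 bad variant sites leave 999 callable bp in a 2-kb locus
    pos = np.arange(1, 1_002)
    block = np.full((1_001, n_haps), MISSING, dtype=np.int8)
    block[:, 0] = 0
    pops = ["JS"] * 20 + ["PO"] * 20
    haps = make_haps(block, pops, length=2_000, positions=pos)
    with pytest.raises(ValueError):
        sample_abc_loci(haps, locus_length=2_000, spacing=125_000,
                        min_length=1_000, min_samples=14)


def test_spacing_larger_than_chromosome_gives_single_locus():
    rng = np.random.default_rng(2)
    block = rng.integers(0, 2, size=(5, 8)).astype(np.int8)
    haps = make_haps(block, ["JS"] * 4 + ["PO"] * 4, length=10_000,
                     positions=np.arange(1, 6))
    loci = sample_abc_loci(haps, locus_length=2_000, spacing=50_000,
                           min_length=100, min_samples=1)
    assert len(loci) == 1


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_identical_loci_have_zero_variances():
    rng = np.random.default_rng(3)
    block = rng.integers(0, 2, size=(12, 8)).astype(np.int8)
    h = make_haps(block, ["JS"] * 4 + ["PO"] * 4, length=2_000,
                  positions=np.arange(1, 13))
    vec = locus_summaries([h, h])
    var_part = vec[10:]
    assert np.allclose(var_part[np.isfinite(var_part)], 0.0)


def test_invariant_loci_summaries():
    h = make_haps(np.empty((0, 8), dtype=np.int8),
                  ["JS"] * 4 + ["PO"] * 4, length=2_000)
    vec = locus_summaries([h, h])
    named = dict(zip(SUMMARY_NAMES, vec))
    assert named["mean_pi_1"] == 0 and named["mean_thetaw_2"] == 0
    assert named["mean_shared"] == 0 and named["mean_private_1"] == 0
    assert np.isnan(named["mean_tajd_1"])  # excluded, not zero


def test_summaries_compose_from_winstats_oracles(im_loci):
    loci = im_loci[:3]
    vec = dict(zip(SUMMARY_NAMES, locus_summaries(loci)))
    pi1 = [winstats.pi_window(h, "JS") for h in loci]
    td1 = [winstats.tajimas_d(h, "JS") for h in loci]
    fst = [winstats.wc_fst(h, "JS", "PO") for h in loci]
    assert vec["mean_pi_1"] == pytest.approx(np.mean(pi1))
    assert vec["mean_tajd_1"] == pytest.approx(np.nanmean(td1))
    assert vec["mean_fst"] == pytest.approx(np.nanmean(fst))
    assert vec["var_pi_1"] == pytest.approx(np.var(pi1, ddof=1))


# ---------------------------------------------------------------------------
# reference table and rejection
# ---------------------------------------------------------------------------

def tiny_spec():
    return LocusSpec(n_loci=10, locus_length=2_000,
                     samples_per_pop={"JS": 6, "PO": 6})


def test_reference_table_shape_and_param_columns():
    models = [ModelSpec("I", "constant"), ModelSpec("IM", "constant")]
    table = build_reference_table(models, 3, tiny_spec(), seed=1)
    assert len(table.frame) == 6
    assert sorted(table.frame["model"].value_counts().to_dict().items()) == [
        ("I+constant", 3), ("IM+constant", 3)]
    assert "param:T" in table.frame.columns


def test_near_point_mass_priors_pin_parameter_columns():
    priors = {"T": PriorSpec(1e5, 1.0001e5),
              "N_JS": PriorSpec(1e4, 1.0001e4),
              "N_PO": PriorSpec(1e4, 1.0001e4),
              "N_ANC": PriorSpec(1e4, 1.0001e4),
              "T_G_frac": PriorSpec(0.49, 0.51, family="uniform")}
    model = ModelSpec("I", "constant", priors=priors)
    table = build_reference_table([model], 4, tiny_spec(), seed=2)
    T = table.frame["param:T"]
    assert T.max() / T.min() < 1.001


def _synthetic_table(centers, n=200, seed=0, spread=0.5):
    """Reference table built directly from Gaussian summary clouds."""
    rng = np.random.default_rng(seed)
    rows = []
    for name, mu in centers.items():
        X = rng.normal(mu, spread, size=(n, 20))
        for k in range(n):
            row = {"model": name, "param:T": float(mu[0])}
            row.update(dict(zip(SUMMARY_NAMES, X[k])))
            rows.append(row)
    return ReferenceTable(pd.DataFrame(rows))


def test_separated_clouds_yield_confident_posterior():
    mu_a = np.zeros(20)
    mu_b = np.full(20, 8.0)
    table = _synthetic_table({"A": mu_a, "B": mu_b})
    post = select_model(mu_b, table, tolerance=0.05)
    assert post["B"] > 0.95
    assert sum(post.values()) == pytest.approx(1.0)


def test_identical_simulators_split_posterior():
    mu = np.zeros(20)
    table = _synthetic_table({"A": mu, "B": mu}, n=400, seed=3)
    post = select_model(np.zeros(20), table, tolerance=0.25)
    assert post["A"] == pytest.approx(0.5, abs=0.15)


def test_posteriors_sum_to_one_across_tolerances():
    table = _synthetic_table({"A": np.zeros(20), "B": np.ones(20)})
    for tol in (0.001, 0.005, 0.01, 0.03):
        post = select_model(np.zeros(20), table, tolerance=tol)
        assert sum(post.values()) == pytest.approx(1.0)


def test_acceptance_is_nested_across_tolerances():
    table = _synthetic_table({"A": np.zeros(20)})
    obs = np.full(20, 0.3)
    sets = []
    for tol in (0.005, 0.01, 0.03, 0.1):
        idx, _ = abcmod._accept(obs, table, tol)
        sets.append(set(idx.tolist()))
    for small, big in zip(sets, sets[1:]):
        assert small <= big


def test_point_mass_posterior_median_is_the_point():
    mu = np.zeros(20)
    table = _synthetic_table({"A": mu}, n=100)
    est = estimate_parameters(mu, table, tolerance=0.3)
    assert est.loc["T", "median"] == pytest.approx(0.0)


def test_estimate_requires_single_model_table():
    table = _synthetic_table({"A": np.zeros(20), "B": np.ones(20)})
    with pytest.raises(ValueError):
        estimate_parameters(np.zeros(20), table, tolerance=0.1)


# ---------------------------------------------------------------------------
# POD validation
# ---------------------------------------------------------------------------

def strong_migration_models():
    shared = {
        "N_JS": PriorSpec(1e3, 1e6), "N_PO": PriorSpec(1e3, 1e6),
        "N_ANC": PriorSpec(1e3, 1e6), "T": PriorSpec(1e4, 1e7),
        "T_G_frac": PriorSpec(0.4, 0.6, family="uniform"),
    }
    mig = dict(shared)
    mig["m12"] = PriorSpec(1e-5, 1e-4)
    mig["m21"] = PriorSpec(1e-5, 1e-4)
    return [ModelSpec("I", "constant", priors=dict(shared)),
            ModelSpec("IM", "constant", priors=mig)]


def test_isolation_vs_strong_migration_pods_recover_truth():
    models = strong_migration_models()
    spec = LocusSpec(n_loci=40, locus_length=2_000,
                     samples_per_pop={"JS": 10, "PO": 10})
    conf = pod_validate(models, 10, 200, spec, tolerance=0.02, seed=5)
    M = conf.to_numpy()
    assert np.trace(M) / M.sum() >= 0.7


def test_pod_matrix_rows_sum_and_determinism():
    models = strong_migration_models()
    spec = tiny_spec()
    c1 = pod_validate(models, 3, 30, spec, tolerance=0.1, seed=9)
    c2 = pod_validate(models, 3, 30, spec, tolerance=0.1, seed=9)
    assert (c1.sum(axis=1) == 3).all()
    assert c1.equals(c2)
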