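import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sticklescan import detect
from sticklescan.detect import (
    HmmConfig,
    ValleySet,
    cluster_outlier_windows,
    fit_hmm_classify,
    gene_overlap_enrichment,
    permutation_independence_test,
    permutation_threshold,
)
from sticklescan.gio import WindowConfig
from sticklescan.winstats import dxy_stats

from conftest import make_haps


# ---------------------------------------------------------------------------
# HMM classification
# ---------------------------------------------------------------------------

def planted_track(seed=0, n=500, runs=((50, 60), (200, 230), (400, 410)),
                  mu_bg=0.85, mu_valley=0.30, sd=0.05):
    rng = np.random.default_rng(seed)
    truth = np.zeros(n, dtype=int)
    for s, e in runs:
        truth[s:e] = 1
    logit_bg = np.log(mu_bg / (1 - mu_bg))
    logit_v = np.log(mu_valley / (1 - mu_valley))
    obs = np.where(truth == 1, rng.normal(logit_v, sd, n),
                   rng.normal(logit_bg, sd, n))
    return expit(obs), truth


def test_hmm_transition_initialisation_is_09_01():
    cfg = HmmConfig()
    assert cfg.p_stay == 0.9 and cfg.p_switch == 0.1
    with pytest.raises(ValueError):
        HmmConfig(p_stay=0.9, p_switch=0.2)


def test_hmm_recovers_planted_valleys_with_high_accuracy():
    vals, truth = planted_track()
    states, info = fit_hmm_classify(vals, HmmConfig())
    assert (states == truth).mean() >= 0.99
    assert info["converged"]


def test_hmm_constant_track_is_single_background_state():
    states, info = fit_hmm_classify(np.full(50, 0.8), HmmConfig())
    assert np.all(states == 0)


def test_hmm_missing_windows_get_no_state():
    vals, truth = planted_track(n=300, runs=((100, 130),))
    vals[40:60] = np.nan
    states, _ = fit_hmm_classify(vals, HmmConfig())
    assert np.all(states[40:60] == -1)
    mask = np.isfinite(vals)
    assert (states[mask] == truth[mask]).mean() >= 0.98


def test_hmm_peak_mode_labels_high_state():
    rng = np.random.default_rng(1)
    truth = np.zeros(200, dtype=int)
    truth[80:100] = 1
    vals = np.where(truth == 1, rng.normal(0.6, 0.05, 200),
                    rng.normal(0.05, 0.05, 200))
    cfg = HmmConfig(transform="identity", mode="peak")
    states, _ = fit_hmm_classify(vals, cfg)
    assert (states == truth).mean() >= 0.99


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _win_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gmin"])


def test_cluster_merges_windows_within_30kb():
    df = _win_df([("chr1", 0, 10_000, 0.1), ("chr1", 20_000, 30_000, 0.2)])
    vs = cluster_outlier_windows(df, gap=30_000, stat_col="gmin")
    assert len(vs) == 1
    iv = vs.intervals.iloc[0]
    assert (iv["start"], iv["end"], iv["length"]) == (0, 30_000, 30_000)
    assert iv["n_windows"] == 2
    assert iv["extreme"] == 0.1


def test_cluster_splits_windows_past_the_gap():
    df = _win_df([("chr1", 0, 10_000, 0.1), ("chr1", 50_000, 60_000, 0.2)])
    vs = cluster_outlier_windows(df, gap=30_000, stat_col="gmin")
    assert len(vs) == 2


def test_single_outlier_window_makes_a_10kb_valley():
    df = _win_df([("chr1", 40_000, 50_000, 0.3)])
    vs = cluster_outlier_windows(df, gap=30_000, stat_col="gmin")
    assert len(vs) == 1
    assert vs.intervals.iloc[0]["length"] == 10_000


def test_valley_intervals_never_overlap():
    rng = np.random.default_rng(7)
    starts = np.sort(rng.choice(np.arange(0, 100) * 10_000, 40,
                                replace=False))
    df = _win_df([("chr1", int(s), int(s) + 10_000, 0.5) for s in starts])
    vs = cluster_outlier_windows(df)
    iv = vs.intervals
    assert (iv["start"].values[1:] >= iv["end"].values[:-1]).all()
    assert vs.total_length() <= 1_000_000


# ---------------------------------------------------------------------------
# permutation threshold
# ---------------------------------------------------------------------------

def test_constant_distance_null_cutoff_equals_the_constant():
    # every haplotype pair differs at exactly half the sites, at every
    # site ordering: the permuted G_MIN null is degenerate at g
    A = np.array([[0, 0, 1, 1], [0, 1, 1, 0]] * 10, dtype=np.int8)
    h = make_haps(A, ["A", "A", "B", "B"], length=10_000,
                  positions=np.arange(1, 21) * 450)
    cfg = WindowConfig(size=10_000, min_usable_sites=5_000)
    g = dxy_stats(h, "A", "B")[2]
    thr = permutation_threshold(h, "A", "B", cfg, n_permutations=5, seed=0)
    finite = {b: c for b, c in thr.cutoffs.items() if np.isfinite(c)}
    assert finite
    for cutoff in finite.values():
        assert cutoff == pytest.approx(g)


def test_permutation_threshold_is_deterministic_per_seed(im_loci):
    from sticklescan.simdata import concat_loci

    cat = concat_loci(im_loci, spacing=2_000)
    cfg = WindowConfig(size=2_000, min_usable_sites=1)
    bins = (1, 1_000, 2_000)
    t1 = permutation_threshold(cat, "JS", "PO", cfg, 5, seed=3, bins=bins)
    t2 = permutation_threshold(cat, "JS", "PO", cfg, 5, seed=3, bins=bins)
    assert t1.cutoffs.keys() == t2.cutoffs.keys()
    assert np.allclose(list(t1.cutoffs.values()),
                       list(t2.cutoffs.values()), equal_nan=True)
    assert any(np.isfinite(v) for v in t1.cutoffs.values())


def test_whole_chromosome_window_null_matches_direct_enumeration():
    # with one window spanning everything, site order is irrelevant, so
    # every permutation reproduces the observed G_MIN exactly
    rng = np.random.default_rng(4)
    A = rng.integers(0, 2, size=(30, 6)).astype(np.int8)
    h = make_haps(A, ["A"] * 3 + ["B"] * 3, length=6_000,
                  positions=np.sort(rng.choice(np.arange(1, 6_001), 30,
                                               replace=False)))
    cfg = WindowConfig(size=6_000, min_usable_sites=5_000)
    expected = dxy_stats(h, "A", "B")[2]
    thr = permutation_threshold(h, "A", "B", cfg, n_permutations=4, seed=1)
    finite = [c for c in thr.cutoffs.values() if np.isfinite(c)]
    assert finite == [pytest.approx(expected)]


# ---------------------------------------------------------------------------
# permutation independence test
# ---------------------------------------------------------------------------

def test_identical_groups_give_large_p():
    vals = np.arange(10.0)
    stat, p = permutation_independence_test(vals, vals, n_perm=500, seed=0)
    assert stat == 0.0
    assert p >= 0.5


def test_small_groups_match_exhaustive_enumeration():
    a, b = [1.0, 2.0], [10.0, 11.0]
    # enumerate all C(4,2) = 6 assignments of labels to the pooled values
    pool = a + b
    obs = np.mean(a) - np.mean(b)
    stats = []
    for pick in itertools.combinations(range(4), 2):
        ga = [pool[i] for i in pick]
        gb = [pool[i] for i in range(4) if i not in pick]
        stats.append(np.mean(ga) - np.mean(gb))
    exact = np.mean([s <= obs for s in stats])
    _, p = permutation_independence_test(a, b, n_perm=20_000, seed=1,
                                         alternative="less")
    assert p == pytest.approx(exact, abs=0.02)


def test_permutation_test_determinism_and_validation():
    a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    r1 = permutation_independence_test(a, b, 200, seed=5)
    r2 = permutation_independence_test(a, b, 200, seed=5)
    assert r1 == r2
    with pytest.raises(ValueError):
        permutation_independence_test(a, b, n_perm=0)
    with pytest.raises(ValueError):
        permutation_independence_test(a, [], n_perm=10)


# ---------------------------------------------------------------------------
# gene overlap enrichment
# ---------------------------------------------------------------------------

def _valleys(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["n_windows"] = 1
    df["length"] = df["end"] - df["start"]
    df["extreme"] = np.nan
    df["min_pair"] = None
    return ValleySet(df)


def test_no_gene_overlap_gives_p_one():
    vs = _valleys([("chr1", 0, 10_000)])
    genes = pd.DataFrame(columns=["chrom", "start", "end", "name"])
    obs, null, p = gene_overlap_enrichment(vs, genes, {"chr1": 100_000},
                                           n_draws=50, seed=0)
    assert obs == 0 and p == 1.0


def test_genes_only_in_valleys_give_minimal_p():
    vs = _valleys([("chr1", 0, 10_000)])
    genes = pd.DataFrame([("chr1", 2_000, 3_000, "g1")],
                         columns=["chrom", "start", "end", "name"])
    obs, null, p = gene_overlap_enrichment(vs, genes, {"chr1": 1_000_000},
                                           n_draws=200, seed=0)
    assert obs == 1
    assert (null == 0).all()
    assert p == pytest.approx(1 / 201)


def test_toy_enrichment_matches_enumeration():
    # 3 genes, 2 inside the single valley; null draws land uniformly on
    # the non-valley 90% of the chromosome where one gene lies
    vs = _valleys([("chr1", 0, 10_000)])
    genes = pd.DataFrame(
        [("chr1", 1_000, 2_000, "g1"), ("chr1", 5_000, 6_000, "g2"),
         ("chr1", 50_000, 51_000, "g3")],
        columns=["chrom", "start", "end", "name"],
    )
    obs, null, p = gene_overlap_enrichment(vs, genes, {"chr1": 100_000},
                                           n_draws=2_000, seed=2)
    assert obs == 2
    # a 10-kb null window overlaps g3 iff its start is in
    # (40,000, 51,000) minus the valley-overlap exclusion; every draw
    # yields 0 or 1 genes, so P(null >= 2) = 0 and p = 1/(n+1)
    assert null.max() <= 1
    assert p == pytest.approx(1 / 2_001)
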