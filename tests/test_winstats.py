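import dendropy
import numpy as np
import pytest
from dendropy.calculate import popgenstat

from sticklescan.gio import MISSING, WindowConfig
from sticklescan.winstats import (
    dxy_stats,
    pi_window,
    scan_windows,
    tajimas_d,
    wc_fst,
    wc_fst_counts,
)

from conftest import make_haps


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST oracle: direct per-site variance components
# ---------------------------------------------------------------------------

def wc_oracle(derived, sizes):
    """Component-by-component variance-components estimator.

    Follows the allele-level random-effects ANOVA definitions literally
    (per-site MSP/MSG, n_c correction, ratio of summed components);
    written independently of the library implementation.
    """
    a_sum = b_sum = 0.0
    for (d1, d2), (n1, n2) in zip(derived, sizes):
        r = 2
        p1, p2 = d1 / n1, d2 / n2
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        pbar = (d1 + d2) / (n1 + n2)
        msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - r)
        a_sum += (msp - msg) / nc
        b_sum += msg
    return a_sum / (a_sum + b_sum)


def test_fixed_difference_matches_variance_component_oracle():
    derived = [(0, 20)]
    sizes = [(20, 20)]
    assert wc_fst_counts(derived, sizes) == pytest.approx(
        wc_oracle(derived, sizes), abs=1e-12
    )
    assert wc_fst_counts(derived, sizes) == pytest.approx(1.0)


def test_multisite_fst_is_ratio_of_sums_not_mean_of_ratios():
    derived = [(3, 15), (10, 2), (0, 8), (7, 7), (1, 19)]
    sizes = [(20, 20)] * 5
    ours = wc_fst_counts(derived, sizes)
    assert ours == pytest.approx(wc_oracle(derived, sizes), abs=1e-12)
    per_site = np.mean([wc_oracle([d], [s])
                        for d, s in zip(derived, sizes)])
    assert ours != pytest.approx(per_site, abs=1e-3)


def test_no_differentiation_gives_nonpositive_small_fst():
    rng = np.random.default_rng(0)
    n = 200
    derived = [(int(c), int(c)) for c in rng.integers(1, n, size=50)]
    sizes = [(n, n)] * 50
    assert wc_fst_counts(derived, sizes) <= 0.02


def test_wc_fst_no_usable_sites_is_flagged_missing():
    h = make_haps(np.empty((0, 4), dtype=np.int8), ["A", "A", "B", "B"])
    assert np.isnan(wc_fst(h, "A", "B"))


# ---------------------------------------------------------------------------
# d_XY / G_MIN
# ---------------------------------------------------------------------------

def test_dxy_full_pair_enumeration():
    # A = {00, 01}, B = {11, 10}: pair distances {1, 0.5, 0.5, 1}
    h = make_haps([[0, 0, 1, 1],
                   [0, 1, 1, 0]], ["A", "A", "B", "B"], length=2)
    dxy, dmin, gmin, pair = dxy_stats(h, "A", "B")
    assert dxy == pytest.approx(0.75)
    assert dmin == pytest.approx(0.5)
    assert gmin == pytest.approx(2 / 3)
    # ties (two pairs at 0.5) resolve to the lexicographically smallest
    assert pair == ("A_0#0", "B_3#3")


def test_single_pair_full_divergence():
    h = make_haps([[0, 1]] * 4, ["A", "B"], length=4)
    dxy, dmin, gmin, _ = dxy_stats(h, "A", "B")
    assert dxy == 1.0 and gmin == 1.0


def test_recent_migrant_haplotype_zeroes_gmin():
    h = make_haps([[0, 0, 1, 0],
                   [0, 0, 1, 0],
                   [0, 1, 1, 1]], ["A", "A", "B", "B"], length=3)
    _, dmin, gmin, _ = dxy_stats(h, "A", "B")
    assert dmin == 0.0 and gmin == 0.0


def test_gmin_invariant_to_haplotype_relabeling():
    rng = np.random.default_rng(3)
    A = rng.integers(0, 2, size=(30, 8)).astype(np.int8)
    pops = ["A"] * 4 + ["B"] * 4
    h = make_haps(A, pops, length=30)
    perm = np.r_[rng.permutation(4), 4 + rng.permutation(4)]
    h2 = make_haps(A[:, perm], pops, length=30)
    assert dxy_stats(h, "A", "B")[2] == pytest.approx(
        dxy_stats(h2, "A", "B")[2])


def test_dxy_additivity_over_concatenated_windows():
    rng = np.random.default_rng(5)
    A = rng.integers(0, 2, size=(40, 6)).astype(np.int8)
    h = make_haps(A, ["A"] * 3 + ["B"] * 3, length=40)
    d_all = dxy_stats(h, "A", "B", window=(0, 40))[0]
    d1 = dxy_stats(h, "A", "B", window=(0, 25))[0]
    d2 = dxy_stats(h, "A", "B", window=(25, 40))[0]
    assert d_all == pytest.approx((25 * d1 + 15 * d2) / 40)


def test_dxy_pairwise_deletion_of_missing():
    h = make_haps([[0, MISSING, 1, 1],
                   [0, 0, 1, 1]], ["A", "A", "B", "B"], length=2)
    dxy, dmin, _, _ = dxy_stats(h, "A", "B", min_call_frac=0.5)
    # pairs: (0,2)=1, (0,3)=1, (1,2)=1/1 (site 1 deleted), (1,3)=1
    assert dxy == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def test_tajimas_d_monomorphic_is_flagged_missing():
    h = make_haps(np.zeros((5, 10), dtype=np.int8), ["P"] * 10, length=5)
    assert np.isnan(tajimas_d(h, "P"))


def test_tajimas_d_matches_dendropy_oracle():
    rng = np.random.default_rng(2)
    for n_haps in (4, 8):
        A = (rng.random((12, n_haps)) < 0.4).astype(np.int8)
        h = make_haps(A, ["P"] * n_haps, length=12)
        seqs = {
            f"t{j}": "".join("T" if A[i, j] else "A" for i in range(12))
            for j in range(n_haps)
        }
        cm = dendropy.DnaCharacterMatrix.from_dict(seqs)
        expected = popgenstat.tajimas_d(cm)
        assert tajimas_d(h, "P") == pytest.approx(expected, abs=1e-9)


def test_tajimas_d_negative_under_expansion():
    from sticklescan import simdata

    params = simdata.DemographicParams(
        scenario="I", m12=0, m21=0, growth="growth",
        T=1e6, T_G=2e4, N_JS=2e5, N_PO=1e4, N_ANC=1e4, N_JSB=2e3,
    )
    spec = simdata.LocusSpec(n_loci=60, locus_length=5_000,
                             samples_per_pop={"JS": 12})
    loci = simdata.simulate_demography(params, spec, seed=3)
    vals = [tajimas_d(h, "JS") for h in loci]
    assert np.nanmean(vals) < 0


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------

def _haps_with_unusable_sites(n_bad):
    """Length-10,000 window with n_bad all-missing variant sites."""
    rng = np.random.default_rng(1)
    n_good = 30
    S = n_good + n_bad
    A = rng.integers(0, 2, size=(S, 8)).astype(np.int8)
    A[n_good:, :] = MISSING
    pos = np.sort(rng.choice(np.arange(1, 10_001), size=S, replace=False))
    return make_haps(A, ["A"] * 4 + ["B"] * 4, length=10_000,
                     positions=pos)


def test_scan_eligibility_is_strictly_more_than_half():
    cfg = WindowConfig(size=10_000, min_usable_sites=5_001)
    ineligible = scan_windows(_haps_with_unusable_sites(5_000),
                              "A", "B", cfg)
    assert ineligible.loc[0, "n_usable"] == 5_000
    assert np.isnan(ineligible.loc[0, "gmin"])
    eligible = scan_windows(_haps_with_unusable_sites(4_999), "A", "B", cfg)
    assert eligible.loc[0, "n_usable"] == 5_001
    assert np.isfinite(eligible.loc[0, "gmin"])


def test_scan_windows_decompose_to_single_window_calls(im_loci):
    from sticklescan.simdata import concat_loci

    cat = concat_loci(im_loci[:6], spacing=2_000)
    cfg = WindowConfig(size=2_000, min_usable_sites=1)
    df = scan_windows(cat, "JS", "PO", cfg)
    assert len(df) == 6
    for _, row in df.iterrows():
        win = (row["start"], row["end"])
        assert row["fst"] == pytest.approx(
            wc_fst(cat, "JS", "PO", win), nan_ok=True)
        dxy, _, gmin, _ = dxy_stats(cat, "JS", "PO", win)
        assert row["dxy"] == pytest.approx(dxy, nan_ok=True)
        assert row["gmin"] == pytest.approx(gmin, nan_ok=True)
        assert row["pi_1"] == pytest.approx(
            pi_window(cat, "JS", win), nan_ok=True)
        assert row["tajd_1"] == pytest.approx(
            tajimas_d(cat, "JS", win), nan_ok=True)
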