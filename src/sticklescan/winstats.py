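"""Per-window divergence and diversity statistics.

All statistics operate on a :class:`~sticklescan.gio.HaplotypeMatrix`
slice.  A window's *usable* site count is its length in bp minus the
variant sites whose call rate falls below the configured fraction
(invariant bases are assumed callable, matching consensus-sequence
practice); per-site statistics divide by usable sites, with pairwise
deletion of missing data in haplotype distances.

``F_ST`` is the Weir & Cockerham variance-components estimator combined
across sites as a ratio of summed components; it is computed at the
haplotype (allele) level, appropriate for (pseudo-)phased data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import MISSING, HaplotypeMatrix, WindowConfig

__all__ = [
    "WindowStatRecord",
    "wc_fst_counts",
    "wc_fst",
    "dxy_stats",
    "pi_window",
    "tajimas_d",
    "tajima_constants",
    "scan_windows",
]


@dataclass
class WindowStatRecord:
    chrom: str
    start: int
    end: int
    n_usable: int
    fst: float = np.nan
    dxy: float = np.nan
    dxy_min: float = np.nan
    gmin: float = np.nan
    min_pair: tuple | None = None
    pi_1: float = np.nan
    pi_2: float = np.nan
    tajd_1: float = np.nan
    tajd_2: float = np.nan


# ---------------------------------------------------------------------------
# usable sites
# ---------------------------------------------------------------------------

def usable_site_mask(haps: HaplotypeMatrix, min_call_frac: float = 1.0
                     ) -> np.ndarray:
    """Mask of variant sites with call rate >= ``min_call_frac``."""
    called = haps.alleles != MISSING
    if haps.n_sites == 0:
        return np.empty(0, dtype=bool)
    return called.mean(axis=1) >= min_call_frac


def n_usable_sites(haps: HaplotypeMatrix, min_call_frac: float = 1.0) -> int:
    """Usable bases in the matrix's span: length minus low-call variant sites."""
    mask = usable_site_mask(haps, min_call_frac)
    return int(haps.length - (~mask).sum())


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_fst_counts(derived, sizes):
    """Weir-Cockerham theta from per-site allele counts.

    Parameters
    ----------
    derived : ndarray (n_sites, n_pops)
        Derived-allele counts per population.
    sizes : ndarray (n_sites, n_pops)
        Called allele (haplotype) counts per population.

    Returns the multi-site ratio-of-sums estimator
    ``sum(a) / sum(a + b)`` of the among/within variance components of
    the allele-level random-effects ANOVA; may be slightly negative.
    Sites where any population has fewer than two called alleles are
    skipped; returns NaN if no site contributes.
    """
    derived = np.atleast_2d(np.asarray(derived, dtype=float))
    sizes = np.atleast_2d(np.asarray(sizes, dtype=float))
    r = derived.shape[1]
    ok = (sizes >= 2).all(axis=1)
    if not ok.any():
        return np.nan
    derived, sizes = derived[ok], sizes[ok]
    n_tot = sizes.sum(axis=1)
    p = derived / sizes
    pbar = derived.sum(axis=1) / n_tot
    n_c = (n_tot - (sizes**2).sum(axis=1) / n_tot) / (r - 1)
    msp = (sizes * (p - pbar[:, None]) ** 2).sum(axis=1) / (r - 1)
    msg = (sizes * p * (1 - p)).sum(axis=1) / (n_tot - r)
    a = (msp - msg) / n_c
    b = msg
    denom = (a + b).sum()
    if denom == 0:
        return np.nan
    return float(a.sum() / denom)


def wc_fst(haps: HaplotypeMatrix, pop1: str, pop2: str, window=None) -> float:
    """Windowed Weir-Cockerham F_ST between two populations."""
    if window is not None:
        haps = haps.slice_window(window)
    out = []
    for pop in (pop1, pop2):
        cols = haps.haplotype_indices(pop)
        sub = haps.alleles[:, cols]
        called = sub != MISSING
        out.append((np.where(called, sub, 0).sum(axis=1),
                    called.sum(axis=1)))
    derived = np.stack([out[0][0], out[1][0]], axis=1)
    sizes = np.stack([out[0][1], out[1][1]], axis=1)
    if derived.shape[0] == 0:
        return np.nan
    return wc_fst_counts(derived, sizes)


# ---------------------------------------------------------------------------
# d_XY, minimum d_XY, G_MIN
# ---------------------------------------------------------------------------

def dxy_stats(haps: HaplotypeMatrix, pop1: str, pop2: str, window=None,
              min_call_frac: float = 1.0):
    """Mean and minimum inter-population haplotype divergence.

    Every inter-population haplotype pair contributes its per-site
    difference count over its own usable denominator (pairwise deletion:
    window length minus sites missing in either member).  Returns
    ``(dxy, dxy_min, gmin, min_pair)``; ``gmin = dxy_min / dxy`` is NaN
    when ``dxy == 0`` and ``min_pair`` is the lexicographically smallest
    pair attaining the minimum.
    """
    if window is not None:
        haps = haps.slice_window(window)
    mask = usable_site_mask(haps, min_call_frac)
    L_usable = haps.length - int((~mask).sum())
    if L_usable <= 0:
        return np.nan, np.nan, np.nan, None
    cols1 = haps.haplotype_indices(pop1)
    cols2 = haps.haplotype_indices(pop2)
    A = haps.alleles[np.ix_(mask.nonzero()[0], cols1)].astype(np.int16)
    B = haps.alleles[np.ix_(mask.nonzero()[0], cols2)].astype(np.int16)
    okA = A != MISSING
    okB = B != MISSING
    # pair-wise over (i in A, j in B)
    both = okA[:, :, None] & okB[:, None, :]
    diff = (A[:, :, None] != B[:, None, :]) & both
    n_diff = diff.sum(axis=0, dtype=np.int64)              # (|A|, |B|)
    n_unusable_pair = (~both).sum(axis=0, dtype=np.int64)  # missing sites/pair
    denom = L_usable - n_unusable_pair
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, n_diff / np.maximum(denom, 1), np.nan)
    if np.all(np.isnan(d)):
        return np.nan, np.nan, np.nan, None
    dxy = float(np.nanmean(d))
    dmin = float(np.nanmin(d))
    ii, jj = np.nonzero(d == dmin)
    names = [
        (haps.sample_of_haplotype[cols1[i]], int(cols1[i]),
         haps.sample_of_haplotype[cols2[j]], int(cols2[j]))
        for i, j in zip(ii, jj)
    ]
    best = min(names)
    min_pair = (f"{best[0]}#{best[1]}", f"{best[2]}#{best[3]}")
    gmin = dmin / dxy if dxy > 0 else np.nan
    return dxy, dmin, gmin, min_pair


# ---------------------------------------------------------------------------
# pi and Tajima's D
# ---------------------------------------------------------------------------

def pi_window(haps: HaplotypeMatrix, pop: str, window=None,
              min_call_frac: float = 1.0, per_site: bool = True) -> float:
    """Nucleotide diversity within a population.

    Mean pairwise difference per site; per-site denominators use the
    non-missing allele count, and the window denominator is the usable
    site count.
    """
    if window is not None:
        haps = haps.slice_window(window)
    mask = usable_site_mask(haps, min_call_frac)
    L_usable = haps.length - int((~mask).sum())
    if L_usable <= 0:
        return np.nan
    cols = haps.haplotype_indices(pop)
    sub = haps.alleles[np.ix_(mask.nonzero()[0], cols)]
    called = sub != MISSING
    n = called.sum(axis=1)
    c = np.where(called, sub, 0).sum(axis=1)
    ok = n >= 2
    n, c = n[ok], c[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        per = 2.0 * c * (n - c) / (n * (n - 1.0))
    total = float(per.sum())
    return total / L_usable if per_site else total


def tajima_constants(n: int) -> dict:
    """The canonical a1, a2, b1, b2, c1, c2, e1, e2 normalising constants."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(haps: HaplotypeMatrix, pop: str, window=None) -> float:
    """Tajima's D for one population in a window.

    Computed from sites fully called within the population; NaN (flagged
    missing) when there are no segregating sites or fewer than four
    haplotypes.
    """
    if window is not None:
        haps = haps.slice_window(window)
    cols = haps.haplotype_indices(pop)
    sub = haps.alleles[:, cols]
    full = (sub != MISSING).all(axis=1)
    sub = sub[full]
    n = len(cols)
    if n < 4:
        return np.nan
    c = sub.sum(axis=1)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    if S == 0:
        return np.nan
    cs = c[seg].astype(float)
    pi_abs = float((2.0 * cs * (n - cs) / (n * (n - 1.0))).sum())
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi_abs - S / k["a1"]) / np.sqrt(var))


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------

DEFAULT_STATS = ("fst", "dxy", "gmin", "pi", "tajd")


def scan_windows(haps: HaplotypeMatrix, pop1: str, pop2: str,
                 cfg: WindowConfig | None = None,
                 which=DEFAULT_STATS,
                 min_call_frac: float = 1.0) -> pd.DataFrame:
    """Compute the selected statistics in tiled windows.

    A window is eligible iff ``n_usable >= cfg.min_usable_sites`` (with
    the default 5,001 for 10-kb windows this is the strict more-than-half
    rule); ineligible windows are still listed, with their usable count
    and missing statistics.
    """
    cfg = cfg or WindowConfig()
    rows = []
    from .gio import iter_windows

    for start, end in iter_windows(haps.length, cfg):
        sl = haps.slice_window((start, end))
        nu = n_usable_sites(sl, min_call_frac)
        rec = WindowStatRecord(haps.chrom, start, end, nu)
        if nu >= cfg.min_usable_sites:
            if "fst" in which:
                rec.fst = wc_fst(sl, pop1, pop2)
            if "dxy" in which or "gmin" in which:
                rec.dxy, rec.dxy_min, rec.gmin, rec.min_pair = dxy_stats(
                    sl, pop1, pop2, min_call_frac=min_call_frac
                )
            if "pi" in which:
                rec.pi_1 = pi_window(sl, pop1, min_call_frac=min_call_frac)
                rec.pi_2 = pi_window(sl, pop2, min_call_frac=min_call_frac)
            if "tajd" in which:
                rec.tajd_1 = tajimas_d(sl, pop1)
                rec.tajd_2 = tajimas_d(sl, pop2)
        rows.append(rec)
    return pd.DataFrame([r.__dict__ for r in rows])
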