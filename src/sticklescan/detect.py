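"""Calling introgression valleys and peaks from window statistics.

Pipeline: a two-state Gaussian hidden Markov model (Baum-Welch fitted,
Viterbi decoded) classifies windows into background vs valley (low
G_MIN) or peak (high f_d) states; outlier windows within 30 kb of one
another are merged into intervals.  Chromosome permutations provide an
independent lower-tail significance threshold, permutation tests compare
groups of windows, and an enrichment test compares gene content of
valleys against size-matched random windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import HaplotypeMatrix, WindowConfig, iter_windows
from . import winstats

__all__ = [
    "HmmConfig",
    "ValleySet",
    "PermThreshold",
    "permutation_threshold",
    "fit_hmm_classify",
    "cluster_outlier_windows",
    "permutation_independence_test",
    "gene_overlap_enrichment",
    "read_bed",
    "logit",
]

EPS = 1e-6


def logit(x, eps: float = EPS):
    """Logit transform with clamping of exact 0/1 values into (0, 1)."""
    x = np.clip(np.asarray(x, dtype=float), eps, 1 - eps)
    return np.log(x / (1 - x))


@dataclass
class HmmConfig:
    """Two-state HMM initialisation.

    Symmetric transitions make it hard to switch state (0.1) and easy to
    stay (0.9); decoding starts in the background state.  Emissions are
    one Gaussian per state, initialised from the empirical distribution;
    G_MIN tracks are logit transformed, f_d tracks are used untransformed.
    """

    p_stay: float = 0.9
    p_switch: float = 0.1
    transform: str = "logit"       # "logit" or "identity"
    mode: str = "valley"           # label outlier state below ("valley")
    #                                or above ("peak") the background mean
    tol: float = 1e-6
    max_iter: int = 500

    def __post_init__(self):
        if not np.isclose(self.p_stay + self.p_switch, 1.0):
            raise ValueError("transition rows must sum to 1")
        if self.transform not in ("logit", "identity"):
            raise ValueError("transform must be 'logit' or 'identity'")
        if self.mode not in ("valley", "peak"):
            raise ValueError("mode must be 'valley' or 'peak'")


@dataclass
class ValleySet:
    """Merged outlier intervals.

    ``intervals`` is a DataFrame with columns chrom, start, end,
    n_windows, length, extreme (most extreme statistic value) and
    min_pair (carried from the window records where available).
    """

    intervals: pd.DataFrame

    def __post_init__(self):
        df = self.intervals
        if len(df):
            for chrom, grp in df.groupby("chrom"):
                s = grp.sort_values("start")
                if (s["start"].values[1:] < s["end"].values[:-1]).any():
                    raise ValueError("valley intervals overlap")

    def __len__(self):
        return len(self.intervals)

    def total_length(self) -> int:
        return int(self.intervals["length"].sum()) if len(self) else 0


@dataclass
class PermThreshold:
    cutoffs: dict            # usable-site bin lower edge -> cutoff (or NaN)
    n_permutations: int
    percentile: float = 1.0  # lower tail


# ---------------------------------------------------------------------------
# permutation null for G_MIN
# ---------------------------------------------------------------------------

DEFAULT_BINS = tuple(range(5_000, 10_001, 500))


def permutation_threshold(haps: HaplotypeMatrix, pop1: str, pop2: str,
                          cfg: WindowConfig | None = None,
                          n_permutations: int = 100,
                          seed: int = 0,
                          bins=DEFAULT_BINS,
                          stat: str = "gmin") -> PermThreshold:
    """Chromosome-permutation null thresholds for window G_MIN.

    Each permutation shuffles the order of variant-site columns jointly
    across all haplotypes (preserving per-site allele configurations
    while destroying spatial order), recomputes the statistic in tiled
    windows, and pools values per usable-site bin.  The cutoff per bin is
    the 1st percentile of the pooled null (the lower tail of the
    "lower 99 percentile" rule); bins that receive no windows get a NaN
    cutoff.  Deterministic per seed.
    """
    cfg = cfg or WindowConfig()
    rng = np.random.default_rng(seed)
    bins = np.asarray(sorted(bins))
    pooled: dict = {int(b): [] for b in bins}
    for _ in range(n_permutations):
        order = rng.permutation(haps.n_sites)
        shuffled = HaplotypeMatrix(
            chrom=haps.chrom,
            positions=haps.positions,
            alleles=haps.alleles[order],
            sample_of_haplotype=haps.sample_of_haplotype,
            pop_of_sample=haps.pop_of_sample,
            length=haps.length,
        )
        for win in iter_windows(haps.length, cfg):
            sl = shuffled.slice_window(win)
            nu = winstats.n_usable_sites(sl)
            if nu < bins[0]:
                continue
            b = int(bins[np.searchsorted(bins, nu, side="right") - 1])
            _, _, gmin, _ = winstats.dxy_stats(sl, pop1, pop2)
            val = gmin
            if np.isfinite(val):
                pooled[b].append(val)
    cutoffs = {
        b: (float(np.percentile(v, 1.0)) if v else np.nan)
        for b, v in pooled.items()
    }
    return PermThreshold(cutoffs=cutoffs, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# HMM classification
# ---------------------------------------------------------------------------

def fit_hmm_classify(values, cfg: HmmConfig | None = None):
    """Baum-Welch fit + Viterbi decode of a two-state Gaussian HMM.

    ``values`` is the per-window statistic track in window order; NaN
    windows break the track into independent sub-sequences and receive
    no state (-1 in the output).  Returns ``(states, info)`` where
    ``states[i]`` is 1 for the outlier state (valley for G_MIN mode,
    peak for f_d mode) and ``info`` carries the fitted parameters and a
    convergence flag.
    """
    import logging

    from hmmlearn.hmm import GaussianHMM

    # hmmlearn logs a warning whenever EM's final step decreases the
    # log-likelihood by ~1e-7 (numerical noise at convergence); the
    # convergence flag below already reports genuine failures
    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

    cfg = cfg or HmmConfig()
    values = np.asarray(values, dtype=float)
    obs = logit(values) if cfg.transform == "logit" else values.copy()
    ok = np.isfinite(obs)
    if ok.sum() < 2:
        raise ValueError("need at least two windows with defined values")

    if np.ptp(obs[ok]) == 0:
        # a constant track has a single state: all background, no outliers
        states = np.full(values.size, -1, dtype=int)
        states[ok] = 0
        return states, {"means": np.array([obs[ok][0]] * 2),
                        "converged": True, "degenerate": True}

    x = obs[ok].reshape(-1, 1)
    # contiguous runs of defined windows
    run_id = np.cumsum(~ok)[ok]
    lengths = [int(c) for _, c in
               zip(*np.unique(run_id, return_counts=True))]

    model = GaussianHMM(
        n_components=2, covariance_type="diag",
        init_params="", params="stmc",
        tol=cfg.tol, n_iter=cfg.max_iter,
    )
    model.startprob_ = np.array([1.0, 0.0])  # start in background state
    model.transmat_ = np.array(
        [[cfg.p_stay, cfg.p_switch], [cfg.p_switch, cfg.p_stay]]
    )
    # emission init from the empirical distribution: background near the
    # median, outlier at the relevant tail
    if cfg.mode == "valley":
        means = np.array([[np.percentile(x, 60)], [np.percentile(x, 2)]])
    else:
        means = np.array([[np.percentile(x, 40)], [np.percentile(x, 98)]])
    model.means_ = means
    sd = max(float(np.std(x)), 1e-3)
    model.covars_ = np.full((2, 1), sd**2)
    model.fit(x, lengths)
    converged = bool(model.monitor_.converged)

    states_ok = model.predict(x, lengths)
    # identify the outlier state by fitted mean
    mu = model.means_.ravel()
    outlier_state = int(np.argmin(mu)) if cfg.mode == "valley" \
        else int(np.argmax(mu))
    labels = (states_ok == outlier_state).astype(int)
    states = np.full(values.size, -1, dtype=int)
    states[ok] = labels
    info = {
        "means": mu,
        "vars": model.covars_.ravel(),
        "transmat": model.transmat_,
        "converged": converged,
        "outlier_state": outlier_state,
        "n_iter": model.monitor_.iter,
    }
    if not converged:
        info["warning"] = "Baum-Welch did not converge; last iterate used"
    return states, info


# ---------------------------------------------------------------------------
# clustering outlier windows
# ---------------------------------------------------------------------------

def cluster_outlier_windows(windows: pd.DataFrame, gap: int = 30_000,
                            stat_col: str | None = None,
                            mode: str = "valley") -> ValleySet:
    """Merge outlier windows within ``gap`` bp of one another.

    ``windows`` needs columns chrom, start, end (0-based half-open) and
    may carry a statistic column (``stat_col``) and ``min_pair``.  The
    extreme value recorded per interval is the minimum (valley mode) or
    maximum (peak mode) of the statistic; the min_pair of the extreme
    window is carried along.
    """
    rows = []
    if len(windows):
        for chrom, grp in windows.groupby("chrom", sort=False):
            grp = grp.sort_values("start").reset_index(drop=True)
            cur = None
            for _, w in grp.iterrows():
                if cur is not None and w["start"] - cur["end"] <= gap:
                    cur["end"] = max(cur["end"], int(w["end"]))
                    cur["n_windows"] += 1
                    cur["members"].append(w)
                else:
                    if cur is not None:
                        rows.append(cur)
                    cur = {"chrom": chrom, "start": int(w["start"]),
                           "end": int(w["end"]), "n_windows": 1,
                           "members": [w]}
            if cur is not None:
                rows.append(cur)
    out = []
    for r in rows:
        rec = {"chrom": r["chrom"], "start": r["start"], "end": r["end"],
               "n_windows": r["n_windows"],
               "length": r["end"] - r["start"],
               "extreme": np.nan, "min_pair": None}
        if stat_col is not None:
            vals = np.array([m.get(stat_col, np.nan) for m in r["members"]],
                            dtype=float)
            if np.isfinite(vals).any():
                i = (np.nanargmin(vals) if mode == "valley"
                     else np.nanargmax(vals))
                rec["extreme"] = float(vals[i])
                rec["min_pair"] = r["members"][i].get("min_pair")
        out.append(rec)
    cols = ["chrom", "start", "end", "n_windows", "length",
            "extreme", "min_pair"]
    return ValleySet(pd.DataFrame(out, columns=cols))


# ---------------------------------------------------------------------------
# permutation independence test
# ---------------------------------------------------------------------------

def permutation_independence_test(values_a, values_b, n_perm: int = 10_000,
                                  seed: int = 0,
                                  alternative: str = "two-sided"):
    """Label-permutation test on the difference in group means.

    Returns ``(statistic, p)`` where ``statistic = mean(a) - mean(b)``
    and ``p = (b + 1) / (n_perm + 1)`` with ``b`` the number of permuted
    statistics at least as extreme as observed, per ``alternative`` in
    {"two-sided", "greater", "less"}.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    obs = a.mean() - b.mean()
    pool = np.concatenate([a, b])
    n_a = a.size
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        stat = pool[:n_a].mean() - pool[n_a:].mean()
        if alternative == "greater":
            count += stat >= obs
        elif alternative == "less":
            count += stat <= obs
        else:
            count += abs(stat) >= abs(obs)
    return float(obs), float((count + 1) / (n_perm + 1))


# ---------------------------------------------------------------------------
# gene overlap enrichment
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end/name."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append({
                "chrom": f[0], "start": int(f[1]), "end": int(f[2]),
                "name": f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}",
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _genes_overlapping(genes: pd.DataFrame, intervals) -> set:
    hit = set()
    for chrom, s, e in intervals:
        sub = genes[genes["chrom"] == chrom]
        ov = (sub["start"] < e) & (sub["end"] > s)
        hit.update(sub.loc[ov, "name"])
    return hit


def gene_overlap_enrichment(valleys: ValleySet, genes: pd.DataFrame,
                            chrom_lengths: dict,
                            n_draws: int = 1_000, seed: int = 0):
    """Are more genes inside valleys than inside random matched windows?

    The observed count is the number of unique genes overlapping any
    valley by >= 1 bp.  Each null draw places, for every valley, a
    random interval of the same length on a uniformly chosen chromosome
    (weighted by placeable length) such that it does not overlap any
    valley, and counts unique genes.  Returns ``(observed, null counts,
    p)`` with the add-one empirical p-value for enrichment.
    """
    iv = valleys.intervals
    observed = len(_genes_overlapping(
        genes, iv[["chrom", "start", "end"]].itertuples(index=False)
    ))
    rng = np.random.default_rng(seed)
    by_chrom = {c: g[["start", "end"]].values
                for c, g in iv.groupby("chrom")}

    def non_valley(chrom, s, e):
        vv = by_chrom.get(chrom)
        if vv is None:
            return True
        return not np.any((vv[:, 0] < e) & (vv[:, 1] > s))

    chroms = list(chrom_lengths)
    null = np.empty(n_draws, dtype=int)
    for d in range(n_draws):
        draw_iv = []
        for length in iv["length"]:
            placed = False
            for _ in range(1_000):
                weights = np.array(
                    [max(chrom_lengths[c] - length, 0) for c in chroms],
                    dtype=float,
                )
                if weights.sum() == 0:
                    break
                c = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
                s = int(rng.integers(0, chrom_lengths[c] - length + 1))
                if non_valley(c, s, s + length):
                    draw_iv.append((c, s, s + length))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    "insufficient non-valley territory to place a null window"
                )
        null[d] = len(_genes_overlapping(genes, draw_iv))
    p = (float((null >= observed).sum()) + 1) / (n_draws + 1)
    return observed, null, p
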