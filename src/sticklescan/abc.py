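"""Rejection ABC over divergence-with-gene-flow coalescent models.

The inference machine: simulate many parameter draws per candidate
model, reduce every simulated dataset (and the observed one) to a fixed
20-element summary vector — mean and variance across loci of
within-population diversity (pi, Watterson's theta, Tajima's D for each
population), F_ST, and shared/private polymorphism counts — then accept
the tolerance-fraction of simulations nearest the observed vector in
MAD-standardised Euclidean distance.  Model posterior probabilities are
per-model acceptance shares; parameter posteriors are the accepted
draws of a single model.  Pseudo-observed datasets (PODs) drawn from
the priors quantify model recovery.

Migration is reported both as the per-generation migrant fraction ``m``
and as the expected number of migrant individuals per generation,
``2 N m``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .simdata import DemographicParams, LocusSpec, build_demography
from .winstats import tajima_constants, wc_fst_counts

__all__ = [
    "SUMMARY_NAMES",
    "PriorSpec",
    "ModelSpec",
    "ReferenceTable",
    "sample_abc_loci",
    "locus_summaries",
    "simulate_summaries",
    "build_reference_table",
    "select_model",
    "estimate_parameters",
    "pod_validate",
    "scaled_migration",
]

_BASE_STATS = (
    "pi_1", "pi_2", "thetaw_1", "thetaw_2", "tajd_1", "tajd_2",
    "fst", "shared", "private_1", "private_2",
)
#: fixed summary-vector ordering: across-locus means then variances
SUMMARY_NAMES = tuple(f"mean_{s}" for s in _BASE_STATS) + tuple(
    f"var_{s}" for s in _BASE_STATS
)


# ---------------------------------------------------------------------------
# priors and models
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """One parameter's prior: loguniform or uniform over (low, high)."""

    low: float
    high: float
    family: str = "loguniform"

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError("prior bounds must satisfy 0 < low < high")
        if self.family not in ("loguniform", "uniform"):
            raise ValueError(f"unknown prior family {self.family!r}")

    def draw(self, rng: np.random.Generator) -> float:
        if self.family == "loguniform":
            return float(np.exp(rng.uniform(np.log(self.low),
                                            np.log(self.high))))
        return float(rng.uniform(self.low, self.high))


def default_priors(scenario: str) -> dict:
    """Wide loguniform priors spanning the plausible demographic ranges."""
    priors = {
        "N_JS": PriorSpec(1e3, 1e6),
        "N_PO": PriorSpec(1e3, 1e6),
        "N_ANC": PriorSpec(1e3, 1e6),
        # bottleneck/founding size as a reduction fraction of the
        # contemporary Japan Sea size: a bottleneck is a contraction
        "N_JSB_frac": PriorSpec(0.01, 1.0),
        "T": PriorSpec(1e4, 1e7),
        "T_G_frac": PriorSpec(0.05, 0.95, family="uniform"),
    }
    if scenario != "I":
        priors["m12"] = PriorSpec(1e-9, 1e-4)
        priors["m21"] = PriorSpec(1e-9, 1e-4)
    if scenario in ("IAM", "IARM"):
        priors["T_anc_frac"] = PriorSpec(0.05, 0.95, family="uniform")
    if scenario in ("IRM", "IARM"):
        priors["T_rec_frac"] = PriorSpec(0.05, 0.95, family="uniform")
    return priors


@dataclass
class ModelSpec:
    """A divergence scenario x growth variant plus its priors."""

    scenario: str = "IM"
    growth: str = "constant"
    priors: dict = field(default_factory=dict)
    mu: float = 7.1e-9

    def __post_init__(self):
        if not self.priors:
            self.priors = default_priors(self.scenario)

    @property
    def name(self) -> str:
        return f"{self.scenario}+{self.growth}"

    def draw_params(self, rng: np.random.Generator) -> DemographicParams:
        d = {k: p.draw(rng) for k, p in self.priors.items()}
        T = d["T"]
        T_G = d.pop("T_G_frac", 0.5) * T
        N_JS = d.get("N_JS", 2e5)
        if "N_JSB_frac" in d:
            N_JSB = d["N_JSB_frac"] * N_JS
        else:
            N_JSB = d.get("N_JSB", N_JS)
        kwargs = dict(
            scenario=self.scenario, growth=self.growth,
            T=T, T_G=T_G, mu=self.mu,
            N_JS=N_JS, N_PO=d.get("N_PO", 1e5),
            N_ANC=d.get("N_ANC", 1e5), N_JSB=N_JSB,
            m12=d.get("m12", 0.0), m21=d.get("m21", 0.0),
        )
        if self.scenario == "I":
            kwargs["m12"] = kwargs["m21"] = 0.0
        if "T_anc_frac" in d:
            kwargs["T_anc_stop"] = d["T_anc_frac"] * T
        if "T_rec_frac" in d:
            kwargs["T_rec_start"] = d["T_rec_frac"] * T_G
        return DemographicParams(**kwargs)


@dataclass
class ReferenceTable:
    """Simulated reference set: model label, parameters, summaries."""

    frame: pd.DataFrame       # columns: model, param:*, SUMMARY_NAMES

    @property
    def summaries(self) -> np.ndarray:
        return self.frame[list(SUMMARY_NAMES)].to_numpy(float)

    @property
    def models(self) -> np.ndarray:
        return self.frame["model"].to_numpy()


# ---------------------------------------------------------------------------
# locus sampling from observed data
# ---------------------------------------------------------------------------

def sample_abc_loci(haps, n_target: int | None = None,
                    locus_length: int = 2_000, spacing: int = 125_000,
                    min_length: int = 1_000, min_samples: int = 14,
                    seed: int = 0) -> list:
    """Sample short loci on a regular grid, filtered for callability.

    Loci start every ``spacing`` bp; a locus survives if it has more
    than ``min_length`` bp of callable sequence and every variant site
    within it is called in at least ``min_samples`` diploid individuals.
    Surviving loci are randomly thinned to ``n_target``.  Returns a list
    of :class:`~sticklescan.gio.HaplotypeMatrix` slices.
    """
    from .gio import MISSING

    rng = np.random.default_rng(seed)
    cols_of_sample: dict = {}
    for col, s in enumerate(haps.sample_of_haplotype):
        cols_of_sample.setdefault(s, []).append(col)
    out = []
    for start in range(0, haps.length - locus_length + 1, spacing):
        sl = haps.slice_window((start, start + locus_length))
        called = sl.alleles != MISSING
        # individuals with every haplotype called, per site
        if sl.n_sites:
            ind_ok = sum(
                called[:, cols].all(axis=1).astype(int)
                for cols in cols_of_sample.values()
            )
        else:
            ind_ok = np.empty(0, dtype=int)
        bad_sites = int((ind_ok < min_samples).sum())
        callable_bp = sl.length - bad_sites
        if callable_bp <= min_length:
            continue
        if bad_sites:
            keep = ind_ok >= min_samples
            sl = type(sl)(
                chrom=sl.chrom, positions=sl.positions[keep],
                alleles=sl.alleles[keep],
                sample_of_haplotype=sl.sample_of_haplotype,
                pop_of_sample=sl.pop_of_sample, length=sl.length,
            )
        out.append(sl)
    if not out:
        raise ValueError("no loci survive the callability filters")
    if n_target is not None and len(out) > n_target:
        idx = rng.choice(len(out), size=n_target, replace=False)
        out = [out[i] for i in sorted(idx)]
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _per_locus_stats(c1, n1, c2, n2, L):
    """The 10 per-locus statistics from derived counts of two populations."""
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    seg1 = (c1 > 0) & (c1 < n1)
    seg2 = (c2 > 0) & (c2 < n2)
    S1, S2 = int(seg1.sum()), int(seg2.sum())
    pi1_abs = float((2 * c1 * (n1 - c1) / (n1 * (n1 - 1))).sum())
    pi2_abs = float((2 * c2 * (n2 - c2) / (n2 * (n2 - 1))).sum())
    k1, k2 = tajima_constants(n1), tajima_constants(n2)

    def tajd(S, pi_abs, k):
        if S == 0:
            return np.nan
        var = k["e1"] * S + k["e2"] * S * (S - 1)
        return (pi_abs - S / k["a1"]) / np.sqrt(var)

    fst = wc_fst_counts(
        np.stack([c1, c2], axis=1),
        np.stack([np.full(c1.size, n1), np.full(c2.size, n2)], axis=1),
    ) if c1.size else np.nan
    shared = int((seg1 & seg2).sum())
    private1 = int((seg1 & ~seg2).sum())
    private2 = int((seg2 & ~seg1).sum())
    return {
        "pi_1": pi1_abs / L, "pi_2": pi2_abs / L,
        "thetaw_1": S1 / k1["a1"] / L, "thetaw_2": S2 / k2["a1"] / L,
        "tajd_1": tajd(S1, pi1_abs, k1), "tajd_2": tajd(S2, pi2_abs, k2),
        "fst": fst, "shared": shared,
        "private_1": private1, "private_2": private2,
    }


def locus_summaries(loci, pop1: str = "JS", pop2: str = "PO") -> np.ndarray:
    """Reduce a locus set to the fixed 20-element summary vector.

    Per-locus statistics that are undefined (monomorphic loci for
    Tajima's D, F_ST without usable sites) are excluded from the
    across-locus moments.
    """
    if len(loci) < 2:
        raise ValueError("need at least two loci")
    from .gio import MISSING

    rows = []
    for h in loci:
        i1 = h.haplotype_indices(pop1)
        i2 = h.haplotype_indices(pop2)
        a1 = h.alleles[:, i1]
        a2 = h.alleles[:, i2]
        ok1 = a1 != MISSING
        ok2 = a2 != MISSING
        # restrict to fully called sites for count-based summaries
        full = ok1.all(axis=1) & ok2.all(axis=1)
        rows.append(_per_locus_stats(
            a1[full].sum(axis=1), len(i1),
            a2[full].sum(axis=1), len(i2), h.length,
        ))
    df = pd.DataFrame(rows)
    means = df.mean(skipna=True)
    vars_ = df.var(skipna=True, ddof=1)
    vec = np.concatenate([
        means[list(_BASE_STATS)].to_numpy(float),
        vars_[list(_BASE_STATS)].to_numpy(float),
    ])
    return vec


def simulate_summaries(params: DemographicParams, spec: LocusSpec,
                       seed: int) -> np.ndarray:
    """Simulate one dataset and summarise it (fast path, no matrices)."""
    pops = list(spec.samples_per_pop)
    if pops[:2] != ["JS", "PO"]:
        raise ValueError("LocusSpec must sample JS and PO (in that order)")
    n1 = spec.samples_per_pop["JS"]
    n2 = spec.samples_per_pop["PO"]
    dem = build_demography(params)
    ss = np.random.SeedSequence(seed)
    anc_seed, mut_base = [int(s) for s in
                          ss.generate_state(2) % (2**31 - 2) + 1]
    reps = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n1, population="JS", ploidy=1),
                 msprime.SampleSet(n2, population="PO", ploidy=1)],
        demography=dem,
        sequence_length=spec.locus_length,
        num_replicates=spec.n_loci,
        random_seed=anc_seed,
        ploidy=2,
    )
    rng = np.random.default_rng(mut_base)
    rows = []
    for ts in reps:
        mts = msprime.sim_mutations(
            ts, rate=params.mu,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel(),
        )
        if mts.num_sites:
            G = (mts.genotype_matrix() > 0)
            c1 = G[:, :n1].sum(axis=1)
            c2 = G[:, n1:].sum(axis=1)
        else:
            c1 = c2 = np.empty(0, dtype=int)
        rows.append(_per_locus_stats(c1, n1, c2, n2, spec.locus_length))
    df = pd.DataFrame(rows)
    return np.concatenate([
        df.mean(skipna=True)[list(_BASE_STATS)].to_numpy(float),
        df.var(skipna=True, ddof=1)[list(_BASE_STATS)].to_numpy(float),
    ])


# ---------------------------------------------------------------------------
# reference table, rejection, posteriors
# ---------------------------------------------------------------------------

def build_reference_table(models, n_sims: int, spec: LocusSpec,
                          seed: int) -> ReferenceTable:
    """Simulate ``n_sims`` parameter draws for each model."""
    if not models:
        raise ValueError("need at least one model")
    rows = []
    ss = np.random.SeedSequence(seed)
    for mi, model in enumerate(models):
        child = np.random.SeedSequence(entropy=ss.entropy,
                                       spawn_key=(mi,))
        rng = np.random.default_rng(child)
        sim_seeds = rng.integers(1, 2**31 - 1, size=n_sims)
        for k in range(n_sims):
            for _attempt in range(5):
                try:
                    params = model.draw_params(rng)
                    vec = simulate_summaries(
                        params, spec, int(sim_seeds[k]) + _attempt
                    )
                    break
                except Exception:  # re-draw on simulator failure
                    continue
            else:
                raise RuntimeError(
                    f"simulation failed repeatedly for model {model.name}"
                )
            row = {"model": model.name}
            row.update({f"param:{k_}": v for k_, v in vars(params).items()
                        if isinstance(v, (int, float)) and v is not None})
            row.update(dict(zip(SUMMARY_NAMES, vec)))
            rows.append(row)
    return ReferenceTable(pd.DataFrame(rows))


def _standardise(table_summ: np.ndarray, observed: np.ndarray):
    """MAD-standardise columns; drop degenerate (zero-spread) columns."""
    med = np.nanmedian(table_summ, axis=0)
    mad = np.nanmedian(np.abs(table_summ - med), axis=0)
    keep = mad > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-spread summary columns",
            stacklevel=3,
        )
    if not keep.any():
        raise ValueError("all summary columns are degenerate")
    ts = (table_summ[:, keep] - med[keep]) / mad[keep]
    obs = (observed[keep] - med[keep]) / mad[keep]
    # NaN summaries (e.g. Tajima's D with no variation anywhere) are
    # neutral in the distance
    ts = np.nan_to_num(ts, nan=0.0)
    obs = np.nan_to_num(obs, nan=0.0)
    return ts, obs


def _accept(observed, table: ReferenceTable, tolerance: float):
    ts, obs = _standardise(table.summaries, np.asarray(observed, float))
    d = np.sqrt(((ts - obs) ** 2).sum(axis=1))
    n_accept = max(1, int(np.ceil(tolerance * d.size)))
    idx = np.argsort(d, kind="stable")[:n_accept]
    return idx, d


def select_model(observed, table: ReferenceTable,
                 tolerance: float = 0.01) -> dict:
    """Rejection-step model posterior probabilities.

    Accepts the nearest ``tolerance`` fraction of simulations and
    returns each model's share of the accepted set (shares sum to 1).
    """
    idx, _ = _accept(observed, table, tolerance)
    models = table.models
    out = {m: 0.0 for m in pd.unique(models)}
    acc = models[idx]
    for m in out:
        out[m] = float((acc == m).sum()) / idx.size
    return out


def estimate_parameters(observed, table: ReferenceTable,
                        tolerance: float = 0.01,
                        params: list | None = None) -> pd.DataFrame:
    """Rejection posterior for the parameters of a single-model table.

    Returns a frame indexed by parameter with the accepted-draw median
    and equal-tailed 95% credible interval on the natural scale (the
    rejection step itself is scale-free; draws are retained untransformed
    and log-transformed quantiles coincide after back-transformation).
    Warns when fewer than 20 draws are accepted.
    """
    if len(pd.unique(table.models)) != 1:
        raise ValueError("parameter estimation expects a one-model table")
    idx, _ = _accept(observed, table, tolerance)
    if idx.size < 20:
        warnings.warn(f"only {idx.size} accepted draws", stacklevel=2)
    cols = params or [c for c in table.frame.columns
                      if c.startswith("param:")]
    cols = [c if c.startswith("param:") else f"param:{c}" for c in cols]
    acc = table.frame.iloc[idx][cols]
    rows = []
    for c in cols:
        v = acc[c].to_numpy(float)
        # conservative (outward-rounded) order statistics: with a few
        # dozen accepted draws, interpolated quantiles understate tails
        rows.append({
            "parameter": c.removeprefix("param:"),
            "median": float(np.median(v)),
            "q2.5": float(np.quantile(v, 0.025, method="lower")),
            "q97.5": float(np.quantile(v, 0.975, method="higher")),
            "n_accepted": idx.size,
        })
    return pd.DataFrame(rows).set_index("parameter")


def pod_validate(models, n_pods_per_model: int, n_sims: int,
                 spec: LocusSpec, tolerance: float = 0.01,
                 seed: int = 0, table: ReferenceTable | None = None
                 ) -> pd.DataFrame:
    """Confusion matrix of true vs selected model over PODs.

    PODs are fresh draws from each model's prior (independent of the
    reference table); each is run through :func:`select_model` and
    assigned to the highest-posterior model.  Rows are true models,
    columns selected models; each row sums to ``n_pods_per_model``.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    if table is None:
        table = build_reference_table(models, n_sims, spec, seed)
    names = [m.name for m in models]
    conf = pd.DataFrame(0, index=names, columns=names)
    ss = np.random.SeedSequence(seed + 1)
    for mi, model in enumerate(models):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(mi,))
        )
        for _ in range(n_pods_per_model):
            params = model.draw_params(rng)
            obs = simulate_summaries(
                params, spec, int(rng.integers(1, 2**31 - 1))
            )
            post = select_model(obs, table, tolerance)
            best = max(post, key=post.get)
            conf.loc[model.name, best] += 1
    return conf


def scaled_migration(N: float, m: float) -> float:
    """Expected migrants per generation, ``2 N m`` (N diploid)."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 <= m < 1:
        raise ValueError("m must satisfy 0 <= m < 1")
    return 2.0 * N * m
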