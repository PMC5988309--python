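"""Ancestry-informative markers, hybrid index and interspecific heterozygosity.

An ancestry-informative marker (AIM) is an autosomal SNP whose allele
frequency difference between two reference parental panels exceeds a
threshold (strictly greater than 0.8 by default).  Per individual,

* hybrid index ``h`` = proportion of its alleles at typed AIMs that are
  of the species-2-associated class, and
* interspecific heterozygosity ``H_int`` = proportion of typed AIMs
  heterozygous for the two species-associated allele classes.

Pure parents sit at (h, H_int) = (0, 0) or (1, 0), F1 hybrids at
(0.5, 1) when markers are fully diagnostic, F2 at (0.5, 0.5) in
expectation, and backcrosses at (0.25 or 0.75, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import MISSING

__all__ = [
    "AimConfig",
    "AncestryRecord",
    "select_aims",
    "ancestry_indices",
]


@dataclass
class AimConfig:
    min_abs_freq_diff: float = 0.8

    def __post_init__(self):
        if not 0 < self.min_abs_freq_diff <= 1:
            raise ValueError("min_abs_freq_diff must be in (0, 1]")


@dataclass
class AncestryRecord:
    sample: str
    h: float
    H_int: float
    n_aims_typed: int


def select_aims(p1, p2, cfg: AimConfig | None = None) -> pd.DataFrame:
    """Select loci with ``|p1 - p2| > threshold`` (strict).

    ``p1``/``p2`` are allele-1 frequencies in the two parental panels.
    The returned frame records, per AIM, its locus index and which
    allele code (0/1) is associated with each species: the
    species-2-associated allele is the one more frequent in panel 2.
    """
    cfg = cfg or AimConfig()
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("panels must cover the same loci")
    dp = np.abs(p1 - p2)
    sel = np.flatnonzero(dp > cfg.min_abs_freq_diff)
    return pd.DataFrame({
        "locus": sel,
        "p1": p1[sel],
        "p2": p2[sel],
        "freq_diff": dp[sel],
        # allele code 1 is species-2-associated where p2 > p1
        "species2_allele": (p2[sel] > p1[sel]).astype(int),
    })


def ancestry_indices(genotypes, aims: pd.DataFrame,
                     sample_names=None) -> pd.DataFrame:
    """Hybrid index and interspecific heterozygosity per individual.

    ``genotypes`` is an ``(n_ind, n_loci, 2)`` array of allele codes
    over the same locus axis the AIM panel frequencies were computed on
    (MISSING entries excluded per sample).  Samples with zero typed AIMs
    yield a flagged all-NaN record.
    """
    g = np.asarray(genotypes)
    if g.ndim != 3 or g.shape[2] != 2:
        raise ValueError("genotypes must have shape (n_ind, n_loci, 2)")
    loci = aims["locus"].to_numpy()
    sp2 = aims["species2_allele"].to_numpy()
    rows = []
    for i in range(g.shape[0]):
        sub = g[i, loci, :]
        typed = (sub != MISSING).all(axis=1)
        n = int(typed.sum())
        name = sample_names[i] if sample_names is not None else f"ind_{i}"
        if n == 0:
            rows.append(AncestryRecord(name, np.nan, np.nan, 0))
            continue
        is2 = sub[typed] == sp2[typed, None]
        h = float(is2.sum()) / (2 * n)
        het = float((is2.sum(axis=1) == 1).sum()) / n
        rows.append(AncestryRecord(name, h, het, n))
    return pd.DataFrame([r.__dict__ for r in rows])
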