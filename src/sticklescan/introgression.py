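"""Frequency-weighted site-pattern statistics for detecting gene flow.

Four-taxon ABBA-BABA ``D`` and ``f_d``, the five-taxon partitioned-D
family (``D1``, ``D2``, ``D12``) and the four-component ``D_FOIL``
system with introgression-event classification.

All statistics replace single-genome site-pattern counts by products of
derived-allele frequencies: a pattern such as ABBA contributes
``(1 - p1) * p2 * p3 * (1 - p4)`` at every site, so polymorphic sites
contribute fractionally and fixed sites reproduce the classic counts.
Sites with a polymorphic outgroup contribute with weight ``(1 - pO)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gio import HaplotypeMatrix, WindowConfig, iter_windows, pop_allele_freqs

__all__ = [
    "DStatRecord",
    "PartitionedDRecord",
    "DfoilRecord",
    "d_and_fd",
    "partitioned_d",
    "dfoil",
    "dfoil_windows",
    "d_fd_windows",
    "DFOIL_EVENTS",
]


def _clean(*tracks):
    """Stack frequency tracks, dropping sites with any NaN."""
    arrs = [np.asarray(t, dtype=float).ravel() for t in tracks]
    n = arrs[0].size
    for a in arrs:
        if a.size != n:
            raise ValueError("frequency tracks must have equal length")
        if np.any((a < 0) & ~np.isnan(a)) or np.any(a > 1):
            raise ValueError("frequencies must lie in [0, 1]")
    ok = ~np.any(np.isnan(np.vstack(arrs)), axis=0)
    return [a[ok] for a in arrs]


# ---------------------------------------------------------------------------
# four-taxon D and f_d
# ---------------------------------------------------------------------------

@dataclass
class DStatRecord:
    chrom: str = ""
    start: int = 0
    end: int = 0
    abba: float = 0.0
    baba: float = 0.0
    D: float = np.nan
    fd: float = np.nan
    n_informative: int = 0


def d_and_fd(p1, p2, p3, p4, chrom: str = "", window=(0, 0)) -> DStatRecord:
    """Patterson's D and Martin's f_d from derived-allele frequencies.

    ``abba = sum (1-p1) p2 p3 (1-p4)`` and ``baba = sum p1 (1-p2) p3
    (1-p4)``; the f_d denominator substitutes the dynamic donor
    frequency ``pD = max(p2, p3)`` (site-wise, ties resolved to p2 —
    identical weights either way) into both the P2 and P3 positions.
    f_d is reported for negative-D windows as well; its proportion
    interpretation is only meaningful where D > 0.
    """
    p1, p2, p3, p4 = _clean(p1, p2, p3, p4)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    pD = np.maximum(p2, p3)
    abba_d = (1 - p1) * pD * pD * (1 - p4)
    baba_d = p1 * (1 - pD) * pD * (1 - p4)
    rec = DStatRecord(
        chrom=chrom, start=window[0], end=window[1],
        abba=float(abba.sum()), baba=float(baba.sum()),
        n_informative=int(((abba + baba) > 0).sum()),
    )
    denom = rec.abba + rec.baba
    if denom > 0:
        rec.D = (rec.abba - rec.baba) / denom
    fdd = float((abba_d - baba_d).sum())
    if fdd != 0:
        rec.fd = (rec.abba - rec.baba) / fdd
    return rec


# ---------------------------------------------------------------------------
# partitioned D
# ---------------------------------------------------------------------------

@dataclass
class PartitionedDRecord:
    chrom: str = ""
    start: int = 0
    end: int = 0
    abbaa: float = 0.0
    babaa: float = 0.0
    ababa: float = 0.0
    baaba: float = 0.0
    abbba: float = 0.0
    babba: float = 0.0
    D1: float = np.nan
    D2: float = np.nan
    D12: float = np.nan


def partitioned_d(p1, p2, p31, p32, pO, chrom: str = "", window=(0, 0)
                  ) -> PartitionedDRecord:
    """Five-taxon partitioned D statistics on tree ((P1,P2),(P3_1,P3_2),O).

    ``D1`` contrasts ABBAA/BABAA weights (derived allele in P3_1 only,
    factor ``p31 (1 - p32)``), ``D2`` contrasts ABABA/BAABA (derived in
    P3_2 only), and ``D12`` contrasts ABBBA/BABBA (derived in both).  A
    positive value indicates an excess of derived-allele sharing between
    P2 and the respective P3 branch, i.e. gene flow P3 -> P2.
    """
    p1, p2, p31, p32, pO = _clean(p1, p2, p31, p32, pO)
    w_o = 1 - pO
    pat = {
        "abbaa": (1 - p1) * p2 * p31 * (1 - p32) * w_o,
        "babaa": p1 * (1 - p2) * p31 * (1 - p32) * w_o,
        "ababa": (1 - p1) * p2 * (1 - p31) * p32 * w_o,
        "baaba": p1 * (1 - p2) * (1 - p31) * p32 * w_o,
        "abbba": (1 - p1) * p2 * p31 * p32 * w_o,
        "babba": p1 * (1 - p2) * p31 * p32 * w_o,
    }
    sums = {k: float(v.sum()) for k, v in pat.items()}
    rec = PartitionedDRecord(chrom=chrom, start=window[0], end=window[1],
                             **sums)
    for name, (l, r) in {
        "D1": ("abbaa", "babaa"),
        "D2": ("ababa", "baaba"),
        "D12": ("abbba", "babba"),
    }.items():
        denom = sums[l] + sums[r]
        if denom > 0:
            setattr(rec, name, (sums[l] - sums[r]) / denom)
    return rec


# ---------------------------------------------------------------------------
# D_FOIL
# ---------------------------------------------------------------------------

# Site patterns are 5-character strings over (P1, P2, P3, P4, O); the
# outgroup is always ancestral (A).  Each component is a left-minus-right
# contrast of weighted pattern sums:
#   D_FO : does P1 share derived alleles with P3 or with P4?
#   D_IL : does P2 share derived alleles with P3 or with P4?
#   D_FI : does P3 share derived alleles with P1 or with P2?
#   D_OL : does P4 share derived alleles with P1 or with P2?
DFOIL_PATTERNS = {
    "DFO": (("BABAA", "BBBAA", "ABABA", "AAABA"),
            ("BAABA", "BBABA", "ABBAA", "AABAA")),
    "DIL": (("ABBAA", "BBBAA", "BAABA", "AAABA"),
            ("ABABA", "BBABA", "BABAA", "AABAA")),
    "DFI": (("BABAA", "BABBA", "ABABA", "ABAAA"),
            ("ABBAA", "ABBBA", "BAABA", "BAAAA")),
    "DOL": (("BAABA", "BABBA", "ABBAA", "ABAAA"),
            ("ABABA", "ABBBA", "BABAA", "BAAAA")),
}

#: sign signature (DFO, DIL, DFI, DOL) -> introgression event.  The
#: polarisation logic: a younger-pair taxon passing genes into the older
#: pair drags its sister along (both DFO and DIL respond), while an
#: older-pair donor leaves its recipient's sister untouched (one of
#: DFO/DIL stays at zero) but shares deep alleles with its own sister
#: (DOL or DFI responds).  Each of the ten events has a unique
#: signature; every signature was verified by coalescent simulation of
#: the corresponding pulse.
DFOIL_SIGN_TABLE = {
    (0, 0, 0, 0): "none",
    (1, 1, 0, 0): "ancestral P12<->P3",
    (-1, -1, 0, 0): "ancestral P12<->P4",
    (1, 0, 1, 1): "P3->P1",
    (1, 1, 1, 0): "P1->P3",
    (0, 1, -1, -1): "P3->P2",
    (1, 1, -1, 0): "P2->P3",
    (-1, 0, 1, 1): "P4->P1",
    (-1, -1, 0, 1): "P1->P4",
    (0, -1, -1, -1): "P4->P2",
    (-1, -1, 0, -1): "P2->P4",
}

DFOIL_EVENTS = tuple(dict.fromkeys(DFOIL_SIGN_TABLE.values()))


@dataclass
class DfoilRecord:
    chrom: str = ""
    start: int = 0
    end: int = 0
    components: dict = field(default_factory=dict)   # name -> value
    left_sums: dict = field(default_factory=dict)
    right_sums: dict = field(default_factory=dict)
    significant: dict = field(default_factory=dict)  # name -> bool
    signs: tuple = (0, 0, 0, 0)
    event: str = "none"
    flag: str = ""


def _pattern_weight(pattern: str, tracks) -> np.ndarray:
    w = np.ones_like(tracks[0])
    for ch, p in zip(pattern, tracks):
        w = w * (p if ch == "B" else (1 - p))
    return w


def dfoil(p1, p2, p3, p4, pO, chrom: str = "", window=(0, 0),
          alpha: float = 0.01) -> DfoilRecord:
    """D_FOIL components and introgression-event classification.

    Assumes the symmetric tree ((P1,P2),(P3,P4),O) with the (P1,P2)
    split younger than the (P3,P4) split.  Each component is tested
    against zero with a chi-squared goodness-of-fit on its left/right
    weighted sums (df = 1); non-significant components count as zero in
    the sign signature, which is then looked up in the published event
    table.  Signatures outside the table yield ``event = "none"`` with a
    flag.
    """
    tracks = _clean(p1, p2, p3, p4, pO)
    rec = DfoilRecord(chrom=chrom, start=window[0], end=window[1])
    signs = []
    total_weight = 0.0
    for name, (left, right) in DFOIL_PATTERNS.items():
        lsum = float(sum(_pattern_weight(p, tracks).sum() for p in left))
        rsum = float(sum(_pattern_weight(p, tracks).sum() for p in right))
        rec.left_sums[name] = lsum
        rec.right_sums[name] = rsum
        total_weight += lsum + rsum
        if lsum + rsum > 0:
            val = (lsum - rsum) / (lsum + rsum)
            chi2 = (lsum - rsum) ** 2 / (lsum + rsum)
            pval = sps.chi2.sf(chi2, df=1)
            sig = bool(pval < alpha)
        else:
            val, sig = np.nan, False
        rec.components[name] = val
        rec.significant[name] = sig
        signs.append(0 if not sig else (1 if val > 0 else -1))
    rec.signs = tuple(signs)
    if total_weight == 0:
        rec.flag = "no informative sites"
        rec.event = "none"
        return rec
    rec.event = DFOIL_SIGN_TABLE.get(rec.signs, "none")
    if rec.signs not in DFOIL_SIGN_TABLE:
        rec.flag = "signature not in table"
    return rec


# ---------------------------------------------------------------------------
# windowed drivers
# ---------------------------------------------------------------------------

def d_fd_windows(haps: HaplotypeMatrix, pops, cfg: WindowConfig | None = None
                 ) -> pd.DataFrame:
    """Windowed D/f_d scan; ``pops`` = (P1, P2, P3, outgroup)."""
    cfg = cfg or WindowConfig(min_usable_sites=1)
    rows = []
    for win in iter_windows(haps.length, cfg):
        freqs, usable, _ = pop_allele_freqs(haps, win, pops=list(pops))
        tracks = [freqs[p][usable] for p in pops]
        rows.append(d_and_fd(*tracks, chrom=haps.chrom, window=win).__dict__)
    return pd.DataFrame(rows)


def dfoil_windows(haps: HaplotypeMatrix, pops,
                  cfg: WindowConfig | None = None,
                  alpha: float = 0.01) -> pd.DataFrame:
    """Windowed D_FOIL scan; ``pops`` = (P1, P2, P3, P4, outgroup).

    Default window size 100 kb.
    """
    cfg = cfg or WindowConfig(size=100_000, min_usable_sites=1)
    rows = []
    for win in iter_windows(haps.length, cfg):
        freqs, usable, _ = pop_allele_freqs(haps, win, pops=list(pops))
        tracks = [freqs[p][usable] for p in pops]
        rec = dfoil(*tracks, chrom=haps.chrom, window=win, alpha=alpha)
        row = {"chrom": rec.chrom, "start": rec.start, "end": rec.end,
               "event": rec.event, "flag": rec.flag}
        row.update(rec.components)
        row.update({f"sig_{k}": v for k, v in rec.significant.items()})
        rows.append(row)
    return pd.DataFrame(rows)
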