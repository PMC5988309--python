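"""Marker-based recombination maps and rate/statistic correlations.

A map is a per-chromosome table of (physical position in bp, cumulative
genetic distance in cM).  Window rates are obtained by piecewise-linear
interpolation of the cumulative map at the window bounds,
``rho = delta cM / (delta bp / 1e6)`` in cM/Mb; windows beyond the
terminal markers take the terminal segment's rate (linear
extrapolation), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RecombMap",
    "read_recomb_map",
    "interpolate_window_rates",
    "correlate_with_stat",
]


@dataclass
class RecombMap:
    """Sorted (pos_bp, cum_cM) markers per chromosome."""

    markers: dict  # chrom -> (pos ndarray, cM ndarray)

    def __post_init__(self):
        for chrom, (pos, cm) in self.markers.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            order = np.argsort(pos)
            pos, cm = pos[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise ValueError(
                    f"cumulative cM must be non-decreasing on {chrom}"
                )
            self.markers[chrom] = (pos, cm)

    def cum_cm(self, chrom: str, x) -> np.ndarray:
        """Cumulative cM at physical positions, extrapolating terminally."""
        if chrom not in self.markers:
            raise KeyError(chrom)
        pos, cm = self.markers[chrom]
        if pos.size < 2:
            raise ValueError(f"need >= 2 markers on {chrom}")
        x = np.asarray(x, dtype=float)
        out = np.interp(x, pos, cm)
        # linear extrapolation with the terminal segments' slopes
        lo = x < pos[0]
        hi = x > pos[-1]
        if lo.any():
            s = (cm[1] - cm[0]) / (pos[1] - pos[0])
            out[lo] = cm[0] + s * (x[lo] - pos[0])
        if hi.any():
            s = (cm[-1] - cm[-2]) / (pos[-1] - pos[-2])
            out[hi] = cm[-1] + s * (x[hi] - pos[-1])
        return out


def read_recomb_map(path) -> RecombMap:
    """Read a ``chrom<TAB>pos_bp<TAB>cum_cM`` marker table."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos_bp", "cum_cM"}
    if not need <= set(df.columns):
        raise ValueError(f"map must have columns {sorted(need)}")
    markers = {
        chrom: (g["pos_bp"].to_numpy(float), g["cum_cM"].to_numpy(float))
        for chrom, g in df.groupby("chrom")
    }
    return RecombMap(markers)


def interpolate_window_rates(rmap: RecombMap, windows: pd.DataFrame
                             ) -> np.ndarray:
    """Per-window recombination rate in cM/Mb.

    ``windows`` needs chrom/start/end columns; windows on chromosomes
    absent from the map get NaN.
    """
    rates = np.full(len(windows), np.nan)
    for chrom, grp in windows.groupby("chrom"):
        if chrom not in rmap.markers:
            continue
        s = grp["start"].to_numpy(float)
        e = grp["end"].to_numpy(float)
        dcm = rmap.cum_cm(chrom, e) - rmap.cum_cm(chrom, s)
        rates[grp.index] = dcm / ((e - s) / 1e6)
    return rates


def correlate_with_stat(rates, values, log10_rate: bool = False):
    """Pearson correlation between window rates and a statistic.

    Pairwise-complete windows only; under ``log10_rate`` zero-rate
    windows are dropped.  Returns ``(r, p)`` with the t-approximation
    p-value.
    """
    rho = np.asarray(rates, dtype=float)
    val = np.asarray(values, dtype=float)
    if rho.shape != val.shape:
        raise ValueError("rates and values must be paired")
    if log10_rate:
        with np.errstate(divide="ignore"):
            rho = np.where(rho > 0, np.log10(np.where(rho > 0, rho, 1.0)),
                           np.nan)
    ok = np.isfinite(rho) & np.isfinite(val)
    if ok.sum() < 3:
        raise ValueError("need at least three complete pairs")
    r, p = sps.pearsonr(rho[ok], val[ok])
    return float(r), float(p)
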