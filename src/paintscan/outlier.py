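"""Local-ancestry outlier scan: the classical comparison method.

Each chromosome is binned into equal windows (default 200, matching the
image width); a window's statistic is the length-weighted mean ancestry-1
proportion across sampled haplotypes.  A window is flagged "under
selection" when its mean deviates from the genome-wide window mean by more
than ``z`` standard deviations (population SD over all windows of all
chromosomes).  The default is two-sided; a one-sided "high" mode flags only
upward deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import SampleSet

__all__ = [
    "WindowScan",
    "window_ancestry_means",
    "flag_outlier_windows",
    "scan_precision_recall",
    "target_windows",
]


@dataclass
class WindowScan:
    """Per-window ancestry means plus the genome-wide moments they imply."""

    means: np.ndarray  # (n_chromosomes, n_windows)
    n_windows: int

    @property
    def genome_mean(self) -> float:
        return float(self.means.mean())

    @property
    def genome_sd(self) -> float:
        return float(self.means.std())  # population SD over genome-wide windows


def _window_black_lengths(ends, anc, edges) -> np.ndarray:
    """Ancestry-1 length within each window for one haplotype."""
    starts = np.concatenate(([0.0], ends[:-1]))
    cum = np.concatenate(([0.0], np.cumsum(anc.astype(float) * (ends - starts))))
    knots = np.concatenate(([0.0], ends))
    return np.diff(np.interp(edges, knots, cum))


def window_ancestry_means(samples: SampleSet, n_windows: int = 200) -> WindowScan:
    """Length-weighted mean ancestry-1 dosage per window, per chromosome,
    averaged over the sampled haplotypes."""
    n_chrom = len(samples.chrom_lengths)
    means = np.zeros((n_chrom, n_windows))
    for c, L in enumerate(samples.chrom_lengths):
        edges = np.linspace(0.0, L, n_windows + 1)
        win_len = L / n_windows
        acc = np.zeros(n_windows)
        for hap in samples.haplotypes:
            ends, anc = hap.tracts[c]
            acc += _window_black_lengths(ends, anc, edges)
        means[c] = acc / (samples.n * win_len)
    return WindowScan(means, n_windows)


def flag_outlier_windows(scan: WindowScan, z: float = 3.0, sided: str = "two") -> np.ndarray:
    """Boolean flags, shaped like ``scan.means``, marking outlier windows.

    mu and sigma are computed over all genome-wide windows.  With sigma = 0
    nothing can be flagged; a warning is emitted if any window deviates.
    """
    if scan.means.size < 2:
        raise ValueError("need at least two windows genome-wide")
    if sided not in {"two", "high"}:
        raise ValueError("sided must be 'two' or 'high'")
    mu = scan.genome_mean
    sd = scan.genome_sd
    dev = scan.means - mu
    if sd == 0:
        if np.any(dev != 0):
            warnings.warn("zero genome-wide SD with nonzero deviations; no flags", stacklevel=2)
        return np.zeros_like(scan.means, dtype=bool)
    if sided == "two":
        return np.abs(dev) > z * sd
    return dev > z * sd


def target_windows(
    variant_position: float, chrom_length: float, n_windows: int = 200, half_width: int = 5
) -> np.ndarray:
    """Truth labels for scoring the scan: an 11-window region (2*half_width
    + 1) centered on the window containing the variant, mirroring the
    detector's pixel target."""
    w = min(int(variant_position / chrom_length * n_windows), n_windows - 1)
    out = np.zeros(n_windows, dtype=bool)
    out[max(w - half_width, 0) : min(w + half_width + 1, n_windows)] = True
    return out


def scan_precision_recall(
    flags_per_sim: list[np.ndarray], targets_per_sim: list[np.ndarray]
) -> tuple[float, float]:
    """Window-level precision and recall pooled over simulations.

    ``flags_per_sim[i]`` holds the flags for the focal chromosome of
    simulation i; targets are the matching truth vectors.
    """
    tp = fp = fn = 0
    for flags, truth in zip(flags_per_sim, targets_per_sim):
        flags = np.asarray(flags, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if flags.shape != truth.shape:
            raise ValueError("flag and target vectors differ in length")
        tp += int(np.sum(flags & truth))
        fp += int(np.sum(flags & ~truth))
        fn += int(np.sum(~flags & truth))
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    return p, r
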