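"""Lindley local-score genome scan: pseudo-p-values, the cumulative score
process, per-scaffold significance thresholds, and zone calling.

Per-SNP association scores (BFdB or X^T^X) are rank-transformed into
pseudo-p-values p_i = rank_i / N over the full SNP set, converted to site
scores x_i = -log10(p_i) - xi, and accumulated per scaffold by the Lindley
recursion h_i = max(0, h_{i-1} + x_i).  Runs of positive h whose peak
exceeds a scaffold-level threshold, and which contain more than three
SNPs, are significant zones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LocalScoreConfig",
    "SignificantZone",
    "pseudo_pvalues",
    "site_scores",
    "lindley",
    "lindley_max",
    "scaffold_threshold",
    "significant_zones",
    "zones_to_bed",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocalScoreConfig:
    xi: float = 3.0
    alpha: float = 0.05
    threshold_method: str = "resampling"  # or "gumbel"
    n_resample: int = 1000
    min_zone_snps: int = 4  # "more than three SNPs"
    min_scaffold_snps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")
        if self.threshold_method not in {"resampling", "gumbel"}:
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


@dataclass
class SignificantZone:
    """1-based inclusive zone on a scaffold (BED export converts)."""

    scaffold: str
    start: int
    end: int
    n_snps: int
    peak: float
    peak_pos: int
    variable: str = ""


def pseudo_pvalues(scores: np.ndarray, positions: np.ndarray | None = None) -> np.ndarray:
    """p_i = rank_i / N, rank 1 for the largest score.

    Ties are broken by genomic position: among equal scores the earlier
    position receives the smaller rank.  ``positions`` defaults to input
    order, which for a genome-ordered track is the same policy.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n == 0:
        raise ValueError("need at least one score")
    if positions is None:
        positions = np.arange(n)
    order = np.lexsort((positions, -scores))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks / n


def site_scores(pseudo_p: np.ndarray, xi: float) -> np.ndarray:
    """x_i = -log10(p_i) - xi."""
    p = np.asarray(pseudo_p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("pseudo-p-values must lie in (0, 1]")
    return -np.log10(p) - xi


def lindley(x: np.ndarray) -> np.ndarray:
    """Lindley recursion h_i = max(0, h_{i-1} + x_i), h_0 = 0, vectorized.

    Equivalent closed form: h_i = S_i - min_{0<=j<=i} S_j with S the
    running sum of x (S_0 = 0) — the identity the tests exploit.
    """
    s = np.concatenate([[0.0], np.cumsum(np.asarray(x, dtype=float))])
    return s[1:] - np.minimum.accumulate(s)[1:]


def lindley_max(x_rows: np.ndarray) -> np.ndarray:
    """Max of the Lindley process for each row of a 2-D score array."""
    s = np.cumsum(x_rows, axis=1)
    s = np.concatenate([np.zeros((x_rows.shape[0], 1)), s], axis=1)
    running_min = np.minimum.accumulate(s, axis=1)
    return (s - running_min).max(axis=1)


def lindley_track(
    scores: np.ndarray,
    scaffolds: np.ndarray,
    xi: float,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Per-SNP Lindley scores; the process resets at scaffold boundaries.

    ``scores`` are raw association scores (ranked globally into pseudo-p).
    """
    p = pseudo_pvalues(scores, positions)
    x = site_scores(p, xi)
    out = np.empty_like(x)
    for scaf in pd.unique(scaffolds):
        sel = scaffolds == scaf
        out[sel] = lindley(x[sel])
    return out


def scaffold_threshold(
    global_scores: np.ndarray,
    n_snps: int,
    config: LocalScoreConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Significance threshold for the max Lindley score of one scaffold.

    Resampling (default): draw ``n_resample`` null tracks of ``n_snps``
    site scores from the genome-wide score pool (site scores are
    exchangeable across the genome under the rank-uniform null), record
    each track's max Lindley score, and take the (1-alpha) quantile.
    Gumbel: fit location/scale to those maxima and take the analytic
    quantile.  A within-scaffold permutation would condition on the
    scaffold's own score multiset and is blind to single-site peaks
    (massively conservative), so the null is built genome-wide.
    """
    global_scores = np.asarray(global_scores, dtype=float)
    if n_snps < config.min_scaffold_snps:
        raise ValueError(
            f"scaffold has {n_snps} SNPs, below minimum {config.min_scaffold_snps}"
        )
    rng = rng or np.random.default_rng(config.seed)
    tracks = rng.choice(global_scores, size=(config.n_resample, n_snps), replace=True)
    maxima = lindley_max(tracks)
    if config.threshold_method == "gumbel":
        # method-of-moments Gumbel fit: scale = sd*sqrt(6)/pi
        scale = maxima.std() * np.sqrt(6.0) / np.pi
        loc = maxima.mean() - np.euler_gamma * scale
        if scale == 0:
            return float(maxima[0])
        return float(loc - scale * np.log(-np.log(1.0 - config.alpha)))
    return float(np.quantile(maxima, 1.0 - config.alpha, method="higher"))


def significant_zones(
    h: np.ndarray,
    thresholds: dict[str, float],
    scaffolds: np.ndarray,
    positions: np.ndarray,
    config: LocalScoreConfig,
    variable: str = "",
) -> list[SignificantZone]:
    """Maximal runs of h > 0 whose peak exceeds the scaffold threshold.

    Zones with fewer than ``min_zone_snps`` SNPs are dropped.  Output is
    sorted by (scaffold, start) and invariant to processing order.
    """
    zones: list[SignificantZone] = []
    for scaf in pd.unique(scaffolds):
        if scaf not in thresholds:
            continue
        thr = thresholds[scaf]
        sel = np.flatnonzero(scaffolds == scaf)
        hs = h[sel]
        pos = positions[sel]
        positive = hs > 0
        if not positive.any():
            continue
        # boundaries of maximal positive runs
        edges = np.diff(np.concatenate([[0], positive.astype(int), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)  # exclusive
        for a, b in zip(starts, ends):
            peak_idx = a + int(np.argmax(hs[a:b]))
            peak = float(hs[peak_idx])
            n_snps = int(b - a)
            if peak > thr and n_snps >= config.min_zone_snps:
                zones.append(
                    SignificantZone(
                        scaffold=str(scaf),
                        start=int(pos[a]),
                        end=int(pos[b - 1]),
                        n_snps=n_snps,
                        peak=peak,
                        peak_pos=int(pos[peak_idx]),
                        variable=variable,
                    )
                )
    zones.sort(key=lambda z: (z.scaffold, z.start))
    return zones


def call_zones(
    scores: np.ndarray,
    scaffolds: np.ndarray,
    positions: np.ndarray,
    config: LocalScoreConfig | None = None,
    variable: str = "",
) -> tuple[np.ndarray, dict[str, float], list[SignificantZone]]:
    """Convenience: pseudo-p -> Lindley -> thresholds -> zones in one call."""
    config = config or LocalScoreConfig()
    rng = np.random.default_rng(config.seed)
    p = pseudo_pvalues(scores, positions)
    x = site_scores(p, config.xi)
    h = np.empty_like(x)
    thresholds: dict[str, float] = {}
    by_size: dict[int, float] = {}  # scaffolds of equal SNP count share a null
    for scaf in pd.unique(scaffolds):
        sel = scaffolds == scaf
        h[sel] = lindley(x[sel])
        n_s = int(sel.sum())
        if n_s >= config.min_scaffold_snps:
            if n_s not in by_size:
                by_size[n_s] = scaffold_threshold(x, n_s, config, rng)
            thresholds[str(scaf)] = by_size[n_s]
        else:
            log.warning("scaffold %s too small for a threshold; skipped", scaf)
    zones = significant_zones(h, thresholds, scaffolds, positions, config, variable)
    return h, thresholds, zones


def zones_to_bed(zones: list[SignificantZone], path) -> None:
    """Write zones as BED (0-based half-open) with peak stats in columns."""
    lines = [
        f"{z.scaffold}\t{z.start - 1}\t{z.end}\t{z.variable or 'zone'}\t{z.peak:.4f}\t."
        for z in zones
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
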