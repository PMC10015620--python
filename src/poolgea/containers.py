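"""Shared in-memory containers for the pool-seq GEA pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PoolCounts", "AlleleFreqMatrix", "pop_labels"]


def pop_labels(n_pops: int) -> list[str]:
    return [f"POP{i + 1:02d}" for i in range(n_pops)]


@dataclass
class PoolCounts:
    """Per-SNP, per-population reference/alternate pooled read counts.

    ``snps`` holds scaffold (text), 1-based position, ref and alt alleles;
    multiallelic records keep a comma-joined ``alt`` string until filtered.
    A cell with zero total depth is a missingness event.
    """

    ref_count: np.ndarray  # (n_snps, n_pops) int
    alt_count: np.ndarray
    snps: pd.DataFrame  # columns: scaffold, pos, ref, alt
    pop_labels: list[str]

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def n_snps(self) -> int:
        return self.ref_count.shape[0]

    @property
    def n_pops(self) -> int:
        return self.ref_count.shape[1]

    def take(self, idx: np.ndarray) -> "PoolCounts":
        return PoolCounts(
            ref_count=self.ref_count[idx],
            alt_count=self.alt_count[idx],
            snps=self.snps.iloc[idx].reset_index(drop=True),
            pop_labels=list(self.pop_labels),
        )


@dataclass
class AlleleFreqMatrix:
    """Alternate-allele frequencies, SNPs x populations, with missingness.

    ``pi`` is the per-SNP unweighted mean over non-missing populations —
    the population is the unit of replication in the hierarchical model,
    so pools are not weighted by read counts.
    """

    freq: np.ndarray  # (n_snps, n_pops)
    mask: np.ndarray  # True where missing
    pi: np.ndarray  # (n_snps,)
    snps: pd.DataFrame
    pop_labels: list[str]

    @property
    def n_snps(self) -> int:
        return self.freq.shape[0]

    @property
    def n_pops(self) -> int:
        return self.freq.shape[1]

    def imputed(self) -> np.ndarray:
        """Frequencies with missing cells replaced by the SNP mean pi."""
        out = self.freq.copy()
        idx = np.nonzero(self.mask)
        out[idx] = self.pi[idx[0]]
        return out
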