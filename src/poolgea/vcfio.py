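"""Pooled-VCF parsing, the sequential SNP filters, and allele frequencies.

One VCF sample per population; per-sample AD (ref,alt read counts) carries
the pooled allele-frequency information.  Filtering follows the fixed
sequential order: non-biallelic sites, indels, mean-depth bounds,
missingness, scaffold whitelist — each step counted on the set surviving
the previous one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import AlleleFreqMatrix, PoolCounts

__all__ = [
    "FilterReport",
    "read_pool_vcf",
    "write_pool_vcf",
    "filter_snps",
    "allele_frequencies",
    "write_frequency_tsv",
]

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Sequential removal counts; ``n_retained`` closes the accounting."""

    n_input: int = 0
    n_removed_multiallelic: int = 0
    n_removed_indel: int = 0
    n_removed_depth: int = 0
    n_removed_missing: int = 0
    n_removed_scaffold: int = 0
    n_retained: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def write_pool_vcf(counts: PoolCounts, path: str | Path) -> None:
    """Write pooled counts as a minimal VCF 4.2 with per-sample AD and DP."""
    path = Path(path)
    scaffold_lengths = (
        counts.snps.groupby("scaffold", sort=False)["pos"].max().astype(int) + 1000
    )
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples with data">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">',
    ]
    for scaf, length in scaffold_lengths.items():
        lines.append(f"##contig=<ID={scaf},length={length}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(counts.pop_labels)
    lines.append("\t".join(header))

    scaf = counts.snps["scaffold"].to_numpy()
    pos = counts.snps["pos"].to_numpy()
    ref = counts.snps["ref"].to_numpy()
    alt = counts.snps["alt"].to_numpy()
    for j in range(counts.n_snps):
        fields = [
            str(scaf[j]),
            str(int(pos[j])),
            ".",
            str(ref[j]),
            str(alt[j]),
            ".",
            "PASS",
            f"NS={counts.n_pops}",
            "DP:AD",
        ]
        for i in range(counts.n_pops):
            r, a = int(counts.ref_count[j, i]), int(counts.alt_count[j, i])
            fields.append(f"{r + a}:{r},{a}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_pool_vcf(path: str | Path, sample_order: list[str] | None = None) -> PoolCounts:
    """Parse a pooled VCF into count matrices.

    Multiallelic records are retained at parse time (alt alleles joined
    with commas; alt counts summed) and flagged for removal by
    :func:`filter_snps`.  A record without the AD format field is an
    explicit failure naming the site.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if sample_order is not None:
        missing = set(sample_order) - set(samples)
        if missing:
            raise ValueError(f"samples absent from VCF: {sorted(missing)}")
        order = [samples.index(s) for s in sample_order]
        labels = list(sample_order)
    else:
        order = list(range(len(samples)))
        labels = samples

    rows, refs, alts = [], [], []
    for rec in vf:
        ref_row = np.zeros(len(order), dtype=np.int64)
        alt_row = np.zeros(len(order), dtype=np.int64)
        for out_i, sample_i in enumerate(order):
            sd = rec.samples[samples[sample_i]]
            ad = sd.get("AD")
            if ad is None or all(v is None for v in np.atleast_1d(ad)):
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} sample {samples[sample_i]} has no AD field"
                )
            ad = [0 if v is None else int(v) for v in np.atleast_1d(ad)]
            ref_row[out_i] = ad[0]
            alt_row[out_i] = sum(ad[1:])
        rows.append(
            {
                "scaffold": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": ",".join(rec.alts or ("*",)),
            }
        )
        refs.append(ref_row)
        alts.append(alt_row)
    vf.close()
    snps = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt"])
    return PoolCounts(
        ref_count=np.array(refs, dtype=np.int64).reshape(len(rows), len(order)),
        alt_count=np.array(alts, dtype=np.int64).reshape(len(rows), len(order)),
        snps=snps,
        pop_labels=labels,
    )


_NUCS = {"A", "C", "G", "T"}


def filter_snps(
    counts: PoolCounts,
    depth_min: float = 6.0,
    depth_max: float = 100.0,
    max_missing_pops: int = 2,
    scaffold_whitelist: set[str] | None = None,
) -> tuple[PoolCounts, FilterReport]:
    """Apply the sequential site filters and report per-step removals.

    Order: (1) non-biallelic, (2) indels, (3) mean read depth outside
    [depth_min, depth_max] (mean over populations with nonzero depth),
    (4) missing (zero depth) in more than ``max_missing_pops`` populations,
    (5) scaffolds outside the whitelist.
    """
    report = FilterReport(n_input=counts.n_snps)
    snps = counts.snps

    keep = ~snps["alt"].str.contains(",")
    report.n_removed_multiallelic = int((~keep).sum())
    counts = counts.take(np.flatnonzero(keep.to_numpy()))

    snps = counts.snps
    is_snv = snps["ref"].isin(_NUCS) & snps["alt"].isin(_NUCS)
    report.n_removed_indel = int((~is_snv).sum())
    counts = counts.take(np.flatnonzero(is_snv.to_numpy()))

    depth = counts.depth
    nonmissing = depth > 0
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(
            nonmissing.any(axis=1),
            depth.sum(axis=1) / np.maximum(nonmissing.sum(axis=1), 1),
            0.0,
        )
    keep = (mean_depth >= depth_min) & (mean_depth <= depth_max)
    report.n_removed_depth = int((~keep).sum())
    counts = counts.take(np.flatnonzero(keep))

    n_missing = (counts.depth == 0).sum(axis=1)
    keep = n_missing <= max_missing_pops
    report.n_removed_missing = int((~keep).sum())
    counts = counts.take(np.flatnonzero(keep))

    if scaffold_whitelist is not None:
        keep = counts.snps["scaffold"].isin(scaffold_whitelist).to_numpy()
        report.n_removed_scaffold = int((~keep).sum())
        counts = counts.take(np.flatnonzero(keep))

    report.n_retained = counts.n_snps
    if report.n_retained == 0:
        log.warning("all sites removed by filtering")
    log.info("filter report: %s", report)
    return counts, report


def allele_frequencies(counts: PoolCounts) -> AlleleFreqMatrix:
    """p_ij = alt/(ref+alt); missing where depth 0; pi = unweighted mean."""
    depth = counts.depth
    mask = depth == 0
    if np.any(mask.all(axis=1)):
        bad = int(np.flatnonzero(mask.all(axis=1))[0])
        site = counts.snps.iloc[bad]
        raise ValueError(
            f"SNP {site['scaffold']}:{site['pos']} missing in all populations "
            "(should have been removed by filtering)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(mask, np.nan, counts.alt_count / np.maximum(depth, 1))
    pi = np.nanmean(np.where(mask, np.nan, freq), axis=1)
    freq = np.where(mask, 0.0, freq)
    return AlleleFreqMatrix(
        freq=freq,
        mask=mask,
        pi=pi,
        snps=counts.snps[["scaffold", "pos"]].copy(),
        pop_labels=list(counts.pop_labels),
    )


def write_frequency_tsv(freqs: AlleleFreqMatrix, path: str | Path) -> None:
    """SNPs as rows, populations as columns; missing cells written as NA."""
    data = np.where(freqs.mask, np.nan, freqs.freq)
    df = pd.concat(
        [freqs.snps.reset_index(drop=True), pd.DataFrame(data, columns=freqs.pop_labels)],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
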