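#!/usr/bin/env python
"""Characterize the ecological side: pollination-network indices per
population, Spearman pruning of the variable set, PCA of the retained
variables, and the genomic ordination (SVD of raw frequencies) with
environment-PC1 correlations.
"""

import argparse
from pathlib import Path

import pandas as pd

from poolgea import ecology, vcfio
from poolgea.pipeline import stage_ecology


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    inputs = args.outdir / "inputs"

    paths = stage_ecology(inputs / "visitation.tsv", inputs / "environment.tsv", args.outdir)
    idx = pd.read_csv(paths["indices"], sep="\t", index_col=0)
    h = idx["partner_diversity"]
    print(
        f"partner diversity: min={h.min():.2f} max={h.max():.2f} mean={h.mean():.2f}; "
        f"d-index mean={idx['d_index'].mean():.2f} "
        f"(low values: populations behave as generalists)"
    )
    pruned = pd.read_csv(paths["env_pruned"], sep="\t", index_col=0)
    print(f"variables retained after |rho|<0.8 pruning: {list(pruned.columns)}")

    counts = vcfio.read_pool_vcf(inputs / "pools.vcf")
    freqs = vcfio.allele_frequencies(vcfio.filter_snps(counts)[0])
    gpc = ecology.genomic_pc(pruned, freqs)
    gpc["scores"].to_csv(args.outdir / "genomic_pc_scores.tsv", sep="\t", float_format="%.6g")
    print(
        f"genomic PC1 explains {100 * gpc['variance_explained'][0]:.1f}% of variance; "
        "env-PC1 Pearson correlations: "
        + ", ".join(f"{k}={v:+.2f}" for k, v in gpc["env_pc1_correlation"].items())
    )


if __name__ == "__main__":
    main()
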