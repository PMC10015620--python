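#!/usr/bin/env python
"""Parse the pooled VCF, apply the sequential site filters, and write the
allele-frequency matrix.

Filters (in order): non-biallelic sites, indels, mean read depth outside
[6, 100], missing in more than two populations, scaffold whitelist.
Writes filter_report.json and allele_frequencies.tsv.
"""

import argparse
import json
from pathlib import Path

from poolgea import vcfio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts = vcfio.read_pool_vcf(args.outdir / "inputs" / "pools.vcf")
    filtered, report = vcfio.filter_snps(counts)
    freqs = vcfio.allele_frequencies(filtered)

    report.to_json(args.outdir / "filter_report.json")
    vcfio.write_frequency_tsv(freqs, args.outdir / "allele_frequencies.tsv")
    print(json.dumps(report.__dict__, indent=2))
    print(
        f"retained {report.n_retained}/{report.n_input} SNPs; "
        f"mean alternate frequency {freqs.pi.mean():.3f}"
    )


if __name__ == "__main__":
    main()
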