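"""Quality-control and harmonize the proxy- and target-trait GWAS files.

Mirrors the published QC ladder: coverage filter on per-SNP sample size,
intersection with allele alignment (flipping the target's sign and
frequency where its effect allele is the proxy's other allele), and the
two-tailed 1st/99th-percentile filter on allele-frequency differences.
Writes the merged table and a QC report under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, load_sumstats, require_study  # noqa: E402

from crosstrait.sumstats import (  # noqa: E402
    align_and_merge,
    coverage_filter,
    maf_divergence_filter,
)


def main() -> None:
    require_study()
    proxy = load_sumstats("gwas_proxy")
    target = load_sumstats("gwas_target")

    proxy, rep_cov = coverage_filter(proxy, min_n=100)
    merged, rep_merge = align_and_merge(proxy, target)
    merged, rep_maf = maf_divergence_filter(merged, 1, 99)

    RESULTS.mkdir(exist_ok=True)
    merged.df.to_csv(RESULTS / "merged_proxy_target.tsv", sep="\t", index=False)
    with open(RESULTS / "qc_report.txt", "w") as fh:
        for label, rep in (
            ("coverage", rep_cov), ("merge", rep_merge), ("maf_divergence", rep_maf)
        ):
            fh.write(f"[{label}]\n{rep.to_text()}\n")
    print(f"harmonized {len(merged)} SNPs "
          f"(dropped: merge {rep_merge.n_dropped}, "
          f"MAF-divergence {rep_maf.n_dropped})")
    print("wrote results/merged_proxy_target.tsv and results/qc_report.txt")


if __name__ == "__main__":
    main()
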