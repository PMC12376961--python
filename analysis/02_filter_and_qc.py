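"""Quality control: locus filtering, heterozygosity, differentiation, PCA.

Applies the MAF/LD filters, then reports per-collection expected
heterozygosity, Weir-Cockerham theta of each river cohort against the
hatchery reference (with bootstrap CIs), and the leading PCA axes.
"""

import numpy as np
import pandas as pd

from common import GENOTYPES_CSV, METADATA_TSV, RESULTS, SEED
from deintrogress.genotype_io import filter_loci, read_genotype_table
from deintrogress.popgen import allele_freqs, expected_heterozygosity, pca, wc_theta


def main():
    gm, meta = read_genotype_table(GENOTYPES_CSV, "wide_csv", METADATA_TSV)
    gm_f, report = filter_loci(gm, meta, maf_min=0.05, r2_max=0.8,
                               polymorphic_in=["WILD_REF", "HAT_REF"])
    print(f"filtering: {report.n_input} -> {report.n_retained} loci "
          f"({len(report.removed)} removed)")
    report.removed.to_csv(RESULTS / "qc_removed_loci.tsv", sep="\t", index=False)

    groups = {}
    for m in meta:
        groups.setdefault(m.collection_label, []).append(m.sample_id)
    freqs = allele_freqs(gm_f, groups=groups)
    het_rows = [
        (label, len(groups[label]), expected_heterozygosity(freqs[label]))
        for label in sorted(groups)
    ]
    het = pd.DataFrame(het_rows, columns=["collection", "n", "mean_hexp"])
    het.to_csv(RESULTS / "qc_heterozygosity.tsv", sep="\t", index=False)
    print("\nexpected heterozygosity per collection:")
    print(het.round(3).to_string(index=False))

    rows = []
    for label in sorted(groups):
        if label == "HAT_REF":
            continue
        res = wc_theta(gm_f, {label: groups[label], "HAT_REF": groups["HAT_REF"]},
                       n_bootstrap=200, seed=SEED)
        rows.append((label, res.theta_multilocus, res.ci_low, res.ci_high))
    theta = pd.DataFrame(rows, columns=["collection", "theta_vs_HAT", "ci_low", "ci_high"])
    theta.to_csv(RESULTS / "qc_theta_vs_hatchery.tsv", sep="\t", index=False)
    print("\ndifferentiation from the hatchery strain (theta, 95% bootstrap CI):")
    print(theta.round(3).to_string(index=False))

    res = pca(gm_f)
    print(f"\nPCA: PC1 {res.explained_variance_ratio[0]:.1%}, "
          f"PC2 {res.explained_variance_ratio[1]:.1%} variance explained")
    coords = pd.DataFrame(res.coordinates[:, :2], columns=["PC1", "PC2"])
    coords.insert(0, "sample_id", res.individuals)
    coords.to_csv(RESULTS / "qc_pca_coordinates.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
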