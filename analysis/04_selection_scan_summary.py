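"""Summarise the temporal drift-vs-selection scan produced by driver 03.

Reports outlier counts per Ne scenario and whether the truly selected loci
(known from the simulation) were recovered.
"""

import pandas as pd

from common import RESULTS, scenario
from deintrogress.synthetic_data import simulate_stocking_scenario


def main():
    scan = pd.read_csv(RESULTS / "pipeline" / "selection_scan.tsv", sep="\t", comment="#")
    _, _, truth = simulate_stocking_scenario(scenario())
    true_sel = {truth.locus_ids[s.locus_index] for s in truth.selected}

    for ne, grp in scan.groupby("Ne"):
        outliers = set(grp.loc[grp["outlier"].fillna(False), "locus_id"])
        hits = outliers & true_sel
        print(f"Ne={ne}: {len(outliers)} outliers after FDR "
              f"({len(hits)}/{len(true_sel)} truly selected loci recovered)")
        top = grp.sort_values("p_value").head(6)
        print(top[["locus_id", "s_hat", "lrt", "p_value", "q_value", "outlier"]]
              .round(4).to_string(index=False))
        print()
    six6 = truth.locus_ids[0]
    row = scan[scan.locus_id == six6]
    print(f"six6-like locus ({six6}) per scenario:")
    print(row[["Ne", "s_hat", "lrt", "p_value", "q_value", "outlier"]]
          .round(4).to_string(index=False))


if __name__ == "__main__":
    main()
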