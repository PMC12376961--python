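"""Summarise the genomic-cline introgression verdicts produced by driver 03."""

import pandas as pd

from common import RESULTS, scenario
from deintrogress.synthetic_data import simulate_stocking_scenario


def main():
    clines = pd.read_csv(RESULTS / "pipeline" / "clines.tsv", sep="\t", comment="#")
    _, _, truth = simulate_stocking_scenario(scenario())
    true_sel = {truth.locus_ids[s.locus_index] for s in truth.selected}

    counts = clines["verdict"].value_counts()
    print(f"cline panel: {len(clines)} informative loci")
    print(counts.to_string())
    reduced = clines[clines.verdict == "reduced"]
    if len(reduced):
        print("\nreduced-introgression loci:")
        print(reduced[["locus_id", "deviance", "direction_statistic", "p_value", "q_value"]]
              .round(4).to_string(index=False))
        hits = set(reduced.locus_id) & true_sel
        print(f"\n{len(hits)}/{len(true_sel)} truly selected loci among the "
              f"reduced-introgression calls")
    six6 = truth.locus_ids[0]
    row = clines[clines.locus_id == six6]
    if len(row):
        print(f"\nsix6-like locus ({six6}):")
        print(row[["deviance", "direction_statistic", "p_value", "q_value", "verdict"]]
              .round(4).to_string(index=False))
    else:
        print(f"\nsix6-like locus ({six6}) not in the informative panel")


if __name__ == "__main__":
    main()
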