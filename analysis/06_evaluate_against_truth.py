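"""Score every pipeline estimate against the simulation ground truth.

Reports q RMSE/bias, the hybrid-class confusion structure, and the
selection-scan and cline-verdict precision/recall.
"""

import pandas as pd

from common import RESULTS, scenario
from deintrogress.hybrid_classes import PAPER_THRESHOLDS
from deintrogress.synthetic_data import evaluate_recovery, simulate_stocking_scenario


def main():
    _, _, truth = simulate_stocking_scenario(scenario())
    pipe = RESULTS / "pipeline"
    q = pd.read_csv(pipe / "admixture_q.tsv", sep="\t", comment="#")
    classes = pd.read_csv(pipe / "class_assignments.tsv", sep="\t", comment="#")
    scan = pd.read_csv(pipe / "selection_scan.tsv", sep="\t", comment="#")
    clines = pd.read_csv(pipe / "clines.tsv", sep="\t", comment="#")

    outliers = scan.loc[
        (scan.Ne == 200) & scan["outlier"].fillna(False), "locus_id"
    ].tolist()
    # true class of each wild-caught fish from its pedigree ancestry interval
    anc = truth.ancestry.set_index("sample_id").true_ancestry
    true_class = {
        s: PAPER_THRESHOLDS.assign(float(anc[s])) for s in classes["sample_id"]
    }
    metrics = evaluate_recovery(
        truth,
        q_estimates=q[["sample_id", "q"]],
        class_assignments=classes,
        true_class=true_class,
        selection_outliers=outliers,
        cline_verdicts=clines,
    )
    print(f"q RMSE vs true ancestry:  {metrics['q_rmse']:.3f}")
    print(f"q bias:                   {metrics['q_bias']:+.3f}")
    print(f"class accuracy (vs ancestry interval): {metrics['class_accuracy']:.2f}")
    print("\nclass confusion (rows = true interval, cols = assigned):")
    print(metrics["class_confusion"].to_string())
    print(f"\nselection scan (Ne=200):  precision {metrics['selection_precision']:.2f}, "
          f"recall {metrics['selection_recall']:.2f}")
    print(f"cline verdicts:           precision {metrics['cline_precision']:.2f}, "
          f"recall {metrics['cline_recall']:.2f}")

    pd.DataFrame(
        [(k, v) for k, v in metrics.items() if not isinstance(v, pd.DataFrame)],
        columns=["metric", "value"],
    ).to_csv(RESULTS / "recovery_metrics.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
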