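"""Shared scenario definition and paths for the numbered analysis drivers.

The study design emulated here: two rivers stocked with a divergent hatchery
strain (multi-locus FST 0.026 against the wild pools) for six generations,
then left to recover for seven more; 288-SNP panel; five loci under selection
(s = 0.25) against the hatchery-associated allele, one of them a six6-like
locus nearly fixed in the hatchery strain; cohorts of 40 spawners sampled at
the end of stocking and 2, 4 and 7 generations later (3.5 years per
generation, anchored at calendar year 2001).
"""

from pathlib import Path

from deintrogress.synthetic_data import two_river_preset

SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA_DIR = RESULTS / "data"

GENOTYPES_CSV = DATA_DIR / "two_rivers_genotypes.csv"
METADATA_TSV = DATA_DIR / "two_rivers_metadata.tsv"
TRUTH_TSV = DATA_DIR / "two_rivers_truth_ancestry.tsv"


def scenario():
    return two_river_preset(n_loci=288, Ne=200, seed=SEED, sample_size=40)
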