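"""Simulated admixture classes, q-threshold calibration and classification.

Five pedigree-defined admixture classes span the wild-to-hatchery continuum:
WILD (expected q = 0), BC_WILD (F1 x wild backcross, 0.25), F1 (0.5), BC_HAT
(F1 x hatchery backcross, 0.75) and HAT (1). Genotypes are simulated per
class from parental allele-frequency tables by explicit gamete sampling;
q-interval classification thresholds are either the published defaults or
calibrated from the simulated class distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, LocusInfo
from .popgen import AlleleFreqs

__all__ = [
    "CLASS_NAMES",
    "EXPECTED_Q",
    "HybridClassSpec",
    "ClassThresholds",
    "ClassificationSummary",
    "simulate_hybrid_class",
    "calibrate_thresholds",
    "summarize_simulated_classes",
    "classify",
    "recovery_trajectory",
    "PAPER_THRESHOLDS",
    "COARSE_WILD_MAX",
    "COARSE_HAT_MIN",
]

CLASS_NAMES = ("WILD", "BC_WILD", "F1", "BC_HAT", "HAT")
EXPECTED_Q = {"WILD": 0.0, "BC_WILD": 0.25, "F1": 0.5, "BC_HAT": 0.75, "HAT": 1.0}

# Coarse screening thresholds used only to pick WILD proxies / confirm HAT refs
COARSE_WILD_MAX = 0.20
COARSE_HAT_MIN = 0.80


@dataclass(frozen=True)
class HybridClassSpec:
    class_name: str
    expected_q: float

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")
        if abs(self.expected_q - EXPECTED_Q[self.class_name]) > 1e-12:
            raise ValueError(
                f"{self.class_name}: expected_q must be {EXPECTED_Q[self.class_name]}"
            )


@dataclass(frozen=True)
class ClassThresholds:
    """Four ordered boundaries partitioning [0,1] into the five class intervals.

    Intervals are (b_prev, b] for the first four classes and (b3, 1] closed
    for HAT except that the third boundary is exclusive on the HAT side:
    WILD [0, b0], low (b0, b1], medium (b1, b2], high (b2, b3), HAT [b3, 1].
    Boundary points between high and HAT go to the higher class.
    """

    boundaries: tuple[float, float, float, float]
    provenance: str = "paper_default"

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) != 4 or not all(b[i] < b[i + 1] for i in range(3)):
            raise ValueError("boundaries must be four strictly increasing values")
        if b[0] < 0 or b[3] > 1:
            raise ValueError("boundaries must lie within [0, 1]")

    def assign(self, q: float) -> str:
        b0, b1, b2, b3 = self.boundaries
        if not (0 <= q <= 1):
            raise ValueError(f"q = {q} outside [0, 1]")
        if q <= b0:
            return "WILD"
        if q <= b1:
            return "BC_WILD"
        if q <= b2:
            return "F1"
        if q < b3:
            return "BC_HAT"
        return "HAT"


#: Printed classification criteria: WILD [0, 0.12], low admixture (0.12, 0.34],
#: medium (0.34, 0.60], high (0.60, 0.84), HAT [0.84, 1].
PAPER_THRESHOLDS = ClassThresholds((0.12, 0.34, 0.60, 0.84), provenance="paper_default")


# ---------------------------------------------------------------------------
# Simulation of the five classes
# ---------------------------------------------------------------------------

def _gametes_from_pool(freq: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n gametes (rows) of reference-allele indicators drawn from a source pool."""
    return rng.random((n, len(freq))) < freq[None, :]


def simulate_hybrid_class(
    wild_freqs: AlleleFreqs,
    hat_freqs: AlleleFreqs,
    class_name: str,
    n: int = 50,
    seed: int | None = None,
    sample_prefix: str | None = None,
) -> GenotypeMatrix:
    """Simulate n multi-locus genotypes of one admixture class.

    Pedigree-based gamete sampling, loci independent: pure-class individuals
    are Hardy-Weinberg draws from their source frequencies; an F1 receives
    one gamete from each source; a backcross receives one gamete from a
    freshly simulated F1 parent (one of the parent's two alleles per locus,
    chosen at random) and one gamete from the pure source.
    """
    if class_name not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_name!r}")
    p_w = np.asarray(wild_freqs.freq, dtype=float)
    p_h = np.asarray(hat_freqs.freq, dtype=float)
    if np.isnan(p_w).any() or np.isnan(p_h).any():
        raise ValueError("frequency tables must be defined at all loci")
    rng = np.random.default_rng(seed)
    L = len(p_w)

    if class_name == "WILD":
        dosage = _gametes_from_pool(p_w, n, rng).astype(np.int8) + _gametes_from_pool(
            p_w, n, rng
        )
    elif class_name == "HAT":
        dosage = _gametes_from_pool(p_h, n, rng).astype(np.int8) + _gametes_from_pool(
            p_h, n, rng
        )
    elif class_name == "F1":
        dosage = _gametes_from_pool(p_w, n, rng).astype(np.int8) + _gametes_from_pool(
            p_h, n, rng
        )
    else:  # backcrosses: explicit F1 parent per individual
        f1_wild_gam = _gametes_from_pool(p_w, n, rng)
        f1_hat_gam = _gametes_from_pool(p_h, n, rng)
        pick_hat_side = rng.random((n, L)) < 0.5  # which F1 allele enters the gamete
        f1_gam = np.where(pick_hat_side, f1_hat_gam, f1_wild_gam)
        pure = p_w if class_name == "BC_WILD" else p_h
        dosage = f1_gam.astype(np.int8) + _gametes_from_pool(pure, n, rng)

    prefix = sample_prefix or f"SIM_{class_name}"
    individuals = [f"{prefix}_{i:03d}" for i in range(n)]
    loci = [LocusInfo(lid, ("A", "B")) for lid in wild_freqs.locus_ids]
    return GenotypeMatrix(individuals, loci, dosage.astype(np.int8))


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

def calibrate_thresholds(
    sim_q_by_class: Mapping[str, Sequence[float]],
    epsilon: float = 0.01,
) -> tuple[ClassThresholds, pd.DataFrame]:
    """Calibrate class boundaries from simulated q distributions.

    The upper boundary of each of the first three classes is the minimum
    simulated q of the next-higher class minus ``epsilon`` (so a simulated
    BC_WILD minimum of 0.13 puts the WILD/low boundary at 0.12, and an F1
    minimum of 0.35 puts the low/medium boundary at 0.34). The HAT lower
    boundary is the lower 90%-interval bound (5th percentile) of simulated
    HAT q. Also returns a per-class report of means, ranges and 90%
    intervals, with a column flagging overlap of adjacent 90% intervals.
    """
    for name in CLASS_NAMES:
        vals = np.asarray(sim_q_by_class.get(name, ()), dtype=float)
        if len(vals) < 10:
            raise ValueError(f"class {name}: need >= 10 simulated q values")
    qs = {name: np.sort(np.asarray(sim_q_by_class[name], float)) for name in CLASS_NAMES}

    b0 = round(float(qs["BC_WILD"].min()) - epsilon, 10)
    b1 = round(float(qs["F1"].min()) - epsilon, 10)
    b2 = round(float(qs["BC_HAT"].min()) - epsilon, 10)
    b3 = round(float(np.percentile(qs["HAT"], 5)), 10)
    if not (b0 < b1 < b2 < b3):
        raise ValueError(
            "class distributions overlap too much to calibrate boundaries: "
            f"candidates {b0}, {b1}, {b2}, {b3} are not increasing"
        )
    if b0 < 0:
        raise ValueError(
            "class distributions overlap too much to calibrate boundaries: "
            f"simulated BC_WILD minimum {qs['BC_WILD'].min():.3f} leaves no WILD "
            "interval (panel likely too small/weakly diverged for calibration)"
        )
    thresholds = ClassThresholds((b0, b1, b2, b3), provenance="calibrated")
    return thresholds, summarize_simulated_classes(sim_q_by_class)


def summarize_simulated_classes(
    sim_q_by_class: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Per-class means, ranges and 90% intervals of simulated q values.

    Flags classes whose 90% interval overlaps a neighbouring class (the
    calibration-quality diagnostic reported alongside thresholds).
    """
    qs = {name: np.sort(np.asarray(sim_q_by_class[name], float)) for name in CLASS_NAMES}
    rows = []
    lo90 = {n: np.percentile(qs[n], 5) for n in CLASS_NAMES}
    hi90 = {n: np.percentile(qs[n], 95) for n in CLASS_NAMES}
    for i, name in enumerate(CLASS_NAMES):
        overlap = False
        if i > 0:
            overlap |= lo90[name] <= hi90[CLASS_NAMES[i - 1]]
        if i < len(CLASS_NAMES) - 1:
            overlap |= hi90[name] >= lo90[CLASS_NAMES[i + 1]]
        rows.append(
            (
                name,
                EXPECTED_Q[name],
                qs[name].mean(),
                qs[name].min(),
                qs[name].max(),
                lo90[name],
                hi90[name],
                overlap,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "class_name",
            "expected_q",
            "mean_q",
            "min_q",
            "max_q",
            "q05",
            "q95",
            "ci90_overlaps_neighbor",
        ],
    )


# ---------------------------------------------------------------------------
# Classification & trajectories
# ---------------------------------------------------------------------------

@dataclass
class ClassificationSummary:
    per_individual: pd.DataFrame  # sample_id, collection_label, q, hybrid_class
    per_collection: pd.DataFrame  # collection, counts/fractions per class, mean q, frac q<0.34


def classify(
    q_table: pd.DataFrame,
    thresholds: ClassThresholds,
    low_admixture_cutoff: float = 0.34,
) -> ClassificationSummary:
    """Classify individuals by q interval and aggregate per collection.

    ``q_table`` needs columns sample_id, collection_label, q. The reported
    "fraction with no or low admixture" counts q < ``low_admixture_cutoff``
    (strictly below, matching the q < 0.34 criterion).
    """
    required = {"sample_id", "collection_label", "q"}
    if not required <= set(q_table.columns):
        raise ValueError(f"q_table must have columns {sorted(required)}")
    q = q_table["q"].to_numpy(dtype=float)
    if np.any((q < 0) | (q > 1) | np.isnan(q)):
        raise ValueError("q values must lie in [0, 1]")
    per_ind = q_table.copy()
    per_ind["hybrid_class"] = [thresholds.assign(v) for v in q]

    rows = []
    for label, grp in per_ind.groupby("collection_label", sort=False):
        counts = {c: int((grp["hybrid_class"] == c).sum()) for c in CLASS_NAMES}
        total = len(grp)
        row = {"collection_label": label, "n": total, "mean_q": grp["q"].mean()}
        for c in CLASS_NAMES:
            row[f"n_{c}"] = counts[c]
            row[f"frac_{c}"] = counts[c] / total
        row["frac_low_or_no_admixture"] = float((grp["q"] < low_admixture_cutoff).mean())
        rows.append(row)
    return ClassificationSummary(per_ind, pd.DataFrame(rows))


def recovery_trajectory(
    summary: ClassificationSummary,
    collection_years: Mapping[str, int],
) -> pd.DataFrame:
    """Chronological table of mean q and class fractions per collection.

    Includes the percent change of mean q between first and last collection
    (a -39% change corresponds to mean q falling 0.46 -> 0.28).
    """
    per = summary.per_collection.copy()
    missing = set(per["collection_label"]) - set(collection_years)
    if missing:
        raise ValueError(f"no year for collections: {sorted(missing)}")
    if len(per) < 2:
        raise ValueError("need >= 2 collections for a trajectory")
    per["year"] = per["collection_label"].map(collection_years)
    per = per.sort_values(["year", "collection_label"], kind="stable").reset_index(drop=True)
    first, last = per["mean_q"].iloc[0], per["mean_q"].iloc[-1]
    per.attrs["percent_change_mean_q"] = percent_change(first, last)
    return per


def percent_change(first_mean_q: float, last_mean_q: float) -> float:
    """Percent change of mean q between two collections (negative = recovery)."""
    if first_mean_q == 0:
        raise ValueError("first mean q is zero; percent change undefined")
    return 100.0 * (last_mean_q - first_mean_q) / first_mean_q
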