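"""Reading, writing, validating and filtering diploid bi-allelic SNP genotype data.

The universal in-memory currency of the pipeline is :class:`GenotypeMatrix`:
an individuals x loci table of reference-allele dosages (0/1/2) with a
missing-data mask. Three on-disk dialects are supported: VCF, the two-row
"structure" text format, and a wide CSV with one dosage column per locus.
Sample metadata (collection, river, year, role) travels in a sidecar TSV.

Dosage always counts copies of the per-locus *reference* allele (the file's
REF, or the first-listed allele), and the reference designation is fixed for
the lifetime of a dataset: merging or comparing two files reconciles allele
polarity explicitly by allele symbols and never flips silently. Strand-
ambiguous pairs (A/T, C/G) cannot be reconciled from symbols alone and are
flagged rather than guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusInfo",
    "CollectionMeta",
    "GenotypeMatrix",
    "GenotypeParseError",
    "read_genotype_table",
    "write_genotype_table",
    "read_metadata",
    "write_metadata",
    "validate_concordance",
    "filter_loci",
]

MISSING_CODE = -9  # structure-dialect missing genotype code

ROLES = ("wild_caught", "hatchery_reference", "wild_reference", "simulated")


class GenotypeParseError(ValueError):
    """Malformed genotype file; message names the offending line/record."""


@dataclass(frozen=True)
class LocusInfo:
    """A bi-allelic SNP locus.

    ``alleles`` is an ordered pair; the first symbol is the designated
    reference allele whose copies the dosage counts.
    """

    locus_id: str
    alleles: tuple[str, str]
    linkage_group: str | None = None
    panel_membership: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError(
                f"locus {self.locus_id!r}: exactly two distinct alleles required, "
                f"got {self.alleles!r}"
            )

    @property
    def ref(self) -> str:
        return self.alleles[0]

    @property
    def alt(self) -> str:
        return self.alleles[1]

    def is_strand_ambiguous(self) -> bool:
        return set(map(str.upper, self.alleles)) in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class CollectionMeta:
    """Per-individual sampling metadata."""

    sample_id: str
    collection_label: str
    river: str
    year: int
    role: str = "wild_caught"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")


class GenotypeMatrix:
    """Individuals x loci diploid dosage table with a missing mask.

    Parameters
    ----------
    individuals:
        Ordered sample ids (unique).
    loci:
        Ordered :class:`LocusInfo` (unique ids).
    dosage:
        Integer array, shape (n_individuals, n_loci), values in {0, 1, 2}
        wherever ``missing`` is False. Masked entries may hold any value.
    missing:
        Boolean array of the same shape; True marks missing calls.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[LocusInfo],
        dosage: np.ndarray,
        missing: np.ndarray | None = None,
    ) -> None:
        self.individuals = list(individuals)
        self.loci = list(loci)
        dosage = np.asarray(dosage, dtype=np.int8)
        if missing is None:
            missing = np.zeros(dosage.shape, dtype=bool)
        missing = np.asarray(missing, dtype=bool)
        if dosage.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if missing.shape != dosage.shape:
            raise ValueError("missing mask shape differs from dosage shape")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate sample_id in individuals")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus_id in loci")
        valid = (dosage >= 0) & (dosage <= 2)
        if not np.all(valid | missing):
            bad = np.argwhere(~valid & ~missing)[0]
            raise ValueError(
                f"dosage out of range at individual {self.individuals[bad[0]]!r}, "
                f"locus {ids[bad[1]]!r}"
            )
        self.dosage = dosage
        self.missing = missing
        self._ind_index = {s: i for i, s in enumerate(self.individuals)}
        self._locus_index = {l.locus_id: j for j, l in enumerate(self.loci)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def locus_index(self, locus_id: str) -> int:
        return self._locus_index[locus_id]

    def individual_index(self, sample_id: str) -> int:
        return self._ind_index[sample_id]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeMatrix({self.n_individuals} individuals x {self.n_loci} loci, "
            f"{self.missing.mean():.1%} missing)"
        )

    # -- subsetting ----------------------------------------------------------

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given sample/locus ids (order kept)."""
        rows = (
            np.arange(self.n_individuals)
            if individuals is None
            else np.array([self._ind_index[s] for s in individuals], dtype=int)
        )
        cols = (
            np.arange(self.n_loci)
            if loci is None
            else np.array([self._locus_index[l] for l in loci], dtype=int)
        )
        return GenotypeMatrix(
            [self.individuals[i] for i in rows],
            [self.loci[j] for j in cols],
            self.dosage[np.ix_(rows, cols)],
            self.missing[np.ix_(rows, cols)],
        )

    def concat_individuals(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack two matrices over the same loci (polarity must already agree)."""
        if self.locus_ids != other.locus_ids:
            raise ValueError("locus sets/order differ; align before concatenation")
        for a, b in zip(self.loci, other.loci):
            if a.alleles != b.alleles:
                raise ValueError(
                    f"allele polarity differs at {a.locus_id}: {a.alleles} vs {b.alleles}"
                )
        return GenotypeMatrix(
            self.individuals + other.individuals,
            self.loci,
            np.vstack([self.dosage, other.dosage]),
            np.vstack([self.missing, other.missing]),
        )


# ---------------------------------------------------------------------------
# Metadata sidecar
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[CollectionMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "collection_label", "river", "year", "role"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeParseError(f"metadata {path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise GenotypeParseError(f"metadata {path}: duplicate sample_id {dup!r}")
    return [
        CollectionMeta(
            sample_id=r.sample_id,
            collection_label=r.collection_label,
            river=r.river,
            year=int(r.year),
            role=r.role,
        )
        for r in df.itertuples()
    ]


def write_metadata(meta: Iterable[CollectionMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (m.sample_id, m.collection_label, m.river, m.year, m.role)
            for m in meta
        ],
        columns=["sample_id", "collection_label", "river", "year", "role"],
    )
    df.to_csv(path, sep="\t", index=False)


def meta_by_sample(meta: Iterable[CollectionMeta]) -> dict[str, CollectionMeta]:
    out: dict[str, CollectionMeta] = {}
    for m in meta:
        if m.sample_id in out:
            raise ValueError(f"duplicate CollectionMeta for sample {m.sample_id!r}")
        out[m.sample_id] = m
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

Format = Literal["vcf", "structure_tworow", "wide_csv"]


def read_genotype_table(
    path: str | Path,
    format: Format,
    metadata_path: str | Path | None = None,
) -> tuple[GenotypeMatrix, list[CollectionMeta]]:
    """Read genotypes (and, if supplied, sidecar metadata) in one of three dialects.

    Returns the matrix plus the metadata records for its individuals
    (an empty list when no sidecar is given).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "structure_tworow":
        gm = _read_structure(path)
    elif format == "wide_csv":
        gm = _read_wide_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    meta: list[CollectionMeta] = []
    if metadata_path is not None:
        bysample = meta_by_sample(read_metadata(metadata_path))
        absent = [s for s in gm.individuals if s not in bysample]
        if absent:
            raise GenotypeParseError(
                f"metadata lacks records for samples: {absent[:5]}"
            )
        meta = [bysample[s] for s in gm.individuals]
    return gm, meta


def write_genotype_table(gm: GenotypeMatrix, path: str | Path, format: Format) -> None:
    path = Path(path)
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "structure_tworow":
        _write_structure(gm, path)
    elif format == "wide_csv":
        _write_wide_csv(gm, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise GenotypeParseError(f"{path}: duplicate sample id in VCF header")
    loci: list[LocusInfo] = []
    dosage_cols: list[np.ndarray] = []
    missing_cols: list[np.ndarray] = []
    n_rejected = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.ALT[0] or var.ALT[0] == ".":
            n_rejected += 1
            continue
        locus_id = var.ID if var.ID and var.ID != "." else f"{var.CHROM}:{var.POS}"
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN/missing, 3 HOM_ALT
        gts = np.asarray(var.gt_types)
        alt_count = np.where(gts == 0, 0, np.where(gts == 1, 1, np.where(gts == 3, 2, 0)))
        miss = gts == 2
        dosage_cols.append((2 - alt_count).astype(np.int8))
        missing_cols.append(miss)
        loci.append(
            LocusInfo(locus_id=locus_id, alleles=(var.REF, var.ALT[0]), linkage_group=var.CHROM)
        )
    if n_rejected:
        warnings.warn(
            f"{path}: rejected {n_rejected} non-bi-allelic site(s)", stacklevel=2
        )
    if not loci:
        raise GenotypeParseError(f"{path}: no usable bi-allelic sites")
    return GenotypeMatrix(
        samples,
        loci,
        np.column_stack(dosage_cols),
        np.column_stack(missing_cols),
    )


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms: list[str] = []
    for loc in gm.loci:
        chrom = loc.linkage_group or "chrUn"
        if chrom not in chroms:
            chroms.append(chrom)
    for chrom in chroms:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.individuals)
    )
    pos_counter: dict[str, int] = {}
    gt_code = {0: "1/1", 1: "0/1", 2: "0/0"}  # dosage of REF -> GT string
    for j, loc in enumerate(gm.loci):
        chrom = loc.linkage_group or "chrUn"
        pos_counter[chrom] = pos_counter.get(chrom, 0) + 1
        calls = [
            "./." if gm.missing[i, j] else gt_code[int(gm.dosage[i, j])]
            for i in range(gm.n_individuals)
        ]
        lines.append(
            f"{chrom}\t{pos_counter[chrom]}\t{loc.locus_id}\t{loc.ref}\t{loc.alt}"
            f"\t.\t.\t.\tGT\t" + "\t".join(calls)
        )
    path.write_text("\n".join(lines) + "\n")


def _read_structure(path: Path) -> GenotypeMatrix:
    """Two-row-per-individual structure dialect.

    Line 1: whitespace-separated locus ids. Then, per individual, two lines:
    ``sample_id a1 a2 ... aL`` where each ``a`` is an allele symbol (one
    haplotype row per line) and -9 codes missing.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise GenotypeParseError(f"{path}: empty header line")
        n_loci = len(header)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != n_loci + 1:
                raise GenotypeParseError(
                    f"{path}: line {lineno}: expected {n_loci + 1} fields, "
                    f"got {len(fields)}"
                )
            rows.append(fields)
    if len(rows) % 2:
        raise GenotypeParseError(f"{path}: odd number of haplotype rows")
    n_ind = len(rows) // 2
    samples: list[str] = []
    alleles_raw = np.empty((2 * n_ind, n_loci), dtype=object)
    for i in range(n_ind):
        r1, r2 = rows[2 * i], rows[2 * i + 1]
        if r1[0] != r2[0]:
            raise GenotypeParseError(
                f"{path}: rows for individual {r1[0]!r}/{r2[0]!r} not paired"
            )
        samples.append(r1[0])
        alleles_raw[2 * i] = r1[1:]
        alleles_raw[2 * i + 1] = r2[1:]
    if len(set(samples)) != len(samples):
        dup = next(s for s in samples if samples.count(s) > 1)
        raise GenotypeParseError(f"{path}: duplicate sample_id {dup!r}")

    miss_code = str(MISSING_CODE)
    loci: list[LocusInfo] = []
    dosage = np.zeros((n_ind, n_loci), dtype=np.int8)
    missing = np.zeros((n_ind, n_loci), dtype=bool)
    for j in range(n_loci):
        col = alleles_raw[:, j]
        observed = sorted({a for a in col if a != miss_code})
        if len(observed) > 2:
            raise GenotypeParseError(
                f"{path}: locus {header[j]!r} shows >2 alleles: {observed}"
            )
        if len(observed) == 0:
            observed = ["1", "2"]  # wholly missing column keeps a placeholder pair
        elif len(observed) == 1:
            # monomorphic in this file: invent a complementary symbol so the
            # bi-allelic invariant holds; dosage stays well defined.
            observed = observed + [observed[0] + "_alt"]
        ref = observed[0]
        for i in range(n_ind):
            a1, a2 = alleles_raw[2 * i, j], alleles_raw[2 * i + 1, j]
            if a1 == miss_code or a2 == miss_code:
                missing[i, j] = True
            else:
                dosage[i, j] = (a1 == ref) + (a2 == ref)
        loci.append(LocusInfo(locus_id=header[j], alleles=(observed[0], observed[1])))
    return GenotypeMatrix(samples, loci, dosage, missing)


def _write_structure(gm: GenotypeMatrix, path: Path) -> None:
    miss = str(MISSING_CODE)
    lines = [" ".join(gm.locus_ids)]
    for i, sample in enumerate(gm.individuals):
        hap1: list[str] = [sample]
        hap2: list[str] = [sample]
        for j, loc in enumerate(gm.loci):
            if gm.missing[i, j]:
                hap1.append(miss)
                hap2.append(miss)
            else:
                d = int(gm.dosage[i, j])
                hap1.append(loc.ref if d >= 1 else loc.alt)
                hap2.append(loc.ref if d == 2 else loc.alt)
        lines.append(" ".join(hap1))
        lines.append(" ".join(hap2))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_wide_csv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, comment="#")
    if "sample_id" not in df.columns:
        raise GenotypeParseError(f"{path}: wide CSV needs a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise GenotypeParseError(f"{path}: duplicate sample_id {dup!r}")
    locus_cols = [c for c in df.columns if c != "sample_id"]
    if not locus_cols:
        raise GenotypeParseError(f"{path}: no locus columns")
    vals = df[locus_cols].to_numpy(dtype=float)
    missing = np.isnan(vals)
    dosage = np.where(missing, 0, vals)
    if not np.isin(dosage[~missing], [0, 1, 2]).all():
        raise GenotypeParseError(f"{path}: dosage values outside {{0,1,2}}")
    loci = [LocusInfo(locus_id=c, alleles=("A", "B")) for c in locus_cols]
    return GenotypeMatrix(
        df["sample_id"].astype(str).tolist(), loci, dosage.astype(np.int8), missing
    )


def _write_wide_csv(gm: GenotypeMatrix, path: Path) -> None:
    vals = gm.dosage.astype(float)
    vals[gm.missing] = np.nan
    df = pd.DataFrame(vals, columns=gm.locus_ids)
    df.insert(0, "sample_id", gm.individuals)
    df.to_csv(path, index=False, float_format="%.0f")


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    rate: float
    n_compared: int
    n_mismatch: int
    mismatches: pd.DataFrame  # sample_id, locus_id, dosage_a, dosage_b
    skipped_loci: list[str]   # shared loci whose allele pairs could not be reconciled


def validate_concordance(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> ConcordanceResult:
    """Proportion of matching non-missing calls over shared individual x locus cells.

    Allele polarity is reconciled by allele symbols before comparison: a locus
    typed with reversed REF/ALT in ``gm_b`` has its dosages flipped (d -> 2-d).
    Strand-ambiguous loci (A/T, C/G) with reversed symbols cannot be told apart
    from a strand flip and are skipped with a report entry.
    """
    shared_inds = [s for s in gm_a.individuals if s in gm_b._ind_index]
    shared_loci = [l for l in gm_a.locus_ids if l in gm_b._locus_index]
    if not shared_inds or not shared_loci:
        raise ValueError("no shared individual x locus cells to compare")

    usable: list[str] = []
    flip: list[bool] = []
    skipped: list[str] = []
    for lid in shared_loci:
        la = gm_a.loci[gm_a.locus_index(lid)]
        lb = gm_b.loci[gm_b.locus_index(lid)]
        if la.alleles == lb.alleles:
            usable.append(lid)
            flip.append(False)
        elif la.alleles == lb.alleles[::-1]:
            if la.is_strand_ambiguous():
                skipped.append(lid)
            else:
                usable.append(lid)
                flip.append(True)
        else:
            skipped.append(lid)
    if not usable:
        raise ValueError("no reconcilable shared loci (all allele pairs incompatible)")

    sub_a = gm_a.subset(shared_inds, usable)
    sub_b = gm_b.subset(shared_inds, usable)
    dos_b = np.where(np.array(flip)[None, :], 2 - sub_b.dosage, sub_b.dosage)
    both = ~sub_a.missing & ~sub_b.missing
    n_compared = int(both.sum())
    if n_compared == 0:
        raise ValueError("shared cells exist but none are non-missing in both")
    match = (sub_a.dosage == dos_b) & both
    mism_idx = np.argwhere(both & ~match)
    mismatches = pd.DataFrame(
        [
            (shared_inds[i], usable[j], int(sub_a.dosage[i, j]), int(dos_b[i, j]))
            for i, j in mism_idx
        ],
        columns=["sample_id", "locus_id", "dosage_a", "dosage_b"],
    )
    return ConcordanceResult(
        rate=float(match.sum()) / n_compared,
        n_compared=n_compared,
        n_mismatch=len(mismatches),
        mismatches=mismatches,
        skipped_loci=skipped,
    )


# ---------------------------------------------------------------------------
# Locus filtering (MAF + LD pruning)
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    removed: pd.DataFrame  # locus_id, reason
    n_input: int
    n_retained: int


def filter_loci(
    gm: GenotypeMatrix,
    meta: Sequence[CollectionMeta] | None = None,
    maf_min: float = 0.05,
    r2_max: float = 0.8,
    polymorphic_in: Sequence[str] = (),
) -> tuple[GenotypeMatrix, FilterReport]:
    """MAF filter within named collections, then greedy LD pruning.

    A locus is kept only if its minor-allele frequency exceeds ``maf_min``
    within *every* collection named in ``polymorphic_in`` (computed on
    non-missing calls). Surviving loci are then pruned pairwise: for each pair
    with genotype (composite) r-squared >= ``r2_max`` the later-listed locus is
    dropped, deterministically.
    """
    removed: list[tuple[str, str]] = []
    keep = np.ones(gm.n_loci, dtype=bool)

    if polymorphic_in:
        if meta is None:
            raise ValueError("polymorphic_in given but no metadata supplied")
        bysample = meta_by_sample(meta)
        for label in polymorphic_in:
            members = [s for s in gm.individuals if bysample[s].collection_label == label]
            if not members:
                raise ValueError(f"collection {label!r} not present in data")
            sub = gm.subset(members)
            nonmiss = (~sub.missing).sum(axis=0) * 2
            with np.errstate(invalid="ignore"):
                p = np.where(
                    nonmiss > 0,
                    sub.dosage.astype(float).sum(axis=0, where=~sub.missing) / np.maximum(nonmiss, 1),
                    np.nan,
                )
            maf = np.fmin(p, 1 - p)
            fails = np.where(~(maf > maf_min))[0]  # NaN (no data) also fails
            for j in fails:
                if keep[j]:
                    keep[j] = False
                    removed.append((gm.locus_ids[j], f"maf<= {maf_min} in {label}"))

    # LD pruning on the MAF survivors, mean-imputed genotype correlation
    surv = np.where(keep)[0]
    if len(surv) >= 2:
        d = gm.dosage[:, surv].astype(float)
        d[gm.missing[:, surv]] = np.nan
        colmean = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), colmean, d)
        sd = d.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (d - d.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        corr = (z.T @ z) / len(d)
        r2 = corr**2
        r2[:, sd == 0] = 0.0
        r2[sd == 0, :] = 0.0
        # identical monomorphic duplicates: catch exact column equality
        keep_local = np.ones(len(surv), dtype=bool)
        for b in range(1, len(surv)):
            earlier = np.where(keep_local[:b])[0]
            if earlier.size and (r2[earlier, b] >= r2_max).any():
                keep_local[b] = False
                a = earlier[np.argmax(r2[earlier, b])]
                removed.append(
                    (
                        gm.locus_ids[surv[b]],
                        f"r2>={r2_max} with {gm.locus_ids[surv[a]]}",
                    )
                )
        keep[surv[~keep_local]] = False

    if not keep.any():
        raise ValueError(
            "all loci removed by filtering; review maf_min/r2_max thresholds"
        )
    retained = [gm.locus_ids[j] for j in np.where(keep)[0]]
    report = FilterReport(
        removed=pd.DataFrame(removed, columns=["locus_id", "reason"]),
        n_input=gm.n_loci,
        n_retained=len(retained),
    )
    return gm.subset(loci=retained), report
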