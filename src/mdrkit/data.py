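"""Data model and I/O for case-control categorical genotype data.

The central container is :class:`GenotypeDataset`: an individuals x factors
matrix of small integer category codes with a binary case/control status and
a free-text stratum tag per subject.  SNP factors are coded ordinally
(0 = homozygous wild type, 1 = heterozygous, 2 = homozygous variant);
environmental exposures (e.g. tobacco habit) are arbitrary categorical
factors on the same footing.  Missing values are stored internally as -1.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: internal sentinel for a missing category code
MISSING: int = -1

#: stratum tags used for the three cohort groups
GROUP_CONTROL = "control"
GROUP_UADT_INSIDE = "UADT_inside"   # at least one tobacco-related cancer in the UADT
GROUP_UADT_OUTSIDE = "UADT_outside"  # tobacco-related cancers, none in the UADT

#: tobacco-habit exposure levels
HABIT_LEVELS = ("no habit", "only T", "T+A")


class DataError(ValueError):
    """Raised for malformed input files or invalid dataset contents."""


@dataclass(frozen=True)
class FactorDefinition:
    """A categorical factor: a SNP genotype or an environmental exposure.

    Parameters
    ----------
    name:
        Column label, e.g. ``"SULT1A1_Arg213His"`` or ``"habit"``.
    kind:
        ``"snp"`` (exactly three ordinal levels 0/1/2) or ``"environment"``.
    levels:
        Ordered category codes.  SNPs use ``(0, 1, 2)`` for wild-type
        homozygote, heterozygote and variant homozygote.
    labels:
        Optional display label per level (amino-acid genotype names etc.).
    missing_code:
        Sentinel string used for absent values in text files.
    """

    name: str
    kind: str
    levels: tuple[int, ...]
    labels: tuple[str, ...] | None = None
    missing_code: str = "NA"

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "environment"):
            raise DataError(f"unknown factor kind {self.kind!r}")
        if len(set(self.levels)) != len(self.levels):
            raise DataError(f"factor {self.name!r}: duplicate levels")
        if self.kind == "snp" and len(self.levels) != 3:
            raise DataError(f"SNP factor {self.name!r} must have exactly 3 levels")
        if self.missing_code in {str(lv) for lv in self.levels}:
            raise DataError(
                f"factor {self.name!r}: missing code {self.missing_code!r} collides with a level"
            )
        if self.labels is not None and len(self.labels) != len(self.levels):
            raise DataError(f"factor {self.name!r}: labels/levels length mismatch")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def label_for(self, code: int) -> str:
        if self.labels is None:
            return str(code)
        return self.labels[self.levels.index(code)]


def snp_factor(name: str, labels: Sequence[str] | None = None,
               missing_code: str = "NA") -> FactorDefinition:
    """Standard biallelic SNP factor with ordinal codes 0/1/2."""
    return FactorDefinition(
        name=name, kind="snp", levels=(0, 1, 2),
        labels=tuple(labels) if labels is not None else None,
        missing_code=missing_code,
    )


def habit_factor(name: str = "habit", binary: bool = False,
                 missing_code: str = "NA") -> FactorDefinition:
    """Tobacco-habit exposure factor.

    Three levels by default (no habit / tobacco only / tobacco+alcohol);
    ``binary=True`` collapses to any-tobacco vs none.
    """
    if binary:
        return FactorDefinition(name=name, kind="environment", levels=(0, 1),
                                labels=("no habit", "tobacco"),
                                missing_code=missing_code)
    return FactorDefinition(name=name, kind="environment", levels=(0, 1, 2),
                            labels=HABIT_LEVELS, missing_code=missing_code)


@dataclass
class GenotypeDataset:
    """Individuals x categorical-factors matrix with case/control status.

    ``values`` holds integer category codes with :data:`MISSING` (-1) for
    absent entries; row ``i`` belongs to ``subjects[i]``.
    """

    subjects: list[str]
    status: np.ndarray            # (n,) int8, 1 = case, 0 = control
    group: np.ndarray             # (n,) object, stratum tag per subject
    factors: list[FactorDefinition]
    values: np.ndarray            # (n, p) int16 codes, MISSING for absent
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        self.group = np.asarray(self.group, dtype=object)
        self.values = np.asarray(self.values, dtype=np.int16)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def factor_index(self, name: str) -> int:
        for i, f in enumerate(self.factors):
            if f.name == name:
                return i
        raise DataError(f"unknown factor {name!r}")

    def factor(self, name: str) -> FactorDefinition:
        return self.factors[self.factor_index(name)]

    def validate(self) -> None:
        n, p = len(self.subjects), len(self.factors)
        if self.values.shape != (n, p):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{n} subjects x {p} factors"
            )
        if self.status.shape != (n,) or not np.isin(self.status, (0, 1)).all():
            raise DataError("status must be a length-n vector of 0/1")
        for j, f in enumerate(self.factors):
            col = self.values[:, j]
            observed = np.unique(col[col != MISSING])
            bad = set(observed.tolist()) - set(f.levels)
            if bad:
                raise DataError(
                    f"factor {f.name!r}: undeclared level codes {sorted(bad)}"
                )
        if self.covariates is not None and len(self.covariates) != n:
            raise DataError("covariates length does not match subjects")

    # -- missingness -------------------------------------------------------

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def missing_per_subject(self) -> np.ndarray:
        return self.missing_mask().sum(axis=1)

    def missing_per_factor(self) -> np.ndarray:
        return self.missing_mask().sum(axis=0)

    # -- manipulation ------------------------------------------------------

    def subset(self, rows: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to the given row indices (order kept)."""
        rows = np.asarray(rows)
        cov = self.covariates.iloc[rows].reset_index(drop=True) \
            if self.covariates is not None else None
        return GenotypeDataset(
            subjects=[self.subjects[i] for i in rows],
            status=self.status[rows].copy(),
            group=self.group[rows].copy(),
            factors=list(self.factors),
            values=self.values[rows].copy(),
            covariates=cov,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: sample_id, status, group, one column per factor."""
        df = pd.DataFrame({"sample_id": self.subjects,
                           "status": self.status.astype(int),
                           "group": self.group})
        for j, f in enumerate(self.factors):
            col = self.values[:, j].astype(object)
            col[self.values[:, j] == MISSING] = None
            df[f.name] = col
        return df

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.subjects == other.subjects
            and np.array_equal(self.status, other.status)
            and np.array_equal(self.group, other.group)
            and self.factors == other.factors
            and np.array_equal(self.values, other.values)
        )


@dataclass
class MissingnessReport:
    """Summary of missing data and of subjects excluded for excess missingness."""

    per_subject: dict[str, int]
    per_factor: dict[str, int]
    excluded: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# TSV reader / writer
# ---------------------------------------------------------------------------

def read_dataset(path: str | Path,
                 factors: Sequence[FactorDefinition] | None = None,
                 missing_code: str = "NA",
                 group_column: str = "group") -> GenotypeDataset:
    """Read a tab-separated case-control genotype table.

    Expected layout: a header row ``sample_id<TAB>status[<TAB>group]<TAB>
    <factor>...``; status must be 0 (control) or 1 (case).  When ``factors``
    is omitted, each remaining column is inferred: codes within {0,1,2} make
    a SNP factor, anything else an environmental factor with its observed
    levels.  Declared missing codes become missing; undeclared category
    codes raise :class:`DataError`.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"{path}: empty file") from None
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "status":
            raise DataError(
                f"{path}: header must start with 'sample_id<TAB>status'"
            )
        has_group = len(header) > 2 and header[2] == group_column
        factor_names = header[3:] if has_group else header[2:]
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise DataError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append((lineno, row))

    if factors is not None:
        factors = list(factors)
        if [f.name for f in factors] != factor_names:
            raise DataError(
                f"{path}: declared factors {[f.name for f in factors]} do not "
                f"match file columns {factor_names}"
            )

    subjects, status, group = [], [], []
    raw_cols: list[list[str]] = [[] for _ in factor_names]
    for lineno, row in rows:
        subjects.append(row[0])
        if row[1] not in ("0", "1"):
            raise DataError(
                f"{path}:{lineno}: status must be 0 or 1, got {row[1]!r}"
            )
        status.append(int(row[1]))
        if has_group:
            group.append(row[2])
            payload = row[3:]
        else:
            group.append(GROUP_CONTROL if row[1] == "0" else "case")
            payload = row[2:]
        for j, cell in enumerate(payload):
            raw_cols[j].append(cell.strip())

    if factors is None:
        factors = []
        for name, col in zip(factor_names, raw_cols):
            observed = sorted({c for c in col if c != missing_code})
            try:
                codes = sorted(int(c) for c in observed)
            except ValueError:
                raise DataError(
                    f"{path}: column {name!r}: non-integer category code"
                ) from None
            if set(codes) <= {0, 1, 2}:
                factors.append(snp_factor(name, missing_code=missing_code))
            else:
                factors.append(FactorDefinition(
                    name=name, kind="environment", levels=tuple(codes),
                    missing_code=missing_code))

    n = len(subjects)
    values = np.full((n, len(factors)), MISSING, dtype=np.int16)
    for j, (fdef, col) in enumerate(zip(factors, raw_cols)):
        level_set = {str(lv): lv for lv in fdef.levels}
        for i, cell in enumerate(col):
            if cell == fdef.missing_code or cell == "":
                continue
            if cell not in level_set:
                raise DataError(
                    f"{path}: column {fdef.name!r}: undeclared category {cell!r}"
                )
            values[i, j] = level_set[cell]

    return GenotypeDataset(subjects=subjects, status=np.array(status),
                           group=np.array(group, dtype=object),
                           factors=list(factors), values=values)


def write_dataset(ds: GenotypeDataset, path: str | Path) -> None:
    """Write ``ds`` in the TSV dialect that :func:`read_dataset` accepts."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "status", "group"] + ds.factor_names)
        for i in range(ds.n_subjects):
            row = [ds.subjects[i], int(ds.status[i]), ds.group[i]]
            for j, f in enumerate(ds.factors):
                v = ds.values[i, j]
                row.append(f.missing_code if v == MISSING else int(v))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# PLINK PED/MAP reader
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read text PLINK PED/MAP files, recoding allele pairs to 0/1/2.

    Codes count copies of the minor allele (the less frequent allele in the
    file; ties broken toward the lexicographically smaller allele as the
    variant).  ``0 0`` genotypes are missing; phenotype must be coded
    1 (control) / 2 (case).
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    snp_names = []
    with map_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise DataError(f"{map_path}:{lineno}: expected >= 2 fields")
            snp_names.append(parts[1])
    n_snps = len(snp_names)

    subjects, status, allele_rows = [], [], []
    with ped_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise DataError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} loci, got {len(parts)}"
                )
            subjects.append(parts[1])
            pheno = parts[5]
            if pheno not in ("1", "2"):
                raise DataError(
                    f"{ped_path}:{lineno}: phenotype must be 1/2, got {pheno!r}"
                )
            status.append(int(pheno) - 1)
            allele_rows.append(parts[6:])

    n = len(subjects)
    values = np.full((n, n_snps), MISSING, dtype=np.int16)
    factors = []
    for j, name in enumerate(snp_names):
        pairs = [(row[2 * j], row[2 * j + 1]) for row in allele_rows]
        counts: Counter[str] = Counter()
        for a1, a2 in pairs:
            for a in (a1, a2):
                if a != "0":
                    counts[a] += 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise DataError(
                f"{ped_path}: locus {name!r} has {len(alleles)} alleles"
            )
        if len(alleles) == 2:
            # minor = less frequent; tie -> lexicographically smaller
            a, b = alleles
            minor = a if (counts[a], a) <= (counts[b], b) else b
        elif len(alleles) == 1:
            minor = None  # monomorphic: every genotype is 0
        else:
            minor = None
        for i, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                if (a1 == "0") != (a2 == "0"):
                    raise DataError(
                        f"{ped_path}: subject {subjects[i]} locus {name!r}: "
                        "half-missing genotype"
                    )
                continue
            values[i, j] = (a1 == minor) + (a2 == minor) if minor else 0
        factors.append(snp_factor(name))

    return GenotypeDataset(
        subjects=subjects, status=np.array(status),
        group=np.array([GROUP_CONTROL if s == 0 else "case" for s in status],
                       dtype=object),
        factors=factors, values=values)


# ---------------------------------------------------------------------------
# Missing-data policy
# ---------------------------------------------------------------------------

def exclude_high_missing(ds: GenotypeDataset, max_missing: int = 5
                         ) -> tuple[GenotypeDataset, MissingnessReport]:
    """Drop subjects with more than ``max_missing`` missing factor values.

    The default of 5 mirrors the study protocol: subjects missing more than
    five of the genotype/exposure factors are removed before interaction
    analysis; a subject missing exactly ``max_missing`` values is retained.
    """
    if max_missing < 0:
        raise DataError("max_missing must be >= 0")
    per_subject = ds.missing_per_subject()
    keep = per_subject <= max_missing
    report = MissingnessReport(
        per_subject={s: int(m) for s, m in zip(ds.subjects, per_subject)},
        per_factor={f.name: int(m)
                    for f, m in zip(ds.factors, ds.missing_per_factor())},
        excluded=[s for s, k in zip(ds.subjects, keep) if not k],
    )
    return ds.subset(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Fixture construction from printed marginal counts
# ---------------------------------------------------------------------------

def from_marginal_counts(
        counts: Sequence[tuple[FactorDefinition, np.ndarray]],
        case_group: str = "case",
        control_group: str = GROUP_CONTROL) -> GenotypeDataset:
    """Build an individual-level dataset from per-SNP genotype-by-status counts.

    Each entry pairs a factor with a 3x2 table (rows = genotype 0/1/2,
    columns = [controls, cases]).  Every SNP column is filled independently
    so that its own genotype-by-status tabulation reproduces the input
    exactly; when tables have unequal totals the shortfall is left missing.
    The joint multi-SNP distribution is deliberately NOT reconstructed —
    only the printed marginals are known.
    """
    tables = []
    for fdef, tab in counts:
        tab = np.asarray(tab, dtype=np.int64)
        if tab.shape != (3, 2):
            raise DataError(f"factor {fdef.name!r}: counts must be 3x2")
        if (tab < 0).any():
            raise DataError(f"factor {fdef.name!r}: negative counts")
        tables.append((fdef, tab))

    n_controls = max((int(t[:, 0].sum()) for _, t in tables), default=0)
    n_cases = max((int(t[:, 1].sum()) for _, t in tables), default=0)

    subjects = ([f"ctrl{i + 1:04d}" for i in range(n_controls)]
                + [f"case{i + 1:04d}" for i in range(n_cases)])
    status = np.array([0] * n_controls + [1] * n_cases, dtype=np.int8)
    group = np.array([control_group] * n_controls + [case_group] * n_cases,
                     dtype=object)
    values = np.full((len(subjects), len(tables)), MISSING, dtype=np.int16)
    for j, (fdef, tab) in enumerate(tables):
        col = np.repeat([0, 1, 2], tab[:, 0])
        values[:len(col), j] = col
        col = np.repeat([0, 1, 2], tab[:, 1])
        values[n_controls:n_controls + len(col), j] = col

    return GenotypeDataset(subjects=subjects, status=status, group=group,
                           factors=[f for f, _ in tables], values=values)
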