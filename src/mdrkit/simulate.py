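"""Case-control genotype simulator and packaged count fixtures.

Generates datasets with the statistical structure the analysis assumes:
biallelic SNPs in Hardy-Weinberg equilibrium at chosen minor-allele
frequencies, a categorical tobacco-habit exposure, disease assigned through
a k-way penetrance table, case-control ascertainment by rejection sampling
(draw from the population, keep until the case and control quotas fill),
and missing-completely-at-random genotype dropout.

Also exposes the published genotype-by-status count panels as ready-made
individual-level fixture datasets (:func:`published_fixture`), so that the
univariate statistics can be exercised against printed values without any
external data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .data import (GROUP_CONTROL, GROUP_UADT_INSIDE, GROUP_UADT_OUTSIDE,
                   MISSING, DataError, FactorDefinition, GenotypeDataset,
                   from_marginal_counts, habit_factor, snp_factor)

#: case-group column names available in the packaged count fixture
PUBLISHED_GROUPS = (GROUP_UADT_INSIDE, GROUP_UADT_OUTSIDE)


@dataclass
class PenetranceModel:
    """Map from a combination of factor levels to disease probability.

    ``factors`` names the factors the table is keyed on (a subset of the
    simulated factors); any combination absent from ``table`` falls back to
    ``baseline``.
    """

    factors: tuple[str, ...]
    table: dict[tuple[int, ...], float]
    baseline: float = 0.05

    def __post_init__(self) -> None:
        probs = list(self.table.values()) + [self.baseline]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise DataError("penetrance probabilities must lie in [0, 1]")
        for key in self.table:
            if len(key) != len(self.factors):
                raise DataError("penetrance key arity != number of factors")

    def probability(self, levels: tuple[int, ...]) -> float:
        return self.table.get(levels, self.baseline)


@dataclass
class SimulationConfig:
    """Population and ascertainment settings for one simulated cohort."""

    n_cases: int
    n_controls: int
    snps: list[tuple[str, float]]                 # (name, minor allele freq)
    penetrance: PenetranceModel
    habit: Sequence[float] | None = None          # exposure level probabilities
    habit_name: str = "habit"
    missing_rate: float = 0.0
    seed: int = 0
    max_draws: int = 2_000_000

    def __post_init__(self) -> None:
        for name, maf in self.snps:
            if not (0.0 < maf <= 0.5):
                raise DataError(f"SNP {name!r}: MAF must lie in (0, 0.5]")
        if self.habit is not None and abs(sum(self.habit) - 1.0) > 1e-9:
            raise DataError("habit level probabilities must sum to 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise DataError("missing_rate must lie in [0, 1)")

    def factor_definitions(self) -> list[FactorDefinition]:
        factors = [snp_factor(name) for name, _ in self.snps]
        if self.habit is not None:
            if len(self.habit) == 3:
                factors.append(habit_factor(self.habit_name))
            else:
                factors.append(FactorDefinition(
                    name=self.habit_name, kind="environment",
                    levels=tuple(range(len(self.habit)))))
        return factors


def simulate_genotypes_hwe(n: int, maf: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` genotypes with Hardy-Weinberg probabilities (p^2, 2pq, q^2)."""
    if not (0.0 < maf <= 0.5):
        raise DataError("MAF must lie in (0, 0.5]")
    q = maf
    p = 1.0 - q
    return rng.choice(3, size=n, p=(p * p, 2 * p * q, q * q)).astype(np.int16)


def simulate_case_control(cfg: SimulationConfig) -> GenotypeDataset:
    """Simulate a case-control cohort under a penetrance model.

    Individuals are drawn from the population model (independent SNPs in
    HWE plus an optional categorical exposure), disease status is Bernoulli
    with the penetrance of the individual's combination, and sampling
    continues until both the case and the control quota are reached.
    Deterministic under ``cfg.seed``.  Raises if the quotas cannot be met
    within ``cfg.max_draws`` population draws (e.g. penetrance all 0).
    """
    rng = np.random.default_rng(cfg.seed)
    factors = cfg.factor_definitions()
    names = [f.name for f in factors]
    pen_cols = [names.index(f) for f in cfg.penetrance.factors]

    batch = max(1000, 4 * (cfg.n_cases + cfg.n_controls))
    kept_vals: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    n_cases = n_controls = 0
    drawn = 0
    while n_cases < cfg.n_cases or n_controls < cfg.n_controls:
        if drawn >= cfg.max_draws:
            raise DataError(
                "ascertainment timeout: case/control quotas unreachable "
                "under this penetrance model")
        vals = np.empty((batch, len(factors)), dtype=np.int16)
        for j, (name, maf) in enumerate(cfg.snps):
            vals[:, j] = simulate_genotypes_hwe(batch, maf, rng)
        if cfg.habit is not None:
            vals[:, len(cfg.snps)] = rng.choice(
                len(cfg.habit), size=batch, p=np.asarray(cfg.habit))
        drawn += batch
        probs = np.array([cfg.penetrance.probability(tuple(int(v) for v in row))
                          for row in vals[:, pen_cols]])
        disease = rng.random(batch) < probs
        need_cases = cfg.n_cases - n_cases
        need_controls = cfg.n_controls - n_controls
        case_rows = np.flatnonzero(disease)[:max(0, need_cases)]
        ctrl_rows = np.flatnonzero(~disease)[:max(0, need_controls)]
        take = np.concatenate([case_rows, ctrl_rows])
        kept_vals.append(vals[take])
        kept_status.append(disease[take].astype(np.int8))
        n_cases += len(case_rows)
        n_controls += len(ctrl_rows)

    values = np.concatenate(kept_vals)
    status = np.concatenate(kept_status)
    # stable layout: cases first, then controls
    reorder = np.concatenate([np.flatnonzero(status == 1),
                              np.flatnonzero(status == 0)])
    values, status = values[reorder], status[reorder]
    subjects = [f"sim{i + 1:05d}" for i in range(len(status))]
    group = np.where(status == 1, "case", GROUP_CONTROL).astype(object)
    ds = GenotypeDataset(subjects=subjects, status=status, group=group,
                         factors=factors, values=values)
    if cfg.missing_rate > 0:
        ds = inject_missingness(ds, cfg.missing_rate, rng)
    return ds


def inject_missingness(ds: GenotypeDataset, rate: float,
                       rng: np.random.Generator) -> GenotypeDataset:
    """Set each genotype cell missing independently with probability ``rate``.

    MCAR: the mask ignores status, group and covariates, which are never
    masked.  ``rate=0`` returns an identical copy.
    """
    if not (0.0 <= rate < 1.0):
        raise DataError("rate must lie in [0, 1)")
    out = ds.subset(np.arange(ds.n_subjects))
    if rate > 0:
        mask = rng.random(out.values.shape) < rate
        out.values[mask] = MISSING
    return out


# ---------------------------------------------------------------------------
# The headline two-locus interaction experiment
# ---------------------------------------------------------------------------

def xor_penetrance(snp_a: str = "SNP_A", snp_b: str = "SNP_B",
                   high: float = 0.45, low: float = 0.05) -> PenetranceModel:
    """Two-locus carrier-XOR disease model.

    Risk is high iff exactly one of the two loci carries at least one
    variant allele — a pure interaction with no marginal single-locus
    effect structure that MDR is designed to detect.
    """
    table = {}
    for ga in range(3):
        for gb in range(3):
            risk = (ga >= 1) != (gb >= 1)
            table[(ga, gb)] = high if risk else low
    return PenetranceModel(factors=(snp_a, snp_b), table=table, baseline=low)


def xor_simulation_config(n_cases: int = 200, n_controls: int = 200,
                          n_noise_snps: int = 10, causal_maf: float = 0.5,
                          noise_maf: float = 0.3, high: float = 0.45,
                          low: float = 0.05, missing_rate: float = 0.0,
                          seed: int = 42) -> SimulationConfig:
    """Standard recovery benchmark: carrier-XOR pair plus noise SNPs."""
    snps = [("SNP_A", causal_maf), ("SNP_B", causal_maf)]
    snps += [(f"NOISE{i + 1:02d}", noise_maf) for i in range(n_noise_snps)]
    return SimulationConfig(
        n_cases=n_cases, n_controls=n_controls, snps=snps,
        penetrance=xor_penetrance(high=high, low=low),
        missing_rate=missing_rate, seed=seed)


# ---------------------------------------------------------------------------
# Packaged fixtures from published genotype-by-status counts
# ---------------------------------------------------------------------------

def _load_published_counts() -> dict[str, dict]:
    panels: dict[str, dict] = {}
    ref = resources.files("mdrkit") / "fixtures" / "published_counts.tsv"
    with ref.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            panel = panels.setdefault(row["snp"], {
                "labels": [], "control": [], GROUP_UADT_INSIDE: [],
                GROUP_UADT_OUTSIDE: []})
            panel["labels"].append(row["genotype"])
            panel["control"].append(int(row["control"]))
            panel[GROUP_UADT_INSIDE].append(int(row["UADT_inside"]))
            panel[GROUP_UADT_OUTSIDE].append(int(row["UADT_outside"]))
    return panels


def published_panels() -> list[str]:
    """Names of the SNP panels packaged from the published count table."""
    return sorted(_load_published_counts())


def published_counts(panel: str, group: str = GROUP_UADT_INSIDE) -> np.ndarray:
    """3x2 counts (rows genotype 0/1/2, columns [controls, cases])."""
    panels = _load_published_counts()
    if panel not in panels:
        raise DataError(f"unknown fixture panel {panel!r}; "
                        f"available: {sorted(panels)}")
    if group not in PUBLISHED_GROUPS:
        raise DataError(f"unknown case group {group!r}; "
                        f"available: {PUBLISHED_GROUPS}")
    p = panels[panel]
    return np.column_stack([p["control"], p[group]]).astype(np.int64)


def published_fixture(panel: str, group: str = GROUP_UADT_INSIDE
                   ) -> GenotypeDataset:
    """Individual-level dataset whose tabulation reproduces a printed panel."""
    panels = _load_published_counts()
    counts = published_counts(panel, group)
    fdef = snp_factor(panel, labels=panels[panel]["labels"])
    return from_marginal_counts([(fdef, counts)], case_group=group)


def published_dataset(group: str = GROUP_UADT_INSIDE) -> GenotypeDataset:
    """All packaged panels in one dataset (per-SNP marginals exact; the
    joint distribution across SNPs is synthetic/unknown by construction)."""
    panels = _load_published_counts()
    counts = []
    for name in sorted(panels):
        fdef = snp_factor(name, labels=panels[name]["labels"])
        counts.append((fdef, published_counts(name, group)))
    return from_marginal_counts(counts, case_group=group)
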