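"""End-to-end analysis pipeline and report writers.

Ties the stages together in the study's order: exclude subjects with excess
missingness, univariate odds ratios for every SNP x case group x collapse
model, Hardy-Weinberg tests in controls, configured pairwise LD, the
repeated-shuffle MDR search, and OR-MDR on the overall best model.  Reports
are written as canonical JSON (machine-readable, deterministic under a
fixed seed apart from the timestamp) plus TSV tables mirroring the
published table layouts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import DataError, GenotypeDataset, exclude_high_missing, read_dataset
from .mdr import or_mdr, repeat_with_shuffles
from .univariate import (COLLAPSE_MODELS, collapse, crude_odds_ratio,
                         hwe_test, ld_pairwise, tabulate)

log = logging.getLogger("mdrkit")


@dataclass
class RunConfig:
    """Settings for one full pipeline run."""

    input_path: str | None = None
    case_groups: list[str] | None = None       # None -> every non-control tag
    models: list[str] = field(default_factory=lambda: list(COLLAPSE_MODELS))
    ld_pairs: list[tuple[str, str]] = field(default_factory=list)
    max_missing: int = 5
    k_min: int = 1
    k_max: int = 3
    folds: int = 10
    repeats: int = 10
    seed: int = 0
    zero_correction: str = "none"
    habit_column: str | None = None            # kept for provenance only
    mdr_factors: list[str] | None = None
    run_mdr: bool = True
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise DataError("k_min must not exceed k_max")
        if self.folds < 2:
            raise DataError("folds must be >= 2")
        if self.repeats < 1:
            raise DataError("repeats must be >= 1")

    def canonical_json(self) -> str:
        d = asdict(self)
        d["ld_pairs"] = [list(p) for p in self.ld_pairs]
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All pipeline outputs plus a provenance block."""

    univariate: list[dict]
    hwe: list[dict]
    ld: list[dict]
    mdr: list[dict]
    or_mdr: list[dict]
    missingness: dict
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        payload = {"provenance": self.provenance,
                   "missingness": self.missingness,
                   "univariate": self.univariate, "hwe": self.hwe,
                   "ld": self.ld, "mdr": self.mdr, "or_mdr": self.or_mdr}
        return json.dumps(payload, indent=indent, sort_keys=True,
                          default=_json_default)


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def _fmt(x: float) -> float | str | None:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return float(x)


def run_pipeline(cfg: RunConfig,
                 dataset: GenotypeDataset | None = None) -> AnalysisReport:
    """Execute the full analysis and return the assembled report.

    ``dataset`` may be passed directly (e.g. a simulated cohort or a
    packaged fixture); otherwise ``cfg.input_path`` is read as TSV.
    """
    if dataset is None:
        if cfg.input_path is None:
            raise DataError("no dataset and no input path configured")
        dataset = read_dataset(cfg.input_path)
    log.info("loaded dataset: %d subjects, %d factors",
             dataset.n_subjects, dataset.n_factors)

    ds, miss_report = exclude_high_missing(dataset, cfg.max_missing)
    log.info("missingness filter (> %d missing): %d subjects excluded, "
             "%d retained", cfg.max_missing, len(miss_report.excluded),
             ds.n_subjects)

    case_groups = cfg.case_groups
    if case_groups is None:
        case_groups = sorted({g for g, s in zip(ds.group, ds.status) if s == 1})

    snps = [f.name for f in ds.factors if f.kind == "snp"]

    univariate_rows = []
    for snp in snps:
        for group in case_groups:
            table = tabulate(ds, snp, case_group=group)
            if table.n_cases == 0 or table.n_controls == 0:
                continue
            for model in cfg.models:
                t = collapse(table, model)
                try:
                    res = crude_odds_ratio(t, cfg.zero_correction, model=model)
                except DataError:
                    continue
                univariate_rows.append({
                    "factor": snp, "group": group, "model": model,
                    "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                    "or": _fmt(res.or_estimate),
                    "ci_low": _fmt(res.ci_low), "ci_high": _fmt(res.ci_high),
                    "p": _fmt(res.p_value),
                    "zero_corrected": res.zero_corrected,
                })
    log.info("univariate: %d rows (%d SNPs x %d groups x %d models)",
             len(univariate_rows), len(snps), len(case_groups),
             len(cfg.models))

    hwe_rows = []
    for snp in snps:
        table = tabulate(ds, snp)
        n0, n1, n2 = (int(x) for x in table.counts[:, 0])
        if n0 + n1 + n2 == 0:
            continue
        res = hwe_test((n0, n1, n2))
        hwe_rows.append({"factor": snp, "n0": n0, "n1": n1, "n2": n2,
                         "chi_square": _fmt(res.chi_square),
                         "p": _fmt(res.p_value),
                         "variant_freq": _fmt(res.variant_freq),
                         "in_hwe_p005": bool(res.p_value >= 0.05)})
    log.info("HWE: tested %d SNPs in controls", len(hwe_rows))

    ld_rows = []
    for snp_a, snp_b in cfg.ld_pairs:
        res = ld_pairwise(ds, snp_a, snp_b)
        ld_rows.append({"snp_a": snp_a, "snp_b": snp_b, "n": res.n,
                        "d": _fmt(res.d), "d_prime": _fmt(res.d_prime),
                        "r_squared": _fmt(res.r_squared),
                        "chi_square": _fmt(res.chi_square),
                        "p": _fmt(res.chi_square_p),
                        "defined": res.defined})
    if cfg.ld_pairs:
        log.info("LD: %d pairs analysed", len(ld_rows))

    mdr_rows: list[dict] = []
    ormdr_rows: list[dict] = []
    if cfg.run_mdr:
        factors = cfg.mdr_factors or ds.factor_names
        k_max = min(cfg.k_max, len(factors))
        rep = repeat_with_shuffles(ds, repeats=cfg.repeats, k_min=cfg.k_min,
                                   k_max=k_max, folds=cfg.folds,
                                   seed=cfg.seed, factors=factors)
        for k in sorted(rep.per_k):
            m = rep.per_k[k]
            mdr_rows.append({
                "k": k, "model": list(m.combination),
                "cvc": _fmt(m.cvc),
                "train_accuracy": _fmt(m.train_accuracy),
                "test_accuracy": _fmt(m.test_accuracy),
                "selected_count_over_repeats": m.selected_count_over_repeats,
                "best_overall": m.combination == rep.best.combination,
            })
        log.info("MDR: searched k=%d..%d over %d factors, %d repeats; "
                 "best model %s (mean CVC %.1f)", cfg.k_min, k_max,
                 len(factors), cfg.repeats, "/".join(rep.best.combination),
                 rep.best.cvc)
        try:
            for cell in or_mdr(ds, rep.best.combination):
                ormdr_rows.append({
                    "model": list(rep.best.combination),
                    "cell": list(cell.cell), "label": cell.label,
                    "n_cases": cell.n_cases, "n_controls": cell.n_controls,
                    "or": _fmt(cell.or_estimate),
                    "ci_low": _fmt(cell.ci_low),
                    "ci_high": _fmt(cell.ci_high),
                    "significant": cell.significant,
                    "zero_corrected": cell.zero_corrected,
                })
        except DataError as exc:
            log.warning("OR-MDR skipped: %s", exc)

    provenance = {
        "package": "mdrkit", "version": __version__,
        "seed": cfg.seed, "config_hash": cfg.config_hash(),
        "config": json.loads(cfg.canonical_json()),
        "n_subjects_input": dataset.n_subjects,
        "n_subjects_analysed": ds.n_subjects,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return AnalysisReport(
        univariate=univariate_rows, hwe=hwe_rows, ld=ld_rows, mdr=mdr_rows,
        or_mdr=ormdr_rows,
        missingness={
            "excluded": miss_report.excluded,
            "per_factor": miss_report.per_factor,
            "max_missing": cfg.max_missing,
        },
        provenance=provenance)


_SECTION_COLUMNS = {
    "univariate": ["factor", "group", "model", "a", "b", "c", "d", "or",
                   "ci_low", "ci_high", "p", "zero_corrected"],
    "hwe": ["factor", "n0", "n1", "n2", "chi_square", "p", "variant_freq",
            "in_hwe_p005"],
    "ld": ["snp_a", "snp_b", "n", "d", "d_prime", "r_squared", "chi_square",
           "p", "defined"],
    "mdr": ["k", "model", "cvc", "train_accuracy", "test_accuracy",
            "selected_count_over_repeats", "best_overall"],
    "or_mdr": ["model", "cell", "label", "n_cases", "n_controls", "or",
               "ci_low", "ci_high", "significant", "zero_corrected"],
}


def write_report(report: AnalysisReport, out_dir: str | Path,
                 formats: tuple[str, ...] = ("json", "tsv"),
                 float_precision: int = 3) -> list[Path]:
    """Write the report as JSON and/or one TSV per section.

    TSV floats are rounded to ``float_precision`` significant digits for
    human diffing; the JSON keeps full precision and is the canonical
    machine-readable output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        path = out_dir / "report.json"
        path.write_text(report.to_json() + "\n")
        written.append(path)
    if "tsv" in formats:
        for section in ("univariate", "hwe", "ld", "mdr", "or_mdr"):
            rows = getattr(report, section)
            path = out_dir / f"{section}.tsv"
            df = pd.DataFrame(rows)
            if df.empty:
                df = pd.DataFrame(columns=_SECTION_COLUMNS[section])
            for col in df.columns:
                if df[col].dtype == float:
                    df[col] = df[col].map(
                        lambda x: float(f"%.{float_precision}g" % x)
                        if pd.notna(x) else x)
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
    return written
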