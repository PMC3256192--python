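"""'Available' Multifactor Dimensionality Reduction (MDR) engine.

MDR pools the cells of a k-way genotype/exposure table into high- and
low-risk classes and scores each candidate factor combination by
cross-validated classification accuracy.  This implementation follows the
*Available* variant: every candidate combination is evaluated on all
subjects with complete data for exactly the factors it contains, so
different combinations may use different subject subsets.

The search protocol:

* 10-fold status-stratified cross-validation, with folds taken as
  consecutive blocks of the current subject order — shuffling the order of
  individuals therefore reshuffles the folds;
* per fold, a cell is high-risk when its training case:control ratio is at
  least the training-set ratio T (ties high; cells empty in training
  classify test subjects as low-risk);
* cross-validation consistency (CVC) of a combination = number of folds in
  which it achieves the best training accuracy (ties broken by test
  accuracy, then by lexicographic factor order);
* the whole search is repeated over several shuffles of the subject order
  and CVC/accuracies are averaged;
* the final model's per-cell effect sizes come from OR-MDR: each cell's
  odds against the pooled low-risk reference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING, DataError, GenotypeDataset
from .univariate import _Z95


@dataclass
class CellTable:
    """Joint level-tuple counts of cases and controls for one combination."""

    combination: tuple[str, ...]
    levels: tuple[tuple[int, ...], ...]   # level codes per factor
    case_counts: np.ndarray               # flat, C-order over level product
    control_counts: np.ndarray
    n_available: int

    @property
    def cells(self) -> dict[tuple[int, ...], tuple[int, int]]:
        """Map level-tuple -> (n_cases, n_controls)."""
        out = {}
        for flat, key in enumerate(itertools.product(*self.levels)):
            out[key] = (int(self.case_counts[flat]),
                        int(self.control_counts[flat]))
        return out


@dataclass
class RiskLabeling:
    """High/low/empty risk label per cell at case:control threshold T."""

    threshold: float
    labels: dict[tuple[int, ...], str]    # 'high' | 'low' | 'empty'


@dataclass
class ModelEvaluation:
    """One combination's cross-validated performance for one subject order."""

    combination: tuple[str, ...]
    train_accuracy: np.ndarray            # per fold
    test_accuracy: np.ndarray             # per fold
    cvc: int = 0
    n_available: int = 0

    @property
    def mean_train(self) -> float:
        return float(self.train_accuracy.mean())

    @property
    def mean_test(self) -> float:
        return float(self.test_accuracy.mean())


@dataclass
class CVResult:
    """Fold bookkeeping for one exhaustive search at one k."""

    folds: int
    per_fold_winner: list[tuple[str, ...]]
    per_fold_train_accuracy: np.ndarray   # of the winner in that fold
    per_fold_test_accuracy: np.ndarray


@dataclass
class KSearchResult:
    k: int
    winner: ModelEvaluation
    cv: CVResult
    evaluations: dict[tuple[str, ...], ModelEvaluation]


@dataclass
class SearchResult:
    by_k: dict[int, KSearchResult]
    best: ModelEvaluation                 # across k: max CVC, tie max mean test


@dataclass
class MDRModel:
    """Shuffle-averaged summary of one combination (one row of a report)."""

    combination: tuple[str, ...]
    cvc: float                            # mean over repeats, in [0, folds]
    train_accuracy: float
    test_accuracy: float
    selected_count_over_repeats: int = 0


@dataclass
class RepeatedSearchResult:
    repeats: int
    per_k: dict[int, MDRModel]
    best: MDRModel
    searches: list[SearchResult] = field(default_factory=list, repr=False)


@dataclass
class CellOddsRatio:
    cell: tuple[int, ...]
    label: str
    n_cases: int
    n_controls: int
    or_estimate: float
    ci_low: float
    ci_high: float
    significant: bool
    zero_corrected: bool = False


# ---------------------------------------------------------------------------
# Available-case handling and cell tabulation
# ---------------------------------------------------------------------------

def available_cases(ds: GenotypeDataset,
                    combination: tuple[str, ...]) -> np.ndarray:
    """Row indices of subjects with complete data on every factor of the
    combination (subjects missing only unrelated factors are kept)."""
    if not combination:
        raise DataError("combination must be non-empty")
    cols = [ds.factor_index(f) for f in combination]
    mask = (ds.values[:, cols] != MISSING).all(axis=1)
    return np.flatnonzero(mask)


def _combo_levels(ds: GenotypeDataset,
                  combination: tuple[str, ...]) -> tuple[tuple[int, ...], ...]:
    return tuple(tuple(ds.factor(f).levels) for f in combination)


def _cell_index(values: np.ndarray, cols: list[int],
                levels: tuple[tuple[int, ...], ...]) -> tuple[np.ndarray, int]:
    """Mixed-radix flat cell index per subject (C-order over level product)."""
    sizes = [len(lv) for lv in levels]
    idx = np.zeros(values.shape[0], dtype=np.int64)
    for j, (col, lv) in enumerate(zip(cols, levels)):
        codes = values[:, col]
        if lv == tuple(range(len(lv))):
            pos = codes.astype(np.int64)
        else:
            lut = {code: p for p, code in enumerate(lv)}
            pos = np.array([lut[int(c)] for c in codes], dtype=np.int64)
        idx = idx * sizes[j] + pos
    return idx, int(np.prod(sizes))


def tabulate_cells(ds: GenotypeDataset, combination: tuple[str, ...],
                   rows: np.ndarray | None = None) -> CellTable:
    """Joint case/control counts over the Cartesian product of factor levels."""
    if rows is None:
        rows = available_cases(ds, combination)
    cols = [ds.factor_index(f) for f in combination]
    levels = _combo_levels(ds, combination)
    idx, ncell = _cell_index(ds.values[rows][:, cols],
                             list(range(len(cols))), levels)
    status = ds.status[rows]
    case_counts = np.bincount(idx[status == 1], minlength=ncell)
    control_counts = np.bincount(idx[status == 0], minlength=ncell)
    return CellTable(combination=tuple(combination), levels=levels,
                     case_counts=case_counts, control_counts=control_counts,
                     n_available=len(rows))


def classify_cells(table: CellTable, threshold: float | None = None
                   ) -> RiskLabeling:
    """Label each cell high/low risk against a case:control ratio cutoff.

    Default threshold T is the table's overall case:control ratio.  A cell
    is high-risk iff cases/controls >= T; cells with cases and no controls
    are high, controls and no cases low, neither empty.  Ties at exactly T
    are labelled high.
    """
    if threshold is None:
        n_ctrl = int(table.control_counts.sum())
        n_case = int(table.case_counts.sum())
        if n_ctrl == 0:
            raise DataError("cannot derive threshold: no controls")
        threshold = n_case / n_ctrl
    if threshold <= 0:
        raise DataError("threshold must be positive")
    labels = {}
    for key, (ca, co) in table.cells.items():
        if ca == 0 and co == 0:
            labels[key] = "empty"
        elif co == 0:
            labels[key] = "high"
        else:
            labels[key] = "high" if ca / co >= threshold else "low"
    return RiskLabeling(threshold=float(threshold), labels=labels)


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

def stratified_folds(status: np.ndarray, folds: int) -> np.ndarray:
    """Fold id per subject: consecutive blocks within each status stratum,
    taken in the given subject order (deterministic; no internal RNG)."""
    fold = np.empty(len(status), dtype=np.int64)
    for s in (0, 1):
        idx = np.flatnonzero(status == s)
        for f, part in enumerate(np.array_split(idx, folds)):
            fold[part] = f
    return fold


def _fold_accuracies(idx: np.ndarray, ncell: int, status: np.ndarray,
                     fold: np.ndarray, folds: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold train/test accuracy of the MDR classifier for one combination.

    Vectorised over folds: cell x fold x status counts via one bincount.
    """
    cnt = np.bincount(idx * (folds * 2) + fold * 2 + status,
                      minlength=ncell * folds * 2).reshape(ncell, folds, 2)
    ctrl_te = cnt[:, :, 0]
    case_te = cnt[:, :, 1]
    tot = cnt.sum(axis=1)                       # (ncell, 2)
    ctrl_tr = tot[:, [0]] - ctrl_te
    case_tr = tot[:, [1]] - case_te
    n_ctrl_tr = ctrl_tr.sum(axis=0)             # per fold
    n_case_tr = case_tr.sum(axis=0)
    if (ctrl_te.sum(axis=0) + case_te.sum(axis=0) == 0).any():
        raise DataError("a fold has zero test subjects; fold count too high")
    empty = (case_tr == 0) & (ctrl_tr == 0)
    # high iff case/ctrl >= T = n_case_tr/n_ctrl_tr, via cross-multiplication
    high = (case_tr * n_ctrl_tr >= ctrl_tr * n_case_tr) & ~empty
    train_correct = np.where(high, case_tr, ctrl_tr).sum(axis=0)
    train_acc = train_correct / (n_case_tr + n_ctrl_tr)
    # test subjects in empty-in-training cells are classified low-risk
    test_correct = np.where(high, case_te, ctrl_te).sum(axis=0)
    test_acc = test_correct / (case_te.sum(axis=0) + ctrl_te.sum(axis=0))
    return train_acc, test_acc


def evaluate_model_cv(ds: GenotypeDataset, combination: tuple[str, ...],
                      folds: int = 10,
                      order: np.ndarray | None = None) -> ModelEvaluation:
    """Cross-validated accuracies for one combination at the current order.

    Folds are status-stratified consecutive blocks of ``order`` restricted
    to the combination's available cases; the classifier is rebuilt on each
    training portion with T = training case:control ratio.
    """
    if order is None:
        order = np.arange(ds.n_subjects)
    avail = available_cases(ds, combination)
    in_avail = np.zeros(ds.n_subjects, dtype=bool)
    in_avail[avail] = True
    order = np.asarray(order, dtype=np.int64)
    rows = order[in_avail[order]]
    if len(rows) < folds:
        raise DataError("fewer available subjects than folds")
    cols = [ds.factor_index(f) for f in combination]
    levels = _combo_levels(ds, combination)
    idx, ncell = _cell_index(ds.values[rows][:, cols],
                             list(range(len(cols))), levels)
    status = ds.status[rows].astype(np.int64)
    fold = stratified_folds(status, folds)
    train_acc, test_acc = _fold_accuracies(idx, ncell, status, fold, folds)
    return ModelEvaluation(combination=tuple(combination),
                           train_accuracy=train_acc, test_accuracy=test_acc,
                           n_available=len(rows))


# ---------------------------------------------------------------------------
# Exhaustive search
# ---------------------------------------------------------------------------

def exhaustive_search(ds: GenotypeDataset, k_min: int = 1, k_max: int = 5,
                      folds: int = 10, order: np.ndarray | None = None,
                      factors: list[str] | None = None) -> SearchResult:
    """Evaluate every k-subset of factors for k in [k_min, k_max].

    Within each fold the winner maximises training accuracy (ties broken by
    higher test accuracy, then by lexicographic factor order as generated);
    CVC(combination) = number of folds it wins.  The per-k winner has
    maximal CVC (tie: higher mean test accuracy); the overall best model is
    chosen the same way across k.
    """
    if factors is None:
        factors = ds.factor_names
    if k_max > len(factors):
        raise DataError("k_max exceeds the number of factors")
    if order is None:
        order = np.arange(ds.n_subjects)

    # Precompute the ordered available-row list per distinct missingness
    # pattern is overkill here; evaluate per combination directly.
    by_k: dict[int, KSearchResult] = {}
    for k in range(k_min, k_max + 1):
        evals: list[ModelEvaluation] = []
        for combo in itertools.combinations(factors, k):
            evals.append(evaluate_model_cv(ds, combo, folds=folds, order=order))
        train = np.stack([e.train_accuracy for e in evals])   # (ncombo, folds)
        test = np.stack([e.test_accuracy for e in evals])
        winner_ids = np.empty(folds, dtype=np.int64)
        for f in range(folds):
            best_train = train[:, f].max()
            cand = np.flatnonzero(train[:, f] == best_train)
            best_test = test[cand, f].max()
            cand = cand[test[cand, f] == best_test]
            winner_ids[f] = cand[0]               # lexicographic order
        for i, e in enumerate(evals):
            e.cvc = int((winner_ids == i).sum())
        # per-k winner: max CVC, tie -> max mean test accuracy, tie -> lexicographic
        best_i = max(range(len(evals)),
                     key=lambda i: (evals[i].cvc, evals[i].mean_test, -i))
        cv = CVResult(
            folds=folds,
            per_fold_winner=[evals[i].combination for i in winner_ids],
            per_fold_train_accuracy=train[winner_ids, np.arange(folds)],
            per_fold_test_accuracy=test[winner_ids, np.arange(folds)],
        )
        by_k[k] = KSearchResult(k=k, winner=evals[best_i], cv=cv,
                                evaluations={e.combination: e for e in evals})

    ks = sorted(by_k)
    best_k = max(ks, key=lambda k: (by_k[k].winner.cvc,
                                    by_k[k].winner.mean_test, -k))
    return SearchResult(by_k=by_k, best=by_k[best_k].winner)


def repeat_with_shuffles(ds: GenotypeDataset, repeats: int = 10,
                         k_min: int = 1, k_max: int = 5, folds: int = 10,
                         seed: int = 0,
                         factors: list[str] | None = None,
                         keep_searches: bool = False) -> RepeatedSearchResult:
    """Full exhaustive search repeated over shuffles of the subject order.

    Repeat r uses the permutation drawn from seed ``seed + r``; folds are
    rebuilt from each shuffled order.  Per k the modal winning combination
    across repeats is reported with its CVC/accuracies averaged over all
    repeats and the number of repeats in which it won.  Overall best model:
    maximal mean CVC, tie broken by maximal mean test accuracy.
    """
    if repeats < 1:
        raise DataError("repeats must be >= 1")
    per_repeat: list[SearchResult] = []
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        order = rng.permutation(ds.n_subjects)
        per_repeat.append(exhaustive_search(ds, k_min=k_min, k_max=k_max,
                                            folds=folds, order=order,
                                            factors=factors))

    per_k: dict[int, MDRModel] = {}
    for k in range(k_min, k_max + 1):
        wins: dict[tuple[str, ...], int] = {}
        for sr in per_repeat:
            combo = sr.by_k[k].winner.combination
            wins[combo] = wins.get(combo, 0) + 1

        def _mean_stats(combo: tuple[str, ...]) -> tuple[float, float, float]:
            cvcs, trains, tests = [], [], []
            for sr in per_repeat:
                e = sr.by_k[k].evaluations[combo]
                cvcs.append(e.cvc)
                trains.append(e.mean_train)
                tests.append(e.mean_test)
            return (float(np.mean(cvcs)), float(np.mean(trains)),
                    float(np.mean(tests)))

        # modal winner; ties broken by mean CVC then mean test accuracy
        stats = {c: _mean_stats(c) for c in wins}
        modal = max(wins, key=lambda c: (wins[c], stats[c][0], stats[c][2]))
        cvc, tr, te = stats[modal]
        per_k[k] = MDRModel(combination=modal, cvc=cvc, train_accuracy=tr,
                            test_accuracy=te,
                            selected_count_over_repeats=wins[modal])

    best_k = max(per_k, key=lambda k: (per_k[k].cvc,
                                       per_k[k].test_accuracy, -k))
    return RepeatedSearchResult(
        repeats=repeats, per_k=per_k, best=per_k[best_k],
        searches=per_repeat if keep_searches else [])


# ---------------------------------------------------------------------------
# OR-MDR: per-cell effect sizes for the final model
# ---------------------------------------------------------------------------

def or_mdr(ds: GenotypeDataset, combination: tuple[str, ...],
           reference: str = "pooled",
           threshold: float | None = None) -> list[CellOddsRatio]:
    """Per-cell odds ratios of the final MDR model against a low-risk reference.

    Cells are labelled on the full available-case data at threshold T (the
    overall case:control ratio by default).  The reference odds a0/b0 pool
    all low-risk cells (``reference="pooled"``) or take the single lowest
    case:control-ratio cell (``reference="lowest"``); each non-empty cell j
    then gets OR_j = (a_j/b_j)/(a0/b0) with the Woolf-type 95% CI
    exp(ln OR +- 1.96 sqrt(1/a_j + 1/b_j + 1/a0 + 1/b0)).  Zero cells are
    Haldane-corrected (+0.5 on the four counts) and flagged; the
    significance flag marks CIs excluding 1.
    """
    table = tabulate_cells(ds, tuple(combination))
    labeling = classify_cells(table, threshold=threshold)
    cells = table.cells
    low_keys = [k for k, lab in labeling.labels.items() if lab == "low"]
    if not low_keys:
        raise DataError("no low-risk cell: OR-MDR reference undefined")
    if reference == "pooled":
        a0 = sum(cells[k][0] for k in low_keys)
        b0 = sum(cells[k][1] for k in low_keys)
    elif reference == "lowest":
        def ratio(k):
            ca, co = cells[k]
            return ca / co if co else math.inf
        kmin = min(low_keys, key=ratio)
        a0, b0 = cells[kmin]
    else:
        raise DataError(f"unknown reference rule {reference!r}")

    out: list[CellOddsRatio] = []
    for key, (ca, co) in sorted(cells.items()):
        lab = labeling.labels[key]
        if lab == "empty":
            continue
        aj, bj, ar, br = float(ca), float(co), float(a0), float(b0)
        corrected = False
        if min(aj, bj, ar, br) == 0:
            aj, bj, ar, br = aj + 0.5, bj + 0.5, ar + 0.5, br + 0.5
            corrected = True
        or_ = (aj / bj) / (ar / br)
        se = math.sqrt(1 / aj + 1 / bj + 1 / ar + 1 / br)
        lo = or_ * math.exp(-_Z95 * se)
        hi = or_ * math.exp(_Z95 * se)
        out.append(CellOddsRatio(cell=key, label=lab, n_cases=ca,
                                 n_controls=co, or_estimate=or_, ci_low=lo,
                                 ci_high=hi, significant=lo > 1.0 or hi < 1.0,
                                 zero_corrected=corrected))
    return out
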