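"""Independent brute-force MDR reimplementation used as a test oracle.

Deliberately naive: dictionaries and explicit loops, no shared code with
mdrkit.mdr beyond the stated protocol (stratified consecutive-block folds
from the subject order, threshold = training case:control ratio with ties
high, empty-in-training cells classified low, fold winner by training then
test accuracy then lexicographic order).
"""

import itertools

import numpy as np

MISSING = -1


def naive_folds(status_list, n_folds):
    """Fold id per subject: consecutive blocks within each status value."""
    fold = [None] * len(status_list)
    for s in (0, 1):
        idx = [i for i, st in enumerate(status_list) if st == s]
        # np.array_split semantics: first (len % n_folds) blocks get one extra
        n = len(idx)
        base, extra = divmod(n, n_folds)
        pos = 0
        for f in range(n_folds):
            size = base + (1 if f < extra else 0)
            for i in idx[pos:pos + size]:
                fold[i] = f
            pos += size
    return fold


def naive_eval(values, status, order, combo_cols, n_folds):
    """Per-fold (train_acc, test_acc) for one combination."""
    rows = [i for i in order
            if all(values[i][c] != MISSING for c in combo_cols)]
    sub_status = [status[i] for i in rows]
    fold = naive_folds(sub_status, n_folds)
    train_accs, test_accs = [], []
    for f in range(n_folds):
        train = [k for k in range(len(rows)) if fold[k] != f]
        test = [k for k in range(len(rows)) if fold[k] == f]
        cells = {}
        for k in train:
            key = tuple(values[rows[k]][c] for c in combo_cols)
            ca, co = cells.get(key, (0, 0))
            if sub_status[k] == 1:
                cells[key] = (ca + 1, co)
            else:
                cells[key] = (ca, co + 1)
        n_case_tr = sum(1 for k in train if sub_status[k] == 1)
        n_ctrl_tr = sum(1 for k in train if sub_status[k] == 0)
        high = set()
        for key, (ca, co) in cells.items():
            if ca == 0 and co == 0:
                continue
            if co == 0 or (n_ctrl_tr and ca / co >= n_case_tr / n_ctrl_tr) \
                    or (n_ctrl_tr == 0 and ca > 0):
                high.add(key)
        correct = 0
        for k in train:
            key = tuple(values[rows[k]][c] for c in combo_cols)
            pred = 1 if key in high else 0
            correct += pred == sub_status[k]
        train_accs.append(correct / len(train))
        correct = 0
        for k in test:
            key = tuple(values[rows[k]][c] for c in combo_cols)
            pred = 1 if key in high else 0  # unseen cells default low
            correct += pred == sub_status[k]
        test_accs.append(correct / len(test))
    return train_accs, test_accs


def naive_search(values, status, order, factor_names, k_min, k_max, n_folds):
    """Full exhaustive search; returns per-k dict with winner and CVCs."""
    result = {}
    for k in range(k_min, k_max + 1):
        combos = list(itertools.combinations(range(len(factor_names)), k))
        evals = {}
        for cols in combos:
            evals[cols] = naive_eval(values, status, order, cols, n_folds)
        cvc = {cols: 0 for cols in combos}
        for f in range(n_folds):
            # lexicographic generation order; strict > keeps the earliest tie
            best = combos[0]
            for cols in combos[1:]:
                tr, te = evals[cols]
                btr, bte = evals[best]
                if (tr[f], te[f]) > (btr[f], bte[f]):
                    best = cols
            cvc[best] += 1
        winner = combos[0]
        for cols in combos[1:]:
            te_mean = sum(evals[cols][1]) / n_folds
            bte_mean = sum(evals[winner][1]) / n_folds
            if (cvc[cols], te_mean) > (cvc[winner], bte_mean):
                winner = cols
        result[k] = {
            "winner": tuple(factor_names[c] for c in winner),
            "cvc": {tuple(factor_names[c] for c in cols): cvc[cols]
                    for cols in combos},
            "evals": {tuple(factor_names[c] for c in cols): evals[cols]
                      for cols in combos},
        }
    return result
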