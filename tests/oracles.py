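"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive and shares no code with the
implementation: confusion cells are recounted record by record, and the
metric formulas are substituted directly.
"""

from fractions import Fraction

from enzannot.ec import ECNumber


def truncate(ec: ECNumber, level: int) -> tuple:
    return tuple(ec.levels[i] if i < level else None for i in range(4))


def brute_force_binary(cells: dict) -> dict:
    """Direct substitution of the five binary metric formulas (exact
    rational arithmetic; 0/0 defined as 0)."""
    tp, fp, tn, fn, up, un = (
        cells["TP"], cells["FP"], cells["TN"], cells["FN"], cells["UP"], cells["UN"]
    )
    total = tp + fp + tn + fn + up + un

    def frac(num, den):
        return Fraction(num, den) if den else Fraction(0)

    acc = frac(tp + tn, total)
    precision = frac(tp, tp + fp)
    npv = frac(tn, tn + fn)
    recall = frac(tp, tp + fn + up)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else Fraction(0)
    )
    return {"acc": acc, "precision": precision, "npv": npv, "recall": recall, "f1": f1}


def brute_force_macro(per_class_cells: list[dict]) -> dict:
    """Macro means of per-class ACC/PR/Recall; mF1 as their harmonic mean."""
    n = len(per_class_cells)
    reps = [brute_force_binary(c) for c in per_class_cells]
    m_acc = sum(r["acc"] for r in reps) / n
    m_pr = sum(r["precision"] for r in reps) / n
    m_rec = sum(r["recall"] for r in reps) / n
    m_f1 = 2 * m_pr * m_rec / (m_pr + m_rec) if m_pr + m_rec else Fraction(0)
    return {"macc": m_acc, "mpr": m_pr, "mrecall": m_rec, "mf1": m_f1}


def recount_task1(gold, predicted) -> dict:
    cells = dict(TP=0, FP=0, TN=0, FN=0, UP=0, UN=0)
    for r in gold:
        pos = bool(r.is_enzyme)
        pred = predicted[r.id]
        if pred is None:
            cells["UP" if pos else "UN"] += 1
        elif len(pred) > 0:
            cells["TP" if pos else "FP"] += 1
        else:
            cells["FN" if pos else "TN"] += 1
    return cells


def recount_task2(gold, predicted, k_max=8) -> list[dict]:
    enzymes = [r for r in gold if r.is_enzyme]
    gold_counts = {r.id: min(len(r.ec_numbers), k_max) for r in enzymes}
    pred_counts = {
        r.id: (len(predicted[r.id]) if predicted[r.id] else None) for r in enzymes
    }
    classes = sorted(
        set(gold_counts.values()) | {c for c in pred_counts.values() if c is not None}
    )
    out = []
    for cls in classes:
        cells = dict(TP=0, FP=0, TN=0, FN=0, UP=0, UN=0)
        for r in enzymes:
            pos = gold_counts[r.id] == cls
            pred = pred_counts[r.id]
            if pred is None:
                cells["UP" if pos else "UN"] += 1
            elif pred == cls:
                cells["TP" if pos else "FP"] += 1
            else:
                cells["FN" if pos else "TN"] += 1
        out.append(cells)
    return out


def recount_task3(gold, predicted, level=4) -> list[dict]:
    gold_sets = {r.id: {truncate(ec, level) for ec in r.ec_numbers} for r in gold}
    pred_sets = {}
    for r in gold:
        pred = predicted[r.id]
        pred_sets[r.id] = (
            None if not pred else {truncate(ec, level) for ec in pred}
        )
    classes = sorted(
        {c for s in gold_sets.values() for c in s}
        | {c for s in pred_sets.values() if s for c in s},
        key=lambda t: tuple(-1 if x is None else x for x in t),
    )
    out = []
    for cls in classes:
        cells = dict(TP=0, FP=0, TN=0, FN=0, UP=0, UN=0)
        for r in gold:
            pos = cls in gold_sets[r.id]
            pred = pred_sets[r.id]
            if pred is None:
                if predicted[r.id] is not None and not r.is_enzyme:
                    cells["TN"] += 1
                else:
                    cells["UP" if pos else "UN"] += 1
            elif cls in pred:
                cells["TP" if pos else "FP"] += 1
            else:
                cells["FN" if pos else "TN"] += 1
        out.append(cells)
    return out
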