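"""Evaluation statistics: precision/recall with exact binomial CIs,
and chance-corrected inter-annotator agreement.

Precision is the proportion of predicted-positive instances that are
gold-positive (positive predictive value); recall the proportion of
gold-positive instances found (sensitivity). Both are binomial
proportions, so their confidence intervals use the exact
Clopper-Pearson construction rather than a normal approximation —
validation sets in this setting are small (tens of positives), where
Wald intervals undercover badly.

Undefined metrics (zero denominator) are reported as ``None``, never
silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import beta as _beta

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "AgreementReport",
    "confusion",
    "confusion_from_spans",
    "precision_recall",
    "clopper_pearson",
    "cohens_kappa",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class EvalReport:
    """Point estimates with exact binomial confidence intervals.

    ``precision``/``recall``/``f1`` are ``None`` when undefined (zero
    denominator). CI bounds bracket the corresponding point estimate.
    """

    counts: ConfusionCounts
    precision: float | None
    recall: float | None
    f1: float | None
    ci_precision: tuple[float, float] | None
    ci_recall: tuple[float, float] | None
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
                "tn": self.counts.tn,
            },
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "ci_precision": list(self.ci_precision) if self.ci_precision else None,
            "ci_recall": list(self.ci_recall) if self.ci_recall else None,
            "confidence_level": self.level,
        }

    def summary(self) -> str:
        def fmt(x, ci):
            if x is None:
                return "undefined"
            s = f"{x:.3f}"
            if ci:
                s += f" ({ci[0]:.3f}-{ci[1]:.3f})"
            return s

        c = self.counts
        pct = int(round(self.level * 100))
        return (
            f"tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn}\n"
            f"precision ({pct}% CI): {fmt(self.precision, self.ci_precision)}\n"
            f"recall    ({pct}% CI): {fmt(self.recall, self.ci_recall)}\n"
            f"f1: {'undefined' if self.f1 is None else f'{self.f1:.3f}'}"
        )


@dataclass(frozen=True)
class AgreementReport:
    observed_agreement: float
    expected_agreement: float
    kappa: float | None  # None when chance agreement is 1 (degenerate)

    def summary(self) -> str:
        k = "undefined" if self.kappa is None else f"{self.kappa:.3f}"
        return (
            f"observed agreement: {self.observed_agreement:.3f}\n"
            f"expected agreement: {self.expected_agreement:.3f}\n"
            f"kappa: {k}"
        )


def confusion(
    predicted: Mapping[str, str], gold: Mapping[str, str]
) -> ConfusionCounts:
    """Confusion counts over a shared key space of labelled units.

    Keys are opaque unit identifiers (instance ids or doc_ids). A key
    present on only one side is treated as negative on the other: an
    unmatched predicted positive is a false positive, an unmatched gold
    positive a false negative.
    """
    tp = fp = fn = tn = 0
    for key in set(predicted) | set(gold):
        p = predicted.get(key, "negative") == "positive"
        g = gold.get(key, "negative") == "positive"
        if p and g:
            tp += 1
        elif p:
            fp += 1
        elif g:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def confusion_from_spans(
    predicted: Sequence[tuple[str, int, int, str]],
    gold: Sequence[tuple[str, int, int, str]],
) -> ConfusionCounts:
    """Span-based instance alignment for confusion counts.

    Each element is ``(doc_id, start, end, label)``. Predicted and gold
    instances align when their anchor spans overlap within the same
    document; matching is greedy, leftmost-first, one-to-one. Duplicate
    spans on either side are an error.
    """

    def keyed(items, side):
        seen = set()
        out = []
        for doc_id, start, end, label in items:
            k = (doc_id, start, end)
            if k in seen:
                raise ValueError(f"duplicate {side} span {k}")
            seen.add(k)
            out.append((doc_id, start, end, label))
        return sorted(out)

    pred = keyed(predicted, "predicted")
    gld = keyed(gold, "gold")
    matched_gold: set[int] = set()
    tp = fp = fn = tn = 0
    for doc_id, start, end, plabel in pred:
        partner = None
        for j, (gdoc, gstart, gend, glabel) in enumerate(gld):
            if j in matched_gold or gdoc != doc_id:
                continue
            if start < gend and gstart < end:  # overlap
                partner = j
                break
        if partner is None:
            if plabel == "positive":
                fp += 1
            else:
                tn += 1
            continue
        matched_gold.add(partner)
        glabel = gld[partner][3]
        if plabel == "positive" and glabel == "positive":
            tp += 1
        elif plabel == "positive":
            fp += 1
        elif glabel == "positive":
            fn += 1
        else:
            tn += 1
    for j, (_, _, _, glabel) in enumerate(gld):
        if j not in matched_gold and glabel == "positive":
            fn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def precision_recall(
    counts: ConfusionCounts, level: float = 0.95
) -> EvalReport:
    """Point estimates plus exact binomial confidence intervals."""
    n_pred = counts.tp + counts.fp
    n_gold = counts.tp + counts.fn
    precision = counts.tp / n_pred if n_pred else None
    recall = counts.tp / n_gold if n_gold else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f1 = 0.0
    return EvalReport(
        counts=counts,
        precision=precision,
        recall=recall,
        f1=f1,
        ci_precision=clopper_pearson(counts.tp, n_pred, level) if n_pred else None,
        ci_recall=clopper_pearson(counts.tp, n_gold, level) if n_gold else None,
        level=level,
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n.

    Bounds come from beta-distribution quantiles — the inversion of the
    binomial tail sums: lower = Beta(alpha/2; k, n-k+1), upper =
    Beta(1-alpha/2; k+1, n-k). The lower bound is exactly 0 when k=0
    and the upper exactly 1 when k=n.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(_beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lower, upper)


def cohens_kappa(table: Sequence[Sequence[float]]) -> AgreementReport:
    """Cohen's kappa from a square two-rater contingency table.

    ``table[i][j]`` counts units rater A put in category i and rater B
    in category j. po = trace/N; pe = sum of products of marginal
    proportions; kappa = (po - pe) / (1 - pe), undefined when pe = 1.
    """
    k = len(table)
    if k == 0 or any(len(row) != k for row in table):
        raise ValueError("contingency table must be square and non-empty")
    n = float(sum(sum(row) for row in table))
    if n <= 0:
        raise ValueError("contingency table must have positive total")
    po = sum(table[i][i] for i in range(k)) / n
    row_marg = [sum(row) for row in table]
    col_marg = [sum(table[i][j] for i in range(k)) for j in range(k)]
    pe = sum(row_marg[i] * col_marg[i] for i in range(k)) / (n * n)
    kappa = None if pe >= 1.0 else (po - pe) / (1.0 - pe)
    return AgreementReport(observed_agreement=po, expected_agreement=pe, kappa=kappa)
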