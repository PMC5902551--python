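"""Evaluation statistics for editing-site predictions.

Two evaluation regimes coexist in this field and both are covered here:

* *verified-subset metrics* — a small panel of candidates has experimental
  truth (knock-down comparisons); predictions are scored against it with
  confusion-matrix metrics.  One wrinkle: the "F1 score" conventionally
  reported alongside these panels is the harmonic mean of sensitivity and
  specificity, not of precision and recall.  We expose it as ``f1_sens_spec``
  and the textbook statistic as ``f1_textbook``.

* *annotation-free proxies* — on genome-scale call sets with no truth,
  precision is proxied by the A-to-I ratio (fraction of calls that are
  A→G) and by an equal-error-rate FDR: assume every non-A-to-I call is
  false and that the 12 mismatch types err at equal rates, so the false
  A-to-I count is estimated as one eleventh of the non-A-to-I count.

Undefined ratios (zero denominators) are reported as ``None`` ("absent"),
never as 0, so aggregate reports are not silently deflated.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .sequence_windows import CandidateSNV, classify_mismatch

SiteKey = tuple[str, int, str, str]


def _as_key(site) -> SiteKey:
    if isinstance(site, tuple):
        return site
    return site.key


# ---------------------------------------------------------------------------
# Verified-subset metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationCounts:
    """Confusion counts over the experimentally verified candidates.

    ``n_predicted_total`` additionally counts *all* predicted sites,
    verified or not; it is the denominator of the validation and
    misclassification rates.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_predicted_total: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn, self.n_predicted_total) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_verified(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def verify_predictions(
    predicted: Iterable,
    verified_true: Iterable,
    verified_false: Iterable,
) -> ValidationCounts:
    """Cross predicted sites with disjoint verified-true/false panels."""
    pred = {_as_key(s) for s in predicted}
    true = {_as_key(s) for s in verified_true}
    false = {_as_key(s) for s in verified_false}
    overlap = true & false
    if overlap:
        raise ValueError(f"{len(overlap)} sites appear in both truth sets")
    return ValidationCounts(
        tp=len(pred & true),
        fp=len(pred & false),
        fn=len(true - pred),
        tn=len(false - pred),
        n_predicted_total=len(pred),
    )


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(counts: ValidationCounts) -> dict[str, float | None]:
    """Confusion-matrix metric suite from verified counts.

    ``f1_sens_spec`` is the harmonic mean of sensitivity and specificity (the
    convention used with these verification panels); ``f1_textbook`` is
    the harmonic mean of precision and recall.  ``validation_rate`` is the
    fraction of all predictions that are verified (either way);
    ``misclassification_rate`` is the fraction verified false.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    gm = float(np.sqrt(sens * spec)) if sens is not None and spec is not None else None
    f1_sens_spec = (
        _ratio(2 * sens * spec, sens + spec)
        if sens is not None and spec is not None and (sens + spec) > 0
        else None
    )
    f1_textbook = (
        _ratio(2 * ppv * sens, ppv + sens)
        if ppv is not None and sens is not None and (ppv + sens) > 0
        else None
    )
    return {
        "accuracy": _ratio(tp + tn, counts.n_verified),
        "sensitivity": sens,
        "specificity": spec,
        "gm": gm,
        "ppv": ppv,
        "f1_sens_spec": f1_sens_spec,
        "f1_textbook": f1_textbook,
        "validation_rate": _ratio(tp + fp, counts.n_predicted_total),
        "misclassification_rate": _ratio(fp, counts.n_predicted_total),
    }


# ---------------------------------------------------------------------------
# Threshold-free curves
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve.

    Equals the Mann–Whitney rank statistic: the probability that a random
    positive outscores a random negative, ties counting one half.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (step-wise integral).

    Computed as the sum of precision × recall-increment over descending
    score thresholds (average precision).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("pr_auc needs both classes present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Annotation-free proxies
# ---------------------------------------------------------------------------

def a_to_i_ratio(sites: Sequence, collapse_revcomp_a2i: bool = False) -> float | None:
    """Fraction of sites whose mismatch is A→G (optionally also T→C).

    Accepts candidates, called sites, or raw (contig, pos, ref, alt)
    tuples.  Used as a precision proxy on call sets without truth, since
    A-to-I dominates genuine editing.
    """
    sites = list(sites)
    if not sites:
        return None
    n_a2i = 0
    for s in sites:
        snv = s.snv if hasattr(s, "snv") else s
        if isinstance(snv, tuple):
            snv = CandidateSNV(*snv[:4])
        if classify_mismatch(snv).is_a_to_i(collapse_revcomp_a2i):
            n_a2i += 1
    return n_a2i / len(sites)


def fdr_equal_error(n_total: int, n_a_to_i: int) -> float | None:
    """Equal-error-rate FDR among A-to-I calls.

    Assume all non-A-to-I calls are false and that errors distribute
    equally over the 12 mismatch types: the 11 non-A-to-I types then share
    the (n_total − n_a_to_i) false calls, so the expected number of false
    A-to-I calls is that count divided by 11, and

        FDR = (n_total − n_a_to_i) / 11 / n_a_to_i.
    """
    if not 0 <= n_a_to_i <= n_total:
        raise ValueError("need 0 <= n_a_to_i <= n_total")
    if n_a_to_i == 0:
        return None
    return (n_total - n_a_to_i) / 11 / n_a_to_i


def reproducibility_overlap(a: Iterable, b: Iterable, mode: str = "jaccard") -> float | None:
    """Overlap ratio of two site sets keyed by (contig, pos, ref, alt).

    ``jaccard``: |a∩b| / |a∪b|.  ``min``: |a∩b| / min(|a|, |b|).  Both are
    offered because "overlap ratio" is reported without a formula in much
    of the literature.
    """
    sa = {_as_key(s) for s in a}
    sb = {_as_key(s) for s in b}
    if not sa and not sb:
        return None
    inter = len(sa & sb)
    if mode == "jaccard":
        return inter / len(sa | sb)
    if mode == "min":
        m = min(len(sa), len(sb))
        return inter / m if m else None
    raise ValueError(f"unknown overlap mode {mode!r}")


def homologous_ratio(n_homologous: int, n_identified: int) -> float | None:
    """Fraction of identified sites with an orthologous site in another species."""
    if n_homologous < 0 or n_identified < 0:
        raise ValueError("counts must be nonnegative")
    if n_homologous > n_identified:
        raise ValueError("homologous count exceeds identified count")
    if n_identified == 0:
        return None
    return n_homologous / n_identified


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Flat record of every statistic computed for one method/condition."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    gm: float | None = None
    ppv: float | None = None
    f1_sens_spec: float | None = None
    f1_textbook: float | None = None
    validation_rate: float | None = None
    misclassification_rate: float | None = None
    auc: float | None = None
    aucpr: float | None = None
    a_to_i_ratio: float | None = None
    fdr_equal_error: float | None = None
    counts: ValidationCounts | None = None

    COLUMN_ORDER = (
        "accuracy sensitivity specificity gm ppv f1_sens_spec f1_textbook "
        "validation_rate misclassification_rate auc aucpr a_to_i_ratio "
        "fdr_equal_error"
    ).split()

    @classmethod
    def from_counts(cls, counts: ValidationCounts, **extra) -> "EvalReport":
        return cls(**confusion_metrics(counts), counts=counts, **extra)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.COLUMN_ORDER}
        if self.counts is not None:
            d["counts"] = asdict(self.counts)
        return d

    def to_tsv_row(self, name: str) -> str:
        cells = [name] + [
            "" if getattr(self, k) is None else f"{getattr(self, k):.6f}"
            for k in self.COLUMN_ORDER
        ]
        return "\t".join(cells)

    @classmethod
    def tsv_header(cls) -> str:
        return "\t".join(["name"] + cls.COLUMN_ORDER)
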