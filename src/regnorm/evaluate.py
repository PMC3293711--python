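"""Separation metrics for regulation-microarray normalization.

The quality of a normalization is judged by how well it preserves the
separation between the enriched and un-enriched components of the
log-ratio distribution.  Negative-control probes (no genomic target,
measuring background) form the negative class and gene-promoter probes
the positive class of a ROC analysis; the AUC quantifies how far the
promoter distribution extends beyond the control distribution.  A
two-component Gaussian mixture fitted by EM summarizes the component
structure directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import MAMatrix, ProbeAnnotation, ProbeCategory

__all__ = [
    "ROCResult",
    "roc_auc",
    "separation_report",
    "MixtureFit",
    "fit_two_component_mixture",
    "MixtureCollapseError",
]


@dataclass
class ROCResult:
    """ROC curve and area for control-vs-promoter separation."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_negative: int
    n_positive: int


def roc_auc(negative_scores: np.ndarray, positive_scores: np.ndarray) -> ROCResult:
    """ROC curve of positive vs negative score vectors.

    The curve is built by sweeping a threshold over the pooled unique
    scores (higher score = called positive).  The area is computed by the
    trapezoidal rule and cross-checked against the Mann-Whitney rank
    formula, U / (n_neg * n_pos) with ties counted half; the two must
    agree to 1e-10 (ties produce diagonal ROC segments whose trapezoids
    equal the half-credit convention exactly).
    """
    neg = np.asarray(negative_scores, dtype=float)
    pos = np.asarray(positive_scores, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both score vectors must be non-empty")
    if not (np.all(np.isfinite(neg)) and np.all(np.isfinite(pos))):
        raise ValueError("scores must be finite")

    thresholds = np.unique(np.concatenate([neg, pos]))[::-1]
    # fraction of each class >= threshold, via descending-sorted search
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    fpr = 1.0 - np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    tpr = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))

    ranks = rankdata(np.concatenate([neg, pos]))
    r_pos = ranks[neg.size :].sum()
    auc_rank = (r_pos - pos.size * (pos.size + 1) / 2.0) / (neg.size * pos.size)
    if abs(auc - auc_rank) > 1e-10:
        raise RuntimeError(
            f"ROC sweep ({auc}) and rank-formula ({auc_rank}) AUC disagree"
        )
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, n_negative=neg.size, n_positive=pos.size)


def _class_summary(values: np.ndarray, prefix: str) -> dict[str, float]:
    qs = np.quantile(values, [0.25, 0.5, 0.75])
    return {
        f"{prefix}_mean": float(values.mean()),
        f"{prefix}_sd": float(values.std(ddof=1)),
        f"{prefix}_q25": float(qs[0]),
        f"{prefix}_median": float(qs[1]),
        f"{prefix}_q75": float(qs[2]),
    }


def separation_report(
    annotation: ProbeAnnotation,
    M_by_method: Mapping[str, MAMatrix | np.ndarray],
) -> pd.DataFrame:
    """Control-vs-promoter separation per method, per array and combined.

    For each entry of ``M_by_method`` (method name -> M matrix aligned to
    ``annotation``) computes the per-array ROC/AUC, the combined ROC/AUC
    with probes pooled across arrays, and density summaries of both
    classes.  Returns a tidy frame with one row per (method, array) plus
    one 'combined' row per method; the across-array AUC standard
    deviation quantifies comparability between microarrays.
    """
    neg_mask = annotation.category_mask(ProbeCategory.NEGATIVE_CONTROL)
    pos_mask = annotation.category_mask(ProbeCategory.PROMOTER)
    if not neg_mask.any():
        raise ValueError("annotation has no negative-control probes")
    if not pos_mask.any():
        raise ValueError("annotation has no promoter probes")

    rows = []
    for method, M in M_by_method.items():
        ids = M.array_ids if isinstance(M, MAMatrix) else None
        M = M.M if isinstance(M, MAMatrix) else np.atleast_2d(np.asarray(M, dtype=float))
        if M.shape[0] != len(annotation):
            raise ValueError(f"M matrix for {method!r} not aligned to annotation")
        if ids is None:
            ids = [f"array{j + 1:02d}" for j in range(M.shape[1])]
        aucs = []
        for j, aid in enumerate(ids):
            roc = roc_auc(M[neg_mask, j], M[pos_mask, j])
            aucs.append(roc.auc)
            rows.append(
                {
                    "method": method,
                    "array": aid,
                    "auc": roc.auc,
                    "n_negative": roc.n_negative,
                    "n_positive": roc.n_positive,
                    **_class_summary(M[neg_mask, j], "neg"),
                    **_class_summary(M[pos_mask, j], "pos"),
                }
            )
        combined = roc_auc(M[neg_mask].ravel(), M[pos_mask].ravel())
        rows.append(
            {
                "method": method,
                "array": "combined",
                "auc": combined.auc,
                "n_negative": combined.n_negative,
                "n_positive": combined.n_positive,
                "auc_sd_across_arrays": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                **_class_summary(M[neg_mask].ravel(), "neg"),
                **_class_summary(M[pos_mask].ravel(), "pos"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture (EM)
# ---------------------------------------------------------------------------


class MixtureCollapseError(RuntimeError):
    """A mixture component collapsed (sd below threshold); the data likely
    support fewer components."""


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture fitted to a log-ratio vector.

    Components are ordered so that ``mean_enriched >= mean_unenriched``;
    ``weight_enriched`` is the mixing weight of the high-mean (enriched)
    component.
    """

    weight_enriched: float
    mean_unenriched: float
    mean_enriched: float
    sd_unenriched: float
    sd_enriched: float
    log_likelihood: float
    converged: bool
    n_iter: int
    diagnostics: dict[str, Any] = field(default_factory=dict)


def _normal_pdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


def fit_two_component_mixture(
    m_values: np.ndarray,
    init: tuple[float, float, float, float, float] | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to log-ratios by EM.

    The log-ratio distribution of a regulation array is modelled as a
    mixture of an un-enriched and an enriched normal component.  ``init``
    is (weight_enriched, mean_unenriched, mean_enriched, sd_unenriched,
    sd_enriched); by default the component means start at the 25th and
    90th percentiles.  Deterministic given ``init``; the log-likelihood is
    non-decreasing across iterations (checked).

    Raises :class:`MixtureCollapseError` when a component sd falls below
    1e-6, which indicates the data support fewer components.
    """
    x = np.asarray(m_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ValueError("mixture fit needs at least 50 finite values")

    if init is None:
        sd0 = float(x.std(ddof=1))
        w, mu1, mu2 = 0.5, float(np.percentile(x, 25)), float(np.percentile(x, 90))
        s1 = s2 = max(sd0, 1e-3)
    else:
        w, mu1, mu2, s1, s2 = map(float, init)

    ll_prev = -np.inf
    ll_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p1 = (1.0 - w) * _normal_pdf(x, mu1, s1)
        p2 = w * _normal_pdf(x, mu2, s2)
        total = p1 + p2
        total = np.where(total <= 0, np.finfo(float).tiny, total)
        resp = p2 / total  # responsibility of the enriched component
        ll = float(np.log(total).sum())
        if ll + 1e-9 < ll_prev:
            raise RuntimeError("EM log-likelihood decreased — numerical failure")
        ll_trace.append(ll)

        n2 = resp.sum()
        n1 = x.size - n2
        w = n2 / x.size
        mu1 = float(((1.0 - resp) * x).sum() / n1)
        mu2 = float((resp * x).sum() / n2)
        s1 = float(np.sqrt(((1.0 - resp) * (x - mu1) ** 2).sum() / n1))
        s2 = float(np.sqrt((resp * (x - mu2) ** 2).sum() / n2))
        if s1 < 1e-6 or s2 < 1e-6:
            raise MixtureCollapseError(
                "a mixture component collapsed (sd < 1e-6); try one component"
            )
        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_prev = ll

    # order components so that the enriched one has the larger mean
    if mu2 < mu1:
        mu1, mu2 = mu2, mu1
        s1, s2 = s2, s1
        w = 1.0 - w

    # a single Gaussian that explains the data as well (by BIC) flags the
    # second component as non-improving
    mu0, sd0 = float(x.mean()), float(x.std())
    ll_one = float(np.log(_normal_pdf(x, mu0, max(sd0, 1e-12))).sum())
    logn = np.log(x.size)
    bic_one = 2 * logn - 2 * ll_one
    bic_two = 5 * logn - 2 * ll_trace[-1]
    diagnostics = {
        "ll_trace": ll_trace,
        "possibly_one_component": bool(
            bic_one <= bic_two or min(w, 1.0 - w) < 0.02
        ),
    }
    return MixtureFit(
        weight_enriched=float(w),
        mean_unenriched=mu1,
        mean_enriched=mu2,
        sd_unenriched=s1,
        sd_enriched=s2,
        log_likelihood=ll_trace[-1],
        converged=converged,
        n_iter=it,
        diagnostics=diagnostics,
    )
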