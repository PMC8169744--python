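"""Agreement and diagnostic-performance statistics.

Implements the comparisons used to judge automated against reference
scoring: Bland–Altman analysis of paired continuous scores, unweighted
Cohen's Kappa on risk buckets with the conventional interpretation bands,
a two-sample Kolmogorov–Smirnov test on score distributions, 5x5 bucket
confusion matrices (reference on rows), and per-cutoff diagnostic metrics
(sensitivity, specificity, PPV, NPV, F1) with normal-approximation 95%
confidence intervals clipped to [0, 1].  F1 is the harmonic mean of
sensitivity and PPV.  Metrics with an empty denominator are reported as NaN
and flagged undefined rather than silently substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import math

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import BUCKETS, CUTOFFS, binary_at_cutoff

__all__ = [
    "BlandAltman",
    "DiagnosticReport",
    "bland_altman",
    "cohen_kappa",
    "kappa_band",
    "ks_test",
    "confusion_matrix",
    "diagnostic_metrics",
    "evaluation_report",
    "report_to_csv",
]

_Z = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class BlandAltman:
    """Mean difference (predicted - reference), 95% limits of agreement and
    the 95% CI of the bias."""

    bias: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    sd: float
    differences: np.ndarray


def bland_altman(pairs) -> BlandAltman:
    """Bland–Altman agreement for (reference, predicted) score pairs."""
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least two (reference, predicted) pairs")
    diffs = pairs[:, 1] - pairs[:, 0]
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    half = _Z * sd
    se = sd / math.sqrt(len(diffs))
    return BlandAltman(bias=bias, loa_low=bias - half, loa_high=bias + half,
                       bias_ci=(bias - _Z * se, bias + _Z * se), sd=sd,
                       differences=diffs)


def cohen_kappa(reference, predicted) -> tuple[float, str]:
    """Unweighted Cohen's Kappa and its interpretation band.

    Categories are taken as the union observed in either rating.  Perfect
    agreement with a single observed category is reported as kappa 1.0
    (chance agreement is degenerate there).
    """
    reference, predicted = list(reference), list(predicted)
    if len(reference) != len(predicted) or not reference:
        raise ValueError("paired, non-empty ratings required")
    cats = sorted(set(reference) | set(predicted), key=str)
    n = len(reference)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for r, p in zip(reference, predicted):
        table[idx[r], idx[p]] += 1
    po = float(np.trace(table)) / n
    pe = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / n ** 2
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return kappa, kappa_band(kappa)


def kappa_band(kappa: float) -> str:
    """Conventional interpretation of a Kappa coefficient."""
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def ks_test(scores_a, scores_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov D statistic and asymptotic p-value."""
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def confusion_matrix(reference_buckets, predicted_buckets) -> np.ndarray:
    """5x5 bucket confusion counts; rows = reference, columns = predicted."""
    m = np.zeros((5, 5), dtype=int)
    for r, p in zip(reference_buckets, predicted_buckets, strict=True):
        m[BUCKETS.index(r), BUCKETS.index(p)] += 1
    return m


def _wald_ci(p: float, n: int) -> tuple[float, float]:
    half = _Z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def _wilson_ci(p: float, n: int) -> tuple[float, float]:
    z2 = _Z ** 2
    center = (p + z2 / (2 * n)) / (1 + z2 / n)
    half = _Z * math.sqrt(p * (1 - p) / n + z2 / (4 * n ** 2)) / (1 + z2 / n)
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass
class DiagnosticReport:
    """One cutoff's diagnostic metrics; proportions in [0, 1] with 95% CIs
    clipped to [0, 1].  ``undefined`` lists metrics with an empty
    denominator (reported as NaN)."""

    cutoff: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = math.nan
    specificity: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    f1: float = math.nan
    sensitivity_ci: tuple = (math.nan, math.nan)
    specificity_ci: tuple = (math.nan, math.nan)
    ppv_ci: tuple = (math.nan, math.nan)
    npv_ci: tuple = (math.nan, math.nan)
    undefined: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def diagnostic_metrics(pairs=None, cutoff: int = 1, *,
                       calls: tuple | None = None,
                       ci: str = "wald") -> DiagnosticReport:
    """Diagnostic metrics at one cutoff.

    ``pairs`` are (reference score, predicted score) rows dichotomized as
    positive iff score >= cutoff on each side; alternatively pass
    ``calls=(reference_bool, predicted_bool)`` directly (e.g., bucket-derived
    calls for the non-gated classifier).  ``ci`` selects the interval method:
    "wald" (normal approximation, clipped — the default) or "wilson".
    """
    if calls is None:
        pairs = np.asarray(pairs, dtype=np.float64)
        ref = np.array([binary_at_cutoff(s, cutoff) for s in pairs[:, 0]])
        pred = np.array([binary_at_cutoff(s, cutoff) for s in pairs[:, 1]])
    else:
        ref, pred = (np.asarray(c, dtype=bool) for c in calls)
    tp = int(np.sum(ref & pred))
    fp = int(np.sum(~ref & pred))
    tn = int(np.sum(~ref & ~pred))
    fn = int(np.sum(ref & ~pred))
    rep = DiagnosticReport(cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn)
    ci_fn = {"wald": _wald_ci, "wilson": _wilson_ci}[ci]

    def fill(name, num, den):
        if den == 0:
            rep.undefined.append(name)
            return
        p = num / den
        setattr(rep, name, p)
        if name != "f1":
            setattr(rep, name + "_ci", ci_fn(p, den))

    fill("sensitivity", tp, tp + fn)
    fill("specificity", tn, tn + fp)
    fill("ppv", tp, tp + fp)
    fill("npv", tn, tn + fn)
    if not math.isnan(rep.sensitivity) and not math.isnan(rep.ppv):
        if rep.sensitivity + rep.ppv > 0:
            rep.f1 = (2 * rep.sensitivity * rep.ppv
                      / (rep.sensitivity + rep.ppv))
        else:
            rep.f1 = 0.0
    else:
        rep.undefined.append("f1")
    return rep


def evaluation_report(pairs, reference_buckets=None, predicted_buckets=None,
                      cutoffs=CUTOFFS) -> dict:
    """Full agreement summary for one cohort, JSON-serializable.

    ``pairs`` are (reference, predicted) total scores; bucket sequences
    default to bucketing the scores.
    """
    from .scoring import bucket as to_bucket
    pairs = np.asarray(pairs, dtype=np.float64)
    if reference_buckets is None:
        reference_buckets = [to_bucket(s) for s in pairs[:, 0]]
    if predicted_buckets is None:
        predicted_buckets = [to_bucket(s) for s in pairs[:, 1]]
    ba = bland_altman(pairs)
    kappa, band = cohen_kappa(reference_buckets, predicted_buckets)
    d, p = ks_test(pairs[:, 0], pairs[:, 1])
    return {
        "n": int(len(pairs)),
        "bland_altman": {"bias": ba.bias, "loa": [ba.loa_low, ba.loa_high],
                         "bias_ci": list(ba.bias_ci)},
        "kappa": kappa,
        "kappa_band": band,
        "ks": {"D": d, "p": p},
        "confusion_matrix": confusion_matrix(
            reference_buckets, predicted_buckets).tolist(),
        "cutoffs": {str(c): diagnostic_metrics(pairs, c).to_dict()
                    for c in cutoffs},
    }


def report_to_csv(report: dict, path) -> None:
    """One row per cutoff, percentages to one decimal as printed reports do."""
    rows = []
    for c, m in report["cutoffs"].items():
        rows.append({
            "cutoff": c,
            **{k: (round(100 * m[k], 1) if isinstance(m[k], float)
                   and not math.isnan(m[k]) else m[k])
               for k in ("sensitivity", "specificity", "ppv", "npv")},
            "f1": m["f1"] if not math.isnan(m["f1"]) else "",
            "kappa": report["kappa"],
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def plot_agreement(pairs, out_path) -> None:
    """Bland–Altman scatter written to an image file (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    pairs = np.asarray(pairs, dtype=np.float64)
    ba = bland_altman(pairs)
    means = pairs.mean(axis=1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, ba.differences, s=12)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (predicted - reference)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
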