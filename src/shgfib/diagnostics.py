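"""Diagnostic-accuracy statistics for the fibrosis index.

The continuous index is evaluated against the ordinal Brunt stage with
Spearman correlation, and against four standard dichotomisations —
mild (0 vs 1–4), significant (0–1 vs 2–4), bridging (0–2 vs 3–4) and
cirrhosis (0–3 vs 4) — with:

* AUROC computed as the Mann–Whitney statistic with half-credit for ties,
  and a 95% confidence interval from the DeLong structural-components
  estimator (a bootstrap interval is available by flag);
* the optimal cutoff by Youden's index (maximal sensitivity + specificity,
  a subject being called positive when the index is strictly greater than
  the cutoff; ties go to the smallest cutoff);
* sensitivity, specificity, likelihood ratios, predictive values and
  accuracy from the 2×2 confusion table at that cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BinaryGrouping:
    """A dichotomisation of the 0–4 stage scale: positive ⇔ stage ≥ min_positive."""

    name: str
    min_positive_stage: int

    def positives(self, stages) -> np.ndarray:
        return np.asarray(stages) >= self.min_positive_stage

    @property
    def description(self) -> str:
        neg = "/".join(str(s) for s in range(self.min_positive_stage))
        pos = "/".join(str(s) for s in range(self.min_positive_stage, 5))
        return f"{neg} vs {pos}"


#: The four standard fibrosis groupings.
GROUPINGS = (
    BinaryGrouping("mild", 1),
    BinaryGrouping("significant", 2),
    BinaryGrouping("bridging", 3),
    BinaryGrouping("cirrhosis", 4),
)


@dataclass
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class CutoffReport:
    """Operating-point metrics at one cutoff (proportions, not percent)."""

    cutoff: float
    sensitivity: float
    specificity: float
    positive_lr: float
    negative_lr: float
    ppv: float
    npv: float
    accuracy: float


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined",
                      stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


@dataclass
class AurocResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auroc(scores, labels, ci: str = "delong", n_boot: int = 2000,
          seed: int = 0) -> AurocResult:
    """AUROC with 95% confidence interval.

    The point estimate is the Mann–Whitney probability that a positive
    outscores a negative, with ties counting one half.  The default CI uses
    DeLong's structural components; ``ci="bootstrap"`` stratified-resamples
    subjects instead.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # structural components: V10[i] = P(pos_i > neg) + ½P(tie)
    all_ranks = _midrank(scores)
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[labels] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[~labels] - neg_ranks) / m
    auc = float(v10.mean())
    if ci == "delong":
        var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
            np.var(v01, ddof=1) / n if n > 1 else 0.0
        )
        se = math.sqrt(max(var, 0.0))
        z = stats.norm.ppf(0.975)
        lo, hi = auc - z * se, auc + z * se
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            ps = pos[rng.integers(0, m, m)]
            ns = neg[rng.integers(0, n, n)]
            r = _midrank(np.concatenate([ps, ns]))
            reps[b] = (r[:m].mean() - (m + 1) / 2) / n
        se = float(reps.std(ddof=1))
        lo, hi = np.quantile(reps, [0.025, 0.975])
    else:
        raise ValueError(f"unknown CI method {ci!r}")
    return AurocResult(auc, float(max(lo, 0.0)), float(min(hi, 1.0)), float(se))


def youden_cutoff(scores, labels):
    """Cutoff maximising sensitivity + specificity.

    Candidates are the observed score values; a subject is positive when its
    score is strictly greater than the cutoff.  Ties in the objective go to
    the smallest cutoff.  Returns ``(cutoff, youden_j)`` with
    J = sens + spec − 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    m, n = int(labels.sum()), int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    candidates = np.unique(scores)
    best_c, best_num = candidates[0], -1
    # integer objective sens·m·n + spec·m·n: exact, so ties are true ties
    for c in candidates:
        called = scores > c
        num = int((called & labels).sum()) * n + int((~called & ~labels).sum()) * m
        if num > best_num:
            best_c, best_num = c, num
    return float(best_c), best_num / (m * n) - 1.0


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionTable:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    called = scores > cutoff
    return ConfusionTable(
        tp=int((called & labels).sum()),
        fp=int((called & ~labels).sum()),
        fn=int((~called & labels).sum()),
        tn=int((~called & ~labels).sum()),
    )


def diagnostic_metrics(table: ConfusionTable, cutoff: float = float("nan")
                       ) -> CutoffReport:
    """Sensitivity, specificity, likelihood ratios, predictive values and
    accuracy from a 2×2 table.  A likelihood ratio with a zero denominator
    (perfect specificity or zero specificity) is reported as infinite, with
    a warning."""
    pos = table.tp + table.fn
    neg = table.tn + table.fp
    if pos == 0 or neg == 0:
        raise ValueError("confusion table margins must be positive")
    sens = table.tp / pos
    spec = table.tn / neg
    if spec == 1.0:
        warnings.warn("specificity 1: positive likelihood ratio infinite",
                      stacklevel=2)
        plr = math.inf
    else:
        plr = sens / (1.0 - spec)
    if spec == 0.0:
        warnings.warn("specificity 0: negative likelihood ratio infinite",
                      stacklevel=2)
        nlr = math.inf
    else:
        nlr = (1.0 - sens) / spec
    ppv = table.tp / (table.tp + table.fp) if table.tp + table.fp else float("nan")
    npv = table.tn / (table.tn + table.fn) if table.tn + table.fn else float("nan")
    return CutoffReport(
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        positive_lr=plr,
        negative_lr=nlr,
        ppv=ppv,
        npv=npv,
        accuracy=(table.tp + table.tn) / table.n,
    )


def staging_performance_report(
    b_indexes, stages, groupings=GROUPINGS, ci: str = "delong"
) -> pd.DataFrame:
    """Per-grouping AUROC (95% CI), Youden cutoff and operating-point
    metrics of cross-validated fibrosis indexes.

    One row per dichotomisation; a grouping with an empty class is marked
    not-estimable (NaN row).  Percentages are reported as proportions.
    """
    b_indexes = np.asarray(b_indexes, dtype=float)
    stages = np.asarray(stages)
    rows = []
    for g in groupings:
        labels = g.positives(stages)
        row: dict[str, object] = {"grouping": g.name, "stages": g.description}
        if labels.all() or not labels.any():
            row.update({k: float("nan") for k in (
                "auroc", "ci_low", "ci_high", "cutoff", "sensitivity",
                "specificity", "positive_lr", "negative_lr", "ppv", "npv",
                "accuracy")})
            row["estimable"] = False
        else:
            res = auroc(b_indexes, labels, ci=ci)
            cutoff, _ = youden_cutoff(b_indexes, labels)
            report = diagnostic_metrics(
                confusion_at_cutoff(b_indexes, labels, cutoff), cutoff
            )
            row.update(
                auroc=res.auc, ci_low=res.ci_low, ci_high=res.ci_high,
                cutoff=cutoff, sensitivity=report.sensitivity,
                specificity=report.specificity,
                positive_lr=report.positive_lr,
                negative_lr=report.negative_lr,
                ppv=report.ppv, npv=report.npv, accuracy=report.accuracy,
                estimable=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def report_to_markdown(report: pd.DataFrame) -> str:
    """Render the staging report as a compact Markdown table (percentages to
    one decimal, likelihood ratios to two)."""
    lines = [
        "| Group | Stages | AUROC (95% CI) | Cutoff | Sens | Spec | +LR | -LR | PPV | NPV |",
        "|---|---|---|---|---|---|---|---|---|---|",
    ]
    for _, r in report.iterrows():
        if not r.get("estimable", True):
            lines.append(f"| {r['grouping']} | {r['stages']} | not estimable "
                         "| — | — | — | — | — | — | — |")
            continue

        def pct(v):
            return f"{100 * v:.1f}%"

        lines.append(
            f"| {r['grouping']} | {r['stages']} "
            f"| {r['auroc']:.3f} ({r['ci_low']:.3f}–{r['ci_high']:.3f}) "
            f"| {r['cutoff']:.2f} | {pct(r['sensitivity'])} "
            f"| {pct(r['specificity'])} | {r['positive_lr']:.2f} "
            f"| {r['negative_lr']:.2f} | {pct(r['ppv'])} | {pct(r['npv'])} |"
        )
    return "\n".join(lines)
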