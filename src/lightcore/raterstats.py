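"""Diagnostic-accuracy and multi-rater agreement statistics.

Binary rating tables (cases x raters, "cancer"/"benign") are scored against
slide-histology ground truth: per-rater and majority-vote confusion counts
and the derived sensitivity/specificity/accuracy/PPV/NPV, plus free-marginal
(Randolph-style) multirater agreement and kappa with a percentile-bootstrap
confidence interval.

A canonical 44-case, 3-rater fixture table is shipped
(:func:`fixture_table`).  It is the unique-up-to-case-permutation solution
of the published per-rater confusion marginals and the observed agreement
level, and reproduces every published metric cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANCER",
    "BENIGN",
    "RatingTable",
    "GroundTruthLabels",
    "ConfusionCounts",
    "DiagnosticMetrics",
    "AgreementResult",
    "confusion_counts",
    "diagnostic_metrics",
    "majority_vote",
    "overall_agreement",
    "free_marginal_kappa",
    "kappa_bootstrap_ci",
    "fixture_table",
    "read_rating_csv",
    "write_rating_csv",
    "table_one",
    "table_two",
    "round_half_up",
]

CANCER = "cancer"
BENIGN = "benign"
_LABELS = (CANCER, BENIGN)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching table formatting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _check_labels(arr: np.ndarray) -> None:
    bad = set(np.unique(arr)) - set(_LABELS)
    if bad:
        raise ValueError(f"invalid labels {sorted(bad)}; expected {_LABELS}")


@dataclass
class RatingTable:
    """N cases x R raters of binary calls; no missing entries allowed."""

    calls: np.ndarray
    case_ids: list[str]
    rater_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2D cases x raters matrix")
        n, r = self.calls.shape
        if n < 1 or r < 1:
            raise ValueError("need at least one case and one rater")
        if len(self.case_ids) != n or len(self.rater_ids) != r:
            raise ValueError("id lists must match the calls matrix shape")
        _check_labels(self.calls)

    @property
    def n_cases(self) -> int:
        return self.calls.shape[0]

    @property
    def n_raters(self) -> int:
        return self.calls.shape[1]

    def column(self, rater: int | str) -> np.ndarray:
        if isinstance(rater, str):
            rater = self.rater_ids.index(rater)
        return self.calls[:, rater]


@dataclass
class GroundTruthLabels:
    """Per-case ground-truth label from slide-based histology consensus."""

    labels: np.ndarray
    case_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1 or len(self.case_ids) != self.labels.size:
            raise ValueError("labels and case_ids must align")
        _check_labels(self.labels)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Proportion metrics; a metric is ``None`` when its denominator is 0."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        return {
            k: (None if v is None else round_half_up(v, ndigits))
            for k, v in vars(self).items()
        }


@dataclass(frozen=True)
class AgreementResult:
    p_overall: float
    kappa_free: float
    k_categories: int
    ci95: tuple[float, float] | None = None


def confusion_counts(calls: np.ndarray, truth: GroundTruthLabels,
                     case_ids: list[str] | None = None) -> ConfusionCounts:
    """Count tp/fn/fp/tn with "cancer" as the positive class.

    ``case_ids``, when given, must match the truth's ids exactly (aligned
    order); otherwise positional alignment is assumed.
    """
    calls = np.asarray(calls, dtype=object)
    _check_labels(calls)
    if calls.shape != truth.labels.shape:
        raise ValueError("calls and truth must have the same length")
    if case_ids is not None and list(case_ids) != list(truth.case_ids):
        raise ValueError("case_ids do not match ground-truth case_ids")
    pos = truth.labels == CANCER
    called_pos = calls == CANCER
    return ConfusionCounts(
        tp=int(np.sum(pos & called_pos)),
        fn=int(np.sum(pos & ~called_pos)),
        fp=int(np.sum(~pos & called_pos)),
        tn=int(np.sum(~pos & ~called_pos)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity, specificity, accuracy, PPV and NPV from the counts."""
    if counts.n == 0:
        raise ValueError("empty confusion counts")
    return DiagnosticMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        accuracy=_ratio(counts.tp + counts.tn, counts.n),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
    )


def majority_vote(table: RatingTable, tie_rule: str = BENIGN) -> np.ndarray:
    """Per-case label chosen by more than half the raters.

    With an even rater count a tie is resolved to ``tie_rule`` (default
    "benign", the conservative choice).
    """
    if tie_rule not in _LABELS:
        raise ValueError(f"tie_rule must be one of {_LABELS}")
    n_cancer = np.sum(table.calls == CANCER, axis=1)
    r = table.n_raters
    out = np.where(n_cancer * 2 > r, CANCER,
                   np.where(n_cancer * 2 < r, BENIGN, tie_rule))
    return out.astype(object)


def overall_agreement(table: RatingTable) -> float:
    """Free-marginal observed agreement P_o.

    ``P_o = (1 / (N R (R-1))) * sum_i sum_j n_ij (n_ij - 1)`` where
    ``n_ij`` is the number of raters assigning case ``i`` to category
    ``j`` — the fraction of agreeing rater pairs.  For three raters a
    unanimous case contributes 1 and a 2-1 split contributes 1/3.
    """
    if table.n_raters < 2:
        raise ValueError("agreement needs at least two raters")
    n, r = table.calls.shape
    total = 0.0
    for j in _LABELS:
        nij = np.sum(table.calls == j, axis=1).astype(float)
        total += float(np.sum(nij * (nij - 1)))
    return total / (n * r * (r - 1))


def free_marginal_kappa(table: RatingTable, k_categories: int = 2
                        ) -> AgreementResult:
    """Free-marginal multirater kappa: ``(P_o - 1/k) / (1 - 1/k)``."""
    if k_categories < 2:
        raise ValueError("need at least two categories")
    p_o = overall_agreement(table)
    kappa = (p_o - 1.0 / k_categories) / (1.0 - 1.0 / k_categories)
    return AgreementResult(p_overall=p_o, kappa_free=kappa,
                           k_categories=k_categories)


def kappa_bootstrap_ci(table: RatingTable, k_categories: int = 2,
                       n_boot: int = 10_000, seed: int = 0,
                       level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the free-marginal kappa, resampling cases."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if table.n_cases < 2:
        raise ValueError("bootstrap needs at least two cases")
    rng = np.random.default_rng(seed)
    n = table.n_cases
    kappas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = RatingTable(
            calls=table.calls[idx],
            case_ids=[table.case_ids[i] for i in idx],
            rater_ids=table.rater_ids,
        )
        kappas[b] = free_marginal_kappa(resampled, k_categories).kappa_free
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(kappas, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def fixture_table() -> tuple[RatingTable, GroundTruthLabels]:
    """The canonical 44-case x 3-rater rating table.

    Ten cases are truth-cancer.  Rating pattern per (rater1, rater2,
    rater3): cases 1-6 (C,C,C); 7-9 (C,B,C); 10 (B,B,B); 11-12 (C,B,C);
    13-19 (B,B,C); 20-44 (B,B,B).  This is the constraint-derived solution
    reproducing the published per-rater confusions (9,1,2,32), (6,4,0,34)
    and (9,1,9,25), the majority confusion (9,1,2,32), and 32 unanimous +
    12 split cases; any case permutation is statistically equivalent.
    """
    C, B = CANCER, BENIGN
    rows: list[tuple[str, str, str]] = []
    rows += [(C, C, C)] * 6       # cases 1-6
    rows += [(C, B, C)] * 3       # cases 7-9
    rows += [(B, B, B)]           # case 10
    rows += [(C, B, C)] * 2       # cases 11-12
    rows += [(B, B, C)] * 7       # cases 13-19
    rows += [(B, B, B)] * 25      # cases 20-44
    calls = np.array(rows, dtype=object)
    case_ids = [f"case{str(i + 1).zfill(2)}" for i in range(44)]
    truth = np.array([C] * 10 + [B] * 34, dtype=object)
    table = RatingTable(calls=calls, case_ids=case_ids,
                        rater_ids=["P1", "P2", "P3"])
    return table, GroundTruthLabels(labels=truth, case_ids=case_ids)


# ---------------------------------------------------------------------------
# report tables and CSV interchange


def table_one(table: RatingTable, truth: GroundTruthLabels,
              ndigits: int = 2) -> pd.DataFrame:
    """Per-rater + majority diagnostic metrics, rounded half-up."""
    columns: dict[str, dict] = {}
    for rid in table.rater_ids:
        m = diagnostic_metrics(confusion_counts(table.column(rid), truth))
        columns[rid] = m.rounded(ndigits)
    maj = diagnostic_metrics(confusion_counts(majority_vote(table), truth))
    columns["majority"] = maj.rounded(ndigits)
    order = ["accuracy", "sensitivity", "specificity", "ppv", "npv"]
    return pd.DataFrame(columns).loc[order]


def table_two(table: RatingTable, *, k_categories: int = 2,
              n_boot: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Agreement summary: percent overall agreement, kappa, bootstrap CI."""
    res = free_marginal_kappa(table, k_categories)
    lo, hi = kappa_bootstrap_ci(table, k_categories, n_boot=n_boot, seed=seed)
    return pd.DataFrame(
        {
            "value": [
                round_half_up(100.0 * res.p_overall, 2),
                round_half_up(res.kappa_free, 2),
                round_half_up(lo, 2),
                round_half_up(hi, 2),
            ]
        },
        index=["percent_overall_agreement", "free_marginal_kappa",
               "kappa_ci95_low", "kappa_ci95_high"],
    )


def read_rating_csv(path: str | Path) -> tuple[RatingTable, GroundTruthLabels]:
    """Read a rating CSV: columns ``case_id``, ``truth``, one per rater."""
    df = pd.read_csv(path, dtype=str)
    required = {"case_id", "truth"}
    if not required <= set(df.columns):
        raise ValueError(f"rating CSV must contain columns {sorted(required)}")
    rater_cols = [c for c in df.columns if c not in required]
    if not rater_cols:
        raise ValueError("rating CSV has no rater columns")
    case_ids = df["case_id"].tolist()
    table = RatingTable(
        calls=df[rater_cols].to_numpy(dtype=object),
        case_ids=case_ids,
        rater_ids=rater_cols,
    )
    truth = GroundTruthLabels(
        labels=df["truth"].to_numpy(dtype=object), case_ids=case_ids,
    )
    return table, truth


def write_rating_csv(table: RatingTable, truth: GroundTruthLabels,
                     path: str | Path) -> Path:
    df = pd.DataFrame({"case_id": table.case_ids, "truth": truth.labels})
    for i, rid in enumerate(table.rater_ids):
        df[rid] = table.calls[:, i]
    df.to_csv(path, index=False)
    return Path(path)
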