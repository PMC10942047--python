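"""Group-wise statistics, correlation analyses and inter-reader agreement.

Implements the evaluation side of the posterior-comparison study: assign
evaluated subjects to the six diagnosis groups, summarize the (scaled)
classifier outputs per group, correlate group means with the analytic
expected posteriors, measure between-CV-model output correlation, and
compute Cohen's κ for two-rater binary agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .posterior import DiagnosisGroup, GROUP_ORDER, expected_posterior
from .synthetic import AnnotationRecord

__all__ = [
    "GroupStatistics",
    "AgreementTable",
    "group_assignments",
    "group_statistics",
    "posterior_correlation",
    "cv_output_correlations",
    "cohens_kappa",
]


@dataclass(frozen=True)
class GroupStatistics:
    """Count, mean and sample SD of an output per diagnosis group."""

    finding: str
    counts: Dict[DiagnosisGroup, int]
    means: Dict[DiagnosisGroup, float]  # NaN for empty groups
    sds: Dict[DiagnosisGroup, float]

    def nonempty(self) -> List[DiagnosisGroup]:
        return [g for g in GROUP_ORDER if self.counts.get(g, 0) > 0]


@dataclass(frozen=True)
class AgreementTable:
    """2×2 contingency counts between two raters' binary calls."""

    both_pos: int
    pos_neg: int  # rater 1 positive, rater 2 negative
    neg_pos: int
    both_neg: int

    def __post_init__(self):
        if min(self.both_pos, self.pos_neg, self.neg_pos, self.both_neg) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.both_pos + self.pos_neg + self.neg_pos + self.both_neg

    @classmethod
    def from_calls(cls, rater1: Sequence[int], rater2: Sequence[int]) -> "AgreementTable":
        a = np.asarray(rater1).astype(int)
        b = np.asarray(rater2).astype(int)
        return cls(
            both_pos=int(np.sum((a == 1) & (b == 1))),
            pos_neg=int(np.sum((a == 1) & (b == 0))),
            neg_pos=int(np.sum((a == 0) & (b == 1))),
            both_neg=int(np.sum((a == 0) & (b == 0))),
        )


def group_assignments(annotations: Sequence[AnnotationRecord],
                      finding: str) -> Dict[DiagnosisGroup, List[str]]:
    """Partition subject ids into the six groups for one finding."""
    out: Dict[DiagnosisGroup, List[str]] = {g: [] for g in GROUP_ORDER}
    for rec in annotations:
        if finding not in rec.calls:
            raise ValueError(f"subject {rec.subject_id}: missing calls for {finding!r}")
        out[rec.group(finding)].append(rec.subject_id)
    return out


def group_statistics(outputs: Mapping[str, float],
                     groups: Mapping[DiagnosisGroup, Sequence[str]],
                     finding: str = "", ddof: int = 1) -> GroupStatistics:
    """Mean and sample SD (ddof=1) of the output per group; empty groups NaN."""
    counts, means, sds = {}, {}, {}
    for g in GROUP_ORDER:
        ids = list(groups.get(g, []))
        vals = np.array([outputs[s] for s in ids if s in outputs])
        counts[g] = len(vals)
        if len(vals) == 0:
            means[g], sds[g] = float("nan"), float("nan")
        else:
            means[g] = float(vals.mean())
            sds[g] = float(vals.std(ddof=ddof)) if len(vals) > ddof else 0.0
    return GroupStatistics(finding=finding, counts=counts, means=means, sds=sds)


def posterior_correlation(stats: GroupStatistics) -> float:
    """Pearson r between group means and the exact expected posteriors."""
    groups = stats.nonempty()
    if len(groups) < 3:
        raise ValueError("need at least 3 non-empty groups for a correlation")
    x = np.array([float(expected_posterior(g)) for g in groups])
    y = np.array([stats.means[g] for g in groups])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def cv_output_correlations(predictions: pd.DataFrame, finding: str,
                           subsets: Optional[Mapping[str, Sequence[str]]] = None
                           ) -> Dict[str, object]:
    """Pearson r of the outputs for every pair of CV models on shared subjects.

    Returns the list of per-pair correlations with mean ± SD, overall and —
    if ``subsets`` maps labels (e.g. second-stage outcomes) to subject ids —
    restricted to each subset.
    """
    sub = predictions[predictions["finding"] == finding]
    wide = sub.pivot(index="subject_id", columns="model_index", values="logit")
    models = list(wide.columns)
    if len(models) < 2:
        raise ValueError("need at least 2 CV models")

    def pairwise(frame: pd.DataFrame) -> Dict[str, object]:
        rs = []
        for a, b in combinations(models, 2):
            x, y = frame[a].to_numpy(), frame[b].to_numpy()
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                rs.append(float("nan"))
            else:
                rs.append(float(np.corrcoef(x, y)[0, 1]))
        arr = np.array(rs)
        ok = arr[~np.isnan(arr)]
        return {
            "pairs": rs,
            "n_pairs": len(rs),
            "mean": float(ok.mean()) if len(ok) else float("nan"),
            "sd": float(ok.std(ddof=1)) if len(ok) > 1 else float("nan"),
        }

    result: Dict[str, object] = {"overall": pairwise(wide)}
    if subsets:
        result["by_subset"] = {
            label: pairwise(wide.loc[[s for s in ids if s in wide.index]])
            for label, ids in subsets.items()
        }
    return result


def cohens_kappa(table: AgreementTable) -> float:
    """Chance-corrected two-rater agreement κ = (p_o - p_e) / (1 - p_e)."""
    n = table.n
    if n == 0:
        raise ValueError("empty agreement table")
    p_o = (table.both_pos + table.both_neg) / n
    p1 = (table.both_pos + table.pos_neg) / n  # rater 1 positive rate
    p2 = (table.both_pos + table.neg_pos) / n
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    if p_e == 1.0:
        raise ValueError("kappa undefined: degenerate marginals (p_e = 1)")
    return float((p_o - p_e) / (1 - p_e))
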