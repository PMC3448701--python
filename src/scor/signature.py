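"""Multi-gene risk scores, two-group stratification and survival contrasts.

A signature is a pair of gene lists with opposite prognostic directions.
Each patient's score is the sum of robustly normalized expression over
good-prognosis genes minus the sum over poor-prognosis genes, so high
scores mean predicted favorable outcome. Patients are split into high/low
score groups by 1-D k-means (k=2), and the split is evaluated with the
log-rank test, a Cox fit on the group indicator and Kaplan-Meier curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.cluster import KMeans

from .datamodel import ExpressionMatrix, SurvivalData
from .preprocess import normalize_center_scale

__all__ = [
    "Signature",
    "SignatureScore",
    "StratificationResult",
    "multi_gene_score",
    "kmeans_stratify",
    "evaluate_stratification",
    "stratification_agreement",
]


@dataclass
class Signature:
    """Good- and poor-prognosis gene lists (disjoint, jointly non-empty)."""

    good_genes: list[str]
    poor_genes: list[str]
    name: str = "signature"

    def __post_init__(self) -> None:
        self.good_genes = [str(g) for g in self.good_genes]
        self.poor_genes = [str(g) for g in self.poor_genes]
        overlap = set(self.good_genes) & set(self.poor_genes)
        if overlap:
            raise ValueError(f"genes in both lists: {sorted(overlap)[:5]}")
        if len(self.good_genes) + len(self.poor_genes) == 0:
            raise ValueError("signature must contain at least one gene")
        for lst in (self.good_genes, self.poor_genes):
            if len(set(lst)) != len(lst):
                raise ValueError("duplicate gene within a signature list")

    def swapped(self) -> "Signature":
        return Signature(list(self.poor_genes), list(self.good_genes), self.name)


def multi_gene_score(
    m: ExpressionMatrix,
    sig: Signature,
    mean: bool = False,
    missing: str = "error",
) -> pd.Series:
    """Per-patient multi-gene score: sum(good) - sum(poor) on normalized rows.

    Each signature gene's expression is median-centered and MAD-scaled
    across patients first, which makes the score invariant to per-gene
    positive affine transforms of the raw data.

    Parameters
    ----------
    mean : bool
        If True, use the average over each list instead of the plain sum
        (an "averaged sum" variant that is insensitive to unequal list
        sizes).
    missing : {"error", "skip"}
        Signature genes absent from the matrix either raise (default) or
        are dropped with a warning.
    """
    if missing not in ("error", "skip"):
        raise ValueError("missing must be 'error' or 'skip'")
    present = set(m.gene_ids)
    good = [g for g in sig.good_genes if g in present]
    poor = [g for g in sig.poor_genes if g in present]
    absent = (set(sig.good_genes) | set(sig.poor_genes)) - present
    if absent:
        if missing == "error":
            raise KeyError(f"signature genes missing from matrix: {sorted(absent)[:5]}")
        warnings.warn(f"skipping {len(absent)} signature genes absent from matrix")
    if not good and not poor:
        raise ValueError("no signature genes left after skipping missing ones")
    norm = normalize_center_scale(m, gene_subset=good + poor)
    frame = norm.to_frame()
    good_part = frame.loc[good].sum(axis=0) if good else 0.0
    poor_part = frame.loc[poor].sum(axis=0) if poor else 0.0
    if mean:
        good_part = good_part / len(good) if good else 0.0
        poor_part = poor_part / len(poor) if poor else 0.0
    score = good_part - poor_part
    if np.isscalar(score):  # only possible if both lists empty, guarded above
        raise ValueError("empty signature")
    score.name = "score"
    return score


@dataclass
class SignatureScore:
    """Scores with a two-group split; "high" is the larger-mean group."""

    sample_ids: list[str]
    score: np.ndarray
    group: np.ndarray  # "high" / "low" per sample
    group_means: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.score, "group": self.group}, index=self.sample_ids
        )


def kmeans_stratify(scores: pd.Series | np.ndarray, seed: int = 0) -> SignatureScore:
    """Split 1-D scores into high/low groups by k-means with k=2.

    Uses 10 seeded restarts; for one-dimensional data the best-of-restarts
    solution coincides with the optimal single-threshold split. Requires at
    least two distinct score values.
    """
    if isinstance(scores, pd.Series):
        sample_ids = [str(s) for s in scores.index]
        x = scores.to_numpy(float)
    else:
        x = np.asarray(scores, dtype=float)
        sample_ids = [f"sample{i}" for i in range(len(x))]
    if len(x) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if np.unique(x).size < 2:
        raise ValueError("all scores identical; cannot split into two groups")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(x[:, None])
    centers = km.cluster_centers_.ravel()
    high_label = int(np.argmax(centers))
    group = np.where(labels == high_label, "high", "low").astype(object)
    return SignatureScore(
        sample_ids=sample_ids,
        score=x,
        group=group,
        group_means={
            "high": float(centers[high_label]),
            "low": float(centers[1 - high_label]),
        },
    )


@dataclass
class StratificationResult:
    """Survival contrast between the high and low score groups.

    ``hazard_ratio`` is for high vs low; with scores oriented so high =
    favorable, a protective signature gives a hazard ratio below 1.
    ``km_curves`` maps group name to a DataFrame with the Kaplan-Meier
    estimate and Greenwood confidence band. ``reliable`` is False when a
    group had no events (the test statistics are then not meaningful).
    """

    logrank_statistic: float
    logrank_p: float
    cox_coefficient: float
    cox_p: float
    hazard_ratio: float
    km_curves: dict[str, pd.DataFrame]
    group_sizes: dict[str, int]
    group_events: dict[str, int]
    reliable: bool


def evaluate_stratification(
    groups: SignatureScore, surv: SurvivalData
) -> StratificationResult:
    """Compare survival between score groups.

    Raises if either group is empty; when a group has zero events the
    Kaplan-Meier curves are still returned but ``reliable`` is False.
    """
    sv = surv.subset(groups.sample_ids)
    is_high = np.asarray(groups.group) == "high"
    n_high, n_low = int(is_high.sum()), int((~is_high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both score groups must be non-empty")
    ev_high = int(sv.event[is_high].sum())
    ev_low = int(sv.event[~is_high].sum())
    reliable = ev_high > 0 and ev_low > 0

    km_curves = {}
    for name, mask in (("high", is_high), ("low", ~is_high)):
        kmf = KaplanMeierFitter()
        kmf.fit(sv.time[mask], sv.event[mask], label=name)
        curve = kmf.survival_function_.copy()
        curve.columns = ["survival"]
        ci = kmf.confidence_interval_
        curve["lower_ci"] = ci.iloc[:, 0].to_numpy()
        curve["upper_ci"] = ci.iloc[:, 1].to_numpy()
        km_curves[name] = curve

    lr = logrank_test(sv.time[is_high], sv.time[~is_high], sv.event[is_high], sv.event[~is_high])

    cox_df = pd.DataFrame(
        {"time": sv.time, "event": sv.event, "high": is_high.astype(float)}
    )
    cox_coef, cox_p = np.nan, np.nan
    if reliable:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(cox_df, duration_col="time", event_col="event")
        cox_coef = float(cph.params_["high"])
        cox_p = float(cph.summary.loc["high", "p"])
    return StratificationResult(
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        cox_coefficient=cox_coef,
        cox_p=cox_p,
        hazard_ratio=float(np.exp(cox_coef)),
        km_curves=km_curves,
        group_sizes={"high": n_high, "low": n_low},
        group_events={"high": ev_high, "low": ev_low},
        reliable=reliable,
    )


def stratification_agreement(labels_a, labels_b) -> float:
    """Fraction of samples assigned the same high/low label by two scores.

    Accepts :class:`SignatureScore` objects or label sequences; samples are
    matched positionally (align beforehand if orders differ).
    """
    a = labels_a.group if isinstance(labels_a, SignatureScore) else np.asarray(labels_a)
    b = labels_b.group if isinstance(labels_b, SignatureScore) else np.asarray(labels_b)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    return float(np.mean(np.asarray(a) == np.asarray(b)))
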