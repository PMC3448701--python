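"""The SCoR procedure: resampled univariate Cox screening with frequency
aggregation and per-round hold-out validation.

Each round draws a fixed-size random subsample of patients (default 75%,
without replacement within the round), fits a univariate Cox model per gene
on the subsample and marks genes whose Wald p falls below the screening
cutoff as positive for that round. Positive frequencies over all rounds are
the selection statistic: genes positive in at least ``frequency_cutoff`` of
rounds (default 75%) form the candidate prognostic list. Because the rounds
are independent subsamples, unstable single-split hits are diluted while
genes with a consistent association accumulate frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cox import InsufficientEventsError, fit_cox_batch
from .datamodel import ExpressionMatrix, SurvivalData

__all__ = [
    "ScorConfig",
    "ScorResult",
    "ValidationSummary",
    "run_scor",
    "internal_validation",
    "frequency_saturation_curve",
]

# a run aborts if more than this fraction of rounds cannot support a fit
_MAX_BAD_ROUND_FRACTION = 0.10


@dataclass
class ScorConfig:
    """Tuning parameters of a screening run.

    subset_fraction : fraction of patients drawn each round (0.75 keeps the
        remaining quarter as that round's hold-out set).
    rounds : number of resampling rounds; selection counts typically
        saturate by ~200 rounds, 400 is a conservative default.
    screen_p_cutoff : per-gene Wald p threshold within a round.
    frequency_cutoff : fraction of rounds a gene must be positive in to be
        selected (0.75 = positive three rounds out of four).
    validation_p_cutoff : p threshold for the hold-out refit; a validation
        pass additionally requires the hold-out coefficient to keep the
        screening round's sign.
    """

    subset_fraction: float = 0.75
    rounds: int = 400
    screen_p_cutoff: float = 0.01
    frequency_cutoff: float = 0.75
    validation_p_cutoff: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subset_fraction < 1:
            raise ValueError("subset_fraction must be in (0, 1)")
        for name in ("screen_p_cutoff", "validation_p_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.frequency_cutoff <= 1:
            raise ValueError("frequency_cutoff must be in (0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScorResult:
    """Per-gene selection frequencies plus the per-round detail needed for
    hold-out validation and saturation analysis."""

    gene_ids: list[str]
    positive_count: np.ndarray
    poor_count: np.ndarray
    good_count: np.ndarray
    rounds_run: int
    config: ScorConfig
    round_subsets: list[np.ndarray] = field(repr=False)
    round_positives: list[np.ndarray] = field(repr=False)
    round_signs: list[np.ndarray] = field(repr=False)
    validation_attempts: np.ndarray | None = None
    validation_passes: np.ndarray | None = None

    @property
    def frequency(self) -> np.ndarray:
        return self.positive_count / self.rounds_run

    @property
    def selected(self) -> np.ndarray:
        return self.selected_at(self.config.frequency_cutoff)

    def selected_at(self, frequency_cutoff: float) -> np.ndarray:
        return self.frequency >= frequency_cutoff

    @property
    def selected_genes(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.selected) if s]

    @property
    def majority_direction(self) -> np.ndarray:
        """Modal direction among each gene's positive rounds.

        "poor" / "good" when one sign dominates, "mixed" on an exact tie,
        "none" for genes never positive.
        """
        out = np.where(
            self.poor_count > self.good_count,
            "poor",
            np.where(self.good_count > self.poor_count, "good", "mixed"),
        ).astype(object)
        out[self.positive_count == 0] = "none"
        return out

    def directions(self) -> dict[str, str]:
        return dict(zip(self.gene_ids, self.majority_direction))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "positive_count": self.positive_count,
                "rounds_run": self.rounds_run,
                "frequency": self.frequency,
                "majority_direction": self.majority_direction,
                "selected": self.selected,
            }
        )
        if self.validation_attempts is not None:
            df["validation_attempts"] = self.validation_attempts
            df["validation_passes"] = self.validation_passes
            with np.errstate(invalid="ignore"):
                df["validation_pass_rate"] = np.where(
                    self.validation_attempts > 0,
                    self.validation_passes / np.maximum(self.validation_attempts, 1),
                    np.nan,
                )
        return df


def run_scor(
    m: ExpressionMatrix, surv: SurvivalData, cfg: ScorConfig | None = None
) -> ScorResult:
    """Run the resampled Cox screen.

    The expression matrix should already be variance-filtered
    (:func:`scor.preprocess.mad_filter`). Sample sets of matrix and survival
    must agree; survival rows are aligned to the matrix column order. The
    run is fully reproducible from ``cfg.rng_seed``.

    Raises
    ------
    InsufficientEventsError
        If more than 10% of rounds draw a subsample with fewer than two
        observed events (cohort too small or too heavily censored).
    """
    cfg = cfg or ScorConfig()
    surv = surv.aligned_to(m)
    n = m.n_samples
    n_sub = int(np.floor(cfg.subset_fraction * n))
    if n_sub < 2:
        raise ValueError("subset_fraction leaves fewer than 2 samples per round")
    rng = np.random.default_rng(cfg.rng_seed)
    G = m.n_genes
    positive_count = np.zeros(G, dtype=int)
    poor_count = np.zeros(G, dtype=int)
    good_count = np.zeros(G, dtype=int)
    round_subsets: list[np.ndarray] = []
    round_positives: list[np.ndarray] = []
    round_signs: list[np.ndarray] = []
    max_bad = _MAX_BAD_ROUND_FRACTION * cfg.rounds
    bad_rounds = 0
    for _r in range(cfg.rounds):
        subset = np.sort(rng.choice(n, size=n_sub, replace=False))
        round_subsets.append(subset)
        sub_surv = SurvivalData(
            [surv.sample_ids[i] for i in subset],
            surv.time[subset],
            surv.event[subset],
        )
        if sub_surv.n_events < 2:
            bad_rounds += 1
            if bad_rounds > max_bad:
                raise InsufficientEventsError(
                    f"{bad_rounds} of {_r + 1} rounds drew subsets with <2 "
                    "events; the cohort is too small or too heavily censored"
                )
            round_positives.append(np.empty(0, dtype=int))
            round_signs.append(np.empty(0, dtype=int))
            continue
        fit = fit_cox_batch(m.values[:, subset], sub_surv)
        pos = np.flatnonzero(fit["converged"] & (fit["p_value"] < cfg.screen_p_cutoff))
        signs = np.sign(fit["coefficient"][pos]).astype(int)
        positive_count[pos] += 1
        poor_count[pos[signs > 0]] += 1
        good_count[pos[signs <= 0]] += 1
        round_positives.append(pos)
        round_signs.append(signs)
    return ScorResult(
        gene_ids=list(m.gene_ids),
        positive_count=positive_count,
        poor_count=poor_count,
        good_count=good_count,
        rounds_run=cfg.rounds,
        config=cfg,
        round_subsets=round_subsets,
        round_positives=round_positives,
        round_signs=round_signs,
    )


@dataclass
class ValidationSummary:
    """Aggregate hold-out validation rates.

    ``overall_rate`` pools every (gene, round) screening hit;
    ``selected_rate`` pools only hits of genes that ended up selected. A
    selective screen should show ``selected_rate`` well above
    ``overall_rate``.
    """

    overall_attempts: int
    overall_passes: int
    selected_attempts: int
    selected_passes: int

    @property
    def overall_rate(self) -> float:
        return self.overall_passes / self.overall_attempts if self.overall_attempts else float("nan")

    @property
    def selected_rate(self) -> float:
        return self.selected_passes / self.selected_attempts if self.selected_attempts else float("nan")


def internal_validation(
    m: ExpressionMatrix, surv: SurvivalData, result: ScorResult
) -> ValidationSummary:
    """Refit each round's screening hits on that round's held-out patients.

    For every round, genes positive in the round are refit on the complement
    of the round's subsample; a gene passes the attempt iff the hold-out
    Wald p is below ``validation_p_cutoff`` and the hold-out coefficient has
    the same sign as in the screening round. Held-out sets with fewer than
    two events are skipped (the attempt is not counted). Per-gene
    attempt/pass counts are stored on ``result``.
    """
    cfg = result.config
    surv = surv.aligned_to(m)
    n = m.n_samples
    G = m.n_genes
    attempts = np.zeros(G, dtype=int)
    passes = np.zeros(G, dtype=int)
    all_idx = np.arange(n)
    for subset, pos, signs in zip(
        result.round_subsets, result.round_positives, result.round_signs
    ):
        if pos.size == 0:
            continue
        held = np.setdiff1d(all_idx, subset, assume_unique=True)
        held_surv = SurvivalData(
            [surv.sample_ids[i] for i in held], surv.time[held], surv.event[held]
        )
        if held_surv.n_events < 2:
            continue
        fit = fit_cox_batch(m.values[np.ix_(pos, held)], held_surv)
        ok = (
            fit["converged"]
            & (fit["p_value"] < cfg.validation_p_cutoff)
            & (np.sign(fit["coefficient"]).astype(int) == signs)
        )
        attempts[pos] += 1
        passes[pos[ok]] += 1
    result.validation_attempts = attempts
    result.validation_passes = passes
    sel = result.selected
    return ValidationSummary(
        overall_attempts=int(attempts.sum()),
        overall_passes=int(passes.sum()),
        selected_attempts=int(attempts[sel].sum()),
        selected_passes=int(passes[sel].sum()),
    )


def frequency_saturation_curve(
    m: ExpressionMatrix,
    surv: SurvivalData,
    cfg: ScorConfig,
    checkpoints,
) -> pd.DataFrame:
    """Selected-gene counts as a function of the number of rounds.

    Runs a single screen of ``max(checkpoints)`` rounds and evaluates the
    cumulative selection frequency at each checkpoint, so the curve reflects
    one nested sequence of rounds rather than independent reruns.
    """
    checkpoints = list(checkpoints)
    if checkpoints != sorted(checkpoints) or len(set(checkpoints)) != len(checkpoints):
        raise ValueError("checkpoints must be strictly increasing")
    if checkpoints and checkpoints[0] < 1:
        raise ValueError("checkpoints must be >= 1")
    full_cfg = ScorConfig(**{**cfg.to_dict(), "rounds": max(checkpoints)})
    result = run_scor(m, surv, full_cfg)
    G = m.n_genes
    cum = np.zeros(G, dtype=int)
    counts = []
    next_i = 0
    for r, pos in enumerate(result.round_positives, start=1):
        cum[pos] += 1
        while next_i < len(checkpoints) and checkpoints[next_i] == r:
            counts.append(int(((cum / r) >= cfg.frequency_cutoff).sum()))
            next_i += 1
    return pd.DataFrame({"rounds": checkpoints, "selected_genes": counts})
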