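"""Indicator-based immunomodulatory scoring and the two-stage screen.

The hard score awards +10 for every IFN panel gene with strictly positive
delta and +10 for every inflammatory panel gene with strictly negative
delta (range 0-100 in steps of 10; delta exactly 0 never scores). The soft
score is its differentiable logistic relaxation used inside the training
loss. Screening is source-agnostic: deltas may come from the model or from
measured profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, SchemaError
from .nn import sigmoid
from .panel import DEFAULT_PANEL, GenePanel


@dataclass(frozen=True)
class ScoreBreakdown:
    ifn_up_count: int
    inflame_down_count: int

    @property
    def total_score(self) -> int:
        return 10 * (self.ifn_up_count + self.inflame_down_count)


@dataclass
class ScreenResult:
    compound_id: str
    breakdown: ScoreBreakdown
    passes_primary: bool = False
    passes_secondary: bool = False
    rank: int | None = None


@dataclass(frozen=True)
class PrimaryCriteria:
    score_threshold: float = 70.0
    sd_multiplier: float = 3.5
    background: str = "library"  # "library" | "permutation_null"

    def __post_init__(self) -> None:
        if not 0 <= self.score_threshold <= 100:
            raise ConfigurationError("score_threshold must lie in [0, 100]")
        if self.sd_multiplier < 0:
            raise ConfigurationError("sd_multiplier must be >= 0")
        if self.background not in ("library", "permutation_null"):
            raise ConfigurationError(f"unknown background {self.background!r}")


def _check_delta(delta: np.ndarray) -> np.ndarray:
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (10,):
        raise SchemaError(f"delta must be a 10-vector, got shape {delta.shape}")
    return delta


def hard_score(delta: np.ndarray, panel: GenePanel = DEFAULT_PANEL) -> ScoreBreakdown:
    """Indicator score: strict inequalities, +10 per satisfied panel gene."""
    delta = _check_delta(delta)
    ifn_up = int(np.sum(delta[:5] > 0))
    inflame_down = int(np.sum(delta[5:] < 0))
    return ScoreBreakdown(ifn_up_count=ifn_up, inflame_down_count=inflame_down)


def soft_score(
    delta: np.ndarray, panel: GenePanel = DEFAULT_PANEL, temperature: float = 10.0
) -> float:
    """Smooth surrogate: 10 * sum of logistic-relaxed indicators, in [0, 100].

    Converges to the hard score as temperature -> infinity on zero-free delta.
    """
    if temperature <= 0:
        raise ConfigurationError("temperature must be > 0")
    delta = _check_delta(delta)
    return float(10.0 * sigmoid(temperature * panel.directions * delta).sum())


def soft_score_batch(
    delta: np.ndarray, panel: GenePanel = DEFAULT_PANEL, temperature: float = 10.0
) -> np.ndarray:
    """Vectorized soft score over an (n, 10) delta matrix."""
    if temperature <= 0:
        raise ConfigurationError("temperature must be > 0")
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 2 or delta.shape[1] != 10:
        raise SchemaError(f"delta matrix must be (n, 10), got {delta.shape}")
    return 10.0 * sigmoid(temperature * panel.directions * delta).sum(axis=1)


def primary_screen(
    results: list[ScoreBreakdown],
    criteria: PrimaryCriteria = PrimaryCriteria(),
    background_scores: np.ndarray | None = None,
) -> list[bool]:
    """Pass iff score >= threshold AND score > mean + sd_multiplier * sd of
    the background distribution (population SD, strict >).

    Default background is the empirical score distribution of the screened
    library itself; an explicit background (e.g. a permutation null) can be
    supplied. With sd_multiplier=0 and a degenerate background the rule
    reduces to the plain threshold.
    """
    if not results:
        raise EmptyInputError("primary_screen needs at least one score")
    scores = np.array([r.total_score for r in results], dtype=float)
    if background_scores is None:
        background_scores = scores
    bg_mean = float(np.mean(background_scores))
    bg_sd = float(np.std(background_scores))  # population (n-denominator) SD
    cutoff = bg_mean + criteria.sd_multiplier * bg_sd
    return [(s >= criteria.score_threshold) and (s > cutoff) for s in scores]


def permutation_null_scores(
    delta_matrix: np.ndarray, seed: int, panel: GenePanel = DEFAULT_PANEL
) -> np.ndarray:
    """Background scores from a seeded within-gene permutation of the deltas."""
    delta_matrix = np.asarray(delta_matrix, dtype=float)
    rng = np.random.default_rng(seed)
    permuted = np.column_stack(
        [rng.permutation(delta_matrix[:, g]) for g in range(delta_matrix.shape[1])]
    )
    return np.array(
        [hard_score(row, panel).total_score for row in permuted], dtype=float
    )


def secondary_screen(
    delta_profiles: np.ndarray, min_per_class: int = 3, panel: GenePanel = DEFAULT_PANEL
) -> list[bool]:
    """Pass iff >= min_per_class IFN genes up AND >= min_per_class inflammatory
    genes down (consistency requirement on both arms)."""
    delta_profiles = np.atleast_2d(np.asarray(delta_profiles, dtype=float))
    if delta_profiles.shape[1] != 10:
        raise SchemaError(f"delta profiles must be (n, 10), got {delta_profiles.shape}")
    flags = []
    for row in delta_profiles:
        b = hard_score(row, panel)
        flags.append(b.ifn_up_count >= min_per_class and b.inflame_down_count >= min_per_class)
    return flags


def rank_candidates(results: list[ScreenResult]) -> list[ScreenResult]:
    """Dense-rank the dual-pass compounds by descending score, ties broken by
    ascending compound_id. Non-passing compounds keep rank None."""
    passing = [r for r in results if r.passes_primary and r.passes_secondary]
    passing.sort(key=lambda r: (-r.breakdown.total_score, r.compound_id))
    for r in results:
        r.rank = None
    for i, r in enumerate(passing):
        r.rank = i + 1
    return passing


def screen_library(
    compound_ids: list[str],
    delta_matrix: np.ndarray,
    criteria: PrimaryCriteria = PrimaryCriteria(),
    min_per_class: int = 3,
    panel: GenePanel = DEFAULT_PANEL,
    null_seed: int = 0,
) -> tuple[list[ScreenResult], dict]:
    """Full screen: score, primary + secondary criteria, ranking.

    Returns all per-compound results plus a summary dict (background mean/SD
    under both background definitions, thresholds, pass counts).
    """
    delta_matrix = np.atleast_2d(np.asarray(delta_matrix, dtype=float))
    if len(compound_ids) != delta_matrix.shape[0]:
        raise SchemaError("compound_ids and delta matrix row count differ")
    breakdowns = [hard_score(row, panel) for row in delta_matrix]
    if criteria.background == "permutation_null":
        background = permutation_null_scores(delta_matrix, null_seed, panel)
    else:
        background = np.array([b.total_score for b in breakdowns], dtype=float)
    primary = primary_screen(breakdowns, criteria, background_scores=background)
    secondary = secondary_screen(delta_matrix, min_per_class, panel)
    results = [
        ScreenResult(cid, b, passes_primary=p, passes_secondary=s)
        for cid, b, p, s in zip(compound_ids, breakdowns, primary, secondary)
    ]
    ranked = rank_candidates(results)
    summary = {
        "background": criteria.background,
        "background_mean": float(np.mean(background)),
        "background_sd": float(np.std(background)),
        "score_threshold": criteria.score_threshold,
        "sd_multiplier": criteria.sd_multiplier,
        "min_per_class": min_per_class,
        "n_compounds": len(results),
        "n_primary_pass": int(sum(primary)),
        "n_secondary_pass": int(sum(secondary)),
        "n_ranked": len(ranked),
    }
    return results, summary


def results_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tidy screen report: one row per compound."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in results],
            "ifn_up_count": [r.breakdown.ifn_up_count for r in results],
            "inflame_down_count": [r.breakdown.inflame_down_count for r in results],
            "score": [r.breakdown.total_score for r in results],
            "passes_primary": [r.passes_primary for r in results],
            "passes_secondary": [r.passes_secondary for r in results],
            "rank": [r.rank for r in results],
        }
    )
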