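"""Synthetic paired-rater data with known agreement structure.

The generator emulates the design of the validation study — two raters
over the same cases, a shared 5-category ordinal scale, a configurable
rate of missing ratings for the second rater and a one-sided systematic
severity offset — while keeping the population agreement analytically
known, so parameter recovery can be tested without any real data.

Agreement mechanism (mixture model): with probability ``theta`` both
raters report one common category drawn from the marginal ``pi``;
otherwise each rater draws independently from ``pi``. Under this mixture

    Po = theta + (1 - theta) * sum(pi^2),   Pe = sum(pi^2),

so the population unweighted Cohen's kappa equals ``theta`` exactly —
the generator's agreement dial is the statistic it should recover.

Draw order per case (fixed, so outputs are stable across releases):
agreement coin, common category, rater A category, rater B category,
missing coin, offset coin. All draws come from one ``numpy`` Generator
seeded by ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import AnswerSet, DecisionModelConfig
from .scales import DM_SCALE, RatingRecord, RatingScale


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PairSimConfig:
    """Parameters of the paired-rater generator.

    ``missing_rate`` replaces rater B's category with the scale's missing
    label (requires a scale with one); ``offset_prob`` shifts rater B down
    one category (severity understatement), floored at the lowest
    category — mimicking a one-sided systematic difference.
    """

    n: int = 200
    pi: tuple[float, ...] = (0.105, 0.06, 0.27, 0.465, 0.10)  # study DM marginal
    theta: float = 0.5
    missing_rate: float = 0.0
    offset_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if self.n < 0:
            raise SimulationError("n must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise SimulationError(f"pi must sum to 1 (got {pi.sum():.12f})")
        if (pi < 0).any() or (pi > 1).any():
            raise SimulationError("pi entries must lie in [0, 1]")
        for name in ("theta", "missing_rate", "offset_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1] (got {v})")


def simulate_pair(
    config: PairSimConfig,
    scale_a: RatingScale = DM_SCALE,
    scale_b: RatingScale = DM_SCALE,
    rater_a: str = "rater_A",
    rater_b: str = "rater_B",
) -> tuple[list[RatingRecord], list[RatingRecord]]:
    """Draw paired ratings for ``config.n`` synthetic cases.

    Returns (rater A records, rater B records) with matching synthetic
    case ids and drug labels; the raters get distinct names even when
    they share a scale. Fully reproducible from ``config.seed``.
    """
    k = len(scale_a)
    if len(scale_b) != k or len(config.pi) != k:
        raise SimulationError("pi and both scales must have matching arity")
    if config.missing_rate > 0 and scale_b.missing_label is None:
        raise SimulationError(
            f"scale {scale_b.name!r} has no missing label; cannot apply missing_rate"
        )
    rng = np.random.default_rng(config.seed)
    pi = np.asarray(config.pi, dtype=float)
    missing_code = (
        scale_b.categories.index(scale_b.missing_label) + 1
        if scale_b.missing_label else None
    )

    recs_a: list[RatingRecord] = []
    recs_b: list[RatingRecord] = []
    for i in range(config.n):
        agree = rng.random() < config.theta
        common = int(rng.choice(k, p=pi)) + 1
        code_a = int(rng.choice(k, p=pi)) + 1
        code_b = int(rng.choice(k, p=pi)) + 1
        if agree:
            code_a = code_b = common
        goes_missing = rng.random() < config.missing_rate
        gets_offset = rng.random() < config.offset_prob  # coin always drawn
        if goes_missing:
            code_b = missing_code
        elif gets_offset:
            code_b = max(code_b - 1, 1)
        cid = f"sim_{i:05d}"
        drug_a, drug_b = f"drug_{i:05d}x", f"drug_{i:05d}y"
        recs_a.append(
            RatingRecord(cid, drug_a, drug_b, rater_a, scale_a.decode(code_a))
        )
        recs_b.append(
            RatingRecord(cid, drug_a, drug_b, rater_b, scale_b.decode(code_b))
        )
    return recs_a, recs_b


def simulate_answersets(
    config: DecisionModelConfig, n: int, seed: int = 0
) -> list[AnswerSet]:
    """Uniform random complete yes/no assignments to every model question.

    Used to fuzz the decision engine: every assignment must resolve to
    exactly one enumerated path regardless of which answers end up unused.
    """
    rng = np.random.default_rng(seed)
    questions = config.questions
    out: list[AnswerSet] = []
    for i in range(n):
        answers = {q: bool(rng.integers(0, 2)) for q in questions}
        out.append(
            AnswerSet(
                case_id=f"fuzz_{i:05d}",
                drug_pair=(f"drug_{i:05d}x", f"drug_{i:05d}y"),
                answers=answers,
            )
        )
    return out
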