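"""Mixed-gamble task design: offers, factorial design tables, summaries.

The task presents a choice between a safe option worth zero and a risky
50/50 gamble defined by a gain amount and a loss amount.  Loss amounts are
derived from the gain by a multiplier, so the full design is the factorial
product of gain levels x multipliers x repetitions.  All money is in euro
cents; losses are stored as negative amounts at exact (possibly fractional
cent) precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GambleOffer",
    "DEFAULT_GAINS",
    "DEFAULT_MULTIPLIERS",
    "default_multipliers",
    "generate_design",
    "expected_value",
    "design_summary",
    "read_design",
    "write_design",
]

DEFAULT_GAINS: tuple[float, ...] = (25.0, 40.0, 55.0, 75.0, 100.0)


def default_multipliers() -> np.ndarray:
    """Default set of 20 loss multipliers in [0.5, 5].

    The multiplier set is chosen so the factorial design over the five
    default gains with two repetitions yields 150 positive-, 40 negative-
    and 10 zero-expected-value trials: 15 values log-spaced in [0.5, 1),
    the value 1.0, and 4 values evenly spaced in (1, 5].
    """
    below = np.exp(np.linspace(np.log(0.5), np.log(1.0), 16))[:15]
    above = np.linspace(1.0, 5.0, 5)[1:]
    return np.concatenate([below, [1.0], above])


DEFAULT_MULTIPLIERS: tuple[float, ...] = tuple(default_multipliers())


@dataclass(frozen=True)
class GambleOffer:
    """A 50/50 gamble: win `gain` or lose `loss` (negative), in euro cents."""

    gain: float
    loss: float
    multiplier: float

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if not (0.5 <= self.multiplier <= 5.0):
            raise ValueError(f"multiplier {self.multiplier} outside [0.5, 5]")
        if not np.isclose(self.loss, -self.gain * self.multiplier, rtol=0, atol=1e-9):
            raise ValueError("loss must equal -(gain * multiplier)")

    @classmethod
    def from_gain_multiplier(cls, gain: float, multiplier: float) -> "GambleOffer":
        return cls(gain=gain, loss=-gain * multiplier, multiplier=multiplier)

    @property
    def ev(self) -> float:
        return expected_value(self)


def expected_value(offer) -> float:
    """Expected value of a fair-coin gamble: mean of its two outcomes."""
    return 0.5 * offer.gain + 0.5 * offer.loss


DESIGN_COLUMNS = [
    "trial",
    "gain_cents",
    "loss_cents",
    "multiplier",
    "ev_cents",
    "gamble_side",
    "repetition",
]


def generate_design(
    gains=DEFAULT_GAINS,
    multipliers=None,
    repetitions: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a randomized factorial design table.

    Parameters
    ----------
    gains
        Positive gain amounts (euro cents).
    multipliers
        Loss multipliers, each in [0.5, 5].  Defaults to
        :func:`default_multipliers`.
    repetitions
        Number of presentations of each unique offer.
    seed
        Seed for trial-order randomization and side counterbalancing.

    Returns
    -------
    pandas.DataFrame
        One row per trial with columns ``trial, gain_cents, loss_cents,
        multiplier, ev_cents, gamble_side, repetition``.  The gamble side
        is counterbalanced exactly 50/50 (left side gets the extra trial
        when the count is odd).
    """
    if multipliers is None:
        multipliers = default_multipliers()
    gains = np.asarray(gains, dtype=float)
    multipliers = np.asarray(multipliers, dtype=float)
    if gains.size == 0 or multipliers.size == 0:
        raise ValueError("gains and multipliers must be nonempty")
    if np.any(gains <= 0):
        raise ValueError("all gains must be positive")
    if np.any((multipliers < 0.5) | (multipliers > 5.0)):
        raise ValueError("all multipliers must lie in [0.5, 5]")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")

    rows = []
    for rep in range(1, repetitions + 1):
        for g in gains:
            for m in multipliers:
                rows.append((g, -g * m, m, 0.5 * g + 0.5 * (-g * m), rep))
    table = pd.DataFrame(
        rows, columns=["gain_cents", "loss_cents", "multiplier", "ev_cents", "repetition"]
    )

    rng = np.random.default_rng(seed)
    n = len(table)
    order = rng.permutation(n)
    table = table.iloc[order].reset_index(drop=True)
    # exact 50/50 side counterbalancing, randomly paired with offers
    sides = np.array(["left"] * (n - n // 2) + ["right"] * (n // 2))
    table["gamble_side"] = rng.permutation(sides)
    table.insert(0, "trial", np.arange(n))
    return table[DESIGN_COLUMNS]


def design_summary(design: pd.DataFrame) -> dict:
    """Counts of positive/negative/zero-EV trials and distinct design levels."""
    ev = design["ev_cents"].to_numpy()
    summary = {
        "n_trials": len(design),
        "positive": int(np.sum(ev > 0)),
        "negative": int(np.sum(ev < 0)),
        "zero": int(np.sum(ev == 0)),
        "n_gain_levels": int(design["gain_cents"].nunique()),
        "n_multiplier_levels": int(design["multiplier"].nunique()),
    }
    assert summary["positive"] + summary["negative"] + summary["zero"] == summary["n_trials"]
    return summary


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path)
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return design[DESIGN_COLUMNS]
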