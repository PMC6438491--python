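"""Seeded synthetic data for the latent class model, in two regimes.

Generates i.i.d. subject-level draws (D ~ Bernoulli(prevalence),
F | D=j ~ Bernoulli(phi_j), L | D=j ~ Bernoulli(lambda_j)) for an
observational ("pre") regime and a post-intervention ("post") regime that
shares the conditional chances but has its own latent prevalence, and reduces
subject tables to cell relative frequencies.

Datasets are plain pandas DataFrames with columns
``subject_id, regime, F, L`` (plus ``D`` only when explicitly requested,
since the latent class is not observable in a real study).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import CELL_ORDER, InterventionRegime, LCAParameters

__all__ = [
    "REGIMES",
    "ObservedFrequencies",
    "sample_dataset",
    "compute_frequencies",
    "simulate_intervention_study",
]

REGIMES = ("pre", "post")

DATASET_COLUMNS = ("subject_id", "regime", "F", "L")


@dataclass(frozen=True)
class ObservedFrequencies:
    """Observed cell relative frequencies r_jk for one regime.

    r_jk is the fraction of the t subjects in the regime with (F=j, L=k).
    """

    r00: float
    r01: float
    r10: float
    r11: float
    t: int
    regime: str

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if int(self.t) != self.t or self.t < 1:
            raise ValueError(f"t must be a positive integer, got {self.t!r}")
        object.__setattr__(self, "t", int(self.t))
        total = 0.0
        for name in ("r00", "r01", "r10", "r11"):
            v = float(getattr(self, name))
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
            object.__setattr__(self, name, v)
            total += v
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"relative frequencies must sum to 1, got {total!r}")
        for name in ("r00", "r01", "r10", "r11"):
            prod = getattr(self, name) * self.t
            if abs(prod - round(prod)) > 1e-9:
                raise ValueError(
                    f"{name} * t = {prod!r} is not an integer count; "
                    "frequencies must come from whole-subject counts"
                )

    def as_array(self) -> np.ndarray:
        """Frequencies in the fixed cell order (00, 01, 10, 11)."""
        return np.array([self.r00, self.r01, self.r10, self.r11])

    def counts(self) -> np.ndarray:
        """Integer cell counts n_jk = r_jk * t, in the fixed cell order."""
        return np.rint(self.as_array() * self.t).astype(int)

    @classmethod
    def from_counts(cls, counts, regime: str) -> "ObservedFrequencies":
        n = np.asarray(counts, dtype=float)
        if n.shape != (4,):
            raise ValueError(f"need 4 cell counts in order {CELL_ORDER}")
        t = int(n.sum())
        if t < 1:
            raise ValueError("counts must have a positive total")
        r = n / t
        return cls(r00=r[0], r01=r[1], r10=r[2], r11=r[3], t=t, regime=regime)

    def to_dict(self) -> dict:
        return {
            "r00": self.r00,
            "r01": self.r01,
            "r10": self.r10,
            "r11": self.r11,
            "t": self.t,
            "regime": self.regime,
        }


def _sample_rows(
    params: LCAParameters,
    prevalence: float,
    n_subjects: int,
    rng: np.random.Generator,
    regime: str,
    keep_latent: bool,
    id_offset: int,
) -> pd.DataFrame:
    d = (rng.random(n_subjects) < prevalence).astype(np.int64)
    phi = np.where(d == 1, params.phi1, params.phi0)
    lam = np.where(d == 1, params.lambda1, params.lambda0)
    f = (rng.random(n_subjects) < phi).astype(np.int64)
    l = (rng.random(n_subjects) < lam).astype(np.int64)
    frame = pd.DataFrame(
        {
            "subject_id": np.arange(id_offset, id_offset + n_subjects),
            "regime": regime,
            "F": f,
            "L": l,
        }
    )
    if keep_latent:
        frame["D"] = d
    return frame


def sample_dataset(
    params: LCAParameters,
    prevalence: float,
    n_subjects: int,
    seed: int,
    *,
    regime: str = "pre",
    keep_latent: bool = False,
) -> pd.DataFrame:
    """Draw ``n_subjects`` i.i.d. subjects at the given latent prevalence.

    The latent column D is written only when ``keep_latent`` is set; real
    studies never observe it.  Identical inputs and seed reproduce the
    identical table bit-for-bit.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects!r}")
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}, got {regime!r}")
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError(f"prevalence must lie in [0, 1], got {prevalence!r}")
    rng = np.random.default_rng(seed)
    return _sample_rows(params, prevalence, n_subjects, rng, regime, keep_latent, 0)


def compute_frequencies(dataset: pd.DataFrame, regime: str) -> ObservedFrequencies:
    """Reduce the rows of one regime to cell relative frequencies."""
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}, got {regime!r}")
    rows = dataset[dataset["regime"] == regime]
    t = len(rows)
    if t == 0:
        raise ValueError(f"dataset contains no rows with regime {regime!r}")
    f = rows["F"].to_numpy()
    l = rows["L"].to_numpy()
    counts = np.array(
        [
            int(np.sum((f == 0) & (l == 0))),
            int(np.sum((f == 0) & (l == 1))),
            int(np.sum((f == 1) & (l == 0))),
            int(np.sum((f == 1) & (l == 1))),
        ]
    )
    return ObservedFrequencies.from_counts(counts, regime)


def simulate_intervention_study(
    params: LCAParameters,
    regime: InterventionRegime,
    n_pre: int,
    n_post: int,
    seed: int,
    *,
    keep_latent: bool = False,
) -> pd.DataFrame:
    """Simulate a two-regime study sharing conditionals across regimes.

    Pre-regime subjects are drawn at prevalence delta, post-regime subjects
    at the post-intervention prevalence delta'; the conditional chances
    (phi_0, phi_1, lambda_0, lambda_1) are identical in both regimes
    (modularity of the stochastic intervention).  The two regimes are
    independent i.i.d. samples drawn from deterministic substreams of the
    master seed, so each regime is reproducible on its own.
    """
    if n_pre < 1 or n_post < 1:
        raise ValueError("n_pre and n_post must be >= 1")
    ss_pre, ss_post = np.random.SeedSequence(seed).spawn(2)
    pre = _sample_rows(
        params,
        params.delta,
        n_pre,
        np.random.default_rng(ss_pre),
        "pre",
        keep_latent,
        0,
    )
    post = _sample_rows(
        params,
        regime.delta_prime,
        n_post,
        np.random.default_rng(ss_post),
        "post",
        keep_latent,
        n_pre,
    )
    return pd.concat([pre, post], ignore_index=True)
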