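"""Core latent class model: parameters and forward equations.

A binary latent class (two-class, two-item) model: a hidden binary variable D
("depression") renders two manifest binary variables F ("fear") and L
("loathing") conditionally independent.  The model is characterised by five
chances,

    delta    = P(D = 1)
    phi_j    = P(F = 1 | D = j),   j = 0, 1
    lambda_j = P(L = 1 | D = j),   j = 0, 1

so the observable cell probabilities over (F, L) form a two-component mixture
of products of Bernoullis.  A stochastic intervention on D replaces delta with
a new prevalence delta' while leaving the conditional chances untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LCAParameters",
    "InterventionRegime",
    "CellDistribution",
    "HypothesisLabel",
    "CELL_ORDER",
    "cell_probabilities",
    "joint_distribution",
    "log_likelihood",
]

#: Fixed cell order used in every table and serialization: (F, L) pairs.
CELL_ORDER = ("00", "01", "10", "11")

_CELL_SUM_TOL = 1e-12


def _check_probability(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class LCAParameters:
    """The five observational-regime chances of the latent class model."""

    delta: float
    phi0: float
    phi1: float
    lambda0: float
    lambda1: float

    def __post_init__(self) -> None:
        for name in ("delta", "phi0", "phi1", "lambda0", "lambda1"):
            object.__setattr__(self, name, _check_probability(getattr(self, name), name))

    def label_swap(self) -> "LCAParameters":
        """Relabel the latent classes D=0 <-> D=1.

        Maps (delta, phi0, phi1, lambda0, lambda1) to
        (1-delta, phi1, phi0, lambda1, lambda0); an involution that leaves
        every observable cell probability unchanged.
        """
        return LCAParameters(
            delta=1.0 - self.delta,
            phi0=self.phi1,
            phi1=self.phi0,
            lambda0=self.lambda1,
            lambda1=self.lambda0,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.delta, self.phi0, self.phi1, self.lambda0, self.lambda1])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "LCAParameters":
        d, p0, p1, l0, l1 = (float(v) for v in x)
        return cls(d, p0, p1, l0, l1)

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "phi0": self.phi0,
            "phi1": self.phi1,
            "lambda0": self.lambda0,
            "lambda1": self.lambda1,
        }

    @classmethod
    def from_dict(cls, record: Mapping[str, float]) -> "LCAParameters":
        return cls(
            delta=record["delta"],
            phi0=record["phi0"],
            phi1=record["phi1"],
            lambda0=record["lambda0"],
            lambda1=record["lambda1"],
        )


_DIRECTIONS = ("reduced", "increased", "unconstrained")


@dataclass(frozen=True)
class InterventionRegime:
    """Post-intervention latent prevalence and qualitative knowledge about it.

    ``direction`` encodes what is assumed about the intervention: ``reduced``
    means the treatment lowers the latent prevalence (delta' < delta),
    ``increased`` the opposite, ``unconstrained`` no assumption.
    """

    delta_prime: float
    direction: str = "unconstrained"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "delta_prime", _check_probability(self.delta_prime, "delta_prime")
        )
        if self.direction not in _DIRECTIONS:
            raise ValueError(
                f"direction must be one of {_DIRECTIONS}, got {self.direction!r}"
            )

    def consistent_with(self, delta: float) -> bool:
        """Check the qualitative constraint against a known pre-regime delta."""
        if self.direction == "reduced":
            return self.delta_prime < delta
        if self.direction == "increased":
            return self.delta_prime > delta
        return True


@dataclass(frozen=True)
class CellDistribution:
    """Joint cell probabilities theta_jk = P(F=j, L=k) over the two items."""

    theta00: float
    theta01: float
    theta10: float
    theta11: float

    def __post_init__(self) -> None:
        for name in ("theta00", "theta01", "theta10", "theta11"):
            v = float(getattr(self, name))
            if v < -_CELL_SUM_TOL or math.isnan(v):
                raise ValueError(f"{name} must be non-negative, got {v!r}")
            object.__setattr__(self, name, max(v, 0.0))
        total = self.theta00 + self.theta01 + self.theta10 + self.theta11
        if abs(total - 1.0) > _CELL_SUM_TOL:
            raise ValueError(f"cell probabilities must sum to 1, got {total!r}")

    def as_array(self) -> np.ndarray:
        """Cells in the fixed serialization order (00, 01, 10, 11)."""
        return np.array([self.theta00, self.theta01, self.theta10, self.theta11])

    @classmethod
    def from_array(cls, cells: Sequence[float]) -> "CellDistribution":
        c00, c01, c10, c11 = (float(v) for v in cells)
        return cls(c00, c01, c10, c11)

    def to_dict(self) -> dict:
        return {
            "theta00": self.theta00,
            "theta01": self.theta01,
            "theta10": self.theta10,
            "theta11": self.theta11,
        }


@dataclass(frozen=True)
class HypothesisLabel:
    """A labelled statistical hypothesis.

    ``H_theta`` hypotheses are indexed by the chance tuple theta; ``G_xi``
    hypotheses are the doubly-labelled reparameterization of a Bernoulli
    model in which the success chance is xi**2 with xi in [-1, 1], so G_xi
    and G_{-xi} have identical likelihoods.
    """

    kind: str
    value: object

    def __post_init__(self) -> None:
        if self.kind not in ("H_theta", "G_xi"):
            raise ValueError(f"kind must be 'H_theta' or 'G_xi', got {self.kind!r}")
        if self.kind == "G_xi":
            v = float(self.value)  # type: ignore[arg-type]
            if not (-1.0 <= v <= 1.0):
                raise ValueError(f"G_xi value must lie in [-1, 1], got {v!r}")
            object.__setattr__(self, "value", v)


# ---------------------------------------------------------------------------
# Forward equations
# ---------------------------------------------------------------------------


def cell_probabilities(params: LCAParameters, prevalence: float) -> CellDistribution:
    """Map model parameters and a latent prevalence to cell probabilities.

    theta_jk = prevalence * phi1^j (1-phi1)^(1-j) * lambda1^k (1-lambda1)^(1-k)
             + (1-prevalence) * phi0^j (1-phi0)^(1-j) * lambda0^k (1-lambda0)^(1-k)

    With ``prevalence = params.delta`` this gives the observational cells;
    with the post-intervention prevalence delta' it gives the post cells,
    since the conditional chances are invariant under the intervention.
    """
    d = _check_probability(prevalence, "prevalence")
    p = params
    cells = {}
    for j in (0, 1):
        fj1 = p.phi1 if j else 1.0 - p.phi1
        fj0 = p.phi0 if j else 1.0 - p.phi0
        for k in (0, 1):
            lk1 = p.lambda1 if k else 1.0 - p.lambda1
            lk0 = p.lambda0 if k else 1.0 - p.lambda0
            cells[f"theta{j}{k}"] = d * fj1 * lk1 + (1.0 - d) * fj0 * lk0
    return CellDistribution(**cells)


def joint_distribution(params: LCAParameters) -> np.ndarray:
    """Full joint P(D, F, L) = P(D) P(F|D) P(L|D) as a (2, 2, 2) array.

    Axes are (D, F, L); marginalizing axis 0 reproduces
    ``cell_probabilities(params, params.delta)``.
    """
    p = params
    joint = np.empty((2, 2, 2))
    for d_val, (pd, phi, lam) in enumerate(
        [(1.0 - p.delta, p.phi0, p.lambda0), (p.delta, p.phi1, p.lambda1)]
    ):
        for f in (0, 1):
            pf = phi if f else 1.0 - phi
            for l in (0, 1):
                pl = lam if l else 1.0 - lam
                joint[d_val, f, l] = pd * pf * pl
    return joint


def _coerce_counts(counts) -> np.ndarray:
    """Accept counts as a mapping keyed by cell labels or a length-4 sequence
    in the fixed order (00, 01, 10, 11)."""
    if isinstance(counts, Mapping):
        arr = np.array([counts[c] for c in CELL_ORDER], dtype=float)
    else:
        arr = np.asarray(counts, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"counts must have 4 cells in order {CELL_ORDER}")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if arr.sum() <= 0:
        raise ValueError("counts must have a positive total")
    return arr


def log_likelihood(params: LCAParameters, prevalence, counts) -> float:
    """Multinomial log-likelihood sum_jk n_jk log theta_jk.

    ``prevalence=None`` uses the parameters' own delta, in which case the
    value is invariant under ``params.label_swap()`` (the mirror hypothesis
    has the identical likelihood function).  Returns -inf when a cell with
    positive count has zero probability.
    """
    n = _coerce_counts(counts)
    if prevalence is None:
        prevalence = params.delta
    theta = cell_probabilities(params, prevalence).as_array()
    total = 0.0
    for n_jk, t_jk in zip(n, theta):
        if n_jk == 0.0:
            continue
        if t_jk <= 0.0:
            return -math.inf
        total += n_jk * math.log(t_jk)
    return total
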