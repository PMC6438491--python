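"""Identifiability analysis of the latent class model.

From observational cell frequencies alone the model is statistically
unidentifiable: the three independent moment equations theta_jk = r_jk leave a
2-dimensional family of parameter tuples with identical likelihoods.  Adding
frequencies observed after a stochastic intervention on the latent node (same
conditionals, new prevalence delta') yields six equations in six unknowns,
whose solution — when it exists and is non-degenerate — is unique up to the
label-swap mirror image.

This module provides

* ``solve_moment_system`` — multistart bound-constrained least squares on the
  combined pre/post moment equations, returning the mirror pair, a degeneracy
  diagnosis, or an infeasibility verdict;
* ``solution_manifold`` — traversal of the 2-D observational solution family
  by predictor–corrector continuation in the Jacobian null space;
* ``dof_analysis`` — dimension counting via the rank of the numerically
  differentiated forward map;
* ``check_feasibility`` — feasible / infeasible / boundary-extremal
  classification with a grid-search oracle as fallback;
* ``double_labelled_demo`` — the toy doubly-labelled Bernoulli model G_xi
  (success chance xi**2) whose likelihood cannot distinguish xi from -xi.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import binom, qmc

from .model_core import CellDistribution, InterventionRegime, LCAParameters
from .simulate import ObservedFrequencies

__all__ = [
    "SolutionSet",
    "DofReport",
    "FeasibilityResult",
    "DoubleLabelledDemo",
    "InfeasibleFrequencies",
    "solve_moment_system",
    "solution_manifold",
    "dof_analysis",
    "check_feasibility",
    "double_labelled_demo",
    "grid_min_residual",
]

# Numerical policy (see docs/methods.md):
#: residual clustering radius for merging multistart solutions
CLUSTER_TOL = 1e-5
#: |delta - delta'| below this on a recovered branch means the intervention
#: did not move the prevalence, restoring the observational degeneracy
DEGENERATE_DELTA_TOL = 1e-3
#: smallest singular value of the 6x6 moment Jacobian below this flags a
#: locally non-identified (degenerate or extremal) solution
DEGENERATE_SV_TOL = 1e-8
#: relative singular-value cutoff for rank decisions
RANK_REL_TOL = 1e-10
#: distance from {0, 1} below which a coordinate counts as on the boundary
BOUNDARY_TOL = 1e-6
#: default number of quasi-random multistart points
N_STARTS = 32


class InfeasibleFrequencies(ValueError):
    """Raised when no parameter tuple reproduces the supplied frequencies."""


# ---------------------------------------------------------------------------
# Input coercion and residuals
# ---------------------------------------------------------------------------


def _cells_and_t(freq) -> tuple[np.ndarray, Optional[int]]:
    """Accept ObservedFrequencies, CellDistribution, or a length-4 array in
    the fixed (00, 01, 10, 11) order; return (cells, sample size or None)."""
    if isinstance(freq, ObservedFrequencies):
        return freq.as_array(), freq.t
    if isinstance(freq, CellDistribution):
        return freq.as_array(), None
    arr = np.asarray(freq, dtype=float)
    if arr.shape != (4,):
        raise ValueError("frequencies must have 4 cells in order (00, 01, 10, 11)")
    if np.any(arr < -1e-12) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be non-negative and sum to 1")
    return np.clip(arr, 0.0, 1.0), None


def _forward_cells(x: np.ndarray, prevalence: float) -> np.ndarray:
    """Cells (00, 01, 10, 11) for parameter vector (delta, phi0, phi1,
    lambda0, lambda1) at the given prevalence (delta itself is x[0] and is
    ignored here; the caller passes the regime's prevalence explicitly)."""
    _, p0, p1, l0, l1 = x
    d = prevalence
    a1 = np.array([(1 - p1) * (1 - l1), (1 - p1) * l1, p1 * (1 - l1), p1 * l1])
    a0 = np.array([(1 - p0) * (1 - l0), (1 - p0) * l0, p0 * (1 - l0), p0 * l0])
    return d * a1 + (1 - d) * a0


def _residual6(x: np.ndarray, cells_pre: np.ndarray, cells_post: np.ndarray) -> np.ndarray:
    """Six moment residuals: cells (01, 10, 11) per regime; x is the combined
    vector (delta, phi0, phi1, lambda0, lambda1, delta_prime)."""
    pre = _forward_cells(x[:5], x[0])[1:] - cells_pre[1:]
    post = _forward_cells(x[:5], x[5])[1:] - cells_post[1:]
    return np.concatenate([pre, post])


def _residual3(x: np.ndarray, cells_pre: np.ndarray) -> np.ndarray:
    """Three observational moment residuals for x = (delta, phi0, phi1,
    lambda0, lambda1)."""
    return _forward_cells(x, x[0])[1:] - cells_pre[1:]


def _swap6(x: np.ndarray) -> np.ndarray:
    """Label-swap of the combined vector: (1-d, phi1, phi0, lam1, lam0, 1-d')."""
    return np.array([1 - x[0], x[2], x[1], x[4], x[3], 1 - x[5]])


def _numeric_jacobian(fun, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian on [0,1]^n, one-sided at the boundary."""
    f0 = np.asarray(fun(x), dtype=float)
    jac = np.empty((f0.size, x.size))
    for i in range(x.size):
        lo = max(x[i] - h, 0.0)
        hi = min(x[i] + h, 1.0)
        xlo, xhi = x.copy(), x.copy()
        xlo[i], xhi[i] = lo, hi
        jac[:, i] = (np.asarray(fun(xhi)) - np.asarray(fun(xlo))) / (hi - lo)
    return jac


def _sobol_starts(dim: int, n: int) -> np.ndarray:
    """Deterministic quasi-random interior starting points in [0.02, 0.98]^dim."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pts = qmc.Sobol(d=dim, scramble=False).random(n)
    return 0.02 + 0.96 * pts


def _multistart_ls(residual_fn, dim: int, n_starts: int, stop_tol: float = 1e-11):
    """Run bound-constrained least squares from quasi-random starts.

    Returns the list of (solution, residual_inf) found, best first; stops
    early once a start reaches ``stop_tol`` on the max-abs residual.
    """
    solutions: list[tuple[np.ndarray, float]] = []
    for x0 in _sobol_starts(dim, n_starts):
        try:
            res = optimize.least_squares(
                residual_fn, x0, bounds=(0.0, 1.0), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:  # pragma: no cover - solver hiccup on a bad start
            continue
        r_inf = float(np.max(np.abs(res.fun)))
        solutions.append((res.x, r_inf))
        if r_inf < stop_tol:
            break
    solutions.sort(key=lambda s: s[1])
    return solutions


def _cluster(solutions, radius: float = CLUSTER_TOL):
    """Merge solutions within an L-infinity radius, keeping the best of each."""
    clusters: list[tuple[np.ndarray, float]] = []
    for x, r in solutions:
        for cx, _ in clusters:
            if np.max(np.abs(x - cx)) < radius:
                break
        else:
            clusters.append((x, r))
    return clusters


# ---------------------------------------------------------------------------
# Grid oracle
# ---------------------------------------------------------------------------


def grid_min_residual(
    freq_pre,
    freq_post=None,
    resolution: int = 11,
) -> tuple[float, np.ndarray]:
    """Brute-force grid search of the max-abs moment residual over the box.

    Evaluates the residual on a uniform ``resolution``-point grid per axis —
    over [0,1]^5 for observational frequencies alone, [0,1]^6 when a post
    regime is supplied — and returns the minimum together with its arg-min
    (combined vector with delta_prime last when post data is present).

    The conditional-parameter axes (phi0, phi1, lambda0, lambda1) are
    vectorized; prevalences are looped, which keeps memory flat while the
    inner work stays in numpy.
    """
    cells_pre, _ = _cells_and_t(freq_pre)
    g = np.linspace(0.0, 1.0, resolution)
    # per-class cell products over (phi, lambda) pairs
    pp, ll = np.meshgrid(g, g, indexing="ij")
    pp, ll = pp.ravel(), ll.ravel()  # G^2 pairs
    prods = np.stack(
        [(1 - pp) * (1 - ll), (1 - pp) * ll, pp * (1 - ll), pp * ll], axis=1
    )  # (G^2, 4)
    n_pair = prods.shape[0]
    # all (phi1, lambda1) x (phi0, lambda0) combinations
    a1 = prods[:, None, :]  # (G^2, 1, 4)
    a0 = prods[None, :, :]  # (1, G^2, 4)

    def regime_dev(cells: np.ndarray) -> np.ndarray:
        """max-abs deviation per (prevalence, class-1 pair, class-0 pair)."""
        out = np.empty((resolution, n_pair, n_pair))
        for i, d in enumerate(g):
            theta = d * a1 + (1 - d) * a0
            out[i] = np.max(np.abs(theta - cells), axis=-1)
        return out

    dev_pre = regime_dev(cells_pre)
    if freq_post is None:
        flat = np.argmin(dev_pre)
        i, j, k = np.unravel_index(flat, dev_pre.shape)
        x = np.array([g[i], pp[k], pp[j], ll[k], ll[j]])
        return float(dev_pre[i, j, k]), x

    cells_post, _ = _cells_and_t(freq_post)
    dev_post = regime_dev(cells_post)
    best = np.inf
    best_idx = (0, 0, 0, 0)
    for i in range(resolution):
        for m in range(resolution):
            combined = np.maximum(dev_pre[i], dev_post[m])
            flat = np.argmin(combined)
            val = combined.flat[flat]
            if val < best:
                best = float(val)
                j, k = np.unravel_index(flat, (n_pair, n_pair))
                best_idx = (i, j, k, m)
    i, j, k, m = best_idx
    x = np.array([g[i], pp[k], pp[j], ll[k], ll[j], g[m]])
    return best, x


# ---------------------------------------------------------------------------
# Combined-system solver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolutionSet:
    """Solutions of the combined moment system.

    ``branches`` holds (LCAParameters, InterventionRegime) pairs.  For status
    ``identified_pair`` there are exactly two, each the label-swap mirror of
    the other (with delta' -> 1 - delta'), canonical branch first.  For
    ``degenerate_infinite`` and ``boundary`` the branches are representative
    members of the infinite solution family found by the solver; for
    ``infeasible`` the list is empty.
    """

    branches: tuple
    residual: float
    status: str


def _default_tol(t_pre: Optional[int], t_post: Optional[int]) -> float:
    """Feasibility tolerance on the max-abs residual.

    Exact (distribution-level) inputs must be met to 1e-9; finite-sample
    frequencies are allowed a least-squares residual of six binomial standard
    errors at the least informative cell, 6 * sqrt(0.25 / t) = 3 / sqrt(t).
    """
    ts = [t for t in (t_pre, t_post) if t is not None]
    if not ts:
        return 1e-9
    return max(1e-9, 3.0 / math.sqrt(min(ts)))


def _branch(x: np.ndarray, direction: str):
    return (
        LCAParameters.from_array(x[:5]),
        InterventionRegime(delta_prime=float(x[5]), direction=direction),
    )


def solve_moment_system(
    freq_pre,
    freq_post,
    direction: str = "unconstrained",
    *,
    n_starts: int = N_STARTS,
    feas_tol: Optional[float] = None,
) -> SolutionSet:
    """Solve theta_jk(params, delta) = r_jk and theta_jk(params, delta') = r'_jk.

    Multistart bound-constrained least squares on the six-equation residual
    (cells 01, 10, 11 per regime; the 00 cell is determined by normalization),
    followed by clustering and a degeneracy diagnosis:

    * ``identified_pair`` — an interior, locally identified solution was
      found; the mirror branch is constructed by the label swap and the
      canonical branch (listed first) is chosen by ``direction``
      (``reduced`` picks delta' < delta);
    * ``degenerate_infinite`` — the best solution has delta' ~ delta or a
      rank-deficient moment Jacobian at an interior point (an infinite
      solution family);
    * ``boundary`` — rank deficiency at a solution on the boundary of the
      parameter box (the extremal-frequency case);
    * ``infeasible`` — no parameter tuple attains the frequencies within
      tolerance; confirmed against a coarse grid search so that solver
      non-convergence is not mistaken for infeasibility.

    With finite-sample inputs the equations are solved in the least-squares
    sense and the max-abs residual is reported; the default tolerance then
    scales with the binomial standard error of the cell frequencies.
    """
    cells_pre, t_pre = _cells_and_t(freq_pre)
    cells_post, t_post = _cells_and_t(freq_post)
    if isinstance(freq_pre, ObservedFrequencies) and freq_pre.regime != "pre":
        raise ValueError("freq_pre must carry the 'pre' regime tag")
    if isinstance(freq_post, ObservedFrequencies) and freq_post.regime != "post":
        raise ValueError("freq_post must carry the 'post' regime tag")
    if direction not in ("reduced", "increased", "unconstrained"):
        raise ValueError(f"unknown direction {direction!r}")
    tol = _default_tol(t_pre, t_post) if feas_tol is None else float(feas_tol)

    def resid(x):
        return _residual6(x, cells_pre, cells_post)

    solutions = _multistart_ls(resid, 6, n_starts)
    best_x, best_r = solutions[0] if solutions else (None, np.inf)

    if best_x is None or best_r > tol:
        # distinguish non-convergence from genuine infeasibility
        grid_r, grid_x = grid_min_residual(cells_pre, cells_post, resolution=11)
        res = optimize.least_squares(
            resid, np.clip(grid_x, 1e-6, 1 - 1e-6), bounds=(0.0, 1.0),
            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        r_inf = float(np.max(np.abs(res.fun)))
        if r_inf <= tol:
            best_x, best_r = res.x, r_inf
        else:
            return SolutionSet(
                branches=(), residual=min(best_r, r_inf), status="infeasible"
            )

    # degeneracy diagnosis at the best solution
    jac = _numeric_jacobian(resid, best_x)
    svals = np.linalg.svd(jac, compute_uv=False)
    on_boundary = bool(
        np.any(best_x < BOUNDARY_TOL) or np.any(best_x > 1 - BOUNDARY_TOL)
    )
    rank_deficient = svals[-1] < DEGENERATE_SV_TOL
    if abs(best_x[0] - best_x[5]) < DEGENERATE_DELTA_TOL or rank_deficient:
        clusters = _cluster(solutions)
        branches = tuple(
            _branch(x, direction) for x, r in clusters if r <= max(tol, best_r)
        )
        status = "boundary" if (rank_deficient and on_boundary) else "degenerate_infinite"
        return SolutionSet(branches=branches, residual=best_r, status=status)

    mirror_x = _swap6(best_x)
    pair = [best_x, mirror_x]
    if direction == "reduced":
        pair.sort(key=lambda x: x[5] - x[0])  # canonical: delta' < delta
    elif direction == "increased":
        pair.sort(key=lambda x: x[0] - x[5])
    else:
        warnings.warn(
            "direction='unconstrained': the mirror pair is returned in an "
            "arbitrary (delta-ascending) order",
            stacklevel=2,
        )
        pair.sort(key=lambda x: x[0])
    branches = tuple(_branch(x, direction) for x in pair)
    return SolutionSet(branches=branches, residual=best_r, status="identified_pair")


# ---------------------------------------------------------------------------
# Observational solution manifold
# ---------------------------------------------------------------------------


def solution_manifold(
    freq_pre,
    n_points: int,
    seed: int,
    *,
    tol: float = 1e-8,
    step: float = 0.08,
    max_tries: Optional[int] = None,
) -> list[LCAParameters]:
    """Sample distinct points of the 2-D observational solution family.

    Starting from a least-squares seed solution of theta_jk = r_jk, the
    traversal takes predictor steps in the 2-dimensional null space of the
    3x5 moment Jacobian and corrects back onto the manifold with bounded
    least squares; rejection sampling from random interior starts serves as
    a fallback when a continuation step stalls.  Every returned tuple
    reproduces the input frequencies within ``tol``.
    """
    cells_pre, _ = _cells_and_t(freq_pre)
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)

    def resid(x):
        return _residual3(x, cells_pre)

    def correct(x0):
        res = optimize.least_squares(
            resid, np.clip(x0, 0.0, 1.0), bounds=(0.0, 1.0), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        return res.x, float(np.max(np.abs(res.fun)))

    seed_sols = _multistart_ls(resid, 5, N_STARTS)
    if not seed_sols or seed_sols[0][1] > tol:
        raise InfeasibleFrequencies(
            "no latent class parameters reproduce the supplied frequencies"
        )
    points: list[np.ndarray] = [seed_sols[0][0]]
    max_tries = max_tries if max_tries is not None else 60 * n_points
    tries = 0
    current = points[0]
    while len(points) < n_points and tries < max_tries:
        tries += 1
        jac = _numeric_jacobian(resid, current)
        null = _null_space(jac)
        if null.shape[1] >= 1:
            direction = null @ rng.standard_normal(null.shape[1])
            norm = np.linalg.norm(direction)
            if norm > 0:
                predictor = current + step * direction / norm
                x, r = correct(predictor)
                if r <= tol and _is_new(x, points):
                    points.append(x)
                    current = x
                    continue
        # fallback: rejection sampling from a random interior start
        x, r = correct(rng.uniform(0.02, 0.98, size=5))
        if r <= tol and _is_new(x, points):
            points.append(x)
            current = x
    if len(points) < n_points:
        raise RuntimeError(
            f"found only {len(points)} of {n_points} requested manifold points"
        )
    return [LCAParameters.from_array(x) for x in points[:n_points]]


def _null_space(jac: np.ndarray) -> np.ndarray:
    u, s, vt = np.linalg.svd(jac)
    cutoff = max(s[0], 1.0) * RANK_REL_TOL if s.size else RANK_REL_TOL
    rank = int(np.sum(s > cutoff))
    return vt[rank:].T


def _is_new(x: np.ndarray, points: Sequence[np.ndarray], sep: float = 1e-4) -> bool:
    return all(np.max(np.abs(x - p)) > sep for p in points)


# ---------------------------------------------------------------------------
# Degrees of freedom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DofReport:
    """Dimension accounting of the moment system at a parameter point."""

    n_parameters: int
    n_constraints: int
    jacobian_rank: int
    solution_dimension: int
    status: str = "generic"


def dof_analysis(
    params: LCAParameters,
    regime: Optional[InterventionRegime] = None,
) -> DofReport:
    """Count parameters and constraints and rank the forward-map Jacobian.

    Without an intervention regime the forward map sends the 5 chances to the
    3 independent observational cells; with one, the 6 chances (delta' added)
    to 6 cells across both regimes.  The Jacobian is differentiated
    numerically and ranked by singular values (relative threshold 1e-10).
    A rank-deficient point (e.g. delta' = delta, or equal conditionals) is
    reported with status ``rank_deficient``; a point on the box boundary with
    status ``boundary`` (one-sided differences are used there).
    """
    x5 = params.as_array()
    if regime is None:
        x = x5
        fun = lambda z: _forward_cells(z, z[0])[1:]
        n_constraints = 3
    else:
        x = np.append(x5, regime.delta_prime)
        fun = lambda z: np.concatenate(
            [_forward_cells(z[:5], z[0])[1:], _forward_cells(z[:5], z[5])[1:]]
        )
        n_constraints = 6
    on_boundary = bool(np.any(x < BOUNDARY_TOL) or np.any(x > 1 - BOUNDARY_TOL))
    jac = _numeric_jacobian(fun, x)
    svals = np.linalg.svd(jac, compute_uv=False)
    cutoff = svals[0] * RANK_REL_TOL if svals.size and svals[0] > 0 else RANK_REL_TOL
    rank = int(np.sum(svals > cutoff))
    n_parameters = x.size
    status = "generic"
    if on_boundary:
        status = "boundary"
    elif rank < min(n_parameters, n_constraints):
        status = "rank_deficient"
    return DofReport(
        n_parameters=n_parameters,
        n_constraints=n_constraints,
        jacobian_rank=rank,
        solution_dimension=n_parameters - rank,
        status=status,
    )


# ---------------------------------------------------------------------------
# Feasibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeasibilityResult:
    """Classification of a frequency record against the model.

    ``status`` is one of ``feasible``, ``infeasible``, ``boundary_extremal``;
    for feasible (and boundary-extremal) inputs a witness parameter tuple is
    returned, with the post-intervention prevalence when a post regime was
    supplied.
    """

    status: str
    residual: float
    witness: Optional[LCAParameters] = None
    witness_delta_prime: Optional[float] = None


def check_feasibility(
    freq_pre,
    freq_post=None,
    *,
    feas_tol: Optional[float] = None,
    n_starts: int = N_STARTS,
) -> FeasibilityResult:
    """Decide whether any parameter tuple reproduces the frequencies.

    Runs the multistart least-squares solver; when it fails to reach the
    tolerance, a coarse grid search over the box supplies a candidate that is
    polished before the input is declared infeasible (overdetermined).
    Feasible inputs with an extremal cell (a relative frequency of exactly 0
    or 1) are classified ``boundary_extremal``: such frequencies are attained
    only on the boundary of the parameter box, where infinitely many tuples
    fit.
    """
    cells_pre, t_pre = _cells_and_t(freq_pre)
    if freq_post is None:
        cells_post, t_post = None, None

        def resid(x):
            return _residual3(x, cells_pre)

        dim = 5
    else:
        cells_post, t_post = _cells_and_t(freq_post)

        def resid(x):
            return _residual6(x, cells_pre, cells_post)

        dim = 6
    tol = _default_tol(t_pre, t_post) if feas_tol is None else float(feas_tol)

    solutions = _multistart_ls(resid, dim, n_starts)
    best_x, best_r = solutions[0] if solutions else (None, np.inf)
    if best_x is None or best_r > tol:
        grid_r, grid_x = grid_min_residual(
            cells_pre, cells_post if freq_post is not None else None, resolution=11
        )
        res = optimize.least_squares(
            resid, np.clip(grid_x, 0.0, 1.0), bounds=(0.0, 1.0), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        r_inf = float(np.max(np.abs(res.fun)))
        if r_inf <= tol:
            best_x, best_r = res.x, r_inf
        else:
            return FeasibilityResult(status="infeasible", residual=min(best_r, r_inf))

    all_cells = cells_pre if cells_post is None else np.concatenate([cells_pre, cells_post])
    extremal = bool(np.any(all_cells < 1e-9) or np.any(all_cells > 1 - 1e-9))
    status = "boundary_extremal" if extremal else "feasible"
    return FeasibilityResult(
        status=status,
        residual=best_r,
        witness=LCAParameters.from_array(best_x[:5]),
        witness_delta_prime=float(best_x[5]) if dim == 6 else None,
    )


# ---------------------------------------------------------------------------
# Doubly-labelled Bernoulli demonstration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoubleLabelledDemo:
    """Likelihoods of G_xi and G_{-xi} and the maximum-likelihood set."""

    xi: float
    log_likelihood_pos: float
    log_likelihood_neg: float
    mle_set: tuple = field(default_factory=tuple)


def double_labelled_demo(xi: float, successes: int, trials: int) -> DoubleLabelledDemo:
    """Binomial likelihood of the doubly-labelled hypotheses G_xi.

    G_xi assigns success chance xi**2, so G_xi and G_{-xi} have identical
    likelihoods for every data set: the model is unidentifiable and the MLE
    is the mirror set {+sqrt(s/t), -sqrt(s/t)} (collapsing to {0} when s=0,
    the single point where the two labels coincide).
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials!r}")
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    if not (-1.0 <= xi <= 1.0):
        raise ValueError(f"xi must lie in [-1, 1], got {xi!r}")
    ll_pos = float(binom.logpmf(successes, trials, xi**2))
    ll_neg = float(binom.logpmf(successes, trials, (-xi) ** 2))
    root = math.sqrt(successes / trials)
    mle = (0.0,) if successes == 0 else (root, -root)
    return DoubleLabelledDemo(
        xi=float(xi),
        log_likelihood_pos=ll_pos,
        log_likelihood_neg=ll_neg,
        mle_set=mle,
    )
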