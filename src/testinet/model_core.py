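"""Bayesian belief and source-trust arithmetic for testimony agents.

An agent holds a subjective probability ``b`` (its *belief*) that a binary
hypothesis ``h`` is true.  Sources — the world, or other agents — assert
either ``h`` or ``not-h``.  A source of perceived reliability ``rho`` is
assumed to report the true state of the world with probability ``rho``,
symmetrically for ``h`` and ``not-h``, so a report updates the belief by
Bayes' rule with likelihood ratio ``rho / (1 - rho)``.

Perceived reliability comes in two flavours:

* *fixed trust* — a constant (conventionally ``0.66``) that is never revised;
* *expectation-based trust* — a full probability density over the source's
  reliability ``tau`` on ``[0, 1]``, initialised to ``Beta(2, 1)`` (mean
  ``2/3``) and revised after every report according to how plausible the
  report's content was under the receiver's current belief.  A surprising
  report lowers the perceived reliability of its source; an expected report
  raises it.

The density is represented on a uniform grid with composite-Simpson
quadrature, which keeps repeated updates cheap while reproducing the exact
mixture-of-Betas posterior to well below 1e-6 at the default grid size.

Everything here is pure computation on scalars and small arrays; the
simulation engine composes these operations into population dynamics.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ReportContent",
    "TrustKind",
    "TrustState",
    "DEFAULT_GRID_SIZE",
    "belief_update_single",
    "belief_update_batch",
    "trust_update",
    "expected_trust",
    "predictive_report_prob",
    "fixed_trust_belief_closed_form",
]

DEFAULT_GRID_SIZE = 201
#: tolerance on the numerical normalisation of a trust density
_NORM_TOL = 1e-9


class ReportContent(enum.Enum):
    """Content of one assertion: the hypothesis is true, or it is false.

    Silence is the *absence* of a report, never a third content value.
    """

    ASSERT_H = 1
    ASSERT_NOT_H = -1


class TrustKind(enum.Enum):
    FIXED = "fixed"
    DENSITY = "density"


def simpson_weights(grid_size: int) -> np.ndarray:
    """Composite-Simpson quadrature weights on a uniform grid over [0, 1].

    Requires an odd number of grid points (an even number of intervals).
    """
    if grid_size < 3 or grid_size % 2 == 0:
        raise ValueError(f"grid_size must be odd and >= 3, got {grid_size}")
    h = 1.0 / (grid_size - 1)
    w = np.ones(grid_size)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


@dataclass(frozen=True)
class TrustState:
    """Perceived reliability of one source.

    Either a FIXED scalar in (0, 1) that never changes, or a DENSITY over
    the reliability ``tau`` in [0, 1], held as non-negative values on a
    uniform grid and normalised so its quadrature integral is 1.
    """

    kind: TrustKind
    fixed_value: float | None = None
    grid: np.ndarray | None = field(default=None, repr=False)
    weights: np.ndarray | None = field(default=None, repr=False)
    quad: np.ndarray | None = field(default=None, repr=False)
    _mean: float | None = field(default=None, repr=False)

    # -- constructors ------------------------------------------------------

    @staticmethod
    def fixed(value: float) -> "TrustState":
        if not 0.0 < value < 1.0:
            raise ValueError(f"fixed trust must lie strictly in (0, 1), got {value}")
        return TrustState(kind=TrustKind.FIXED, fixed_value=value)

    @staticmethod
    def from_density(values: np.ndarray, grid_size: int | None = None) -> "TrustState":
        """Build a DENSITY state from raw density values on the uniform grid.

        The values are validated (non-negative, not all zero) and
        renormalised to integrate to exactly 1 under Simpson quadrature.
        """
        values = np.asarray(values, dtype=float)
        grid_size = grid_size or values.size
        if values.size != grid_size:
            raise ValueError("density length does not match grid size")
        if np.any(values < 0.0) or np.any(~np.isfinite(values)):
            raise ValueError("trust density must be finite and non-negative")
        quad = simpson_weights(grid_size)
        z = float(quad @ values)
        if z <= 0.0:
            raise ValueError("trust density integrates to zero")
        values = values / z
        grid = np.linspace(0.0, 1.0, grid_size)
        mean = float(quad @ (grid * values))
        return TrustState(
            kind=TrustKind.DENSITY, grid=grid, weights=values, quad=quad, _mean=mean
        )

    @staticmethod
    def beta(a: float = 2.0, b: float = 1.0, grid_size: int = DEFAULT_GRID_SIZE) -> "TrustState":
        """Discretised Beta(a, b) trust prior (default Beta(2, 1), mean 2/3)."""
        grid = np.linspace(0.0, 1.0, grid_size)
        return TrustState.from_density(stats.beta.pdf(grid, a, b), grid_size)

    # -- queries -----------------------------------------------------------

    @property
    def mean(self) -> float:
        """Expected reliability E[tau]; the rho used in belief updates."""
        if self.kind is TrustKind.FIXED:
            return float(self.fixed_value)  # type: ignore[arg-type]
        return float(self._mean)  # type: ignore[arg-type]

    def integral(self) -> float:
        if self.kind is TrustKind.FIXED:
            return 1.0
        return float(self.quad @ self.weights)  # type: ignore[operator]


# ---------------------------------------------------------------------------
# belief revision


def _validate_belief(belief: float) -> float:
    if not 0.0 <= belief <= 1.0 or not math.isfinite(belief):
        raise ValueError(f"belief must lie in [0, 1], got {belief}")
    return float(belief)


def _validate_rho(rho: float) -> float:
    if not 0.0 < rho < 1.0:
        raise ValueError(f"source reliability must lie strictly in (0, 1), got {rho}")
    return float(rho)


def belief_update_single(belief: float, rho: float, content: ReportContent) -> float:
    """Posterior belief after one report from a source of reliability rho.

    Bayes' rule with the symmetric-reliability likelihoods
    P(assert h | h) = P(assert not-h | not-h) = rho:

        ASSERT_H:     b' = b*rho / (b*rho + (1-b)*(1-rho))
        ASSERT_NOT_H: b' = b*(1-rho) / (b*(1-rho) + (1-b)*rho)
    """
    b = _validate_belief(belief)
    r = _validate_rho(rho)
    if content is ReportContent.ASSERT_H:
        num, alt = b * r, (1.0 - b) * (1.0 - r)
    elif content is ReportContent.ASSERT_NOT_H:
        num, alt = b * (1.0 - r), (1.0 - b) * r
    else:  # pragma: no cover - enum exhausts the cases
        raise TypeError(f"not a ReportContent: {content!r}")
    return num / (num + alt)


def belief_update_batch(
    belief: float, reports: Iterable[Tuple[float, ReportContent]]
) -> float:
    """Posterior belief after a batch of reports from independent sources.

    Agents treat their sources as conditionally independent given the
    hypothesis (naive-Bayes aggregation), so the posterior odds are the
    prior odds times the product of the individual likelihood ratios.
    The result is order-invariant and identical to iterating
    :func:`belief_update_single` with the same (fixed) reliabilities.
    """
    b = _validate_belief(belief)
    num = b
    alt = 1.0 - b
    for rho, content in reports:
        r = _validate_rho(rho)
        if content is ReportContent.ASSERT_H:
            num *= r
            alt *= 1.0 - r
        elif content is ReportContent.ASSERT_NOT_H:
            num *= 1.0 - r
            alt *= r
        else:  # pragma: no cover
            raise TypeError(f"not a ReportContent: {content!r}")
    if num + alt == 0.0:  # both saturated: keep the (degenerate) prior
        return b
    return num / (num + alt)


# ---------------------------------------------------------------------------
# trust revision


def trust_update(trust: TrustState, belief_in_content: float) -> TrustState:
    """Revise a DENSITY trust state after one report from its source.

    ``belief_in_content`` is the receiver's pre-update probability that the
    report's content is true: its belief b for an ASSERT_H report, 1 - b for
    ASSERT_NOT_H.  Writing b_c for that value, the report is evidence about
    the source's reliability tau with likelihood

        P(report | tau) = b_c * tau + (1 - b_c) * (1 - tau),

    i.e. the source spoke truly (probability tau) and the content is true,
    or it spoke falsely and the content is false.  The density is updated
    pointwise and renormalised on the grid.  Fixed-trust states are never
    revised; passing one here is an error.
    """
    if trust.kind is not TrustKind.DENSITY:
        raise ValueError("trust_update requires a DENSITY trust state; "
                         "fixed-trust agents never revise trust")
    b_c = float(belief_in_content)
    if not 0.0 <= b_c <= 1.0:
        raise ValueError(f"belief_in_content must lie in [0, 1], got {b_c}")
    if abs(trust.integral() - 1.0) > _NORM_TOL:
        raise ValueError("input trust density is not normalised")
    tau = trust.grid
    likelihood = b_c * tau + (1.0 - b_c) * (1.0 - tau)
    return TrustState.from_density(trust.weights * likelihood, tau.size)


def expected_trust(trust: TrustState) -> float:
    """Expected reliability of a source under its current trust state."""
    return trust.mean


def predictive_report_prob(belief: float, trust: TrustState) -> float:
    """Agent's subjective probability that a speaking source asserts h.

    Marginalises over the truth of the hypothesis: the source asserts h if
    h is true and it reports truly, or h is false and it errs:
    ``b * rho + (1 - b) * (1 - rho)`` with rho the expected reliability.
    """
    b = _validate_belief(belief)
    rho = trust.mean
    return b * rho + (1.0 - b) * (1.0 - rho)


def fixed_trust_belief_closed_form(
    n_pos: int, n_neg: int, t: float, prior: float
) -> float:
    """Belief of a fixed-trust agent after n_pos ASSERT_H and n_neg
    ASSERT_NOT_H reports, all at reliability t.

    Posterior odds = prior odds * (t / (1 - t)) ** (n_pos - n_neg); only the
    report surplus matters.  Serves as an analytic oracle for fixed-trust
    belief trajectories.
    """
    b = _validate_belief(prior)
    r = _validate_rho(t)
    k = int(n_pos) - int(n_neg)
    num = b * r**max(k, 0) * (1.0 - r) ** max(-k, 0)
    alt = (1.0 - b) * (1.0 - r) ** max(k, 0) * r ** max(-k, 0)
    if num + alt == 0.0:
        return b
    return num / (num + alt)
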