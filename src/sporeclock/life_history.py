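"""Deterministic life-history model of one growth-and-transfer cycle.

A filamentous fungus founded by ``P0`` propagules grows hyphae
exponentially at specific rate ``r_h`` (per hour) until the conidiation
onset time ``t_c``, after which the accumulated hyphal biomass produces
single-celled conidia linearly at rate ``r_c`` (conidia per hyphal unit
per hour) until the transfer time ``T``.  A fraction ``f`` of the hyphae
fragments into suspended, transferable particles.  The propagules
available at transfer are the suspended fragments plus the conidia:

    H_T = P0 * exp(r_h * t_c)
    C_T = r_c * H_T * (T - t_c)
    P_T = f * H_T + C_T

Maximizing ``P_T`` over the onset time gives the closed form

    t_c* = T + f / r_c - 1 / r_h

clamped to ``[0, T]``.  The clamp is exact: dP_T/dt_c is the positive
factor ``P0 exp(r_h t_c)`` times a strictly decreasing linear function of
``t_c``, so ``P_T`` is unimodal on the real line and the constrained
argmax is the unconstrained root projected onto the interval.

Counts here are real-valued expectations; integerization belongs to the
serial-transfer simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "LifeHistory",
    "PropaguleCensus",
    "ParameterDomainError",
    "NoPropaguleRouteError",
    "hyphal_total",
    "census",
    "optimal_onset",
    "optimal_onset_bruteforce",
    "onset_surface",
    "load_life_history",
    "save_onset_surface",
]


class ParameterDomainError(ValueError):
    """A life-history parameter is outside its valid domain."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class NoPropaguleRouteError(ValueError):
    """Raised when f = 0 and r_c = 0: no propagule can ever be produced."""


@dataclass(frozen=True)
class LifeHistory:
    """Parameter vector of the single-cycle propagule model.

    Parameters
    ----------
    r_h : hyphal specific growth rate, per hour (>= 0).
    r_c : conidia production rate, conidia per hyphal unit per hour (>= 0).
    f : fraction of hyphal biomass fragmenting into suspended particles,
        in [0, 1].
    T : transfer interval in hours (> 0); defaults to the daily regime.
    t_c : conidiation onset time in hours, in [0, T].
    P0 : founding propagule count (>= 0, real-valued expectation).
    """

    r_h: float
    r_c: float
    f: float
    T: float = 24.0
    t_c: float = 0.0
    P0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r_h", "r_c", "f", "T", "t_c", "P0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterDomainError(name, f"must be finite, got {v!r}")
        if self.r_h < 0:
            raise ParameterDomainError("r_h", f"must be >= 0, got {self.r_h}")
        if self.r_c < 0:
            raise ParameterDomainError("r_c", f"must be >= 0, got {self.r_c}")
        if not 0.0 <= self.f <= 1.0:
            raise ParameterDomainError("f", f"must be in [0, 1], got {self.f}")
        if self.T <= 0:
            raise ParameterDomainError("T", f"must be > 0, got {self.T}")
        if not 0.0 <= self.t_c <= self.T:
            raise ParameterDomainError(
                "t_c", f"must be in [0, T={self.T}], got {self.t_c}"
            )
        if self.P0 < 0:
            raise ParameterDomainError("P0", f"must be >= 0, got {self.P0}")

    def with_onset(self, t_c: float) -> "LifeHistory":
        return replace(self, t_c=t_c)


@dataclass(frozen=True)
class PropaguleCensus:
    """Per-cycle output census: H_T, f*H_T, C_T and their sum P_T."""

    hyphal_total: float
    suspended_fragments: float
    conidia: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "total", self.suspended_fragments + self.conidia
        )


def hyphal_total(p: LifeHistory) -> float:
    """Total hyphal biomass at onset: H_T = P0 * exp(r_h * t_c)."""
    return p.P0 * math.exp(p.r_h * p.t_c)


def census(p: LifeHistory) -> PropaguleCensus:
    """Evaluate the one-cycle model at ``p``.

    Conidia accumulate linearly on the hyphal biomass frozen at onset:
    C_T = r_c * H_T * (T - t_c); fragments are f * H_T.
    """
    h = hyphal_total(p)
    return PropaguleCensus(
        hyphal_total=h,
        suspended_fragments=p.f * h,
        conidia=p.r_c * h * (p.T - p.t_c),
    )


def optimal_onset(
    r_h: float, r_c: float, f: float, T: float = 24.0
) -> float:
    """Closed-form propagule-maximizing conidiation onset, clamped to [0, T].

    Interior root: t_c* = T + f/r_c - 1/r_h.  Conventions for the
    degenerate limits:

    * ``r_c = 0`` with ``f > 0``: fragments are the only propagules and
      grow with the hyphae, so the optimum is ``T``.
    * ``r_h = 0``: hyphae cannot grow, so there is no benefit to delaying
      onset; returns 0 (the limit of the clamped root as r_h -> 0+ when
      the root diverges to -inf).
    * ``r_c = 0`` and ``f = 0``: P_T is identically zero;
      raises :class:`NoPropaguleRouteError`.
    """
    p = LifeHistory(r_h=r_h, r_c=r_c, f=f, T=T)  # domain validation
    if p.r_c == 0.0 and p.f == 0.0:
        raise NoPropaguleRouteError(
            "r_c = 0 and f = 0: no propagule route, P_T is identically zero"
        )
    if p.r_h == 0.0:
        return 0.0
    if p.r_c == 0.0:
        return p.T
    root = p.T + p.f / p.r_c - 1.0 / p.r_h
    return min(max(root, 0.0), p.T)


def optimal_onset_bruteforce(
    r_h: float,
    r_c: float,
    f: float,
    T: float = 24.0,
    grid_step: float = 1e-3,
    P0: float = 1.0,
) -> float:
    """Grid argmax of P_T over t_c in [0, T]; oracle for :func:`optimal_onset`.

    Ties break toward the earliest onset (first grid point attaining the
    maximum).  The grid includes both endpoints.
    """
    if grid_step <= 0:
        raise ValueError(f"grid_step must be > 0, got {grid_step}")
    p = LifeHistory(r_h=r_h, r_c=r_c, f=f, T=T, P0=P0)
    n = int(math.ceil(T / grid_step))
    t = np.minimum(np.arange(n + 1) * grid_step, T)
    totals = p.P0 * np.exp(p.r_h * t) * (p.f + p.r_c * (p.T - t))
    return float(t[int(np.argmax(totals))])


def onset_surface(
    rates: Sequence[float],
    fragmentations: Sequence[float],
    T: float = 24.0,
) -> np.ndarray:
    """Optimal-onset matrix for the equal-rates case r_h = r_c = rate.

    Entry ``(i, j)`` is ``optimal_onset(rates[i], rates[i],
    fragmentations[j], T)``.  With equal rates the closed form reduces to
    ``T + (f - 1) / r``, so onset increases with fragmentation and, for
    f < 1, with the common production rate.
    """
    if len(rates) == 0 or len(fragmentations) == 0:
        raise ValueError("rates and fragmentations must be non-empty")
    out = np.empty((len(rates), len(fragmentations)))
    for i, r in enumerate(rates):
        for j, frac in enumerate(fragmentations):
            out[i, j] = optimal_onset(r, r, frac, T)
    return out


def load_life_history(path) -> LifeHistory:
    """Read a flat key-value (YAML) parameter file into a LifeHistory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    allowed = {"r_h", "r_c", "f", "T", "t_c", "P0"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    return LifeHistory(**{k: float(v) for k, v in raw.items()})


def save_onset_surface(
    path,
    rates: Sequence[float],
    fragmentations: Sequence[float],
    surface: np.ndarray,
) -> None:
    """Write the surface as CSV: first row the fragmentation axis, first
    column the rate axis, cells t_c* with 6 decimals."""
    with open(path, "w") as fh:
        fh.write("rate\\fragmentation," + ",".join(f"{f:.6f}" for f in fragmentations) + "\n")
        for r, row in zip(rates, surface):
            fh.write(f"{r:.6f}," + ",".join(f"{v:.6f}" for v in row) + "\n")
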