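"""Core patch-occupancy model of a competitive hierarchy with a
competition-colonisation tradeoff.

Species are ranked ``i = 1..N`` from best (``i = 1``) to worst competitor.
Each species occupies a proportion ``p_i`` of microsites and obeys

    dp_i/dt = (c_i p_i + h_i) (1 - sum_{j<=i} p_j)
              - (m_i + sum_{j<i} (c_j p_j + h_j)) p_i

where ``c_i`` is the per-capita colonisation rate, ``m_i`` the per-capita
mortality rate and ``h_i`` an external propagule supply expressed as the
fraction of microsites that externally sourced propagules could colonise per
unit time in an empty landscape.  Superior competitors displace inferior ones
on contact, so species ``i`` is affected only by species ranked at or above
it; the system is lower-triangular in rank order.

Coexistence requires a tradeoff: in a baseline community the colonisation
rates increase strictly with rank index (better competitors are worse
colonisers).  The equilibrium is obtained in closed form by solving the
steady state sequentially from the best competitor downwards.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "Metacommunity",
    "OccupancyState",
    "EquilibriumResult",
    "rhs",
    "solve_equilibrium",
    "batch_feasible",
    "FEASIBILITY_TOL",
]

#: occupancies at or below this value count as zero when judging coexistence
FEASIBILITY_TOL = 1e-12


def _as_vector(x, n: int | None, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float)).copy()
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if n is not None and arr.size != n:
        raise ValueError(f"{name} has length {arr.size}, expected {n}")
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class Metacommunity:
    """Parameter set of an N-species hierarchical metacommunity.

    Arrays are indexed by competitive rank: position 0 holds species
    ``s_1``, the best competitor.  External surfaces (reports, serialised
    records) use 1-based ranks throughout.

    Parameters
    ----------
    c : array of float
        Per-capita colonisation rates, one per rank, all > 0.  In a
        baseline (tradeoff-conforming) community ``c`` increases strictly
        with rank index.
    m : array of float
        Per-capita mortality rates, all > 0.
    h : array of float
        External propagule supply per species, all >= 0; the fraction of
        microsites that anthropogenic propagules could colonise per unit
        time in an empty landscape.
    community_id : str
        Opaque identifier.
    seed_provenance : dict
        Record of the random draws that produced the community.
    off_surface_rank : int or None
        1-based rank of the single species manipulated off the tradeoff
        surface, if any.
    """

    c: np.ndarray
    m: np.ndarray
    h: np.ndarray
    community_id: str = ""
    seed_provenance: dict[str, Any] = field(default_factory=dict)
    off_surface_rank: int | None = None

    def __post_init__(self) -> None:
        c = _as_vector(self.c, None, "c")
        m = _as_vector(self.m, c.size, "m")
        h = _as_vector(self.h, c.size, "h")
        if c.size == 0:
            raise ValueError("metacommunity needs at least one species")
        if not np.all(c > 0):
            raise ValueError("all colonisation rates must be > 0")
        if not np.all(m > 0):
            raise ValueError("all mortality rates must be > 0")
        if not np.all(h >= 0):
            raise ValueError("external propagule rates must be >= 0")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "h", h)
        if self.off_surface_rank is not None and not (
            1 <= self.off_surface_rank <= c.size
        ):
            raise ValueError("off_surface_rank out of range")

    @property
    def N(self) -> int:
        return self.c.size

    def conforms_to_tradeoff(self) -> bool:
        """True iff colonisation rate increases strictly with rank and no
        species receives external propagules."""
        return bool(np.all(np.diff(self.c) > 0) and np.all(self.h == 0))

    def replace(self, **changes) -> "Metacommunity":
        fields = dict(
            c=self.c, m=self.m, h=self.h,
            community_id=self.community_id,
            seed_provenance=self.seed_provenance,
            off_surface_rank=self.off_surface_rank,
        )
        fields.update(changes)
        return Metacommunity(**fields)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "community_id": self.community_id,
            "N": self.N,
            "c": self.c.tolist(),
            "m": self.m.tolist(),
            "h": self.h.tolist(),
            "seed_provenance": dict(self.seed_provenance),
        }
        if self.off_surface_rank is not None:
            d["off_surface_rank"] = self.off_surface_rank
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Metacommunity":
        mc = cls(
            c=d["c"], m=d["m"], h=d["h"],
            community_id=d.get("community_id", ""),
            seed_provenance=d.get("seed_provenance", {}),
            off_surface_rank=d.get("off_surface_rank"),
        )
        if "N" in d and d["N"] != mc.N:
            raise ValueError("declared N does not match array lengths")
        return mc

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Metacommunity":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class OccupancyState:
    """Per-species site-occupancy proportions at a moment in time."""

    p: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        p = _as_vector(self.p, None, "p")
        if np.any(p < 0):
            raise ValueError("occupancies must be >= 0")
        if p.sum() > 1.0 + 1e-9:
            raise ValueError("total occupancy exceeds the site pool")
        object.__setattr__(self, "p", p)

    @property
    def N(self) -> int:
        return self.p.size


def rhs(state: OccupancyState | np.ndarray, mc: Metacommunity) -> np.ndarray:
    """Time derivative of occupancy for every species.

    Species ``i`` gains sites by colonising the space not taken by itself or
    by any superior competitor, and loses sites to mortality and to
    displacement by superiors (including their external propagules).  The
    derivative of species ``i`` depends only on species ``j <= i``.
    """
    if isinstance(state, OccupancyState):
        p = state.p
    else:
        p = np.asarray(state, dtype=float)
        if np.any(p < 0):
            raise ValueError("occupancies must be >= 0")
    if p.size != mc.N:
        raise ValueError(f"state has {p.size} species, community has {mc.N}")
    return _rhs_raw(p, mc.c, mc.m, mc.h)


def _rhs_raw(p: np.ndarray, c: np.ndarray, m: np.ndarray,
             h: np.ndarray) -> np.ndarray:
    """RHS without validation; used inside integrators.

    Occupancies are clamped at zero for the flux/pressure terms: adaptive
    steppers probe slightly negative states near extinctions (within
    absolute tolerance), and the clamp keeps those excursions
    self-correcting instead of letting the quadratic terms run away.
    """
    q = np.maximum(p, 0.0)
    flux = c * q + h
    vacant = 1.0 - np.cumsum(q)            # 1 - sum_{j<=i} p_j
    press = np.cumsum(flux) - flux          # sum_{j<i} (c_j p_j + h_j)
    return flux * vacant - (m + press) * p


@dataclass(frozen=True)
class EquilibriumResult:
    """Sequentially solved steady state of a metacommunity.

    ``p`` holds the equilibrium occupancies (clamped at exactly 0 for
    species excluded at equilibrium); ``feasible`` is true iff every
    species retains strictly positive occupancy.
    """

    p: np.ndarray
    feasible: bool

    @property
    def extinct_mask(self) -> np.ndarray:
        return self.p <= FEASIBILITY_TOL


def solve_equilibrium(mc: Metacommunity,
                      tol: float = FEASIBILITY_TOL) -> EquilibriumResult:
    """Closed-form sequential equilibrium of the hierarchy.

    Solves the steady state one species at a time from the best competitor
    downwards.  Let ``S = sum_{j<i} p_j*`` and
    ``D = m_i + sum_{j<i} (c_j p_j* + h_j)``.  With ``h_i = 0`` the
    positive fixed point is ``p_i* = (1 - S) - D / c_i``.  With
    ``h_i > 0`` it is the unique nonnegative root of

        -c_i p^2 + p (c_i (1 - S) - h_i - D) + h_i (1 - S) = 0.

    A species whose solved occupancy comes out <= 0 is set to exactly 0
    before the recursion continues, so species excluded at equilibrium
    exert no abundance-dependent competitive pressure (their external
    propagules, if any, still do).
    """
    n = mc.N
    p = np.zeros(n)
    S = 0.0        # occupied fraction of superiors
    P = 0.0        # sum_{j<i} (c_j p_j + h_j)
    feasible = True
    for i in range(n):
        ci, mi, hi = mc.c[i], mc.m[i], mc.h[i]
        D = mi + P
        space = 1.0 - S
        pi = _equilibrium_occupancy(ci, hi, D, space)
        p[i] = pi
        if pi <= tol:
            feasible = False
        S += pi
        P += ci * pi + hi
    return EquilibriumResult(p=p, feasible=feasible)


def _equilibrium_occupancy(c: float, h: float, D: float,
                           space: float) -> float:
    """Steady-state occupancy of one species given the pressure of its
    superiors.  ``space`` is the fraction of sites they leave vacant and
    ``D`` the total per-capita loss rate the species experiences."""
    if space <= 0.0:
        return 0.0
    if h == 0.0:
        if c <= 0.0:
            return 0.0
        raw = space - D / c
        return raw if raw > 0.0 else 0.0
    if c <= 0.0:
        # degenerate linear balance: h (space - p) = D p
        return h * space / (h + D)
    # quadratic -c p^2 + b p + h*space = 0; the product of its roots is
    # -h*space/c < 0, so exactly one root is nonnegative: take it.  The
    # conjugate form avoids cancellation when b < 0 (small c or strong
    # suppression) and degrades gracefully to the linear balance as c -> 0.
    b = c * space - h - D
    s = math.sqrt(b * b + 4.0 * c * h * space)
    if b >= 0.0:
        return (b + s) / (2.0 * c)
    return 2.0 * h * space / (s - b)


def batch_feasible(cmat: np.ndarray, m0: float,
                   tol: float = FEASIBILITY_TOL) -> np.ndarray:
    """Vectorised feasibility of many baseline communities at once.

    ``cmat`` is a (batch, N) array of colonisation rates sorted ascending
    within each row; mortality is uniform ``m0`` and ``h = 0``.  Returns a
    boolean mask of rows whose sequential equilibrium keeps every species
    strictly positive.  Row ``k`` gives a result identical to
    ``solve_equilibrium`` on the corresponding single community: the
    recursion is the same arithmetic, evaluated across the batch.
    """
    cmat = np.asarray(cmat, dtype=float)
    B, n = cmat.shape
    # rows are abandoned as soon as one species fails: feasibility needs all
    # of them positive, and an extinct species would be clamped to zero,
    # contributing nothing further to S or P.
    idx = np.arange(B)
    S = np.zeros(B)
    P = np.zeros(B)
    for i in range(n):
        ci = cmat[idx, i]
        pi = 1.0 - S - (m0 + P) / ci
        alive = pi > tol
        idx = idx[alive]
        S = S[alive] + pi[alive]
        P = P[alive] + ci[alive] * pi[alive]
    mask = np.zeros(B, dtype=bool)
    mask[idx] = True
    return mask
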