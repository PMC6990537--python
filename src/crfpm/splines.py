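"""Natural cubic spline basis on the log-time scale.

Flexible parametric survival models express the log cumulative (sub)hazard
as a restricted cubic spline in ``ln t``.  The basis used here is the
restricted-cubic parameterization

    v_1(x) = x
    v_{j+1}(x) = (x - k_j)^3_+ - lam_j (x - k_min)^3_+ - (1 - lam_j) (x - k_max)^3_+

with ``lam_j = (k_max - k_j) / (k_max - k_min)`` for each internal knot
``k_j``.  The cubic terms cancel outside the boundary knots, so the basis is
exactly linear there, and with no internal knots the model reduces to a
Weibull (linear in ``ln t``).  "Degrees of freedom" follows the
rstpm2/stpm2 convention: ``df = #internal knots + 1``, excluding the
intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KnotSet", "SplineBasis", "place_knots", "ncs_basis", "ncs_derivative"]


class DegenerateKnotsError(ValueError):
    """Raised when requested knots collide (heavily tied event times)."""


@dataclass(frozen=True)
class KnotSet:
    """Boundary and internal knots on the log-time scale.

    Parameters
    ----------
    boundary
        ``(k_min, k_max)`` on the log-time scale, typically the log of the
        first and last observed event times of one cause.
    internal
        Sorted knots strictly inside the boundary; may be empty.
    cause
        Event code the knots were derived from (bookkeeping only).
    """

    boundary: tuple[float, float]
    internal: tuple[float, ...] = ()
    cause: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise DegenerateKnotsError(
                f"boundary knots must be finite and increasing, got ({lo}, {hi})"
            )
        ks = (lo, *self.internal, hi)
        if any(a >= b for a, b in zip(ks, ks[1:])):
            raise DegenerateKnotsError(
                f"knots must be strictly increasing: {ks}"
            )

    @property
    def df(self) -> int:
        """Basis dimension excluding the intercept (= #internal + 1)."""
        return len(self.internal) + 1

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray((self.boundary[0], *self.internal, self.boundary[1]))

    def to_dict(self) -> dict:
        return {
            "boundary": [float(b) for b in self.boundary],
            "internal": [float(k) for k in self.internal],
            "cause": self.cause,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnotSet":
        return cls(
            boundary=tuple(d["boundary"]),
            internal=tuple(d.get("internal", ())),
            cause=d.get("cause"),
        )


@dataclass(frozen=True)
class SplineBasis:
    """A knot set together with its basis dimension."""

    knots: KnotSet
    df: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "df", self.knots.df)

    def __call__(self, x) -> np.ndarray:
        return ncs_basis(x, self.knots)

    def derivative(self, x) -> np.ndarray:
        return ncs_derivative(x, self.knots)


def place_knots(event_times, df: int, cause: int | None = None) -> KnotSet:
    """Place knots for one cause at equally spaced centiles of log event times.

    Boundary knots sit at the log of the smallest and largest event times;
    the ``df - 1`` internal knots at the 100*j/df centiles (j = 1..df-1) of
    the log event times, e.g. df=3 puts internal knots at the 33.3rd and
    66.7th centiles.

    Parameters
    ----------
    event_times
        Uncensored event times (> 0) of the cause being modelled.
    df
        Spline degrees of freedom (#internal knots + 1), >= 1.

    Raises
    ------
    DegenerateKnotsError
        If centile knots collide with each other or the boundary
        (heavily tied event times), or fewer than two distinct times.
    """
    t = np.asarray(event_times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two event times to place knots")
    if np.any(t <= 0):
        raise ValueError("event times must be positive")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    logt = np.log(np.sort(t))
    if logt[0] == logt[-1]:
        raise DegenerateKnotsError("all event times identical; no knot span")
    if df == 1:
        internal: tuple[float, ...] = ()
    else:
        qs = np.arange(1, df) / df
        internal = tuple(np.quantile(logt, qs))
    return KnotSet(boundary=(float(logt[0]), float(logt[-1])), internal=internal, cause=cause)


def _as_1d(x) -> tuple[np.ndarray, bool]:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    return arr, np.ndim(x) == 0


def ncs_basis(x, knots: KnotSet) -> np.ndarray:
    """Evaluate the restricted cubic basis at log-time values ``x``.

    Returns an array of shape ``(n, df)`` (or ``(df,)`` for scalar input).
    Column 0 is ``x`` itself; columns 1.. are the restricted cubic terms,
    one per internal knot.  The basis is exactly linear outside the
    boundary knots and all cubic columns vanish at the left boundary.
    """
    xa, scalar = _as_1d(x)
    kmin, kmax = knots.boundary
    out = np.empty((xa.size, knots.df))
    out[:, 0] = xa
    if knots.internal:
        span = kmax - kmin
        a = np.maximum(xa[:, None] - kmin, 0.0) ** 3
        b = np.maximum(xa[:, None] - kmax, 0.0) ** 3
        for j, kj in enumerate(knots.internal):
            lam = (kmax - kj) / span
            out[:, j + 1] = (
                np.maximum(xa - kj, 0.0) ** 3 - lam * a[:, 0] - (1.0 - lam) * b[:, 0]
            )
    return out[0] if scalar else out


def ncs_derivative(x, knots: KnotSet) -> np.ndarray:
    """Componentwise d/dx of :func:`ncs_basis` (needed to turn cumulative
    hazards into hazards)."""
    xa, scalar = _as_1d(x)
    kmin, kmax = knots.boundary
    out = np.empty((xa.size, knots.df))
    out[:, 0] = 1.0
    if knots.internal:
        span = kmax - kmin
        a = np.maximum(xa - kmin, 0.0) ** 2
        b = np.maximum(xa - kmax, 0.0) ** 2
        for j, kj in enumerate(knots.internal):
            lam = (kmax - kj) / span
            out[:, j + 1] = 3.0 * (
                np.maximum(xa - kj, 0.0) ** 2 - lam * a - (1.0 - lam) * b
            )
    return out[0] if scalar else out
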