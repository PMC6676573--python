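"""Interval-union algebra on the marker domain.

Treatment selection rules produce finite unions of disjoint closed
intervals within the marker domain [0, 1] (the set ``C`` of marker values
for which a future patient is recommended the new treatment).  This module
provides the :class:`SelectionSet` container together with the set algebra
(union, intersection, difference, complement, probability mass) that the
rule constructions and the quality measures are built on, and a helper that
turns a polynomial sign condition ``p(x) >= 0`` into such a set.

All sets follow the closed-interval convention: boundary points where a
rule's defining function is exactly zero belong to the set.  Single points
(degenerate intervals) are retained — they carry no probability mass and do
not affect any quality measure.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

#: Default marker domain.
DOMAIN: tuple[float, float] = (0.0, 1.0)

_TOL = 1e-12


def _normalise(
    intervals: Iterable[Sequence[float]],
) -> tuple[tuple[float, float], ...]:
    """Sort, validate and merge overlapping/touching closed intervals."""
    ivals = []
    for pair in intervals:
        lo, hi = float(pair[0]), float(pair[1])
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"non-finite interval ({lo}, {hi})")
        if hi < lo - _TOL:
            raise ValueError(f"interval with hi < lo: ({lo}, {hi})")
        ivals.append((lo, max(lo, hi)))
    ivals.sort()
    merged: list[list[float]] = []
    for lo, hi in ivals:
        if merged and lo <= merged[-1][1] + _TOL:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return tuple((lo, hi) for lo, hi in merged)


class SelectionSet:
    """A finite union of disjoint closed intervals.

    Parameters
    ----------
    intervals : iterable of (lo, hi) pairs
        Closed intervals; they are sorted and overlapping or touching
        intervals are merged, so the stored representation is canonical
        (disjoint and ordered).
    """

    __slots__ = ("_intervals",)

    def __init__(self, intervals: Iterable[Sequence[float]] = ()) -> None:
        self._intervals = _normalise(intervals)

    # -- constructors -------------------------------------------------
    @classmethod
    def empty(cls) -> "SelectionSet":
        return cls(())

    @classmethod
    def whole(cls, domain: tuple[float, float] = DOMAIN) -> "SelectionSet":
        return cls((domain,))

    # -- basic accessors ----------------------------------------------
    @property
    def intervals(self) -> tuple[tuple[float, float], ...]:
        return self._intervals

    @property
    def is_empty(self) -> bool:
        return not self._intervals

    def __bool__(self) -> bool:
        return bool(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SelectionSet):
            return NotImplemented
        if len(self._intervals) != len(other._intervals):
            return False
        return all(
            abs(a[0] - b[0]) <= 1e-10 and abs(a[1] - b[1]) <= 1e-10
            for a, b in zip(self._intervals, other._intervals)
        )

    def __hash__(self) -> int:  # canonical representation is hashable
        return hash(tuple((round(a, 10), round(b, 10)) for a, b in self._intervals))

    def __repr__(self) -> str:
        body = ", ".join(f"[{lo:.6g}, {hi:.6g}]" for lo, hi in self._intervals)
        return f"SelectionSet({{{body}}})" if body else "SelectionSet(∅)"

    def contains(self, x: float, atol: float = 1e-12) -> bool:
        """Whether the marker value ``x`` belongs to the set."""
        return any(lo - atol <= x <= hi + atol for lo, hi in self._intervals)

    __contains__ = contains

    def measure(self, cdf: Callable[[float], float] | None = None) -> float:
        """Total length (default) or probability mass of the set.

        With ``cdf`` given, returns ``sum_i cdf(hi_i) - cdf(lo_i)`` — the
        probability that a marker drawn from that distribution falls in
        the set.
        """
        if cdf is None:
            return float(sum(hi - lo for lo, hi in self._intervals))
        return float(sum(cdf(hi) - cdf(lo) for lo, hi in self._intervals))

    # -- algebra ------------------------------------------------------
    def union(self, other: "SelectionSet") -> "SelectionSet":
        return SelectionSet(self._intervals + other._intervals)

    __or__ = union

    def intersection(self, other: "SelectionSet") -> "SelectionSet":
        out = []
        for alo, ahi in self._intervals:
            for blo, bhi in other._intervals:
                lo, hi = max(alo, blo), min(ahi, bhi)
                if lo <= hi:
                    out.append((lo, hi))
        return SelectionSet(out)

    __and__ = intersection

    def complement(self, domain: tuple[float, float] = DOMAIN) -> "SelectionSet":
        """Closure of the complement within ``domain``."""
        dlo, dhi = domain
        clipped = self.intersection(SelectionSet((domain,)))
        out = []
        cursor = dlo
        for lo, hi in clipped._intervals:
            if lo - cursor > _TOL:
                out.append((cursor, lo))
            cursor = max(cursor, hi)
        if dhi - cursor > _TOL:
            out.append((cursor, dhi))
        return SelectionSet(out)

    def difference(
        self, other: "SelectionSet", domain: tuple[float, float] = DOMAIN
    ) -> "SelectionSet":
        """Set difference ``self \\ other`` (via closed complement).

        Degenerate touch points created when an interval of ``other``
        exactly abuts one of ``self`` are kept only if they have positive
        width after merging; isolated points of width zero are dropped
        here because a selection that retains a single marker value
        selects no patients.
        """
        diff = self.intersection(other.complement(domain))
        return SelectionSet(
            (lo, hi) for lo, hi in diff._intervals if hi - lo > _TOL
        )

    # -- serialisation ------------------------------------------------
    def to_pairs(self) -> list[list[float]]:
        return [[lo, hi] for lo, hi in self._intervals]

    def to_json(self) -> str:
        return json.dumps(self.to_pairs())

    @classmethod
    def from_json(cls, text: str) -> "SelectionSet":
        return cls(json.loads(text))


def _real_roots_in(coefs: np.ndarray, lo: float, hi: float) -> list[float]:
    """Real roots of a polynomial (ascending coefficients) inside [lo, hi]."""
    scale = np.max(np.abs(coefs))
    if scale == 0.0:
        return []
    c = np.trim_zeros(np.asarray(coefs, dtype=float), "b")
    # drop numerically-negligible leading coefficients for stability
    while len(c) > 1 and abs(c[-1]) < 1e-13 * scale:
        c = c[:-1]
    if len(c) <= 1:
        return []
    roots = np.polynomial.polynomial.polyroots(c)
    real = roots[np.abs(roots.imag) < 1e-8].real
    real = real[(real >= lo - 1e-12) & (real <= hi + 1e-12)]
    return sorted(float(np.clip(r, lo, hi)) for r in real)


def polynomial_nonneg_set(
    coefs: Sequence[float],
    domain: tuple[float, float] = DOMAIN,
    refine: Callable[[float], float] | None = None,
) -> SelectionSet:
    """The set ``{x in domain : p(x) >= 0}`` for a polynomial ``p``.

    ``coefs`` are in ascending order (constant first).  The domain is
    partitioned at the real roots of ``p``; each cell is classified by the
    sign of ``p`` (or of ``refine`` when given — used when ``p`` is a
    squared surrogate of the actual boundary function) at its midpoint,
    and sign-change boundaries are sharpened by Brent root-finding.

    The zero polynomial satisfies ``p >= 0`` everywhere, so it returns the
    whole domain.  Isolated tangency points (double roots of a function
    that is negative on both sides) carry no mass and are ignored.
    """
    lo, hi = domain
    coefs = np.asarray(coefs, dtype=float)
    f = refine if refine is not None else (
        lambda x: float(np.polynomial.polynomial.polyval(x, coefs))
    )
    if np.all(coefs == 0.0) and refine is None:
        return SelectionSet.whole(domain)
    breaks = [lo] + _real_roots_in(coefs, lo, hi) + [hi]
    breaks = sorted(set(breaks))
    mids = [(a + b) / 2 for a, b in zip(breaks[:-1], breaks[1:])]
    signs = [f(m) >= 0 for m in mids]
    # sharpen boundaries where the classifying function actually crosses
    pts = list(breaks)
    for i in range(1, len(breaks) - 1):
        fa, fb = f(mids[i - 1]), f(mids[i])
        if fa * fb < 0:
            try:
                pts[i] = float(brentq(f, mids[i - 1], mids[i], xtol=1e-12))
            except ValueError:  # pragma: no cover - bracket lost to rounding
                pass
    out = [
        (pts[i], pts[i + 1]) for i, keep in enumerate(signs) if keep
    ]
    return SelectionSet(out)
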