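"""Gauss linking integrals for polygonal curves.

The Gauss linking number of two curves r1, r2 is

    GLN = (1/4pi) oint oint (r1 - r2) . (dr1 x dr2) / |r1 - r2|^3 .

For two disjoint *closed* curves it is an integer topological invariant;
for open curves it is a real-valued entanglement measure.  On polygonal
(piecewise-linear) curves the double integral decomposes exactly into a
sum over segment pairs, and each segment-pair term has a closed form as a
signed solid angle of the spherical quadrilateral spanned by the four
endpoints (Banchoff; Klenin & Langowski).

This module provides the segment-pair primitive, end-to-end chain closure,
and the per-chain cumulative GLN profile used by the sliding-window link
scan: ``prefix[k]`` holds the winding of the focused chain's first ``k-1``
segments around the *closed* partner chain, so the GLN of any fragment
(atoms ``l..k``) is the prefix difference ``prefix[k] - prefix[l]``.  The
fragment's own virtual end-to-end closure contributes nothing under this
definition, which is what makes the O(N1*N2) prefix representation exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GLNProfile",
    "segment_pair_gauss",
    "segment_gauss_vector",
    "close_chain",
    "gln_prefix",
    "whole_chain_gln",
    "DegenerateGeometryError",
    "TooShortChainError",
]

#: Two segments closer than this (in Angstrom) are treated as intersecting.
INTERSECTION_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when two segments intersect (the Gauss integrand diverges)."""


class TooShortChainError(ValueError):
    """Raised when a chain has too few atoms for the requested operation."""


@dataclass(frozen=True)
class GLNProfile:
    """Cumulative Gauss-linking values of one open chain against a closed partner.

    Attributes
    ----------
    prefix : ndarray, shape (focus_N,)
        ``prefix[k-1]`` (1-based ``k``) is the GLN of the focused chain's
        segments ``1..k-1`` against the closed partner; ``prefix[0] == 0``.
        The implicit lower-triangular GLN matrix is ``S[k, l] =
        prefix[k-1] - prefix[l-1]`` for ``k > l`` and 0 otherwise.
    focus_N : int
        Atom count of the focused (open, scanned) chain.
    partner_N : int
        Atom count of the partner chain before closure.
    """

    prefix: np.ndarray
    focus_N: int
    partner_N: int
    closed_partner: bool = True

    def fragment_gln(self, i: int, j: int) -> float:
        """GLN of the fragment from atom ``i`` to atom ``i + j`` (1-based, signed)."""
        if not (1 <= i and i + j <= self.focus_N):
            raise IndexError(f"fragment ({i}, {i + j}) outside chain of {self.focus_N} atoms")
        return float(self.prefix[i + j - 1] - self.prefix[i - 1])


def _quad_area(r13, r14, r24, r23, r12, r34):
    """Vectorized signed solid-angle quadrilateral formula.

    All inputs are (..., 3) arrays of the difference vectors between the
    endpoints of segment pairs (a: r1->r2, b: r3->r4).  Returns the Gauss
    integral contribution of each pair.  Degenerate pairs (zero-length
    segments, collinear configurations) yield 0.
    """
    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)

    def _unit(v):
        norm = np.linalg.norm(v, axis=-1, keepdims=True)
        # zero-norm => coplanar/degenerate contribution; keep vector at 0
        return np.divide(v, norm, out=np.zeros_like(v), where=norm > 0)

    n1, n2, n3, n4 = _unit(n1), _unit(n2), _unit(n3), _unit(n4)

    def _asin_dot(a, b):
        return np.arcsin(np.clip(np.sum(a * b, axis=-1), -1.0, 1.0))

    area = _asin_dot(n1, n2) + _asin_dot(n2, n3) + _asin_dot(n3, n4) + _asin_dot(n4, n1)
    sign = np.sign(np.sum(np.cross(r34, r12) * r13, axis=-1))
    return area * sign / (4.0 * np.pi)


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between segments [p1,p2] and [q1,q2]."""
    u = p2 - p1
    v = q2 - q1
    w = p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-14:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:  # parallel
        s = 0.0
    t = (b * s + e) / c if c > 1e-14 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for the clamped t
    if a > 1e-14:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(p1 + s * u - (q1 + t * v)))


def segment_pair_gauss(p1, p2, q1, q2) -> float:
    """Exact Gauss integral of the segment pair (p1->p2, q1->q2).

    Signed: antisymmetric under reversing either segment, symmetric under
    exchanging the two segments.  Coplanar pairs give exactly 0.

    Raises
    ------
    DegenerateGeometryError
        If the segments intersect (closer than ``INTERSECTION_TOL``).
    """
    p1, p2, q1, q2 = (np.asarray(x, dtype=float) for x in (p1, p2, q1, q2))
    if np.linalg.norm(p2 - p1) < INTERSECTION_TOL or np.linalg.norm(q2 - q1) < INTERSECTION_TOL:
        import warnings

        warnings.warn("zero-length segment contributes 0 to the Gauss integral", stacklevel=2)
        return 0.0
    if _segment_distance(p1, p2, q1, q2) < INTERSECTION_TOL:
        raise DegenerateGeometryError("segments intersect; Gauss integrand diverges")
    return float(
        _quad_area(q1 - p1, q2 - p1, q2 - p2, q1 - p2, p2 - p1, q2 - q1)
    )


def segment_gauss_vector(a_pts: np.ndarray, b_pts: np.ndarray, block: int = 256) -> np.ndarray:
    """Per-segment Gauss sums of open polyline ``a`` against open polyline ``b``.

    Returns ``g`` with ``g[s]`` = sum over all segments ``t`` of ``b`` of the
    segment-pair Gauss integral of (a-segment ``s``, b-segment ``t``).
    Evaluation is blocked over a-segments to bound memory.
    """
    a_pts = np.asarray(a_pts, dtype=float)
    b_pts = np.asarray(b_pts, dtype=float)
    na, nb = len(a_pts) - 1, len(b_pts) - 1
    if na < 1 or nb < 1:
        return np.zeros(max(na, 0))
    p1, p2 = a_pts[:-1], a_pts[1:]
    q1, q2 = b_pts[:-1], b_pts[1:]
    out = np.empty(na)
    for lo in range(0, na, block):
        hi = min(lo + block, na)
        P1 = p1[lo:hi, None, :]
        P2 = p2[lo:hi, None, :]
        contrib = _quad_area(
            q1[None] - P1, q2[None] - P1, q2[None] - P2, q1[None] - P2,
            P2 - P1, (q2 - q1)[None],
        )
        out[lo:hi] = np.nansum(contrib, axis=1)
    return out


def close_chain(points: np.ndarray) -> np.ndarray:
    """Close a polyline end-to-end: returns vertices with the first repeated last.

    The returned array defines a closed polygon with N segments for N input
    atoms (the last segment is the virtual closure from last atom to first).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise TooShortChainError(f"need >= 3 atoms to close a chain, got {len(points)}")
    return np.vstack([points, points[:1]])


def gln_prefix(focus_pts: np.ndarray, partner_pts: np.ndarray) -> GLNProfile:
    """Cumulative GLN profile of the open focus chain against the closed partner.

    ``prefix[k-1]`` (1-based ``k``) is the Gauss integral of focus segments
    ``1..k-1`` against the end-to-end-closed partner, so every fragment GLN
    is a prefix difference and carries no contribution from the fragment's
    own virtual closure.
    """
    focus_pts = np.asarray(focus_pts, dtype=float)
    partner_pts = np.asarray(partner_pts, dtype=float)
    if len(focus_pts) < 2:
        raise TooShortChainError(f"focus chain needs >= 2 atoms, got {len(focus_pts)}")
    closed = close_chain(partner_pts)
    g = segment_gauss_vector(focus_pts, closed)
    prefix = np.concatenate([[0.0], np.cumsum(g)])
    return GLNProfile(prefix=prefix, focus_N=len(focus_pts), partner_N=len(partner_pts))


def whole_chain_gln(a_pts: np.ndarray, b_pts: np.ndarray) -> float:
    """Gauss linking number of the two chains, each closed end-to-end.

    This is the global-perspective diagnostic: both chains are turned into
    closed polygons by connecting their termini.  For disjoint closed curves
    the result is an integer up to numerical error; for wrapped-but-unlinked
    open chains the artificial closure can create spurious integer links,
    and opposite-sign local windings can cancel to ~0 — the two failure
    modes the sliding-window scan avoids.
    """
    ca = close_chain(a_pts)
    cb = close_chain(b_pts)
    return float(segment_gauss_vector(ca, cb).sum())
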