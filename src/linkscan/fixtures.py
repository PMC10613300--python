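"""Synthetic two-chain systems with known link topology.

Every generator emits backbone traces at protein-like geometry (~3.8 A
between consecutive Ca atoms, N and C interpolated onto the Ca polyline)
so the interface cutoff D behaves as it does on real structures.  Open
curves for the linked fixtures are built from closed parametric links with
a short arc removed, so detection must succeed without termini closure:

- ``hopf``            one chain threads a nearly-closed ring once (true Hopf
                      topology): 1 link, |whole GLN| ~ 1.
- ``multi_winding``   a tight coil wraps ``w`` times around the partner's
                      arm in one region: 1 linked region, |whole GLN| ~ |w|.
- ``cancellation``    two opposite-handed wraps in separated regions: local
                      links exist but the global GLN cancels to ~0 (the
                      Whitehead-link failure mode of termini closure).
- ``wrapped_unlinked`` one chain tracks along the partner while slowly
                      rotating around it once: deeply wrapped, no link, yet
                      termini closure yields |whole GLN| ~ 1 (the
                      false-positive mechanism of global methods).
- ``distant``         no interface at all.
- ``broken_interface`` a wrapped pair with interior residues deleted at the
                      interface, emulating missing residues that break the
                      chain and can fake a link.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import BackboneChain, write_backbone_pdb

__all__ = ["CurveSpec", "FixturePair", "make_pair", "write_fixture_pdb", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "hopf",
    "multi_winding",
    "cancellation",
    "wrapped_unlinked",
    "distant",
    "broken_interface",
)

_SELF_AVOID = 0.5  # A; minimum nonadjacent atom separation
_MAX_RETRIES = 10


class FixtureSpecError(ValueError):
    """The requested fixture is geometrically impossible."""


@dataclass(frozen=True)
class CurveSpec:
    """Recipe for one synthetic chain pair.

    ``n_atoms`` counts backbone atoms per chain (3 per residue); ``scale``
    is the Ca-Ca spacing in Angstrom; ``winding_count`` is the signed wrap
    number for multi_winding / cancellation; ``noise_sd`` adds Gaussian
    jitter to the Ca path.
    """

    kind: str
    n_atoms: int = 150
    winding_count: int = 1
    noise_sd: float = 0.0
    seed: int = 0
    scale: float = 3.8

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise FixtureSpecError(f"unknown fixture kind {self.kind!r}")
        if self.n_atoms < 12:
            raise FixtureSpecError("n_atoms must be >= 12 (4 residues)")
        if self.noise_sd < 0:
            raise FixtureSpecError("noise_sd must be nonnegative")
        if self.scale <= 0:
            raise FixtureSpecError("scale must be positive")
        if self.kind in ("multi_winding", "cancellation") and self.winding_count == 0:
            raise FixtureSpecError(f"{self.kind} requires winding_count != 0")

    @property
    def n_res(self) -> int:
        return self.n_atoms // 3


@dataclass(frozen=True)
class FixturePair:
    """A generated chain pair with its ground-truth topology."""

    a: BackboneChain
    b: BackboneChain
    true_links: int
    kind: str
    expect_break_warning: bool = False


# ---------------------------------------------------------------- geometry


def _resample(points: np.ndarray, n: int, spacing: float) -> np.ndarray:
    """Resample a dense polyline at ``n`` points with uniform arclength spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    want = np.arange(n) * spacing
    if want[-1] > total + 1e-9:
        # stretch to fit: use the full curve length instead of the nominal spacing
        want = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(want, cum, points[:, d])
    return out


def _backbone_from_ca(ca: np.ndarray, chain_id: str, first_resnum: int = 1) -> BackboneChain:
    """Interpolate N and C onto the Ca polyline (topology-preserving refinement)."""
    n = len(ca)
    fwd = np.empty_like(ca)
    fwd[:-1] = ca[1:] - ca[:-1]
    fwd[-1] = fwd[-2]
    bwd = np.empty_like(ca)
    bwd[1:] = ca[:-1] - ca[1:]
    bwd[0] = -fwd[0]
    f_n, f_c = 0.384, 0.40  # ~1.46 / ~1.52 A bonds at 3.8 A Ca spacing
    n_atoms = ca + f_n * bwd
    c_atoms = ca + f_c * fwd
    atoms = np.empty((3 * n, 3))
    atoms[0::3] = n_atoms
    atoms[1::3] = ca
    atoms[2::3] = c_atoms
    return BackboneChain(
        chain_id=chain_id,
        atoms=atoms,
        residue_ids=[str(first_resnum + i) for i in range(n)],
        break_flags=np.zeros(n, dtype=bool),
    )


def _frame(theta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local frame on the arc: radial u, out-of-plane y, tangent t."""
    u = np.array([np.cos(theta), 0.0, np.sin(theta)])
    y = np.array([0.0, 1.0, 0.0])
    t = np.array([-np.sin(theta), 0.0, np.cos(theta)])
    return u, y, t


_ARC_ANGLE = 3.0  # central angle of the bowed partner arc, rad


def _arc_and_wraps(spec: CurveSpec, wraps: list[tuple[int, int]]):
    """Bowed arc plus a tracking chain coiling around it at one or two sites.

    ``wraps`` lists ``(turns, handedness)`` per site.  The tracking chain
    follows the arc at contact distance along the whole span, so the wrap
    sites sit deep inside both interface subchains and the subchain
    closure chord cuts across the bow, clear of the coils.  The coil
    radius shrinks automatically for short chains, where the bow is
    tighter.
    """
    s = spec.scale
    n_res = spec.n_res
    total_len = n_res * s
    radius = total_len / _ARC_ANGLE
    for rho, pitch in ((7.0, 4.5), (5.0, 4.0), (4.0, 3.5)):
        turn_len = float(np.hypot(2.0 * np.pi * rho, pitch))
        wrap_len = sum(abs(w) for w, _ in wraps) * turn_len
        track_len = total_len - wrap_len
        if track_len < 40.0:
            continue
        dtheta = track_len / radius
        sites = [0.0] if len(wraps) == 1 else [-dtheta / 4.0, +dtheta / 4.0]
        # clearance of the span chord from the innermost coil
        worst = max(abs(th) for th in sites)
        sagitta = radius * (np.cos(worst) - np.cos(dtheta / 2.0))
        if sagitta < rho + 1.5:
            continue
        theta = np.linspace(-_ARC_ANGLE / 2.0, _ARC_ANGLE / 2.0, 20 * n_res)
        arc = np.c_[radius * np.cos(theta), np.zeros_like(theta), radius * np.sin(theta)]
        arc_ca = _resample(arc, n_res, s)
        wrap_dense = _track_and_wrap(
            radius, theta_lo=-dtheta / 2.0, theta_hi=dtheta / 2.0,
            sites=[(th, w, h) for th, (w, h) in zip(sites, wraps)],
            rho=rho, pitch=pitch,
        )
        wrap_ca = _resample(wrap_dense, n_res, s)
        return arc_ca, wrap_ca
    raise FixtureSpecError(
        f"n_atoms={spec.n_atoms} too small for {wraps} wraps plus tracking"
    )


def _track_and_wrap(radius: float, theta_lo: float, theta_hi: float,
                    sites: list[tuple[float, int, int]], rho: float,
                    pitch: float) -> np.ndarray:
    """Dense path tracking an arc at offset ``rho`` along +y, with helical wraps.

    ``sites`` lists ``(theta, turns, handedness)``.  Each wrap coils around
    the arc's local tangent, starting and ending on the tracking offset so
    the path is continuous.
    """
    y = np.array([0.0, 1.0, 0.0])

    def arc_pt(th):
        return np.array([radius * np.cos(th), 0.0, radius * np.sin(th)])

    def offset_pts(th0, th1, n=300):
        th = np.linspace(th0, th1, n)
        return np.c_[radius * np.cos(th), np.full_like(th, rho), radius * np.sin(th)]

    pieces = []
    cur = theta_lo
    for th_s, turns, handed in sorted(sites):
        u, _, t = _frame(th_s)
        half = pitch * turns / (2.0 * radius)  # arc-angle consumed by the wrap span
        pieces.append(offset_pts(cur, th_s - half)[:-1])
        phi = np.linspace(0.0, 2.0 * np.pi * turns, 140 * turns)
        helix = (
            arc_pt(th_s)[None, :]
            + rho * (np.cos(phi)[:, None] * y[None, :] + handed * np.sin(phi)[:, None] * u[None, :])
            + (pitch * turns * (phi / (2.0 * np.pi * turns) - 0.5))[:, None] * t[None, :]
        )
        pieces.append(helix)
        cur = th_s + half
    pieces.append(offset_pts(cur, theta_hi)[1:])
    return np.vstack(pieces)


def _wrapped_unlinked(spec: CurveSpec) -> tuple[np.ndarray, np.ndarray]:
    """Arc plus a chain that tracks it while rotating around it once, slowly."""
    s = spec.scale
    n_res = spec.n_res
    radius = n_res * s / np.pi  # half circle
    theta = np.linspace(0.0, np.pi, 20 * n_res)
    arc = np.c_[radius * np.cos(theta), np.zeros_like(theta), radius * np.sin(theta)]
    arc_ca = _resample(arc, n_res, s)
    d = 7.0  # tracking offset, within the interface cutoff
    psi = 2.0 * np.pi * (theta - theta[0]) / (theta[-1] - theta[0])
    u = np.c_[np.cos(theta), np.zeros_like(theta), np.sin(theta)]
    y = np.array([0.0, 1.0, 0.0])
    coil = arc + d * (np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * y[None, :])
    coil_ca = _resample(coil, n_res, s)
    return arc_ca, coil_ca


def _distant(spec: CurveSpec) -> tuple[np.ndarray, np.ndarray]:
    s = spec.scale
    n_res = spec.n_res
    z = np.arange(n_res) * s
    wiggle = 2.0 * np.sin(np.arange(n_res) * 0.7)
    a = np.c_[wiggle, np.zeros(n_res), z]
    b = np.c_[60.0 + wiggle, np.zeros(n_res), z]
    return a, b


def _min_separation(chain: BackboneChain) -> float:
    """Minimum distance between non-neighboring atoms of one chain."""
    from scipy.spatial import cKDTree

    pts = chain.atoms
    pairs = cKDTree(pts).query_pairs(_SELF_AVOID, output_type="ndarray")
    if len(pairs) == 0:
        return np.inf
    gaps = np.abs(pairs[:, 0] - pairs[:, 1])
    far = pairs[gaps > 2]
    if len(far) == 0:
        return np.inf
    d = np.linalg.norm(pts[far[:, 0]] - pts[far[:, 1]], axis=1)
    return float(d.min())


def _self_avoiding(a: BackboneChain, b: BackboneChain) -> bool:
    from scipy.spatial import cKDTree

    if _min_separation(a) < _SELF_AVOID or _min_separation(b) < _SELF_AVOID:
        return False
    inter, _ = cKDTree(b.atoms).query(a.atoms, k=1)
    return bool(inter.min() >= _SELF_AVOID)


def make_pair(spec: CurveSpec) -> FixturePair:
    """Generate a chain pair with ground-truth link count (deterministic per seed)."""
    w = abs(spec.winding_count)
    expect_break = False
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng((spec.seed + 1_000_003 * attempt) % 2**31)
        if spec.kind == "hopf":
            ca_b, ca_a = _arc_and_wraps(spec, [(1, +1)])
            truth = 1
        elif spec.kind == "multi_winding":
            ca_b, ca_a = _arc_and_wraps(spec, [(w, +1)])
            truth = 1  # one tight region of |w| windings
        elif spec.kind == "cancellation":
            ca_b, ca_a = _arc_and_wraps(spec, [(w, +1), (w, -1)])
            truth = 2  # two genuine local links that cancel globally
        elif spec.kind in ("wrapped_unlinked", "broken_interface"):
            ca_b, ca_a = _wrapped_unlinked(spec)
            truth = 0
        elif spec.kind == "distant":
            ca_a, ca_b = _distant(spec)
            truth = 0
        if spec.noise_sd > 0:
            ca_a = ca_a + rng.normal(0.0, spec.noise_sd, ca_a.shape)
            ca_b = ca_b + rng.normal(0.0, spec.noise_sd, ca_b.shape)
        a = _backbone_from_ca(ca_a, "A")
        b = _backbone_from_ca(ca_b, "B")
        if spec.kind == "broken_interface":
            a = _delete_interior(a, n_delete=6)
            expect_break = True
        if spec.noise_sd == 0 or _self_avoiding(a, b):
            return FixturePair(a=a, b=b, true_links=truth, kind=spec.kind,
                               expect_break_warning=expect_break)
    raise FixtureSpecError(
        f"could not generate a self-avoiding {spec.kind} pair in {_MAX_RETRIES} tries"
    )


def _delete_interior(chain: BackboneChain, n_delete: int) -> BackboneChain:
    """Remove residues from the middle of a chain, flagging the resulting break."""
    n = chain.n_residues
    lo = n // 2 - n_delete // 2
    hi = lo + n_delete
    keep = list(range(lo)) + list(range(hi, n))
    atoms = np.vstack([chain.atoms[3 * i : 3 * i + 3] for i in keep])
    flags = np.zeros(len(keep), dtype=bool)
    flags[lo] = True  # residue after the deletion
    return BackboneChain(
        chain_id=chain.chain_id,
        atoms=atoms,
        residue_ids=[chain.residue_ids[i] for i in keep],
        break_flags=flags,
        residue_names=[chain.residue_names[i] for i in keep],
    )


def write_fixture_pdb(pair: FixturePair, path) -> None:
    """Write the pair as a minimal two-chain PDB file (glycine backbone)."""
    write_backbone_pdb([pair.a, pair.b], path)
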