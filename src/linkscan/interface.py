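"""Interface selection: reduce a chain pair to two consecutive interface subchains.

Link formation between two chains is a property of the interaction
interface, so each chain is restricted to the contiguous backbone span
running from its first to its last atom lying within a cutoff distance D
of the partner chain ("the atoms between them" are kept so the span stays
consecutive and the mutual topology is preserved).  Flexible termini are
trimmed first — dangling tails can wrap the partner without any physical
meaning.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import BACKBONE_ATOMS, BackboneChain

__all__ = ["Config", "InterfaceSubchain", "trim_termini", "select_interface"]


@dataclass(frozen=True)
class Config:
    """Hyperparameters of the link-detection pipeline.

    Attributes
    ----------
    D : float
        Interface cutoff distance in Angstrom; backbone atoms of one chain
        within ``D`` of the other chain define the interface.
    Ts : float
        GLN threshold score; a fragment whose absolute GLN against the
        closed partner reaches ``Ts`` marks its middle atom.
    Rb, Re : int
        Minimum and maximum scanned fragment length, in atoms.
    trim : int
        Residues removed from each terminus of each chain before interface
        selection (flexible tails).
    re_bump : int
        Increment added to ``Re`` once when the maximal window score falls
        just short of ``Ts`` (adaptive smoothing).
    re_bump_trigger : float
        Fraction of ``Ts`` above which the near-miss triggers the bump.
    merge_gap : int
        Index gap between marked atoms still merged into one run (0 =
        strict adjacency).
    adaptive : bool
        Disable to skip the ``Re`` bump entirely (ablation).
    """

    D: float = 10.0
    Ts: float = 0.8
    Rb: int = 4
    Re: int = 36
    trim: int = 15
    re_bump: int = 3
    re_bump_trigger: float = 0.9
    merge_gap: int = 0
    adaptive: bool = True

    def __post_init__(self):
        if not (0 < self.Rb < self.Re):
            raise ValueError(f"need 0 < Rb < Re, got Rb={self.Rb}, Re={self.Re}")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.Ts <= 0:
            raise ValueError("Ts must be positive")
        if self.trim < 0 or self.re_bump < 0 or self.merge_gap < 0:
            raise ValueError("trim, re_bump and merge_gap must be nonnegative")
        if not (0 < self.re_bump_trigger < 1):
            raise ValueError("re_bump_trigger must lie in (0, 1)")


@dataclass(frozen=True)
class InterfaceSubchain:
    """Contiguous interface span of one chain, re-indexed 1..N.

    ``origin_map[k]`` maps re-indexed atom ``k+1`` back to
    ``(chain_id, residue_id, atom_name)`` in the source structure.
    ``break_flags``/``residue_ids`` are per residue of the span and feed the
    interface-integrity diagnostics.
    """

    chain_id: str
    atoms: np.ndarray
    origin_map: tuple[tuple[str, str, str], ...]
    residue_ids: tuple[str, ...]
    break_flags: np.ndarray

    @property
    def N(self) -> int:
        return len(self.atoms)

    @classmethod
    def empty(cls, chain_id: str) -> "InterfaceSubchain":
        return cls(
            chain_id=chain_id,
            atoms=np.zeros((0, 3)),
            origin_map=(),
            residue_ids=(),
            break_flags=np.zeros(0, dtype=bool),
        )

    @classmethod
    def from_chain_span(cls, chain: BackboneChain, first_atom: int, last_atom: int) -> "InterfaceSubchain":
        """Subchain covering atoms ``first_atom..last_atom`` (0-based, inclusive)."""
        res_lo, res_hi = first_atom // 3, last_atom // 3
        sub = chain.sub_residues(res_lo, res_hi + 1)
        origin = tuple(
            (chain.chain_id, sub.residue_ids[i // 3], BACKBONE_ATOMS[i % 3])
            for i in range(sub.n_atoms)
        )
        return cls(
            chain_id=chain.chain_id,
            atoms=sub.atoms,
            origin_map=origin,
            residue_ids=tuple(sub.residue_ids),
            break_flags=sub.break_flags,
        )


def trim_termini(chain: BackboneChain, trim: int) -> BackboneChain:
    """Remove ``trim`` residues from each end; empty result if the chain is too short."""
    if trim < 0:
        raise ValueError("trim must be nonnegative")
    n = chain.n_residues
    if n <= 2 * trim:
        return chain.sub_residues(0, 0)
    return chain.sub_residues(trim, n - trim)


def _contact_mask(a_atoms: np.ndarray, b_atoms: np.ndarray, D: float) -> np.ndarray:
    """Boolean mask over ``a_atoms``: within ``D`` of any atom of ``b``."""
    if len(a_atoms) == 0 or len(b_atoms) == 0:
        return np.zeros(len(a_atoms), dtype=bool)
    dist, _ = cKDTree(b_atoms).query(a_atoms, k=1)
    return dist <= D


def select_interface(
    a: BackboneChain, b: BackboneChain, D: float
) -> tuple[InterfaceSubchain, InterfaceSubchain]:
    """Interface subchains of the pair at cutoff ``D``.

    Each retained span runs from the first to the last backbone atom whose
    minimum distance to the partner's backbone is <= D; spans are expanded
    to whole residues so the N/Ca/C trace stays intact.  No contacts in
    either chain gives two empty subchains (no interface, zero links).
    """
    if D <= 0:
        raise ValueError("D must be positive")
    mask_a = _contact_mask(a.atoms, b.atoms, D)
    mask_b = _contact_mask(b.atoms, a.atoms, D)
    if not mask_a.any() or not mask_b.any():
        return InterfaceSubchain.empty(a.chain_id), InterfaceSubchain.empty(b.chain_id)
    ia = np.flatnonzero(mask_a)
    ib = np.flatnonzero(mask_b)
    sub_a = InterfaceSubchain.from_chain_span(a, int(ia[0]), int(ia[-1]))
    sub_b = InterfaceSubchain.from_chain_span(b, int(ib[0]), int(ib[-1]))
    return sub_a, sub_b
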