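"""Sliding-window link detection over GLN profiles.

For each chain of an interface pair the cumulative GLN profile against the
closed partner is scanned with windows of every length from Rb to Re atoms.
A window whose absolute GLN reaches the threshold Ts marks the fragment's
middle atom as link-forming; maximal runs of consecutive marked atoms are
individual links, and the link count of the pair is the larger of the two
per-chain run counts.  Bounding the window length is the geometric
constraint that separates a genuine tight link (a full winding completed
within <= Re atoms) from the gradual large-scale wrapping of two chains
around each other, which never concentrates a full winding in one window.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gauss import GLNProfile, gln_prefix, whole_chain_gln
from .interface import Config, InterfaceSubchain, select_interface, trim_termini
from .structure_io import BackboneChain, InterfaceIntegrity, assert_interface_integrity

__all__ = [
    "MarkSet",
    "LinkReport",
    "scan_windows",
    "count_consecutive_runs",
    "marked_runs",
    "detect_pair",
    "detect_complex",
]

MIN_PARTNER_ATOMS = 3  # closing a chain needs a polygon
MIN_FOCUS_ATOMS = 2  # at least one segment to scan


@dataclass
class MarkSet:
    """Atoms of one chain flagged as link-forming by the window scan.

    ``marked`` holds 1-based indices in the re-indexed interface frame.
    ``triggers[m]`` lists the ``(i, j, delta_s)`` windows that marked atom
    ``m`` (an atom may be marked by several windows).  ``max_delta_s`` is
    the largest window score seen, marked or not — it drives the adaptive
    Re rule.
    """

    chain_role: str
    N: int
    marked: set[int] = field(default_factory=set)
    triggers: dict[int, list[tuple[int, int, float]]] = field(default_factory=dict)
    max_delta_s: float = 0.0

    def sorted_marked(self) -> list[int]:
        return sorted(self.marked)


@dataclass
class LinkReport:
    """Link-detection result for one chain pair."""

    pair_id: tuple[str, str]
    n_links: int
    linked_regions: dict[str, list[str]]
    max_abs_gln: float
    re_effective: int
    diagnostics: dict
    marks: dict[str, MarkSet] | None = None
    whole_gln: float | None = None

    def to_dict(self) -> dict:
        out = {
            "pair": list(self.pair_id),
            "n_links": self.n_links,
            "linked_regions": self.linked_regions,
            "max_abs_gln": round(self.max_abs_gln, 6),
            "re_effective": self.re_effective,
            "diagnostics": self.diagnostics,
        }
        if self.whole_gln is not None:
            out["whole_gln"] = round(self.whole_gln, 6)
        return out


def scan_windows(profile: GLNProfile, cfg: Config, re_effective: int | None = None,
                 chain_role: str = "A") -> MarkSet:
    """Mark middle atoms of every window whose |GLN| reaches Ts.

    Windows are fragments from atom ``i`` to ``i + j`` (1-based) for every
    length ``j`` in ``[Rb, re_effective]`` and start ``i`` in ``[1, N-j]``;
    the window score is the prefix difference ``|prefix[i+j] - prefix[i]|``
    and the marked atom is ``floor(i + j/2)``, the fragment's middle atom.
    """
    N = profile.focus_N
    re_eff = cfg.Re if re_effective is None else re_effective
    ms = MarkSet(chain_role=chain_role, N=N)
    prefix = profile.prefix
    for j in range(cfg.Rb, re_eff + 1):
        if j >= N:
            break
        ds = np.abs(prefix[j:] - prefix[:-j])  # i = 1..N-j
        if ds.size == 0:
            continue
        ms.max_delta_s = max(ms.max_delta_s, float(ds.max()))
        for idx in np.flatnonzero(ds >= cfg.Ts):
            i = int(idx) + 1
            m = i + j // 2
            ms.marked.add(m)
            ms.triggers.setdefault(m, []).append((i, j, float(ds[idx])))
    return ms


def marked_runs(ms: MarkSet, merge_gap: int = 0) -> list[tuple[int, int]]:
    """Maximal runs of consecutive marked indices as (first, last) pairs."""
    idx = ms.sorted_marked()
    if not idx:
        return []
    runs = []
    start = prev = idx[0]
    for m in idx[1:]:
        if m - prev > merge_gap + 1:
            runs.append((start, prev))
            start = m
        prev = m
    runs.append((start, prev))
    return runs


def count_consecutive_runs(ms: MarkSet, merge_gap: int = 0) -> int:
    """Number of maximal consecutive runs in the marked set."""
    return len(marked_runs(ms, merge_gap))


def _regions_for(sub: InterfaceSubchain, runs: Sequence[tuple[int, int]]) -> list[str]:
    """Translate runs of re-indexed atoms to author residue ranges like 'A:45-52'."""
    regions = []
    for first, last in runs:
        _, r1, _ = sub.origin_map[first - 1]
        cid, r2, _ = sub.origin_map[last - 1]
        regions.append(f"{cid}:{r1}-{r2}" if r1 != r2 else f"{cid}:{r1}")
    return regions


def _skipped_report(a_id: str, b_id: str, cfg: Config, reason: str,
                    diagnostics: dict | None = None) -> LinkReport:
    diag = {"skipped": reason}
    if diagnostics:
        diag.update(diagnostics)
    return LinkReport(
        pair_id=(a_id, b_id),
        n_links=0,
        linked_regions={a_id: [], b_id: []},
        max_abs_gln=0.0,
        re_effective=cfg.Re,
        diagnostics=diag,
    )


def _integrity_dict(tag: str, integ: InterfaceIntegrity) -> dict:
    return {
        f"breaks_{tag}": integ.n_breaks,
        f"interface_{tag}": integ.warning,
    }


def detect_pair(
    a: BackboneChain,
    b: BackboneChain,
    cfg: Config | None = None,
    include_whole_gln: bool = False,
) -> LinkReport:
    """Run the full three-step detection on one chain pair.

    Steps: trim termini -> select the interface subchains -> compute both
    GLN profiles (each chain scanned open against the closed partner) ->
    window scan with the adaptive Re rule -> count runs of marked atoms.
    ``n_links`` is the larger per-chain run count; marked regions are
    reported in author residue numbering.  Fully deterministic.
    """
    cfg = cfg or Config()
    t0 = time.perf_counter()
    a_t = trim_termini(a, cfg.trim)
    b_t = trim_termini(b, cfg.trim)
    if a_t.n_atoms == 0 or b_t.n_atoms == 0:
        return _skipped_report(a.chain_id, b.chain_id, cfg, "chain empty after trimming")
    sub_a, sub_b = select_interface(a_t, b_t, cfg.D)
    if sub_a.N == 0 or sub_b.N == 0:
        return _skipped_report(a.chain_id, b.chain_id, cfg, "no interface contacts")

    diag = {}
    diag.update(_integrity_dict("a", assert_interface_integrity(sub_a)))
    diag.update(_integrity_dict("b", assert_interface_integrity(sub_b)))

    whole = None
    if include_whole_gln and a_t.n_atoms >= 3 and b_t.n_atoms >= 3:
        whole = whole_chain_gln(a_t.atoms, b_t.atoms)

    if min(sub_a.N, sub_b.N) < MIN_PARTNER_ATOMS or max(sub_a.N, sub_b.N) < MIN_FOCUS_ATOMS:
        rep = _skipped_report(a.chain_id, b.chain_id, cfg, "interface subchain too short", diag)
        rep.whole_gln = whole
        return rep

    prof_a = gln_prefix(sub_a.atoms, sub_b.atoms)
    prof_b = gln_prefix(sub_b.atoms, sub_a.atoms)

    n_min = min(sub_a.N, sub_b.N)

    def _scan(re_limit: int) -> tuple[MarkSet, MarkSet]:
        re_eff = min(re_limit, n_min)
        return (
            scan_windows(prof_a, cfg, re_eff, chain_role=sub_a.chain_id),
            scan_windows(prof_b, cfg, re_eff, chain_role=sub_b.chain_id),
        )

    re_used = min(cfg.Re, n_min)
    ms_a, ms_b = _scan(cfg.Re)
    max_ds = max(ms_a.max_delta_s, ms_b.max_delta_s)
    if cfg.adaptive and cfg.re_bump > 0 and cfg.re_bump_trigger * cfg.Ts <= max_ds < cfg.Ts:
        re_used = min(cfg.Re + cfg.re_bump, n_min)
        ms_a, ms_b = _scan(cfg.Re + cfg.re_bump)
        max_ds = max(ms_a.max_delta_s, ms_b.max_delta_s)
        diag["re_bumped"] = True

    runs_a = marked_runs(ms_a, cfg.merge_gap)
    runs_b = marked_runs(ms_b, cfg.merge_gap)
    diag["elapsed_s"] = round(time.perf_counter() - t0, 4)
    return LinkReport(
        pair_id=(a.chain_id, b.chain_id),
        n_links=max(len(runs_a), len(runs_b)),
        linked_regions={
            sub_a.chain_id: _regions_for(sub_a, runs_a),
            sub_b.chain_id: _regions_for(sub_b, runs_b),
        },
        max_abs_gln=max_ds,
        re_effective=re_used,
        diagnostics=diag,
        marks={sub_a.chain_id: ms_a, sub_b.chain_id: ms_b},
        whole_gln=whole,
    )


def detect_complex(
    chains: Sequence[BackboneChain],
    cfg: Config | None = None,
    include_whole_gln: bool = False,
) -> list[LinkReport]:
    """One :class:`LinkReport` per unordered chain pair of an M-chain complex.

    An M-chain complex splits into M(M-1)/2 two-chain problems; the complex
    is flagged linked if any pair has ``n_links > 0``.
    """
    if len(chains) < 2:
        raise ValueError(f"need >= 2 chains, got {len(chains)}")
    return [
        detect_pair(a, b, cfg, include_whole_gln=include_whole_gln)
        for a, b in itertools.combinations(chains, 2)
    ]
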