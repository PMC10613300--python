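# linkscan

Detection, counting and localization of **topological links** between chains
of protein–protein complex structures.

Structure-prediction tools occasionally emit complex models in which one
chain's backbone threads through a loop of the other — a topological link
that cannot form physically without unfolding a chain. Screening for such
artifacts is hard because a protein chain is an *open* curve: its topology is
only defined after the chain is artificially closed, and naive closure of
the termini both creates links that are not there (deeply wrapped but
unlinked chains) and destroys links that are (opposite-sign windings that
cancel globally). `linkscan` solves this chain-closure problem locally: it
slides windows along each chain at the interaction interface and measures
each fragment's Gauss linking number against the closed partner chain, so a
genuine tight link is detected where it sits, independent of what the
termini do. It is written for structural bioinformaticians who screen
predicted (or experimental) complex structures for interface artifacts.

## Method

For two chains reduced to their backbone (N, Cα, C) traces:

1. **Interface selection.** The first and last 15 residues of each chain are
   trimmed; each chain is then restricted to the contiguous span from its
   first to its last backbone atom within *D* = 10 Å of the partner,
   re-indexed 1..N.
2. **Window scan.** For the focused chain against the end-to-end–closed
   partner, the Gauss linking number of every fragment of *j* atoms starting
   at atom *i* is evaluated for all *j* ∈ [R_b, R_e] = [4, 36] and all valid
   *i*. With the cumulative profile S(k) = GLN of segments 1..k−1 against
   the closed partner, each fragment value is the prefix difference
   Δs(i, j) = |S(i+j) − S(i)|, so the whole scan costs one O(N₁·N₂) pass of
   segment-pair Gauss integrals:

       GLN = (1/4π) ∮∮ (r₁ − r₂) · (dr₁ × dr₂) / |r₁ − r₂|³

   evaluated in closed form per segment pair (signed solid angle). Whenever
   Δs(i, j) ≥ T_s = 0.8 the fragment's middle atom ⌊i + j/2⌋ is marked.
   If the best score over both chains lands just below threshold
   (≥ 0.9 T_s), the scan is repeated once with R_e + 3.
3. **Inference.** Maximal runs of consecutive marked atoms are individual
   links; the link count of the pair is the larger of the two per-chain run
   counts, and marked runs are mapped back to author residue numbers.
   An M-chain complex is screened as all M(M−1)/2 pairs.

The bounded window length is the geometric constraint that separates a
genuine link (a full winding completed within ≤ 36 atoms ≈ 12 residues)
from gradual large-scale wrapping, which never concentrates a winding in
one window.

## Worked example

Generate a synthetic pair whose chains are locally linked with opposite
signs — the case global (termini-closure) methods miss — and scan it:

```sh
python - <<'EOF'
from linkscan import CurveSpec, make_pair, write_fixture_pdb
write_fixture_pdb(make_pair(CurveSpec(kind="cancellation")), "cancellation.pdb")
EOF
linkscan detect cancellation.pdb --trim 0 --whole-gln
```

Output (abridged):

```json
{
  "n_links_total": 2,
  "linked": true,
  "pairs": [
    {
      "pair": ["A", "B"],
      "n_links": 2,
      "linked_regions": {
        "A": ["A:11-16", "A:35-40"],
        "B": ["B:15-23", "B:29-37"]
      },
      "max_abs_gln": 1.0825,
      "re_effective": 36,
      "whole_gln": 0.0
    }
  ]
}
```

The local scan finds **two** links and places them at residues 11–16 and
35–40 of chain A (15–23 and 29–37 of chain B), with a peak window |GLN| of
1.08. The global diagnostic `whole_gln` — both chains closed through their
termini — is 0.0: the two opposite-sign windings cancel exactly, so a
termini-closure method would call this structure unlinked. `--trim 0` is
used because synthetic curves have no flexible tails to remove; on real
structures keep the default 15-residue trim.

Batch screening of a directory, with per-file TSV rows and aggregate
percentage, runs via `linkscan batch DIR --glob '*.pdb' --tsv out.tsv`
(add `--top-ranked-only` to keep only top-ranked models of a prediction
set). All hyperparameters (`--d`, `--ts`, `--rb`, `--re`, `--trim`) are
exposed, plus `--no-adaptive-re` and `--merge-gap` for ablations.

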