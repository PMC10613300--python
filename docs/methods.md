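# Methods

## Model and assumptions

A protein chain is represented by the ordered polyline through its backbone
heavy atoms N, Cα, C (three atoms per residue). All topology statements are
statements about these polylines: side chains, hydrogens and covalent
cross-links (disulfides, isopeptide bonds) are outside the model, so a pair
of chains genuinely linked *through* a covalent loop is out of scope by
construction.

The entanglement measure is the Gauss linking number

    GLN = (1/4π) ∮∮ (r₁ − r₂) · (dr₁ × dr₂) / |r₁ − r₂|³ ,

an integer invariant for disjoint closed curves and a real-valued winding
measure for open ones. On polygonal curves the double integral splits
exactly into segment-pair terms, each evaluated in closed form as the
signed solid angle of the spherical quadrilateral spanned by the four
endpoints (the Klenin–Langowski construction). The closed form is validated
in the test suite against adaptive and composite Gauss–Legendre quadrature
of the integrand.

Because a chain is open, its topology depends on how it is closed. The
method takes a local perspective: only the *partner* chain is closed (one
virtual segment joining its termini), while the focused chain is scanned
open, fragment by fragment. A fragment's GLN is defined as the sum of its
actual segments' contributions against the closed partner — equivalently a
difference of two cumulative ("prefix") values — so the fragment's own
virtual closure contributes nothing. This is the definition that makes the
lower-triangular fragment-GLN matrix representable by prefix differences
S(k,l) = S(k,1) − S(l,1) and the whole scan O(N₁·N₂) instead of O(N₁²·N₂);
it is also, by that same identity, the operative definition used when
windows of every length are compared against one threshold.

## Pipeline

1. **Parsing.** PDB/mmCIF via gemmi; first model, highest-occupancy altloc
   (ties: first encountered), non-polymer entities excluded, nonstandard
   amino acids with complete backbones kept. Residues missing any of
   N/Cα/C are dropped whole — interpolating coordinates would invent
   geometry that can change topology — and the following retained residue
   is flagged as a chain break, as is any residue whose C(i−1)–N(i)
   distance exceeds 2.0 Å (the peptide bond is ~1.33 Å; 2.0 Å separates
   bonded from broken at any realistic resolution). Breaks inside the
   interface are reported as a `broken-interface` warning because a
   backbone jump across a gap can thread the partner and fake a link;
   detection still runs.
2. **Trimming.** 15 residues removed from each terminus of each chain
   (flexible tails wrap partners without physical meaning). Trimming is
   applied before interface selection, so a tail can neither define the
   contact span nor contribute windows.
3. **Interface selection.** A backbone atom is a contact if its minimum
   distance to any backbone atom of the partner is ≤ D = 10 Å (k-d tree;
   identical to the brute-force all-pairs definition, which the tests
   enforce). Each chain keeps the single contiguous span from first to
   last contact atom, expanded to whole residues, re-indexed 1..N with a
   map back to author numbering. Multiple interface patches therefore
   collapse into one span; no contacts at all yields empty subchains and
   zero links.
4. **Window scan.** Cumulative GLN profile of each subchain against the
   closed partner subchain; windows of length j ∈ [R_b, R_e] = [4, 36]
   atoms at every start; score Δs = |prefix difference|; scores ≥ T_s = 0.8
   mark the middle atom ⌊i + j/2⌋. R_e is clamped to min(N₁, N₂). If the
   best score over both chains falls in [0.9·T_s, T_s), the scan repeats
   once with R_e + 3 (R_e is the most sensitive parameter; the single bump
   smooths threshold effects for windings spread just past the window).
   The rescan recomputes all window lengths; by the subset property of
   longer scans this equals rescanning only the added lengths.
5. **Inference.** Maximal runs of consecutive marked atoms (a gap of ≥ 1
   index splits runs; `merge_gap` can relax this for robustness studies,
   default 0) are individual links. The pair's link count is the larger of
   the two per-chain run counts; a complex of M chains is screened as all
   M(M−1)/2 pairs and called linked if any pair is.

A global diagnostic, the termini-closure GLN of both full chains
(`whole_gln`), is available for comparison with the local result; it is
exactly the quantity whose failure modes (spurious links on wrapped
chains, cancellation of opposite windings) motivate the window scan.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| D | 10 | Å | interface cutoff (backbone atom-to-atom) |
| T_s | 0.8 | – | window |GLN| threshold for marking |
| R_b | 4 | atoms | shortest window (≈ 1.3 residues) |
| R_e | 36 | atoms | longest window (≈ 12 residues) |
| trim | 15 | residues | removed per terminus before selection |
| re_bump / trigger | 3 / 0.9 | atoms / fraction of T_s | one-shot R_e increase on a near miss |
| merge_gap | 0 | atoms | marked-run gap tolerance |

T_s trades sensitivity for specificity: a full winding scores ~1, gradual
wrapping within one window scores well below 0.8. R_e is the geometric
constraint separating tight links from wrapping; detection counts only
windings completed within ≤ R_e atoms.

## Synthetic data

The generators emit protein-like backbone geometry: Cα points at ~3.8 Å
spacing with N and C interpolated onto the Cα polyline (a topology-
preserving refinement), so D = 10 Å behaves as on real structures. Linked
fixtures are built from closed parametric constructions with the closure
arc removed, so detection must succeed without termini closure:

- **hopf / multi_winding(w):** a chain tracks along a strongly bowed arc at
  contact distance and coils 1 (resp. w) full turns around the arc's arm
  at one site. Each turn pierces the closed arc's spanning surface once:
  true link count 1, |whole GLN| ≈ w. The coil radius shrinks automatically
  (7 → 5 → 4 Å) for short chains.
- **cancellation:** two coil sites of opposite handedness on the same arc:
  two genuine local links, whole GLN ≈ 0 (the Whitehead-type failure mode
  of global closure).
- **wrapped_unlinked:** the tracking chain rotates exactly once around the
  arc over its whole length — deeply wrapped, no link — while closing the
  termini yields |whole GLN| ≈ 1 (the global false-positive mode).
- **distant:** no interface.
- **broken_interface:** a wrapped pair with six interior residues deleted
  at the interface, emulating the missing-residue defects that break a
  chain at an interface and can fake links in real structures.

Chains default to 150 atoms (50 residues); Gaussian jitter (`noise_sd`, 0.3
Å in the batch suites) perturbs the Cα path, with self-avoidance at 0.5 Å
enforced by bounded regeneration. What these fixtures do **not** emulate:
side-chain packing, secondary structure, realistic interface shapes,
multi-patch interfaces, or crystallographic pathologies beyond simple
residue deletion. Passing the synthetic suites therefore demonstrates the
correctness of the geometry and of the scanning logic, not field
performance on predicted structures; the CLI exists to run the same
pipeline on real PDB/mmCIF files.

Synthetic curves carry no flexible termini, so the example workflows and
test suites run them with `trim = 0`; the default trim targets real
protein tails.

## Numerical choices

- Segment pairs closer than 10⁻⁹ Å are treated as intersecting: the scalar
  API raises rather than returning garbage; zero-length segments (e.g. a
  closure between coincident termini) contribute 0 with a warning.
  Degenerate cross products in the solid-angle formula are zeroed, which
  returns exactly 0 for coplanar pairs.
- Inner products are clipped to [−1, 1] before `asin`.
- The pairwise Gauss kernel is evaluated vectorized in blocks of 256 focus
  segments to bound memory on large interfaces.
- Ties in altloc occupancy keep the first conformer encountered; parsing
  is otherwise order-independent (tested by record shuffling).
- Everything is deterministic: identical inputs and configuration give
  bit-identical reports, independent of batch worker count.

## Design decisions

- Fragment closure contributes nothing to fragment GLN (see above): the
  prefix-difference identity is taken as the operative definition.
- The adaptive R_e bump triggers on the maximum score over *both* chains
  of a pair (per structure, not per chain) and applies exactly once.
- Interface membership uses backbone atoms only — they are the only atoms
  the model retains, so the interface is defined in the same geometry that
  is scanned.
- Chains are trimmed before contacts are computed.
- A single marked run in one chain and two in the other reports two links
  (the per-chain maximum), with per-chain regions listed verbatim.
- Problem sizes in the validation suites — 150-atom chains, 50 fixtures
  per class, 300–1000 oracle segment pairs — are chosen so the whole suite
  completes in well under a minute while every class is exercised at
  protein-like geometry.

## Limitations

- Link *type* is not classified (Hopf vs Solomon etc.), and no per-link
  sign is reported beyond diagnostics.
- Curves that wind gradually over more than R_e + 3 atoms per turn are
  reported unlinked by design; that is the intended reading of the
  geometric constraint, not a numerical limit.
- Two links lying closer than one atom apart along a chain merge into one
  run.
- Interfaces with several separated patches are spanned by a single
  subchain, which can include long non-contact stretches between patches.
- NMR ensembles are reduced to one model; ensemble-level statements are
  out of scope.
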