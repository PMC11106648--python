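# Methods

## The dissimilarity score

Two chains of identical sequence are compared through their Cα distance
matrices. For chain *a* over modeled residues `R_a`, `D_a[i,j]` is the
Euclidean Cα–Cα distance. Over the common residue set `R_a ∩ R_b` (paired by
reference-sequence numbering — no alignment is computed), the score is

```
GLOCON(a, b) = N( T_τ(|D_a − D_b|) ) · f(a, b)
```

with three choices fixed as follows.

**Noise filter `T_τ`.** Entries strictly below τ are zeroed; entries equal
to τ pass. Default τ = 3 Å. The strict inequality at the boundary is a
convention and is pinned by tests. The filter runs before any averaging.

**Normalization `N`.** Two modes:

- `literal_product` (default): `N` is the plain upper-triangle sum, so the
  score is `Σ_{i<j} filtered[i,j] · f`. Note the double effect of gaps: a
  missing residue removes summands *and* shrinks `f`. For pairs of very
  different coverage this can make a gappy dissimilar pair score below a
  complete similar pair.
- `mean_then_fraction`: `N` divides by the number of summed pairs first
  (upper-triangle mean), then multiplies by `f`. This keeps scores
  comparable across pairs with different coverage.

Both are pure functions selected by `GloconParams.normalization_mode`; the
clustering layer is agnostic. The default follows the plainest reading of
the procedure the score reproduces; the alternative is provided because the
double gap penalty is a real concern on sparsely modeled segments.

**Gap fraction `f`.** `f = |R_a ∩ R_b| / L_segment`, the fraction of the
*segment* interval modeled in both chains. Using the segment length (rather
than either chain's length) makes `f` symmetric in (a, b) and comparable
across all pairs of one segment. `f ∈ (0, 1]`; pairs sharing fewer than
three residues are a hard error (`InsufficientOverlapError`), never imputed.

Corrupt inputs — non-finite coordinates or pairwise distances above
10⁴ Å — abort the affected computation rather than propagating garbage.

## Segmentation

Chains sharing an accession are merged into a segment when their mapped
intervals overlap by at least `min_overlap_fraction` (default 0.8) of the
shorter interval, closed transitively by union-find. 0.8 tolerates
expression-tag trimming while keeping separately expressed N-/C-terminal
domain constructs apart. Sequence identity is taken on trust from the
mapping table, which plays SIFTS's role. One caveat of the
fraction-of-shorter definition: a construct fully nested inside a longer one
always has overlap fraction 1.0 and therefore always merges, at any
threshold.

## Clustering

UPGMA average linkage, implemented in-house so that every tie-break is
specified: among cluster pairs with equal average dissimilarity, the pair
whose (lexicographically smallest member id per cluster) pair sorts first is
merged. Inter-cluster averages are maintained by the Lance–Williams update
`d(k, i∪j) = (n_i d(k,i) + n_j d(k,j))/(n_i + n_j)`, which is exact for
average linkage; the test suite checks equality against a from-scratch
recompute-every-average reference and against scipy's average linkage.

The tree is cut at `c × max(G)` with c = 0.7 by default; merges at exactly
the cut height are kept (threshold inclusive). Cluster labels are 1-based,
ordered by size (ties by smallest member id); each cluster's representative
is its **medoid** — the member minimizing summed dissimilarity to the rest,
ties to the smallest id. Medoid selection is the package's own choice of
representative rule: it is parameter-free and reuses the already-computed
matrix. The 70% default can be overridden per run (`--cut-fraction`); no
automatic per-segment optimization is attempted because no principled
objective for one is established.

Newick export writes ultrametric branch lengths (leaf depth = merge
height / 2), so tree viewers show the usual UPGMA layout.

## Superposition

Rigid superposition is a Kabsch/SVD least-squares fit over **all** common
residues, with the reflection branch corrected to a proper rotation
(det = +1) and collinear point sets rejected. This deliberately differs from
conserved-core superposition engines (GESAMT-style): for hinge or
fold-switch proteins the all-residue RMSD reported here is larger than a
core RMSD would be. The trade-off is a closed-form, exactly testable
procedure; tests verify agreement with an independent quaternion (Horn)
solution to 1e-6 Å and global optimality under random perturbations.

For display, chains are superposed all-vs-reference (the top cluster's
medoid by default): the GLOCON matrix already covers all-vs-all
dissimilarity, and a common frame needs only O(n) transforms.

A predicted model is compared by Kabsch RMSD against each cluster
representative over their common residues; clusters whose representative
shares fewer than three residues with the model are reported as undefined,
not dropped. The arg-min cluster is the model's predicted state.

## Structure I/O conventions

- mmCIF (preferred) and legacy PDB are read via gemmi; output is mmCIF with
  one model per chain (coordinates carry ~1e-3 Å format precision).
- Reference numbering is 1-based with closed intervals; author numbers are
  shifted by the mapping row's offset at extraction time and only then.
- Multi-model files are always reduced to the first model *in file order*
  (the NMR convention), regardless of model numbering.
- Alt-locations: highest occupancy wins, ties to the smallest altloc id.
- Residues without a carbon Cα atom (waters, ligands, calcium ions named
  "CA", backbone-incomplete residues) count as unmodeled.
- Insertion codes cannot be expressed by an integer offset; they are a hard
  error unless an explicit per-residue `(author number, icode) → reference
  number` map is supplied. Failing loudly beats silent misnumbering.
- Chains with fewer than three mapped Cα are rejected ("chain too short").

## The synthetic generator

`fixtures.generate_ensemble` emulates the features the method actually
consumes:

- **Backbone**: an ideal α-helical Cα trace (rise 1.5 Å/residue,
  100°/residue, radius 2.3 Å → consecutive Cα spacing ≈ 3.8 Å). Constants
  are fixed in code; any self-avoiding curve would do, determinism matters
  more than realism.
- **Domain architecture**: a fixed 90° structural bend at the hinge residue,
  shared by every state (`base_bend`, default residue 30, 90°). This matters:
  a dead-straight chain puts the two hinge domains in line, and for collinear
  domains a 30° hinge changes pairwise distances by at most
  `a + b − √(a² + b² + 2ab·cos 30°)` ≈ 3 Å for 45 Å arms — exactly at the
  noise threshold, so the planted signal would vanish by construction. With
  perpendicular arms, the same 30° swing changes cross-domain distances by
  10–20 Å, the scale of real inter-domain motions.
- **States**: rigid rotation of the post-hinge residues about the x-axis
  through the hinge Cα (`apply_hinge`), and/or a local loop translation of a
  few Å (`apply_loop_shift`).
- **Noise**: i.i.d. Gaussian jitter per coordinate (default σ = 0.2 Å),
  seeded. **Gaps**: per-chain missing intervals, which must leave ≥3
  residues and may not swallow an entire hinge flank.

The canonical benchmark (`two_state_spec`) is a 60-residue chain, 5 open +
5 closed copies differing by a 30° hinge at residue 30, σ = 0.2 Å — a
two-state problem a structural biologist would call clearly separated but
not trivial (the jitter is above crystallographic coordinate error, and the
within-state scores are identically zero only because of the 3 Å filter).

What the generator does **not** emulate: side chains, secondary-structure
realism, correlated (domain-breathing) noise, crystal-contact artifacts,
sequence variation, alternate conformers, or the mixed-resolution
heterogeneity of real archive entries. Passing tests therefore demonstrate
the correctness of the machinery — score invariances, clustering and
superposition optimality, gap bookkeeping, determinism — not the field
performance of the 3 Å / 70% defaults on real proteins, which the method's
operators tune per deployment.

## Problem sizes and numerical choices

The test suite and the acceptance script run on 60-residue chains, 10-chain
segments, 20-seed replications and 100-trial oracle comparisons; these sizes
were chosen to exercise every code path (gaps, ties, multi-model files,
failure isolation) while keeping a full run in seconds. Tolerances: rigid
motion invariance and transform recovery at 1e-9 (floating-point exactness
for sums of ~10³ terms), quaternion-oracle agreement at 1e-6 Å, mmCIF round
trips at 1e-3 Å (format precision). Degenerate inputs (collinear point
sets, empty overlaps, zero models) raise typed errors listed in
`glocon.errors`.

## Known limitations

- All-residue RMSD (no conserved-core detection) overstates deviation for
  partially moving structures; it is labelled as such in the outputs.
- `literal_product` normalization lets heavy gapping shrink large true
  differences; prefer `mean_then_fraction` on sparsely modeled segments.
- The 70% cut is global per segment; segments mixing small and large
  motions can hide the small ones inside one cluster.
- Point mutations are invisible: identity is asserted by the mapping table,
  not re-verified from sequences.
- UPGMA is O(n³) as implemented; segments with thousands of chains would
  need the usual nearest-neighbor-chain optimizations.
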