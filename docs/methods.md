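# Methods

## The model

`pathtrace` infers the evolutionary history — presence, gain ("genesis")
and loss — of metabolic pathways on a rooted species/strain phylogeny,
from protein-level similarity searches. The procedure has five stages:

1. **Pathway composition.** A pathway is an ordered set of n member
   enzymes, read from a TSV or extracted from a BioPAX Level 3 document
   (`bp:Pathway` + `bp:ProteinReference` elements). Embedded sequences
   are used when present; otherwise a local FASTA can resolve them.
   Running the similarity search itself (BLAST etc.) is out of scope:
   the package consumes tabular (outfmt 6) output.

2. **Homology matrix.** M_H is the n_enzymes x m_genomes grid where
   h_gij counts the *distinct* subject genes of genome j hit by enzyme
   g_i with e-value ≤ the cutoff (default 1e-6). Repeated HSPs for the
   same (query, subject) pair are deduplicated keeping the best e-value;
   counting genes rather than HSP rows is deliberate, since a single
   homologue often produces several alignments. Self-hits are counted
   like any other hit — source genomes act as positive controls.
   Pangenomes can enter either as pooled search databases (a "genome"
   in the gene map) or post hoc via `aggregate_pangenome`, which adds
   one virtual column per block. The default aggregation is the max
   over member strains: it approximates a search against the
   non-redundant union of the strain proteomes without double-counting
   orthologues shared by strains; `mean` and `sum` are available.

3. **Fuzzy pathway profiles.** f_j = (Σ_i h_gij) / n, the per-genome
   mean homologue count over the pathway's enzymes — an unbounded,
   real-valued likelihood-of-presence score. The denominator is the
   *declared* pathway size, so a pathway enzyme missing from the matrix
   is an error rather than a silent zero: dropping it would bias f_j.
   Discretization: d_j = 1 iff f_j ≥ α. The boundary is inclusive
   (ties at α count as presence). When the user supplies no α, the
   default is the grand mean of all fuzzy cells in the run; a
   per-pathway variant (row means) is available behind a switch. The
   appropriate α depends on the evolutionary spread of the target set —
   tight strain collections need a strict threshold, distant taxa a
   permissive one — which is why α is always logged and overridable.

4. **Ancestral reconstruction.** Each tree node carries a binary state;
   leaves take the discrete profile (virtual pangenome leaves included,
   as ordinary leaves). A single bottom-up pass assigns internal nodes:

   - R1: children uniformly present/absent → parent inherits the state.
   - R2: else, if (potential gains − potential losses) > GAIN and
     presence occurs in ≥ 2 children subtrees → PRESENT.
   - R3: else, if (potential losses − potential gains) > LOSS → ABSENT.
   - R4: else, strict majority of the subtree's leaves; exact tie →
     ABSENT (absence is the conservative completion, since pathway
     absence is the hardest claim to assert).

   "Potential gains/losses" are counted in two modes. `leaf-count`
   (default) uses present/absent leaves of the subtree; `event-count`
   uses maximal uniformly present/absent clades below the node, a
   Dollo-style reading in which GAIN trades independent origins against
   the leaf-level evidence. Defaults GAIN=5, LOSS=2.

   Events are computed afterwards from state differences on edges:
   parent ABSENT → child PRESENT is a GAIN, the reverse a LOSS. There
   is no top-down smoothing pass.

5. **BioPAX output.** States are written back into BioPAX L3 as a
   structured comment, `$$custom comment$$:present` or
   `$$custom comment$$:absent` (exact grammar, xsd:string datatype),
   under the Pathway and/or ProteinReference elements — one annotated
   document per tree node in pipeline runs. Annotation replaces any
   previous flag (idempotent), and stripping flags restores a document
   canonically equal to the input.

## Properties and caveats of the reconstruction rules

Two consequences of the R1–R4 cascade are worth stating plainly,
because they bound what the thresholds can do:

- In `leaf-count` mode the rules are *subsumed by the leaf majority*:
  R2 can only fire when present leaves already outnumber absent ones
  (and then R4 would agree), and symmetrically for R3, so the GAIN and
  LOSS settings cannot change any outcome. Threshold behaviour is only
  observable in `event-count` mode, and there only at nodes where the
  clade-count balance and the leaf majority disagree within the
  threshold window. In practice reconstructions are therefore stable
  across wide ranges of GAIN/LOSS for pathway profiles *and* for
  single-enzyme profiles alike; the package does not reproduce a
  differential threshold-sensitivity between the two (see
  `threshold_insensitivity_win_fraction` in the acceptance output,
  honestly reported near zero).

- **Polarization needs context.** A state flip planted on a clade that
  holds at least as many leaves as its sibling subtree cannot be
  polarized: the rules place the complementary event set (e.g. root
  absent plus a gain, instead of a loss) or hit the tie → ABSENT
  branch. This is why published analyses of this kind include an
  outgroup. The planted-history recovery checks therefore plant events
  only on clades strictly smaller than their sibling context, where the
  single-origin history is identifiable; under that condition recovery
  is exact on noise-free data.

Monotonicity (flipping a leaf 0→1 never demotes any node
PRESENT→ABSENT) is verified exhaustively on small trees in the default
mode. In `event-count` mode a flip can split a maximal absent clade and
shift the clade balance non-monotonically, so the guarantee is stated
for the default mode only.

## Target-set diagnostics

Whether the inference is well-posed depends on the target ensemble.
Two bounded scores on the binarized matrix (cell > 0) quantify this:

- **entropy** = H(q)/1 bit, q the fraction of present cells: 0 for a
  homogeneous matrix, 1 at half present. Measures contrast.
- **segmentation** (gradient entropy): with g_j the Hamming distance
  between adjacent binarized columns and p = g/Σg, the score is
  1 − H(p)/log2(m−1). All variation at one boundary scores 1; variation
  spread evenly scores 0. A fully homogeneous matrix (Σg = 0) is
  defined as one perfect segment and scores 1 — 0 would also be
  defensible; the choice is deliberate and documented here. A
  two-column matrix has a single boundary and scores 1 by convention.

Scattered single genomes give high entropy / low segmentation; a lone
pangenome the reverse; several pangenomes score high on both, which is
the recommended operating regime. The published numeric values of these
diagnostics are not reproduced — the original estimators were never
specified — only the qualitative ordering, which the test suite checks
on simulated ensembles (block layouts beat their column-shuffled
counterparts in ≥ 95% of replicates).

## The synthetic-data generator

`synth` emulates the block structure of real pangenome homology
matrices: strains grouped into genus-level blocks, blocks forming
clades of a caterpillar tree (strains as polytomies, or balanced
subtrees behind a flag), pathways planted present/absent per block.

- Present cells draw Poisson counts with mean `lambda_present`
  (default 3.0 — real matrices show small integers, mostly 0–14),
  thinned by a per-cell `dropout` probability (missed homologues).
- Absent cells carry a spurious single hit with probability `epsilon`.
- Default study shape: 5 blocks x 12 strains, one 6-enzyme pathway.

The planted truth covers every node: a homogeneous subtree takes its
uniform state, any mixed node the majority state over all leaves (tie →
present). This yields exactly one event per maximal minority-uniform
clade — the single-origin semantics that `plant_event` composes one
event at a time. The matrix is realized by drawing a fixed set of
variates per cell and selecting by planted state, so planting an event
leaves all unaffected cells byte-identical and every ensemble is exactly
reproducible from its integer seed.

What the generator does *not* emulate: sequence evolution (counts are
drawn, not aligned), correlated loss across enzymes of an operon,
genome-size effects on hit counts, horizontal transfer between blocks,
and paralogue inflation in specific lineages. Passing tests on these
ensembles show the bookkeeping and the rule algebra are correct under
block-structured noise; they do not validate biological conclusions on
real pangenomes.

## Numerical and interface choices

- Newick parsing is topological: branch lengths and support values are
  read and discarded. Multifurcations are preserved. Duplicate leaf
  names are an error; malformed strings report the offending position.
- A virtual pangenome leaf attaches to the root of the smallest clade
  containing the block's strains; for a single-strain block, to that
  leaf's parent. A name collision with an existing leaf is an error,
  never a silent rename.
- Matrix columns are ordered block-contiguously (blocks in order of
  first appearance), which the segmentation metric requires.
- The homology counter is order-independent and monotone in the e-value
  cutoff; both are property-tested.
- All randomness flows through `numpy.random.default_rng` seeds;
  reruns of any pipeline or simulation with the same config and seed
  are byte-identical (hash-checked in the tests).
- Problem sizes in the test-suite and acceptance script (trees ≤ 12
  leaves for oracle comparisons, exhaustive 2^L enumeration at L ≤ 10,
  100–200 simulation replicates, ensembles up to the 249-strain
  ten-block layout) were chosen so every check completes in seconds
  while still exercising multifurcations, deep caterpillars and all
  rule branches.

## Known limitations

- A single global α for all pathways; taxon-specific thresholds are
  only available as per-run overrides.
- No probabilistic gain/loss model, no horizontal-transfer detection,
  no branch lengths.
- BioPAX support covers Pathway/ProteinReference identity, names,
  embedded sequences and the presence/absence flag; the full object
  model (reactions, stoichiometry, controls) is passed through
  untouched but not interpreted.
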