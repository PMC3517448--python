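# Methods

## Orthology and alignment model

Orthology between a template and a target proteome is operationalized as
the bidirectional best hit (BBH): genes *a*, *b* are called orthologs when
*b* is *a*'s highest-bit-score hit in the target and *a* is *b*'s highest in
the template, both passing the E-value cutoff. BBH assumes mostly 1:1
orthology; with recent duplications it returns at most one pair per gene
(never two), and may return none when paralogs split the reciprocity — this
is intended behaviour, surfaced to the user as a hole rather than guessed.

Alignment scores come from Smith–Waterman local alignment (via Biopython's
`PairwiseAligner`) under BLOSUM62 with affine gaps; a gap of length *L*
costs `gap_open + L·gap_extend` (defaults 11 + L·1, the convention of
protein BLAST). Raw scores are converted with the Karlin–Altschul
statistics `bits = (λS − ln K)/ln 2`, `E = mn·2^(−bits)` using the ungapped
BLOSUM62 constants λ = 0.3176, K = 0.134; the search space *mn* is query
length × total subject residues. These constants slightly overestimate the
significance of gapped alignments; since the pipeline only thresholds and
ranks within one parameterization, this affects the absolute meaning of the
10⁻⁶ cutoff, not orderings. The aligner is a pluggable score backend: any
component producing the same (raw, bit, E) hit records — e.g. a wrapper
around an external search tool — can be substituted without touching the
mapping logic.

Degenerate inputs: sequences must be over the 20 amino acids plus X;
`e_cutoff = 0` yields no hits (E-values are strictly positive); an empty
candidate set is a hole, never an exception.

## Operon-constrained mapping

Each template pathway member's candidate set contains every hit with
E ≤ cutoff whose bit score is within a fraction *f* (default 0.9) of that
member's best bit score, plus its reciprocal BBH partner unconditionally.
The mapper selects at most one candidate per member, maximizing
`Σ bits − λ·(#distinct target operons covered)`, where a gene outside any
operon counts as a singleton operon. λ (default 1.0, bit-score units per
operon) expresses the prior that bacterial pathway genes co-occur in few
transcription units; λ = 0 reduces to independent best hits, large λ can
drop weakly supported members entirely (they are then reported as holes
with their best hit noted). The near-best fraction *f* exists because the
published description of the mapping step states only the maximization
principle; admitting near-best secondary hits is this package's documented
choice, and `f = 1` restricts candidates to best hits and BBH partners.

Instances with ≤ 20 members are solved exactly by depth-first
branch-and-bound (bound: current score plus best remaining bits, charging
no further operon penalty — an admissible relaxation because λ ≥ 0). Larger
instances use best-improvement local search seeded with per-member best
candidates; on random small instances the heuristic is verified to stay
within 80 % of the exact optimum and usually attains it. Ties everywhere
break lexicographically by gene identifier (members processed in sorted
order, candidates best-bit-then-lexicographic, "unmapped" last; the first
optimum found is kept), so results are exactly reproducible.

Two template genes may select the same target gene; the collision is kept,
recorded as two `mapped_from` provenances and a conflict flag — as is a
target gene claimed by several templates at merge time. Conflicts are never
silently resolved: the plain-text model files are meant to be inspected and
edited between stages.

## Expansion

Recruitment is anchored exclusively on *initial* (mapped) entries and is
single-hop: operon mates of initial genes, and genes linked to an initial
gene by a selected association edge type (ppi, coexpression, coevolution,
user) with score ≥ `min_score` (unscored edges always pass; default
threshold 0 because association sources ship without a universal score
scale). Recruits do not recruit further — transitive closure over
association networks is known to flood models with unrelated genes, and
conservatism here is deliberate. A gene reachable via k (source, anchor)
combinations keeps k provenance records but one entry. Consequences tested
as invariants: expansion is monotone, local (every recruit at evidence
distance 1 from an initial gene), idempotent, and additive across channels.
Whether a recruit found via two anchors of the same source type should
deduplicate is not externally specified; this package keeps one record per
(source, anchor) pair.

## Validation and evaluation

Validation marks an entry `validated` iff its gene appears in the supplied
differential-expression list, else `predicted`; it is idempotent and
monotone in the evidence set. Evaluation has two modes:

* **standard** — TP = |predicted ∩ gold|, FP = |predicted \ gold|,
  FN = |gold \ predicted|; precision and recall are undefined (reported as
  NA/None, never 0) when their denominator is 0.
* **paper_literal** — reproduces a published variant whose FP counts
  template genes that were never mapped or whose mapped target is wrong.
  That definition conflicts with the published per-pathway numbers it
  accompanied (a pathway with 11 template genes and 6 mapped is reported
  with FP = 0), so it cannot be reconstructed from gene sets alone; the
  mode therefore also accepts explicit TP/FP/FN counts, and the set-based
  form approximates "mapped template genes" by |predicted|. The standard
  mode is the default; the literal mode exists for comparability and is
  exercised only on counts or synthetic data.

Percentages render integers bare ("75%"), exact tenths with one decimal
("62.5%"), and otherwise round half-up to the nearest integer; summary
averages are arithmetic means of the per-pathway percentage columns, half-up
to integer percent. The bundled 17-pathway *E. coli* → *B. subtilis*
reference table reproduces its published averages (90/76 and 28/87) under
exactly these rules.

## Synthetic data generator

The generator emulates the material of a desk-scale mapping study. Gene
families get i.i.d.-uniform root sequences (length 80–300); each organism
receives a primary copy mutated at the per-copy divergence rate (default
0.15), with optional paralogs mutated again from the primary. Substitution
proposals are drawn proportional to 2^BLOSUM62(a,b), keeping diverged pairs'
bit scores realistic; the default model has no indels (an optional indel
rate exists), so planted pairs keep equal lengths and their identity obeys a
binomial bound along the two branches (≥ 1 − 2d − 3σ). A planted pathway
uses organism 1's copies as the template (chained `pathway` interactions)
and arranges the target copies into `n_operons_for_pathway` operons padded
with non-pathway genes, of which `padding_true_fraction` (default 0.5) are
designated additional true members — these make the gold set strictly
larger than what mapping alone can recover, so the expansion stage has
something real to find. Association edges link gold pairs with probability
`edge_sensitivity` per channel and add decoys from gold to random non-gold
genes at `decoy_rate`; expression lists sample gold at a chosen sensitivity
plus a false-positive rate. Everything derives from one integer seed
(NumPy `default_rng` with per-stage substreams) and is byte-deterministic.

What the generator does *not* emulate: genome rearrangement, horizontal
transfer, compositional bias, indel-rich divergence, realistic operon length
distributions, or correlated noise between evidence channels. Passing tests
on this material therefore demonstrates correctness of the algorithms under
their stated assumptions, not field performance on real genomes.

## Benchmark problem sizes

The self-benchmarks (`orthopath.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) use: 50 proteome pairs of
8 families for BBH symmetry/identity checks; 100 random assignment
instances with 2–12 members and ≤ 4 candidates each, resampled so full
enumeration stays ≤ 50 000 combinations (keeping the brute-force reference
exact); 200 random 25–55-residue pairs against a hand-written Gotoh DP;
20-seed batches of 15-family pan-genomes (6-gene pathways) for parameter
recovery; and 20-replicate batches of 20–24-family studies for the
expansion trade-off (decoy rate 0.3) and end-to-end recall (divergence
0.15, edge sensitivity 0.8, decoy rate 0.1). These sizes exercise every
code path while keeping a full run around a minute on one CPU.

## Known limitations

* BBH-based orthology under-calls in the presence of recent paralogs by
  construction; profile or tree-based methods are out of scope.
* The operon objective treats operon count linearly; no synteny beyond
  operon membership is used.
* Association evidence is binary-or-scored edges; no probabilistic
  integration or ranking of recruits.
* Identifier reconciliation across database namespaces is the caller's
  responsibility (apply an alias table before input).
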