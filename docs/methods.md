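# Methods

## The model

`nuchmm` fits and decodes an alternating two-state semi-Markov (duration
HMM) model of chromatin:

* **Nucleosome state.** Fixed duration of 147 bp.  Emissions follow a
  time-dependent 4th-order Markov chain: `freqN4` is the joint distribution
  of the 4-mer at nucleosomal positions 1–4 (256 entries), and for each
  position t = 5…147 `tranN4[t]` is a 256×4 conditional table
  P(base at t | bases at t−4…t−1).  Position dependence lets the model
  capture rotational (≈10 bp periodic) and translational sequence
  preferences along the histone–DNA interface.
* **Linker state.** Duration d ~ `Pd`, a distribution on 1…500 bp.
  Emissions follow a homogeneous 4th-order chain entered through an order
  ramp — `freqL` for the first base, then `tranL`, `tranL2`, `tranL3`, and
  `tranL4` from the fifth base on — so linkers of any length ≥ 1 bp are
  scorable.
* State alternation is strict; two nucleosomes cannot be adjacent because
  `Pd` has no mass at 0.

The model assumes positioning is driven by sequence composition and linker
spacing only.  It knows nothing about trans-acting factors, remodelers, or
replication/transcription machinery, so predicted occupancy is a statement
about intrinsic sequence suitability, not a literal in vivo prediction.

## Training

Inputs are a genome (FASTA) and a map of *unique* (non-overlapping,
representative) nucleosome dyads.  Genomic regions covered by the 147-bp
footprints of those dyads are nucleosome regions; the uncovered complement,
including chromosome-end flanks, are linker regions.  Rules applied in
order:

1. dyads within 73 bp of a chromosome end are dropped (their footprint is
   incomplete);
2. the coverage partition is formed from the remaining footprints (if the
   user's map contains overlapping dyads, the union is used for coverage and
   every dyad still contributes its own training sequence);
3. nucleosome footprints and linker intervals containing N are dropped from
   the training sequences (Ns are preserved at load so that hard-masked
   genomes can be used);
4. linker *lengths* of 1–500 bp feed `Pd`; linker *sequences* of 7–500 bp
   feed the linker chain; lengths > 500 bp contribute to neither.

Counts are turned into probabilities with an add-one pseudocount per
conditional row (and per joint table), **on by default**: without it, any
5-mer absent from the training data sends an HBA query to −∞.  A
`pseudocount=False` switch exists for exact hand-count checks and for
parameter-recovery experiments.

`tranN4` (across the position axis, per context/base cell) and `Pd` are
smoothed with a 3-window simple moving average and renormalized.  The
default is a **trailing** window — the value at t averages t−2, t−1, t, with
shortened windows at the left boundary — matching the common time-series SMA
convention; a centered variant is available (`sma="centered"`) because the
smoothing flavor is a genuine ambiguity.  `freqN4`, `freqN4S` and the linker
tables are not smoothed.

Training is strand-asymmetric by default (the plus-strand sequence of each
mapped footprint); `augment_revcomp=True` adds reverse complements of the
nucleosome and linker sequences to the sequence models (linker lengths are
unaffected).

Models serialize to a single JSON container of named, dimensioned arrays
plus a version tag and a provenance block (chromosome lengths, retained and
dropped counts, full training configuration).  JSON floats use the shortest
round-trip representation, so save/load is bit-exact.

## HBA and local HBA

For a window with dyad i, `a_i = log P_N(window) − log G_L(window | 147)`,
natural log, reported at the dyad coordinate.  Local HBA computes the same
ratio for thirteen overlapping subsegments A–M (21 or 20 bp; A = positions
1–21, B = 12–31, …, M = 127–147), each spanning two superhelical-location
contact sites shared with its neighbors.  The nucleosome-side probability of
a segment starts from that segment's own joint 4-mer table (`freqN4S`, built
from the 4-mers at the segment's first four nucleosomal positions) and
continues through `tranN4`; the linker-side probability restarts the order
ramp at the segment's first base.  Under i.i.d. emission laws the seven
non-overlapping segments {A,C,E,G,I,K,M} telescope exactly to `a_i`; for
trained models the sum differs from `a_i` only by the six boundary
corrections (joint start table vs chained conditionals, ramp restart vs
continuation), an identity the test suite checks term by term.

Output modes: `raw` (default), `centered` (per-query mean subtracted, the
display convention for profile figures), and `smoothed55` (centered 55-bp
moving average, emulating the MNase-era output convention).

**N policy.** By default any window (or segment) overlapping an N scores as
missing (NaN); `n_policy="uniform"` instead scores N-touching terms as
log(1/4).  The decoder always uses the uniform policy so that decoding is
defined on any input.

## Decoding and boundary conventions

All dynamic programming is in natural-log space with max-shifted
log-sum-exp; no probability-scaling tricks.  Time is O(n·500), memory O(n).

The query may begin and end mid-linker.  An initial linker of observed
length d (0…500) carries the survival weight S(d) = Σ_{k≥d} Pd(k), and
symmetrically for the final linker; S(0) = 1, so the query may start or end
exactly at a nucleosome edge.  Nucleosomes are never truncated — a query
shorter than 147 bp decodes as all-linker.  A linker spanning the *entire*
query is truncated at both ends and carries duration weight 1 (no duration
boundary is observed), which guarantees a legal path for any input length.
No transition weight beyond `Pd` and the emissions is applied.

Two documented consequences:

* nucleosome-free stretches longer than 500 bp cannot occur between two
  predicted nucleosomes (only at query boundaries); an optional geometric
  linker tail is deliberately **not** provided by default to keep the model
  faithful to `Pd`;
* when the nucleosome/linker emission contrast is weak, the all-linker path
  can beat every nucleosome-containing path (each nucleosome must buy back
  its ≈ −log Pd(d) duration cost in emission advantage), so the MAP path may
  legitimately contain no nucleosomes.  Posterior tracks remain informative
  in that regime.

Viterbi ties are broken deterministically in favor of the path whose current
segment starts later.  `P-dyad(j)` is dyad-anchored: the posterior
probability that a nucleosome occupies exactly [j−73, j+73].  Occupancy is
the ±73 bp windowed sum of P-dyad, truncated at the ends.

## Mutation-effect prediction

An edit (1-based position, replaced substring `ref`, inserted string `alt`)
is applied to a plain sequence window; wild-type and edited sequences are
decoded with the same model and paired through a monotone coordinate map
(identity before the edit, shifted by len(alt)−len(ref) after it).
Occupancy deltas are reported in the wild-type frame; inserted positions are
reported separately in the edited frame.  Edits are local by construction:
positions farther than 647 bp (max linker + nucleosome) from the edit are
unaffected beyond numerical noise.

## Evaluation protocol

Predicted nucleosomes are the maximal 147-bp N runs on the Viterbi path
(dyad = run start + 73).  Matching is many-to-one and per chromosome: each
predicted dyad is judged against its nearest reference dyad, and a
prediction matches at window w if that distance is ≤ w bp; rates are pooled
over all predictions and are non-decreasing in w by construction.  Reported
rates are rounded to one decimal in percent.  For dense maps,
`select_top_by_density` keeps the ⌊genome length / target density⌋
highest-scoring dyads (ties broken by coordinate); genome length is the sum
of loaded chromosome lengths with no gap exclusion.  Unique-nucleosome
enrichment is (unique rate / redundant rate) / (unique count / redundant
count).

## Synthetic fixtures

`fixtures.random_model(spec)` builds a valid model whose nucleosome/linker
divergence is controlled by `spec.divergence` ∈ [0,1]: 0 gives identical
laws (HBA ≡ 0), 1 gives disjoint preferred bases (G/C-favoring nucleosome
laws, optionally with a 10-bp rotational modulation of the A/T share, vs
A/T-rich linkers) plus per-row jitter that scales with divergence.  `Pd` is
a negative binomial (default mean 25 bp, dispersion 3 — a typical yeast-like
linker-length scale) shifted to support 1…500.  `fixtures.simulate` draws
the alternating process up to the requested length through a single seeded
`numpy` `default_rng`; outputs are a pure function of (seed, spec), and a
final truncated segment is excluded from the truth map.  At mid divergence
(0.5) the mean HBA at true dyads is ≈ 8.5 nats, comparable to a strongly
positioned promoter nucleosome, so fixture conditions represent strong
positioning signal rather than an easy caricature.

The generator produces exactly the data the decoder assumes: no mapping
noise, no missed or spurious dyads, no cleavage bias, no repeats, no
trans-acting factors.  Passing fixture tests therefore demonstrates
correctness of estimation and decoding under the model's own assumptions —
not prediction accuracy on real chromatin.

## Verification and problem sizes

* The decoder (Viterbi score and path, total likelihood, P-dyad) is checked
  against exhaustive enumeration of all legal segmentations on random
  instances up to ~440 bp (tolerance 1e-8).
* Affinity scoring is checked against closed forms under i.i.d. laws (e.g.
  147·ln 0.625 ≈ −69.09 for an all-A query with P_L(A) = 0.4), against an
  independent per-base accumulation oracle, and via the exact telescoping
  and boundary-correction identities.
* Parameter recovery uses 50,000 simulated nucleosomes: the count-weighted
  mean per-row total-variation distance of `tranN4` and the TV distance of
  `Pd` are both required to be < 0.05 with smoothing and pseudocounts off.
  (Weighting rows by observed context counts measures recovery where data
  exist; unweighted means over never-visited contexts would measure the
  pseudocount policy instead.)
* End-to-end runs (simulate → train → decode → evaluate) use 50–120 kb
  chromosomes, large enough for a few hundred nucleosomes while keeping the
  full suite fast on one CPU.
* For the divergence-monotonicity check ({0.2, 0.5, 0.9}) the match rate of
  an empty prediction set is taken as 0 — at divergence 0.2 the MAP path
  contains no nucleosomes (see the all-linker note above), which is the
  correct degenerate limit, and the rate then rises with divergence.

## Rebuilding published species models (offline recipe)

Re-deriving the published chemical-map models requires external downloads
and is not part of the test suite.  The recipe: download a reference genome
(e.g. budding yeast sacCer3) and the corresponding chemical-map unique-dyad
table; convert the table to the package's TSV (chromosome, 1-based dyad
position, NCP score); run `nuchmm train --genome genome.fa --dyads
unique.tsv --out model.json`.  At genome scale the training rules above
reproduce the published region bookkeeping (end-rule and N-rule drops,
7–500 bp linker filter).  Genome-wide matching experiments then follow the
evaluation protocol with `nuchmm predict`/`evaluate`, using
`select_top_by_density` for dense redundant maps.

## Known limitations

* Occupancy in dense arrays is dominated by packing (the `Pd` spacing
  constraint) and can mask local sequence effects; mutation-effect analyses
  are most informative around isolated, strongly positioned nucleosomes.
* The linker chain cannot represent nucleosome-free regions longer than
  500 bp in the query interior.
* HBA values are comparable within a model, not across differently trained
  models.
* The N policy is an extension; reference implementations of this model
  family assumed N-free inputs.
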