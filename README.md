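# nuchmm — duration-HMM nucleosome positioning from base-pair-resolution dyad maps

`nuchmm` predicts nucleosome positioning along arbitrary DNA sequences with a
duration hidden Markov model (dHMM) whose parameters are trained from a
genome plus a base-pair-resolution nucleosome **dyad map** (for example an in
vivo chemical-cleavage map), rather than from MNase-seq coverage.  It is
aimed at chromatin researchers who want to

* train positioning models from their own dyad maps,
* decode Viterbi nucleosome positions and posterior dyad/occupancy tracks,
* score the suitability of any 147-bp sequence for nucleosome formation
  (histone binding affinity, HBA) and of its 13 subsegments (local HBA), and
* predict the effect of insertions/replacements on nucleosome positioning.

## Model

The generative model alternates two states along the genome:

* a **nucleosome** state of fixed duration 147 bp whose emissions follow a
  time-dependent 4th-order Markov chain: `freqN4`, the joint law of the
  4-mer at nucleosomal positions 1–4, and `tranN4[t]`, position-specific
  tables P(base at t | preceding 4-mer) for t = 5…147;
* a **linker** state whose duration d is drawn from `Pd` on 1…500 bp and
  whose emissions follow a homogeneous 4th-order chain with an order ramp
  (`freqL`, `tranL`, `tranL2`, `tranL3`, `tranL4`).

The histone binding affinity of the 147-bp window centered at dyad i is the
natural-log likelihood ratio

```
a_i = log [ P_N(x_{i-73}, …, x_{i+73}) / G_L(x_{i-73}, …, x_{i+73} | 147) ]
```

and the local HBA `l_i` applies the same ratio to each of thirteen
overlapping 20–21 bp subsegments A–M of the window (A = nucleosomal
positions 1–21, B = 12–31, …, M = 127–147), each spanning two
superhelical-location contact sites.  A negative `a_i` on its own carries no
meaning — nucleosome and linker training sequences never overlap — so no
operation thresholds HBA at zero.

Decoding is exact semi-Markov dynamic programming in log space: Viterbi for
the MAP segmentation (every predicted nucleosome is exactly 147 bp) and
forward–backward for `P-dyad(i)` (posterior probability that a dyad sits at
i) and occupancy (posterior coverage, the ±73 bp windowed sum of P-dyad).

**Coordinates are 1-based and inclusive at both ends everywhere.**  A dyad at
position p implies the footprint [p−73, p+73]; convert 0-based BED starts
with `seqio.bed_start_to_dyad_pos`.

## Worked example

Simulate a 50-kb chromosome from a known model, re-train from the simulated
genome + dyad map, decode, and evaluate against the truth:

```sh
nuchmm simulate --seed 7 --length 50000 --divergence 0.8 --out-prefix demo
# simulated 50000 bp, 291 nucleosomes
nuchmm train --genome demo.fa --dyads demo.dyads.tsv --out demo.trained.json
# n_nucleosomes: 291 ... n_linkers: 292
nuchmm predict --model demo.trained.json --seq demo.fa \
    --out demo.pred.tsv --dyads-out demo.pred_dyads.tsv
# 291 Viterbi nucleosomes; loglik -63108.5
nuchmm evaluate --pred demo.pred_dyads.tsv --ref demo.dyads.tsv
```

The evaluation table reports the fraction of predicted nucleosomes whose
dyad lies within ±w bp of the nearest true dyad, for w = 0…9:

```
w	matched_fraction
0	0.649485
1	0.848797
2	1
```

so 65% of the 291 predicted dyads sit exactly on a true dyad, 85% within
1 bp, and all within 2 bp — the curve is non-decreasing in w by
construction, and its step from w=0 to w=1 reflects rotational (helical
phase) precision.  `demo.pred.tsv` holds one row per position:

```
pos	pdyad	occup	viterbi	hba
159	0	1	1	-0.789952
160	0	1	1	-0.839512
```

(`viterbi` is 1 inside predicted nucleosomes; `hba` is reported at the dyad
of each 147-bp window and is `NA` within 73 bp of the sequence ends or where
the window overlaps an N.)

Affinity scoring and mutation-effect prediction work on plain sequences:

```sh
nuchmm hba      --model demo.trained.json --seq query.fa --mode centered
nuchmm localhba --model demo.trained.json --seq query.fa --png local.png
nuchmm mutpredict --model demo.trained.json --seq wt.fa \
    --pos 200 --alt AAAAAAAAAA --out paired.tsv
```

The same functionality is available as a library (`nuchmm.train`,
`nuchmm.predict`, `nuchmm.compute_hba`, `nuchmm.compute_local_hba`,
`nuchmm.predict_edit`, …); see `docs/methods.md` for the full model
description and design choices.

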