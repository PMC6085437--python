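# Methods

This note documents the models and procedures `bfscan` implements, the
parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## The screening model

A bifurcating (Bf) enzyme complex is called from three nested filters,
each of which can be satisfied or fail independently:

**Homology thresholds.** Each subunit role has one or more bait
sequences and a maximum E-value.  The internal backend computes
Smith–Waterman local alignments (BLOSUM62, BLAST-convention gaps 11/1)
with Biopython's C aligner and converts scores to a Karlin–Altschul
style expectation `E = K·m·n·exp(−λS)` with `K = 0.041`, `λ = 0.267`
(the canonical gapped BLOSUM62-11-1 constants — configuration, not
fitted values), `m` the bait length and `n` the residue count of the
searched proteome.  Search scope is per genome, so E-values are
comparable within a run; the scope is configurable (`database_size`)
because pooled-database searches rescale every E-value by the pool
size.  Hits are one-way (bait → proteome), deduplicated to the best E
per (protein, role).  A protein may carry several candidate catalytic
roles after thresholds (the HydA/HytA/HylA and FdhA/FdhF2 families are
genuinely cross-matching); disambiguation is deliberately deferred to
the motif screen and gene context.  Alternatively, HMMER3
`--domtblout` files from an external phmmer run are parsed
(full-sequence E-value column), giving identical downstream behavior.

**Motif screens.** Motifs are short contiguous patterns (grammar:
uppercase = required residue, `x` = any, `xN` = N-fold run, lowercase =
weakly conserved).  They are scanned on unaligned sequences: because
the patterns are contiguous, a multiple alignment would anchor their
position but not change their content, so direct scanning is
equivalent and dependency-free; a generator test plants motifs in
arbitrary flanking context to confirm position-independence.  Lowercase
positions (the `cc` in `AYDPCccCATH`) are required by default
(`strict`); `wildcard` relaxes them and can only ever match more, never
fewer, sequences.  Roles whose screens are published only by citation
(NfnS/NfnL, MetF) ship with empty motif sets that pass everything and
log prominently; users can supply their own patterns in the motif
config.  A protein ambiguous after screening (e.g. HydA vs HytA, which
share all three L-motifs) keeps both candidates.

**Gene context.** Windows count annotated ORF ranks on one replicon —
never base pairs, never strand (operon membership in the source data is
defined by ORF counts, and strand is not part of the published
criteria).  `ALL` windows (the HdrABC partners of Mvh, Fdh, Met) accept
any replicon.  A catalytic gene satisfying every required clause is a
bifurcating call; one failing context is recorded as a non-bifurcating
homolog, which is the denominator of the "fraction bifurcating"
summaries.  When one gene is catalytic-eligible for several complexes
the complex with the most co-localized required companions wins; ties
go Hyt > Hyl > Fdh among the formate-dehydrogenase complexes and to
rule order otherwise.  A catalytic gene joins at most one call;
companion genes are shareable across calls (one EtfAB pair can serve
Bcd and Ldh) — except HdrABC, which is inventoried (below).  A
non-bifurcating bookkeeping call whose catalytic gene already serves as
a companion inside a bifurcating call (FdhA inside a called Hyt operon)
is suppressed rather than double-reported.  The optional HydD subunit
of tetrameric Hyd is recorded when present within the Hyd window but
never required; since no threshold is published for it, it uses HydB's
(both are FeS-cluster companions of the same complex).

**Hdr2 accounting.** Stand-alone heterodisulfide reductase cannot be
called by flanking windows because HdrA is typically not co-localized
and multiple HdrABC copies per genome are common.  Instead the HdrA/B/C
hit inventory is counted: one complete set is reserved for the union of
the genome's called Mvh/Fdh/Met complexes (`shared`, the default —
MvhAG and FdhAB compete for the same MvhD/Hdr module, so one module can
plausibly serve all partnerships) or one per call (`per_complex`, the
conservative alternative, exposed as a flag).  Leftover complete sets
whose HdrB and HdrC genes are mutually within ±2 ORFs become
bifurcating Hdr2 calls.  A genome with a called partner complex but no
complete Hdr set is impossible by construction and asserts.

**Metagenome mode** works per contig: Mvh requires only co-localized
MvhAGD, Fdh only FdhAB, Met only MetF+MetV+MvhD (their Hdr partners are
assumed to be encoded in the same source genome, which cannot be
verified across contigs), Hdr2 is never assessed, and any `ALL` window
of a remaining complex is restricted to the contig.  Split operons
yield non-bifurcating bookkeeping calls on the catalytic contig.

## Statistics

- **Co-occurrence**: the hypergeometric ("probabilistic") model.  With
  complex 1 in `n1` of `N` genomes and complex 2 in `n2`, the joint
  count under independence is `P(j) = C(n2,j)·C(N−n2,n1−j)/C(N,n1)`;
  `p_lt`/`p_gt` are the inclusive lower/upper tails and verdicts are two
  one-sided tests at α = 0.05 with no multiplicity correction.  Pairs
  with single-point support are random by definition.  The default
  site set is genomes with ≥ 1 call (row filtering is exposed, since
  including empty genomes inflates `N` and every positive verdict).
- **p-distance**: mismatches over comparable columns, pairwise deletion
  of gapped columns (the common default for protein p-distances;
  complete deletion is available).
- **Mantel**: one-sided (positive association), Pearson r over the
  condensed upper triangle, joint row/column permutations of the second
  matrix, `p = (1 + #{r* ≥ r}) / (1 + n_perm)`; for n ≤ 6 an exact mode
  enumerates all n! relabelings.  Comparisons use a 1e-12 floating
  tolerance on r so exact ties count as exceedances.
- **Greedy identity binning**: longest-first incremental clustering;
  a sequence joins the first cluster whose representative it matches at
  ≥ 60% global identity (matches / alignment columns), else founds a
  new cluster.  Deterministic by construction (length, then lexical
  tie-break) so results do not depend on input order.
- **Abundance**: bifurcating calls per assembled Mbp (a flag adds
  non-Bf calls for sensitivity analysis); environment groups come from
  an ordered keyword map over free-text metadata with a built-in depth
  rule (marine sediments are subsurface only when stated > 1 m below
  sea floor); surface/subsurface contrast uses Welch's two-sided
  t-test (scipy, Welch–Satterthwaite df).
- **Diversity**: all-pairs search E-values transformed `t = −10⁴·E`
  (strictly monotone, sign-reversing), summarized by median/IQR; the
  reference-side residue total is the E-value database size.

## Synthetic data: what it emulates and what it does not

The generator plants operons that satisfy the shipped windows and
motifs exactly, with three ablation types that each violate exactly one
clause: `drop_subunit`, `out_of_window` (the gene exists ≥ 11 ORFs
away, beyond every window), and `motif_ablate` (motif regions rewritten
until no match; partial ablation of the L-motifs is allowed and
correctly yields *no* call, since HylA resolution needs all three
absent).  Planted proteins are point-mutated bait copies — no indels by
default, so internal E-values remain analytically predictable — with
motif positions excluded from mutation, so a planted bifurcating item
keeps its motif content at any rate.  Hyd-family and FdhA/FdhF2 baits
share backbones (~25% mutated, motifs ablated where required) so
paralog cross-hits and their disambiguation are exercised exactly as in
real data.  Filler genes are random sequences screened against every
bait at a conservative database size (n = 1000, smaller than any
generated proteome, hence strictly harder to pass) and resampled if any
role threshold could fire; this makes "fillers hit nothing" a generator
guarantee rather than a probability.

The default study set (21 genomes, ~320 genes) covers all 12 complexes
as bifurcating items, every ablation type, the Hdr2 leftover
constructions and the shared-EtfAB genome.  Metadata (oxygen class,
environment keywords, assembly Mbp in 2–6) are assigned
deterministically.  Metagenomes are produced by splitting replicons at
ORF boundaries with geometric contig lengths (default mean 12 genes;
the truth table is recomputed per contig under the relaxed rules).
Co-evolution test beds build two alignments sharing a fraction
`shared_signal` of columns (one divergence realization) with the rest
evolved independently, so the two p-distance matrices are exactly equal
at signal 1 and independent at 0.

What the generator does **not** emulate: real amino-acid composition
and domain architecture (fillers are i.i.d. uniform residues; real
proteomes contain genuinely homologous paralog families beyond the two
built-in ones), indels and fragmentary gene calls, pseudogenes,
horizontal transfer, or phmmer's exact E-value model.  Passing the
planted-truth tests therefore demonstrates that the rule logic,
screens, windows and accounting are implemented correctly — not that
the shipped thresholds would achieve the same precision/recall on real
genomes, where threshold choice is the empirical burden.

## Problem sizes and numerical choices

Tests and the acceptance script run the full study at 21 genomes /
~320 genes (one CPU, a few minutes end to end), 1000 null matrices for
the co-occurrence calibration at N = 100 genomes with 0.5 marginals,
500 null and 200 power replicates for Mantel (n = 10 taxa × 120
columns and n = 20 × 200 respectively, 199/999 permutations) — sizes
chosen as the smallest at which the calibrations are statistically
meaningful.  E-values are floored at the smallest positive double so
they stay strictly positive; degenerate inputs (empty sequences,
zero-variance Mantel matrices, singleton diversity sets, zero
comparable p-distance columns, both-groups-constant Welch) raise typed
errors rather than returning NaN.  All randomness flows from explicit
`numpy` generators seeded per call; no global RNG state is touched.

## Known limitations

- The internal E-value is a calibrated convenience, not a phmmer
  replica; absolute E-values differ between backends even though both
  recover planted truth (a test verifies backend agreement of the hit
  sets on planted data against a real phmmer run).
- Nfn and Bf-MetF motif screens are pass-through until users supply
  patterns; on real data this means those calls rest on thresholds and
  context alone.
- Hdr2 accounting reserves whole HdrABC sets; it does not attempt to
  resolve which physical copy serves which partner complex, and in
  metagenomes Hdr2 is not assessed at all.
- Multi-replicon `ALL` windows accept plasmid-encoded partners; there
  is no distance or replicon-type weighting.
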