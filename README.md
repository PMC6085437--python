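# bfscan

Screening genomes and metagenomes for flavin-based electron-bifurcating
(Bf) enzyme complexes, with the downstream comparative statistics.

## The scientific problem

Flavin-based electron bifurcation couples an exergonic and an endergonic
redox reaction at a protein-bound flavin, letting anaerobes reduce
low-potential ferredoxin and squeeze extra energy out of reactions near
thermodynamic equilibrium.  Twelve enzyme complexes are biochemically
confirmed to bifurcate (the NAD(H)- and NADP(H)-dependent
[FeFe]-hydrogenases Hyd and Hyt, the [NiFe]-hydrogenase/heterodisulfide
reductase Mvh, the Hdr-linked and NAD(H)-dependent formate dehydrogenases
Fdh and Hyl, the transhydrogenase Nfn, the electron-transfer-flavoprotein
complexes Fix, Bf-Bcd, Car and Bf-Ldh, the stand-alone heterodisulfide
reductase Hdr2, and the methylene-H₄F reductase complex Met).

A catalytic-subunit homolog alone does not imply bifurcation: the same
oxidoreductase usually has abundant non-bifurcating paralogs.  `bfscan`
implements the genomic screen that separates the two:

1. **Homology search** — representative bait sequences per subunit role,
   with an empirically chosen per-role E-value cut-off that demarcates Bf
   subunit homologs from their closest paralogs (e.g. HydA at 2e-20,
   MvhA at 1e-90, MetV at 0.1).  Either an internal Smith–Waterman
   backend with a Karlin–Altschul style E-value
   `E = K·m·n·exp(−λS)`, or parsed HMMER3 `--domtblout` output from an
   external phmmer run.
2. **Motif screen** — contiguous active-site motifs scanned on the
   unaligned sequence: L1/L2/L3 (`TSCCPxW`, `MPCxxKxxE`,
   `ExMACxxGCxxGGGxP`) required for HydA/HytA and required-absent for
   HylA; `ICGxCxxxH` and `AYDPCccCATH` for MvhA; the cysteine signature
   `CxxCxxCx26C` required for FdhA and required-absent for FdhF2.
3. **Gene-neighborhood calling** — companion subunits must lie within
   per-complex ORF windows of the catalytic gene (e.g. HydB/HydC within
   ±5 ORFs), or anywhere in the genome for the remotely encoded HdrABC
   partners of Mvh/Fdh/Met.  Catalytic genes passing thresholds and
   motifs but failing context are recorded as non-bifurcating homologs.
   Stand-alone Hdr2 is called only from HdrABC copies left over after
   the genome's Mvh/Fdh/Met partnerships are accounted for.  Metagenome
   mode works per contig with relaxed complements (MvhAGD, FdhAB,
   MetF+MetV+MvhD; Hdr2 is never assessed).
4. **Statistics** — hypergeometric pairwise co-occurrence of complexes
   across genomes; Mantel tests on subunit p-distance matrices
   (co-evolution); greedy 60%-identity homolog binning; per-Mbp
   abundance by environment group with a surface/subsurface Welch
   t-test; pairwise E-value diversity with the `t = −10⁴·E` transform.

Because the original genome/metagenome corpora are not redistributable,
the package ships a first-class synthetic-data module that plants
operons with known ground truth (correct complements and motifs,
plus single-clause violations) so every stage is testable end to end.
The shipped baits are synthetic stand-ins generated deterministically
(`data/baits_synthetic.fasta`); point `--baits` at real representative
sequences for production use.

## Worked example

```bash
bfscan simulate --out demo --seed 1          # 21 synthetic genomes + truth.tsv
bfscan run-all --input-dir demo --out results --seed 1
```

The run prints a stage funnel and writes TSV artifacts:

```
INFO bfscan.pipeline: loaded 21 genomes (323 genes)
INFO bfscan.pipeline: search: 108 hits passed thresholds, 95 survived motif screens; 21 calls
pipeline complete: results
```

`results/calls.tsv` holds one row per call, e.g. (abridged):

```
genome_id        complex  bf_flag          catalytic_gene         members                              missing
G00_Hyd_bf       Hyd      bifurcating      G00_Hyd_bf_chr_002     HydA=..._chr_002;HydB=..._chr_003;HydC=..._chr_004
G12_Hyd_dropB    Hyd      non_bifurcating  G12_Hyd_dropB_chr_002  HydA=..._chr_002;HydC=..._chr_003    HydB
```

and `results/summary_bf_fraction.tsv` the per-complex percentage of
catalytic homologs in bifurcating context:

```
complex  n_bf  n_non_bf  pct_bf
Hyd      1     2         33.333333333333336
Hyl      1     1         50.0
Mvh      2     1         66.66666666666667
```

Two of the three Hyd catalytic homologs are planted violations (a
dropped HydB and a HydB displaced beyond the ±5 window), so one third
of Hyd homologs — exactly the planted bifurcating operon — survive the
full screen; the planted motif-less HydA copy correctly surfaces as the
non-bifurcating Hyl homolog instead.  `results/cooccur.tsv` scores every complex
pair against the hypergeometric null, and `results/abundance.tsv` gives
per-genome bifurcating calls per assembled Mbp with the
surface/subsurface environment class.

Feature tables are accepted as GFF3 (CDS features with
`ID`/`protein_id`) or the canonical 6-column TSV
(`genome_id  replicon_id  gene_id  start  end  strand`); coordinates are
1-based inclusive, and all neighborhood logic counts annotated ORFs,
never base pairs.  The environment keyword map (groups: groundwater,
deep subsurface, hydrothermal vents/springs, subsurface sediments,
deep marine sediments → subsurface; saline, surface water, soil, other →
surface) is editable config (`data/env_groups.json`).

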