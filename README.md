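# ice-scout

Detection and classification of **integrative conjugative elements
(ICEs)** in annotated bacterial genomes.

ICEs are mobile genetic elements that sit integrated in the host
chromosome, excise, circularize, and transfer themselves by conjugation
through a type IV secretion system (T4SS).  They carry industrially and
clinically relevant cargo, yet — unlike plasmids — are easy to miss in
genome annotation because nothing about a single gene says "this is part
of a mobile element".  What does give them away is *gene-cluster
geometry*: five lifecycle functions that every self-transmissible
element of this kind needs, encoded close together.

`ice-scout` is for comparative genomicists who want a reproducible,
scriptable version of that logic: find candidate elements, derive their
conserved gene repertoire, classify them into families, and ask whether
a conjugation cluster is ICE- or plasmid-derived.

## Method

1. **Detection.** Each proteome is scored against profile HMMs for five
   functions — tyrosine recombinase (*int*), muramidase, VirB4 ATPase,
   relaxase (*mobT*), coupling protein (*tcpA*) — with presence called
   on curated bit cutoffs (gathering-cutoff convention).  Every relaxase
   hit seeds a ±100 kbp window; a candidate ICE is called when ≥ 4 of
   the 5 categories co-localize in the window.  The conserved core
   region is delimited by the integrase and coupling-protein genes and
   checked for the canonical order *int* ≺ *mur* ≺ *virB4* ≺ *mobT* ≺
   *tcpA*.
2. **Core genes.** Reference-ICE ORFs are matched into every candidate
   by Smith–Waterman (BLOSUM62, 11/1); members need > 35% identity over
   > 80% reference coverage, and families kept are those present in
   ≥ ⌈0.833·N⌉ of the N elements.  Short-but-matching genes are flagged
   as truncations, not absences.
3. **Clades and families.** Per family: MAFFT alignment → uncorrected
   p-distances → neighbor-joining tree → algorithmic clade cut → one
   profile HMM per clade, validated by requiring every member to beat
   every cross-clade member by a 10-bit margin (within-clade scores
   leave-one-out).  The per-ICE vector of clade labels then groups the
   elements into families by marker-gene agreement.
4. **VirB4 origin.** Labelled ICE- and plasmid-derived VirB4 sets give
   origin HMMs with *stringent* cutoffs (poorest leave-one-out training
   score), classifying query ATPases as ICE, plasmid, ambiguous, or no
   call — the basis for cross-species host-range scans.

A synthetic-data module generates annotated genomes with planted ICEs
(canonical gene order, 12–21 kbp spans, cargo insertions, truncations,
strand mirroring, isolated decoy genes) and a ground-truth manifest, so
the whole pipeline is testable end to end without downloads.  See
`docs/methods.md` for the full model description and parameter
rationale.

## Worked example

```bash
python examples/01_detect_ices.py
```

```
planted ICEs: 2, detected candidates: 2
  ice_id  region_length_bp  region_orf_count
SYN001_1             19691                31
SYN008_1             17499                28
```

Ten synthetic genomes carried two planted ICEs; both (and nothing else —
the scattered decoy function genes never reach four categories in any
window) are recovered, with the integrase-to-coupling span and ORF count
of each element.  `examples/02_core_genes_and_families.py` continues
into core-gene families and family assignment, and
`examples/03_virb4_origin.py` shows the VirB4 origin classifier making a
call on a held-out ICE-derived ATPase and refusing one on a shuffled
decoy.

The same functionality is scriptable from the shell:

```bash
ice-scout simulate --seed 7 --n-genomes 20 --out data/
ice-scout detect --genomes data/genomes --hmms hmms.yaml --out results/
ice-scout all --config run.yaml --out results/
```

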