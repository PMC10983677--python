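# Methods

`ice-scout` detects integrative conjugative elements (ICEs) in annotated
bacterial genomes from the co-localization of five lifecycle functions,
derives the conserved core-gene repertoire of the detected elements,
classifies them into families from clade-discriminating profile HMMs,
and separates ICE-derived from plasmid-derived VirB4 conjugation
ATPases.  This note records the model, the tunable parameters with their
defaults and rationale, the synthetic benchmark, and the numerical
choices a maintainer needs to know.

## Profile HMMs and scoring

All homology detection runs on protein profile HMMs (plan7-style match /
insert / delete architecture, 20-letter emissions per match state).
Profiles are read and written in the HMMER3 text format — the files this
package writes are accepted by HMMER 3.4 — with a `GA` line mapped to a
curated presence cutoff in bits, following the gathering-cutoff
convention of curated protein-family databases.

Scoring is **local/local Viterbi**: an alignment may enter and exit the
model at any match state against any subsequence of the query, with
entry and exit free, and the bit score is the log2 odds of the best path
against an i.i.d. background (Robinson–Robinson amino-acid frequencies).
A fully conserved one-state model therefore scores `log2(1/b_a)` on its
consensus residue `a`.  The recursion is exact and is verified against
exhaustive path enumeration on small instances in the test suite; a
numba kernel accelerates the O(L·M) dynamic program, with a pure-numpy
fallback that computes identical scores.  Ambiguous residues (B, J, Z,
X, U, O) emit the background and contribute zero log-odds.  Forbidden
transitions receive a large finite penalty rather than −∞ so that the
delete-run cumulative-sum trick never forms `inf − inf`.

Profiles built from alignments use maximum likelihood with a
background-mixture pseudocount: columns with gap fraction < 0.5 become
match states, match emissions are `(count + w·20·bg) / (n_obs + w·20)`
with weight `w = 0.1`, insert emissions equal the background, and
transitions are counted from each row's state path with the analogous
per-option pseudocount.  This is deliberately simpler than Dirichlet
mixture priors: it is closed-form testable, and at the divergences the
pipeline operates on, emission sharpness is not the limiting factor.

**Presence decisions use bit scores only.**  E-values are available via
an explicit Gumbel calibration (scale fixed at λ = ln 2 per bit;
location fit by the method of moments, μ = mean − γ/λ, on
length-matched residue shuffles of the query set; E = database size ×
tail probability) but never gate any decision, because curated bit
cutoffs are portable across database sizes while E-values are not.

## Detection by co-localization

Every gene of a genome is scored against every profile of the five
function categories — tyrosine recombinase (integrase), muramidase,
VirB4 ATPase, relaxase (MobT), coupling protein (TcpA).  Multiple
profiles per category are OR-combined and only the best-scoring profile
is kept per (gene, category).  A gene may pass two categories; it counts
toward both and a warning is logged.

An ICE transfers as one contiguous element, so its functions must
co-localize.  Each relaxase hit seeds a window of ± `window_bp`
(default 100 000 bp) around its gene midpoint on its own contig —
distances are midpoint-to-midpoint, insensitive to gene length — and a
candidate is called when hits for at least `min_categories` (default 4)
of the 5 categories fall inside.  Candidates sharing any member gene are
merged (union of members, leftmost relaxase as seed), so tandem
relaxases in one element give one call while genuinely separate elements
in the same genome stay distinct.  The windowed algorithm is checked
against a brute-force distance oracle in the tests.

The conserved core region is delimited by the outermost coordinates of
the integrase and coupling-protein genes (the two boundary functions);
orientation is *forward* when the integrase is leftmost.  The synteny
check asks whether, after orientation normalisation, the best-scoring
gene of each present category follows the canonical order
integrase ≺ muramidase ≺ virB4 ≺ relaxase ≺ coupling.

## Core-gene families

Families are anchored on the ORFs of a reference ICE (auto-selected as
the first candidate carrying all five functions with a delimited region,
or set explicitly).  For each reference ORF, the best Smith–Waterman
match (BLOSUM62, gap open 11 / extend 1) among each ICE's core-region
genes becomes that ICE's member when it exceeds `min_identity` (default
35%, identity counted over all alignment columns including gaps) and
`min_coverage` (default 80% of the reference protein length).
"Similarity" is read as percent identity — the stricter, reproducible
interpretation; a positives-based reading would be tool-dependent.
Families present in at least `ceil(min_presence_frac · N)` of the N
detected ICEs are retained (default 0.833, which makes 30 of 36).  The
five function genes take their literature names (int, mur, virB4, mobT,
tcpA); the rest are numbered positionally (`L.ICE_CG1..`).

Truncations: a region gene that matches the reference well over its
aligned span but covers less than 80% of it — and spans at least half of
its own length, to exclude spurious short local matches — is recorded as
*present but truncated* rather than absent.  Truncation is additionally
judged against the **median member length** of the family: if the
reference ORF is itself a fragment, full-length members would otherwise
pass its (short) coverage bar and genuine fragments would go unflagged.

## Clading and clade-HMM validation

Per family, full-length members are aligned (MAFFT, deterministic
default mode; already-rectangular inputs skip the aligner), pairwise
uncorrected p-distances are computed over mutually non-gap columns, and
a neighbor-joining tree is built (canonical Q-criterion and branch
lengths; ties broken on the lexicographically smallest label pair;
negative branch estimates clamped to zero with a log warning).  NJ is
verified in the tests against additive-data exactness, an exhaustive
least-squares topology search for five taxa, and scikit-bio's
implementation.

Clades replace manual tree inspection with a branch-stretch rule: an
internal branch is cut when longer than `stretch_factor` (default 2.0)
times the leave-one-out mean of the other internal branches.  Terminal
branches reflect within-group divergence and stay out of the reference;
they serve only as a fallback scale for trees with ≤ 3 internal branches
where equally long separating branches would shield each other.
Connected leaf groups of ≥ 2 become clades; singletons are outliers.

Each clade of ≥ 2 members gets its own profile HMM, and the clade
structure is **validated**: every member is scored against every clade
HMM, and a clade is confirmed when its poorest within-clade score beats
the best cross-clade score by `margin_bits` (default 10 bits ≈ three
orders of E-value magnitude).  Within-clade scores are computed
*leave-one-out* (each member scored against a profile rebuilt without
its own alignment row) whenever the clade has ≥ 3 members — with plain
scores, a member's own contribution to the profile inflates its score by
tens of bits and any random split of a homogeneous group would
self-confirm; the permutation-control test demonstrates exactly this.
If validation fails, the tree is re-cut once with one fewer clade and
the better-validated assignment kept.  Truncated members are excluded
from alignment and tree and receive their clade label post hoc from the
best-scoring clade HMM.

## ICE families

Each detected ICE is summarised as a clade vector over the retained
families (clade label, `missing`, `truncated`, or `outlier`).  Families
of ICEs are single-linkage components under the rule: two ICEs link when
they share identical clade labels on at least `agreement_frac` (default
0.6) of the marker genes informative in both (missing/truncated excluded
from the denominator).  The default markers are the most coherently
clading genes (`L.ICE_CG3..CG6`, `tcpA`, `mobT`); marker lists are
filtered to the columns actually present.  Families are numbered by
descending size, so labels are deterministic but need not match any
external numbering.  Within a family, subfamily suffixes (A, B, …) split
by the clade signature of the conjugation-module columns
(`L.ICE_CG9`, `tcpE`, `virB4`, `L.ICE_CG10`), which are exchanged
between elements as a block; missing or truncated entries there inherit
the family's modal label, since absence of evidence is no evidence of a
different module.  An ICE is flagged *mixed* when its marker labels
match two families' modal labels at ≥ 2 markers each.

## VirB4 origin discrimination

VirB4 is the one protein conserved across all type IV secretion systems,
making it the marker for asking whether a conjugation cluster is ICE- or
plasmid-derived.  The ICE reference set is the virB4 core-gene family of
the detected elements; the plasmid set is screened against the VirB4
detection profile, deduplicated at full sequence identity, and
restricted to near-full-length members (≥ 0.8 × the set median).  Each
set is claded as above (outlier training sequences are excluded from HMM
training but reported) and one profile HMM is built per clade, so the
number of origin HMMs follows the data rather than being hard-coded.

Each HMM carries a **stringent cutoff**: the poorest leave-one-out score
of its training members.  Plain minimum training scores would be
systematically unreachable for held-out members (the overfit effect
above, in reverse); the leave-one-out minimum is the honest "worst score
a genuine member achieves".  A query is classified to the origin of its
best cutoff-passing HMM when it beats the other origin by `margin_bits`
(default 10); both passing within the margin gives `ambiguous`; nothing
passing gives `none`.  Because the cutoff is the minimum of a finite
training sample, a small tail of genuine held-out members can still fall
below it — a deliberate property of a cutoff designed to avoid false
positives in large cross-species scans.

## The synthetic benchmark

The generator plants ground-truth ICEs in annotated genomes so every
stage is testable without downloads.  Default study conditions: 50
genomes; 3 sequence families; 0 / 1 / 2 ICEs per genome with
probabilities 0.58 / 0.32 / 0.10 (most genomes carry none, two-ICE
genomes are a small minority, matching the prevalence the detector is
built for); integrase-to-coupling spans uniform in 12–21 kbp; 17 core
genes per element in the canonical order with 0–2 random cargo genes per
inter-core gap; per-gene 5′-truncation probability 0.01 (to 40% length;
the two boundary genes are exempt so the planted span stays exactly the
measured one); one isolated decoy function gene per genome in
expectation, placed > 100 kbp from every planted ICE and every other
decoy so that no decoy window can reach four categories (asserted after
generation).

Sequence evolution is uniform replacement: each site mutates with
probability *d* to a uniform amino-acid draw (redraws allowed), so one
step at rate *d* leaves expected identity `1 − d·19/20`.  The three
family templates derive from a shared root at **half** the configured
between-family divergence each, so the *pairwise* divergence between
family templates matches the configured value (default 0.50 →
cross-family member identity ≈ 48%, above the 35% core-gene threshold,
while clades separate cleanly); members mutate from their template at
the within-family rate (default 0.10).  Plasmid-origin VirB4 sets derive
from the ICE virB4 root at the inter-origin rate (default 0.50) in two
subgroups.  Gene lengths are role-specific (virB4 550–700 aa, coupling
450–550, relaxase 350–450, integrase 300–400, muramidase 250–350, other
core genes 100–250) so the 17-gene core plus cargo fits the 12–21 kbp
span range.  Nucleotide sequence is back-generated with one fixed codon
per amino acid; intergenic sequence is random.  All randomness flows
from one seed through named substreams, so datasets and results are
byte-reproducible.

What the generator does **not** emulate: indels (other than the 40%
truncations), rate heterogeneity across sites, realistic codon usage or
GC content, paralogy, assembly fragmentation, and annotation errors.
Passing the benchmark therefore demonstrates the correctness of the
algorithms under the stated divergence geometry, not performance on real
genomes, where alignment quality, domain architecture, and curated
cutoffs carry additional weight.

## Numerical and operational choices

- Internal coordinates are 0-based half-open; every on-disk format keeps
  its native 1-based inclusive convention.  Co-localization never
  crosses contigs.
- Detection profiles built from family templates carry a default 25-bit
  presence cutoff — the magnitude typical of curated gathering cutoffs;
  genuine members score in the hundreds of bits, unrelated proteins near
  the Gumbel bulk well below it.
- Pairwise alignment uses Biopython's `PairwiseAligner`; trees and
  profiles are this package's own code; MAFFT performs multiple
  alignment (it is the standard tool for the step, and a single aligner
  serves both tree building and clade-HMM construction).
- Problem sizes: the test suite and the acceptance script run the
  50-genome benchmark once (seed 7 in the tests, the given seed in the
  script) and a 10-seed recovery sweep at 20 genomes per seed — sizes
  chosen to exercise two-ICE genomes, truncations and all three families
  with comfortable margins.
- Degenerate inputs: families with fewer than 3 full-length members form
  a single trivial clade; a clading in which every component is a
  singleton falls back to one clade; an empty plasmid set after
  filtering skips the plasmid origin model with a warning.

## Known limitations

- Excisionase (*xis*) detection is not attempted; the sequence diversity
  of ICE excisionases defeats family-level profiles.
- Full element boundaries (att sites) and cargo regions beyond the
  integrase-to-coupling span are out of scope.
- The family assignment formalises what is, in the field, partly a
  visual judgement; its `agreement_frac` and marker list are exposed
  precisely because reasonable alternatives exist.
- E-value calibration is approximate (moment fit, fixed λ); it is
  reported for context, never used for gating.
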