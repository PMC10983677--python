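"""Conserved core-gene families across detected ICEs.

Starting from a reference ICE (the role the well-characterised element
Tn6098 plays for the lactococcal ICEs), every ORF inside the reference
core region is searched against the core-region genes of each detected
ICE by Smith–Waterman alignment (BLOSUM62, gap open 11 / extend 1).  A
gene is a family member when it exceeds the identity and coverage
cutoffs (defaults: >35% identity over >80% of the reference length), and
a family is retained when present in at least ``ceil(min_presence_frac *
N)`` of the N ICEs — with the default 0.833 this reproduces a 30-of-36
presence rule.  Members that align well but cover only part of the
reference are flagged as truncations rather than counted absent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from ice_scout.detect import CandidateICE
from ice_scout.genome_io import GeneFeature, GenomeRecord

log = logging.getLogger(__name__)

_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class AlignStats:
    """Identity and reference coverage of one local protein alignment."""

    identity_pct: float
    coverage_pct: float
    aln_len: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.identity_pct <= 100 and 0 <= self.coverage_pct <= 100):
            raise ValueError("percentages out of range")


@dataclass
class FamilyMember:
    gene_id: str
    protein: str
    stats: AlignStats
    truncated: bool = False


@dataclass
class CoreGeneFamily:
    """An ortholog family anchored on one reference-ICE ORF."""

    family_id: str
    reference_gene: str
    reference_protein: str
    members: dict[str, FamilyMember] = field(default_factory=dict)  # ice_id ->

    @property
    def presence_count(self) -> int:
        return len(self.members)

    def member_proteins(self) -> dict[str, str]:
        """member key (ice_id) -> protein, for clading."""
        return {ice: m.protein for ice, m in self.members.items()}

    def truncated_ices(self) -> set[str]:
        return {ice for ice, m in self.members.items() if m.truncated}


def pairwise_align(a: str, b: str) -> AlignStats:
    """Local alignment statistics of query/reference ``a`` vs ``b``.

    Identity counts identical aligned positions over all alignment
    columns (gap columns included); coverage is the aligned span on
    ``a`` relative to its full length.  A pair with no positive-scoring
    local alignment returns zeros.
    """
    for name, s in (("a", a), ("b", b)):
        if not s:
            raise ValueError(f"sequence {name} is empty")
        bad = set(s.upper()) - _VALID
        if bad:
            raise ValueError(f"sequence {name}: invalid characters {sorted(bad)}")
    a, b = a.upper(), b.upper()
    score = _ALIGNER.score(a, b)
    if score <= 0:
        return AlignStats(0.0, 0.0, 0, 0.0)
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    columns = aln.length
    identity = 100.0 * counts.identities / columns if columns else 0.0
    blocks_a = aln.aligned[0]
    span = int(blocks_a[-1][1] - blocks_a[0][0])
    coverage = 100.0 * span / len(a)
    return AlignStats(identity, min(coverage, 100.0), columns, float(score))


def _region_genes(c: CandidateICE, genome: GenomeRecord) -> list[GeneFeature]:
    contig = next(ct for ct in genome.contigs if ct.contig_id == c.contig_id)
    if c.region_start is None:
        # no boundary pair: fall back to the span of all member genes
        idx = genome.gene_index()
        members = [idx[g] for g in c.member_gene_ids]
        lo = min(g.start for g in members)
        hi = max(g.end for g in members)
    else:
        lo, hi = c.region_start, c.region_end
    return [g for g in contig.genes if g.start >= lo and g.end <= hi and g.protein]


#: literature names for the five detection functions, applied when the
#: reference ORF is itself one of the detected function genes
FUNCTION_NAMES = {
    "integrase": "int",
    "muramidase": "mur",
    "virB4": "virB4",
    "relaxase": "mobT",
    "coupling": "tcpA",
}


def build_core_families(
    ices: list[CandidateICE],
    genomes: dict[str, GenomeRecord],
    reference_ice: str,
    min_identity: float = 35.0,
    min_coverage: float = 80.0,
    min_presence_frac: float = 0.833,
    trunc_coverage: float = 80.0,
) -> list[CoreGeneFamily]:
    """Derive retained core-gene families from the reference ICE's ORFs.

    For each reference ORF the best-scoring gene within every ICE's core
    region becomes that ICE's member if it passes the identity/coverage
    thresholds (ties broken by leftmost gene).  Families present in at
    least ``ceil(min_presence_frac * N)`` ICEs are retained, in reference
    gene order.  Well-matching but short members are truncation-flagged
    via :func:`flag_truncations` before the presence filter, mirroring
    how a truncated gene still marks the function as present.
    """
    by_id = {c.ice_id: c for c in ices}
    if reference_ice not in by_id:
        raise ValueError(f"reference ICE {reference_ice!r} not among detected ICEs")
    ref = by_id[reference_ice]
    ref_genome = genomes[ref.genome_id]
    ref_orfs = _region_genes(ref, ref_genome)
    if not ref_orfs:
        raise ValueError(f"reference ICE {reference_ice} has no region ORFs")

    # name the five function genes by their literature names; a gene with
    # hits in several categories (weak cross-category passes happen) is
    # named after its best-scoring category
    best_hit: dict[str, object] = {}
    for hit in ref.hits:
        cur = best_hit.get(hit.gene.gene_id)
        if cur is None or hit.bit_score > cur.bit_score:
            best_hit[hit.gene.gene_id] = hit
    fun_by_gene = {
        gid: FUNCTION_NAMES[h.category] for gid, h in best_hit.items()
    }

    n_ices = len(ices)
    threshold = math.ceil(min_presence_frac * n_ices)
    families: list[CoreGeneFamily] = []
    for orf in ref_orfs:
        fam = CoreGeneFamily("", orf.gene_id, orf.protein)
        for c in sorted(ices, key=lambda c: c.ice_id):
            genome = genomes[c.genome_id]
            best_gene, best_score = None, -1.0
            # cheap score pass first; ties go to the leftmost gene
            for gene in _region_genes(c, genome):
                s = _ALIGNER.score(orf.protein, gene.protein)
                if s > best_score:
                    best_gene, best_score = gene, s
            if best_gene is None:
                continue
            best_stats = pairwise_align(orf.protein, best_gene.protein)
            if (
                best_stats.identity_pct > min_identity
                and best_stats.coverage_pct > min_coverage
            ):
                fam.members[c.ice_id] = FamilyMember(
                    best_gene.gene_id, best_gene.protein, best_stats
                )
        fam = flag_truncations(
            fam,
            {c.ice_id: _region_genes(c, genomes[c.genome_id]) for c in ices},
            min_identity=min_identity,
            trunc_coverage=trunc_coverage,
        )
        _flag_short_members(fam, trunc_coverage)
        if fam.presence_count >= threshold:
            families.append(fam)
    # name the retained families: literature names for the five detection
    # functions (first claimant wins on a collision), positional
    # L.ICE_CG numbering for the rest
    cg_counter = 0
    used: set[str] = set()
    for fam in families:
        name = fun_by_gene.get(fam.reference_gene)
        if name is not None and name not in used:
            fam.family_id = name
            used.add(name)
        else:
            cg_counter += 1
            fam.family_id = f"L.ICE_CG{cg_counter}"
    log.info(
        "retained %d core-gene families (presence >= %d of %d ICEs)",
        len(families),
        threshold,
        n_ices,
    )
    return families


def _flag_short_members(family: CoreGeneFamily, trunc_coverage: float) -> None:
    """Mark members much shorter than the family's typical protein.

    Truncation is judged against the median member length rather than
    the reference alone, so that a family anchored on a reference gene
    that is itself a fragment still distinguishes its full-length
    members from genuinely truncated ones.
    """
    if not family.members:
        return
    import statistics

    median_len = statistics.median(len(m.protein) for m in family.members.values())
    for member in family.members.values():
        if len(member.protein) < trunc_coverage / 100.0 * median_len:
            member.truncated = True


def flag_truncations(
    family: CoreGeneFamily,
    region_genes: dict[str, list[GeneFeature]],
    min_identity: float = 35.0,
    trunc_coverage: float = 80.0,
) -> CoreGeneFamily:
    """Record short-but-well-matching genes as truncated members.

    For ICEs without a full member, a region gene that passes the
    identity threshold over its aligned span, covers less than
    ``trunc_coverage`` percent of the reference, and is itself shorter
    than that fraction of the reference length, is added as a member
    with ``truncated=True``.  To exclude spurious short local matches,
    the alignment must also span at least half of the candidate gene.
    """
    ref_len = len(family.reference_protein)
    for ice_id, genes in sorted(region_genes.items()):
        if ice_id in family.members:
            continue
        best: tuple[float, GeneFeature, AlignStats] | None = None
        for gene in genes:
            # a genuine fragment of the reference scores far above noise;
            # skip full alignment statistics for clearly unrelated genes
            if _ALIGNER.score(family.reference_protein, gene.protein) < 100:
                continue
            stats = pairwise_align(family.reference_protein, gene.protein)
            member_view = pairwise_align(gene.protein, family.reference_protein)
            if (
                stats.identity_pct > min_identity
                and stats.coverage_pct < trunc_coverage
                and len(gene.protein) < trunc_coverage / 100.0 * ref_len
                and stats.aln_len > 0
                and member_view.coverage_pct >= 50.0
            ):
                if best is None or stats.score > best[0]:
                    best = (stats.score, gene, stats)
        if best is not None:
            family.members[ice_id] = FamilyMember(
                best[1].gene_id, best[1].protein, best[2], truncated=True
            )
    return family
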