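"""ICE detection by relaxase-anchored co-localization of function hits.

The detector scans a genome's proteome against profile HMMs for the five
ICE lifecycle functions — tyrosine recombinase (integrase), muramidase,
VirB4 ATPase, relaxase, and coupling protein — keeping genes that pass
each profile's curated bit cutoff.  Because an ICE transfers as one
contiguous element, its functions must co-localize: every relaxase hit
seeds a window (default +/- 100 kbp around the gene midpoint, never
crossing a contig) and a candidate ICE is called when hits for at least
4 of the 5 categories fall inside.  Candidates sharing member genes are
merged, so tandem relaxases inside one element yield a single call while
genuinely separate elements in one genome remain distinct.

The conserved core region is delimited by the integrase and coupling
protein, the outermost functions of the canonical gene order
integrase - muramidase - virB4 - relaxase - coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from ice_scout.genome_io import GeneFeature, GenomeRecord
from ice_scout.phmm import ProfileHMM, call_presence, score_sequence

log = logging.getLogger(__name__)

#: The five ICE lifecycle function categories.
CATEGORIES = ("integrase", "muramidase", "virB4", "relaxase", "coupling")

#: Canonical order of the functions along the core region, integrase first.
CANONICAL_ORDER = ("integrase", "muramidase", "virB4", "relaxase", "coupling")


@dataclass
class FunctionHit:
    """Best-scoring assignment of one gene to one function category."""

    gene: GeneFeature
    category: str
    hmm_name: str
    bit_score: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class CandidateICE:
    """A relaxase-seeded co-localized set of function hits."""

    ice_id: str
    genome_id: str
    contig_id: str
    seed_relaxase: str
    members: dict[str, list[str]]  # category -> gene ids (genomic order)
    hits: list[FunctionHit] = field(default_factory=list, repr=False)
    n_categories: int = 0
    region_start: int | None = None
    region_end: int | None = None
    orientation: str = "undefined"
    region_orf_count: int | None = None
    synteny_ok: bool | None = None

    @property
    def region_length_bp(self) -> int | None:
        if self.region_start is None or self.region_end is None:
            return None
        return self.region_end - self.region_start

    @property
    def member_gene_ids(self) -> set[str]:
        return {g for genes in self.members.values() for g in genes}


def scan_proteome(
    genome: GenomeRecord,
    hmm_sets: dict[str, list[ProfileHMM]],
    overrides: dict[str, float] | None = None,
) -> list[FunctionHit]:
    """Score every gene against every category profile and call presence.

    Multiple profiles per category are OR-combined: a gene is a hit for a
    category if any of its profiles passes, and only the best-scoring
    profile is retained per (gene, category).  A gene passing two
    categories counts toward both (logged as a warning).
    """
    overrides = overrides or {}
    missing = [c for c in CATEGORIES if not hmm_sets.get(c)]
    if missing:
        raise ValueError(f"no HMMs configured for categories: {missing}")
    hits: list[FunctionHit] = []
    for gene in genome.genes():
        if not gene.protein:
            continue
        gene_cats = []
        for category in CATEGORIES:
            best: FunctionHit | None = None
            for hmm in hmm_sets[category]:
                hit = score_sequence(hmm, gene.protein, seq_id=gene.gene_id)
                if not call_presence(hit, hmm, overrides.get(hmm.name)):
                    continue
                if best is None or hit.bit_score > best.bit_score:
                    best = FunctionHit(gene, category, hmm.name, hit.bit_score)
            if best is not None:
                hits.append(best)
                gene_cats.append(category)
        if len(gene_cats) > 1:
            log.warning(
                "gene %s hits multiple categories: %s", gene.gene_id, gene_cats
            )
    return hits


def colocalize(
    hits: list[FunctionHit],
    genome_id: str,
    window_bp: int = 100_000,
    min_categories: int = 4,
) -> list[CandidateICE]:
    """Call candidate ICEs from one genome's function hits.

    Each relaxase hit seeds a window of +/- ``window_bp`` around its gene
    midpoint on its own contig; all hits whose midpoints fall inside are
    collected and a candidate is emitted when at least ``min_categories``
    distinct categories (including the relaxase) are present.  Candidates
    sharing any member gene are merged (union of members; the leftmost
    relaxase becomes the seed).  Output is invariant to the order of
    ``hits``: candidates are numbered by genomic position.
    """
    hits = sorted(hits, key=lambda h: (h.gene.contig_id, h.gene.start, h.gene.gene_id, h.category))
    raw: list[dict] = []
    for seed in hits:
        if seed.category != "relaxase":
            continue
        window = [
            h
            for h in hits
            if h.gene.contig_id == seed.gene.contig_id
            and abs(h.gene.midpoint - seed.gene.midpoint) <= window_bp
        ]
        categories = {h.category for h in window}
        if len(categories) >= min_categories:
            raw.append({"seed": seed, "hits": window})

    # merge candidates that share at least one member gene
    merged = True
    while merged:
        merged = False
        for i in range(len(raw)):
            for j in range(i + 1, len(raw)):
                genes_i = {h.gene.gene_id for h in raw[i]["hits"]}
                genes_j = {h.gene.gene_id for h in raw[j]["hits"]}
                if genes_i & genes_j:
                    keep: dict[tuple[str, str], FunctionHit] = {}
                    for h in raw[i]["hits"] + raw[j]["hits"]:
                        keep[(h.gene.gene_id, h.category)] = h
                    seeds = [raw[i]["seed"], raw[j]["seed"]]
                    seeds.sort(key=lambda h: (h.gene.start, h.gene.gene_id))
                    raw[i] = {
                        "seed": seeds[0],
                        "hits": sorted(
                            keep.values(),
                            key=lambda h: (h.gene.start, h.gene.gene_id, h.category),
                        ),
                    }
                    del raw[j]
                    merged = True
                    break
            if merged:
                break

    raw.sort(key=lambda r: (r["seed"].gene.contig_id, r["seed"].gene.start))
    out = []
    for ordinal, entry in enumerate(raw, 1):
        members: dict[str, list[str]] = {}
        for h in sorted(entry["hits"], key=lambda h: (h.gene.start, h.gene.gene_id)):
            members.setdefault(h.category, [])
            if h.gene.gene_id not in members[h.category]:
                members[h.category].append(h.gene.gene_id)
        out.append(
            CandidateICE(
                ice_id=f"{genome_id}_{ordinal}",
                genome_id=genome_id,
                contig_id=entry["seed"].gene.contig_id,
                seed_relaxase=entry["seed"].gene.gene_id,
                members=members,
                hits=list(entry["hits"]),
                n_categories=len(members),
            )
        )
    return out


def _best_gene_per_category(c: CandidateICE) -> dict[str, GeneFeature]:
    best: dict[str, FunctionHit] = {}
    for h in c.hits:
        cur = best.get(h.category)
        if cur is None or h.bit_score > cur.bit_score:
            best[h.category] = h
    return {cat: h.gene for cat, h in best.items()}


def annotate_candidate(c: CandidateICE, genome: GenomeRecord) -> CandidateICE:
    """Delimit and orient the conserved core region of a candidate.

    With both boundary functions present, the region spans the outermost
    coordinates of the integrase and coupling-protein genes; orientation
    is forward when the integrase lies leftward.  The synteny check asks
    whether, after orientation normalisation, the categories present
    appear in the canonical order along the region.
    """
    genes = _best_gene_per_category(c)
    out = replace(c)
    if "integrase" in genes and "coupling" in genes:
        g_int, g_cp = genes["integrase"], genes["coupling"]
        out.region_start = min(g_int.start, g_cp.start)
        out.region_end = max(g_int.end, g_cp.end)
        out.orientation = "forward" if g_int.start <= g_cp.start else "reverse"
        contig = next(ct for ct in genome.contigs if ct.contig_id == c.contig_id)
        out.region_orf_count = sum(
            1
            for g in contig.genes
            if g.start >= out.region_start and g.end <= out.region_end
        )
    else:
        out.region_start = out.region_end = None
        out.orientation = "undefined"
        out.region_orf_count = None

    present = [cat for cat in CANONICAL_ORDER if cat in genes]
    positions = [genes[cat].midpoint for cat in present]
    if out.orientation == "reverse":
        positions = [-p for p in positions]
    out.synteny_ok = all(a <= b for a, b in zip(positions, positions[1:]))
    if out.orientation == "undefined" and len(present) >= 2:
        # no boundary pair: accept either reading direction
        rev = [-p for p in positions]
        out.synteny_ok = all(a <= b for a, b in zip(positions, positions[1:])) or all(
            a <= b for a, b in zip(rev, rev[1:])
        )
    return out


def region_stats(candidates: list[CandidateICE]) -> pd.DataFrame:
    """Size and ORF-count table for candidates with a delimited region."""
    rows = [
        {
            "ice_id": c.ice_id,
            "region_length_bp": c.region_length_bp,
            "region_orf_count": c.region_orf_count,
        }
        for c in candidates
        if c.region_length_bp is not None
    ]
    return pd.DataFrame(rows, columns=["ice_id", "region_length_bp", "region_orf_count"])
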