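"""Origin discrimination for VirB4 conjugation ATPases.

VirB4 is the only protein conserved across all type IV secretion
systems, which makes it the natural marker for asking whether a
conjugation cluster is ICE- or plasmid-derived.  Labelled reference sets
(VirB4 proteins pulled from detected ICEs, and plasmid-encoded VirB4
passing the detection profile) are claded and one profile HMM is built
per clade.  Each HMM carries a *stringent* cutoff — the lowest bit score
of its own training members — so that hits below anything seen in
training are never classified.  A query is assigned the origin of its
best-scoring HMM when that score passes the stringent cutoff and beats
the other origin by a bit margin; otherwise it is ambiguous, or no call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ice_scout import msa as msa_mod
from ice_scout.clades import (
    CladeAssignment,
    cut_clades,
    nj_tree,
    p_distance_matrix,
)
from ice_scout.coregenes import CoreGeneFamily
from ice_scout.genome_io import GenomeRecord
from ice_scout.phmm import Msa, ProfileHMM, build_profile, call_presence, score_sequence

log = logging.getLogger(__name__)

ICE = "ICE"
PLASMID = "plasmid"
AMBIGUOUS = "ambiguous"
NONE = "none"


@dataclass
class OriginModel:
    """Clade HMMs for one origin (ICE or plasmid) with stringent cutoffs."""

    origin: str
    hmms: list[ProfileHMM] = field(default_factory=list)
    # per HMM name: minimum training-member bit score
    stringent_cutoff_bits: dict[str, float] = field(default_factory=dict)
    outliers: list[str] = field(default_factory=list)

    def best_passing_bits(self, query: str) -> float | None:
        """Best bit score over this origin's HMMs among those whose
        stringent cutoff the query reaches; None if none reached."""
        best = None
        for hmm in self.hmms:
            bits = score_sequence(hmm, query).bit_score
            if bits >= self.stringent_cutoff_bits[hmm.name]:
                if best is None or bits > best:
                    best = bits
        return best


def collect_virb4(
    ices_virb4_family: CoreGeneFamily | dict[str, str],
    plasmid_proteins: list[tuple[str, str]],
    detection_hmm: ProfileHMM | None = None,
    min_length_frac: float = 0.8,
) -> tuple[dict[str, str], dict[str, str]]:
    """Assemble the labelled ICE and plasmid VirB4 reference sets.

    The ICE set is the VirB4 core-gene family of the detected ICEs.  The
    plasmid set is screened against ``detection_hmm`` (the VirB4 family
    profile) when given, deduplicated at full sequence identity, and
    restricted to full-length members (length at least
    ``min_length_frac`` of the set median).
    """
    if isinstance(ices_virb4_family, CoreGeneFamily):
        ice_set = dict(sorted(ices_virb4_family.member_proteins().items()))
    else:
        ice_set = dict(sorted(ices_virb4_family.items()))

    candidates = []
    for name, seq in plasmid_proteins:
        if detection_hmm is not None:
            hit = score_sequence(detection_hmm, seq, seq_id=name)
            if not call_presence(hit, detection_hmm):
                continue
        candidates.append((name, seq))
    # collapse identical sequences, keeping the first name
    seen: dict[str, str] = {}
    for name, seq in candidates:
        if seq not in seen:
            seen[seq] = name
    plasmid_set = {name: seq for seq, name in seen.items()}
    if plasmid_set:
        median = float(np.median([len(s) for s in plasmid_set.values()]))
        plasmid_set = {
            n: s for n, s in plasmid_set.items() if len(s) >= min_length_frac * median
        }
    if not plasmid_set:
        log.warning("plasmid VirB4 set empty after filtering")
    return ice_set, dict(sorted(plasmid_set.items()))


def _clade_sets(members: dict[str, str], stretch_factor: float = 2.0) -> CladeAssignment:
    if len(members) < 3:
        return CladeAssignment("", {m: "clade_1" for m in members}, k=1)
    aln = msa_mod.align_proteins(sorted(members.items()))
    assignment = cut_clades(nj_tree(p_distance_matrix(aln)), stretch_factor=stretch_factor)
    if assignment.k == 0:
        assignment = CladeAssignment("", {m: "clade_1" for m in members}, k=1)
    return assignment


def build_origin_models(
    ice_set: dict[str, str],
    plasmid_set: dict[str, str],
    stretch_factor: float = 2.0,
) -> list[OriginModel]:
    """Clade each labelled set and build one stringent-cutoff HMM per clade.

    Clade outliers (deviant single sequences) are excluded from HMM
    training but reported on the model.  The stringent cutoff is the
    poorest *leave-one-out* score of the clade's training members (each
    member scored against a profile rebuilt without its own row), so a
    member never raises the bar through its own contribution to the
    profile; every training member still reaches the cutoff with its
    plain score, by construction.
    """

    def stringent_cutoff(aln, ids, hmm) -> float:
        scores = []
        for m in ids:
            if len(ids) >= 3:
                rest = Msa(
                    [i for i in aln.ids if i != m],
                    [r for i, r in zip(aln.ids, aln.rows) if i != m],
                )
                loo = build_profile(rest, name="loo")
                scores.append(score_sequence(loo, _strip_gaps(aln, m)).bit_score)
            else:
                scores.append(score_sequence(hmm, _strip_gaps(aln, m)).bit_score)
        return min(scores)

    def _strip_gaps(aln, member_id):
        row = aln.rows[aln.ids.index(member_id)]
        return row.replace("-", "").replace(".", "")

    models = []
    for origin, members in ((ICE, ice_set), (PLASMID, plasmid_set)):
        if len(members) < 2:
            raise ValueError(f"{origin} set needs at least 2 sequences")
        assignment = _clade_sets(members, stretch_factor)
        model = OriginModel(origin)
        model.outliers = assignment.members_of("outlier")
        clades = [
            (clade, assignment.members_of(clade))
            for clade in assignment.clade_names()
        ]
        if not clades:
            # all members fell out as outliers: train one HMM on everything
            clades = [("clade_1", sorted(members))]
        for clade, ids in clades:
            aln = msa_mod.align_proteins([(i, members[i]) for i in ids])
            hmm = build_profile(aln, name=f"{origin}_{clade}")
            cutoff = stringent_cutoff(aln, ids, hmm)
            hmm.cutoff_bits = cutoff
            model.hmms.append(hmm)
            model.stringent_cutoff_bits[hmm.name] = cutoff
        models.append(model)
    return models


def classify_virb4(
    models: list[OriginModel], query: str, margin_bits: float = 10.0
) -> str:
    """Classify one VirB4 protein as ICE, plasmid, ambiguous, or none.

    ``none``: no HMM of any origin reaches its stringent cutoff.
    ``ambiguous``: both origins pass but the bit gap is below the margin.
    """
    best: dict[str, float] = {}
    for model in models:
        bits = model.best_passing_bits(query)
        if bits is not None:
            best[model.origin] = bits
    if not best:
        return NONE
    if len(best) == 1:
        return next(iter(best))
    ranked = sorted(best.items(), key=lambda kv: -kv[1])
    if ranked[0][1] - ranked[1][1] >= margin_bits:
        return ranked[0][0]
    return AMBIGUOUS


def host_range_scan(
    models: list[OriginModel],
    genomes: list[GenomeRecord],
    margin_bits: float = 10.0,
) -> list[dict]:
    """Classify every protein of every genome; emit only positive rows.

    The survey analogue of scanning a large representative-genome
    collection for ICE- or plasmid-type VirB4 carriers.
    """
    rows = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        for gene in genome.genes():
            if not gene.protein:
                continue
            origin = classify_virb4(models, gene.protein, margin_bits)
            if origin == NONE:
                continue
            bits = max(
                (m.best_passing_bits(gene.protein) or -np.inf for m in models),
            )
            rows.append(
                {
                    "genome": genome.genome_id,
                    "gene": gene.gene_id,
                    "origin": origin,
                    "bits": round(float(bits), 2),
                }
            )
    return rows
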