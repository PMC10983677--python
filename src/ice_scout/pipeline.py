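"""End-to-end orchestration: detect -> core genes -> clades -> families
-> VirB4 origin models.

`RunConfig` carries every tunable threshold of the method with its
default; `run_pipeline` executes the stages in order on in-memory
genomes and returns a structured result.  Each stage is independently
callable through the stage modules; the orchestrator adds nothing but
sequencing, logging and the run summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

from ice_scout import clades as clades_mod
from ice_scout import coregenes as coregenes_mod
from ice_scout import detect as detect_mod
from ice_scout import families as families_mod
from ice_scout import virb4 as virb4_mod
from ice_scout.genome_io import GenomeRecord
from ice_scout.phmm import ProfileHMM

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with defaults."""

    window_bp: int = 100_000
    min_categories: int = 4
    min_identity: float = 35.0
    min_coverage: float = 80.0
    min_presence_frac: float = 0.833
    stretch_factor: float = 2.0
    margin_bits: float = 10.0
    agreement_frac: float = 0.6
    marker_genes: list[str] = field(
        default_factory=lambda: list(families_mod.DEFAULT_MARKERS)
    )
    reference_ice: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.min_categories <= 5:
            raise ValueError("min_categories must be between 1 and 5")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage")
        if not 0 < self.min_presence_frac <= 1:
            raise ValueError("min_presence_frac must lie in (0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    hits: dict[str, list]  # genome_id -> FunctionHit list
    candidates: list
    core_families: list
    clade_assignments: dict
    clade_validations: dict
    trees: dict
    matrix: list
    assignment: object
    report: dict
    summary: dict
    virb4_models: object = None


def detect_stage(
    genomes: list[GenomeRecord],
    hmm_sets: dict[str, list[ProfileHMM]],
    config: RunConfig,
    overrides: dict[str, float] | None = None,
):
    """Scan, co-localize and annotate candidates for every genome."""
    hits = {}
    candidates = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        genome_hits = detect_mod.scan_proteome(genome, hmm_sets, overrides)
        hits[genome.genome_id] = genome_hits
        cands = detect_mod.colocalize(
            genome_hits,
            genome.genome_id,
            window_bp=config.window_bp,
            min_categories=config.min_categories,
        )
        candidates.extend(detect_mod.annotate_candidate(c, genome) for c in cands)
    return hits, candidates


def choose_reference_ice(candidates) -> str:
    """Deterministic reference pick: the first candidate (by id) carrying
    all five functions and a delimited region."""
    for c in sorted(candidates, key=lambda c: c.ice_id):
        if c.n_categories == 5 and c.region_start is not None:
            return c.ice_id
    if not candidates:
        raise ValueError("no candidates to choose a reference from")
    return sorted(candidates, key=lambda c: c.ice_id)[0].ice_id


def run_pipeline(
    genomes: list[GenomeRecord],
    hmm_sets: dict[str, list[ProfileHMM]],
    config: RunConfig | None = None,
    plasmid_virb4: list[tuple[str, str]] | None = None,
    overrides: dict[str, float] | None = None,
) -> PipelineResult:
    """Run detection through family assignment (and VirB4 models when a
    plasmid set is supplied); returns the full structured result."""
    config = config or RunConfig()
    t0 = time.time()
    by_genome = {g.genome_id: g for g in genomes}
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    hits, candidates = detect_stage(genomes, hmm_sets, config, overrides)
    summary["stages"]["detect"] = {
        "n_genomes": len(genomes),
        "n_hits": sum(len(h) for h in hits.values()),
        "n_candidates": len(candidates),
    }
    log.info("detect: %d candidates", len(candidates))

    core_families = []
    assignments: dict = {}
    validations: dict = {}
    trees: dict = {}
    matrix: list = []
    assignment = families_mod.FamilyAssignment({}, {})
    report: dict = {}

    if candidates:
        reference = config.reference_ice or choose_reference_ice(candidates)
        core_families = coregenes_mod.build_core_families(
            candidates,
            by_genome,
            reference,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            min_presence_frac=config.min_presence_frac,
        )
        summary["stages"]["coregenes"] = {
            "reference_ice": reference,
            "n_families": len(core_families),
        }

        for fam in core_families:
            members = fam.member_proteins()
            truncated = fam.truncated_ices()
            a, v, tree, _hmms = clades_mod.clade_family(
                members,
                family_id=fam.family_id,
                truncated=truncated,
                stretch_factor=config.stretch_factor,
                margin_bits=config.margin_bits,
            )
            assignments[fam.family_id] = a
            validations[fam.family_id] = v
            trees[fam.family_id] = tree
        summary["stages"]["clades"] = {
            "clades_per_family": {
                f: assignments[f].k for f in sorted(assignments)
            },
            "all_confirmed": all(
                v is None or v.all_confirmed for v in validations.values()
            ),
        }

        matrix = families_mod.clade_matrix(candidates, core_families, assignments)
        assignment = families_mod.assign_families(
            matrix,
            marker_genes=config.marker_genes,
            agreement_frac=config.agreement_frac,
        )
        report = families_mod.family_report(assignment, matrix, candidates)
        summary["stages"]["families"] = {
            "family_sizes": report.get("family_sizes", {}),
        }

    virb4_models = None
    if plasmid_virb4 is not None and candidates:
        virb4_fam = next(
            (f for f in core_families if f.family_id == "virB4"), None
        )
        if virb4_fam is not None:
            full_members = {
                ice: m.protein
                for ice, m in virb4_fam.members.items()
                if not m.truncated
            }
            detection_hmm = hmm_sets["virB4"][0] if hmm_sets.get("virB4") else None
            ice_set, plasmid_set = virb4_mod.collect_virb4(
                full_members, plasmid_virb4, detection_hmm=detection_hmm
            )
            if len(ice_set) >= 2 and len(plasmid_set) >= 2:
                virb4_models = virb4_mod.build_origin_models(ice_set, plasmid_set)
                summary["stages"]["virb4"] = {
                    "n_ice_training": len(ice_set),
                    "n_plasmid_training": len(plasmid_set),
                    "n_hmms": sum(len(m.hmms) for m in virb4_models),
                }

    summary["wall_seconds"] = round(time.time() - t0, 2)
    result = PipelineResult(
        hits=hits,
        candidates=candidates,
        core_families=core_families,
        clade_assignments=assignments,
        clade_validations=validations,
        trees=trees,
        matrix=matrix,
        assignment=assignment,
        report=report,
        summary=summary,
        virb4_models=virb4_models,
    )
    return result
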