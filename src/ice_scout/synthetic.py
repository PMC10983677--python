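"""Synthetic annotated genomes with planted ICEs and ground truth.

The generator emulates the situation the detector faces in real
bacterial chromosomes: genomes carrying zero, one, or two ICE core
regions with the canonical gene order (integrase - muramidase - virB4 -
relaxase - coupling protein, with further conserved core genes and
variable cargo genes between them), integrase-to-coupling spans in the
12-21 kbp range, elements on either strand, occasional 5'-truncated core
genes, scattered single-function decoy genes that must never assemble
into a candidate, and labelled ICE- and plasmid-origin VirB4 reference
sets.

Sequence evolution is a deliberately simple uniform-replacement model:
each site of a protein is independently replaced with probability *d*
by a uniform draw from the 20 amino acids (the same residue may be
redrawn), so two sequences derived from a common ancestor at rates d1,
d2 have expected identity (1 - d1*19/20)(1 - d2*19/20) plus a small
coincidental-match term.  Three sequence families are derived from a
shared root: each family template mutates from the root at HALF the
configured between-family divergence so that the divergence between two
family templates is approximately the configured value, while members
within a family mutate from their template at the within-family rate.

All randomness flows from a single seed through named substreams, so a
given configuration is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from ice_scout.genome_io import Contig, GeneFeature, GenomeRecord
from ice_scout.phmm import AMINO_ACIDS, Msa, ProfileHMM, build_profile

#: canonical layout of the 17 core genes along an ICE; the five
#: detection functions keep the conserved order integrase < muramidase <
#: virB4 < relaxase < coupling, with the other core genes in the gaps
CORE_LAYOUT = (
    "int",
    "L.ICE_CG1",
    "L.ICE_CG2",
    "mur",
    "L.ICE_CG3",
    "L.ICE_CG4",
    "virB4",
    "L.ICE_CG5",
    "L.ICE_CG6",
    "mobT",
    "L.ICE_CG7",
    "L.ICE_CG8",
    "L.ICE_CG9",
    "L.ICE_CG10",
    "L.ICE_CG11",
    "L.ICE_CG12",
    "tcpA",
)

#: gene role -> detection function category (None for plain core genes)
ROLE_CATEGORY = {
    "int": "integrase",
    "mur": "muramidase",
    "virB4": "virB4",
    "mobT": "relaxase",
    "tcpA": "coupling",
}

#: amino-acid length ranges per role, sized so that the 17-gene core
#: plus cargo fits the observed 12-21 kbp integrase-to-coupling span
ROLE_LENGTHS = {
    "int": (300, 400),
    "mur": (250, 350),
    "virB4": (550, 700),
    "mobT": (350, 450),
    "tcpA": (450, 550),
}
CG_LENGTHS = (100, 250)

#: boundary genes are exempt from truncation so that the planted span
#: stays exactly the measured integrase-to-coupling span
_NO_TRUNCATION = {"int", "tcpA"}

TRUNCATION_FRACTION = 0.4  # 5'-truncations keep this fraction of the protein

_AA = np.array(list(AMINO_ACIDS))


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    seed: int = 7
    n_genomes: int = 50
    n_families: int = 3
    # probabilities of a genome carrying 0 / 1 / 2 ICEs (field-realistic:
    # most genomes carry none, two-ICE genomes are a small minority)
    ices_per_genome: dict[int, float] = field(
        default_factory=lambda: {0: 0.58, 1: 0.32, 2: 0.10}
    )
    core_span_bp: tuple[int, int] = (12_000, 21_000)
    within_family_divergence: float = 0.10
    between_family_divergence: float = 0.50
    cargo_genes_per_gap: tuple[int, int] = (0, 2)
    decoy_rate: float = 1.0
    truncation_rate: float = 0.01
    n_plasmid_virb4: int = 17
    n_plasmid_subgroups: int = 2
    inter_origin_divergence: float = 0.5

    def __post_init__(self) -> None:
        for d in (
            self.within_family_divergence,
            self.between_family_divergence,
            self.inter_origin_divergence,
        ):
            if not 0.0 <= d <= 1.0:
                raise ValueError("divergences must lie in [0, 1]")
        if self.core_span_bp[0] <= 0 or self.core_span_bp[1] < self.core_span_bp[0]:
            raise ValueError("core_span_bp must be a positive range")
        total = sum(self.ices_per_genome.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("ices_per_genome probabilities must sum to 1")


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA, size=length))


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Uniform-replacement mutation: each site replaced with probability
    ``divergence`` by a uniform amino-acid draw (redraws allowed)."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    if divergence == 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < divergence
    n = int(mask.sum())
    if n:
        arr[mask] = rng.choice(_AA, size=n)
    return "".join(arr)


@dataclass
class TemplateSet:
    roots: dict[str, str]  # role -> root protein
    families: list[dict[str, str]]  # per family: role -> template protein


def make_templates(seed: int, config: SimConfig | None = None) -> TemplateSet:
    """Root proteins for the 17 core genes plus per-family templates.

    Each family template is mutated from the root at half the
    between-family divergence, so the pairwise divergence between two
    family templates matches the configured value.
    """
    config = config or SimConfig(seed=seed)
    rng = np.random.default_rng([seed, 0])
    roots = {}
    for role in CORE_LAYOUT:
        lo, hi = ROLE_LENGTHS.get(role, CG_LENGTHS)
        roots[role] = random_protein(int(rng.integers(lo, hi + 1)), rng)
    half = config.between_family_divergence / 2.0
    families = []
    for _f in range(config.n_families):
        families.append({role: mutate_protein(roots[role], half, rng) for role in CORE_LAYOUT})
    return TemplateSet(roots, families)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

_CODON = {  # fixed codon per amino acid for back-translation
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "X": "GCT",
}


def back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


@dataclass
class _PlannedGene:
    gene_id: str
    role: str  # core role, "cargo", "decoy:<category>", "background"
    protein: str
    truncated: bool = False


def plant_ice(
    templates: TemplateSet,
    family: int,
    span_bp: int,
    config: SimConfig,
    rng: np.random.Generator,
    strand: str,
    ice_tag: str,
) -> tuple[list[tuple[_PlannedGene, int, int, str]], dict]:
    """Lay out one ICE core region of exactly ``span_bp`` base pairs.

    Returns (gene placements relative to the region start, truth row).
    Core genes follow the canonical order (mirrored on the '-' strand),
    cargo genes are inserted in the inter-core gaps, and leftover space
    becomes intergenic spacing.  Interior core genes are 5'-truncated to
    40% length with probability ``truncation_rate``.
    """
    fam_templates = templates.families[family]
    core: list[_PlannedGene] = []
    for i, role in enumerate(CORE_LAYOUT):
        protein = mutate_protein(
            fam_templates[role], config.within_family_divergence, rng
        )
        truncated = False
        if role not in _NO_TRUNCATION and rng.random() < config.truncation_rate:
            protein = protein[: max(int(len(protein) * TRUNCATION_FRACTION), 30)]
            truncated = True
        core.append(_PlannedGene(f"{ice_tag}_{role}", role, protein, truncated))

    min_gap = 50
    core_bp = sum(len(back_translate(g.protein)) for g in core)
    budget = span_bp - core_bp - min_gap * (len(core) - 1)
    if budget < 0:
        raise ValueError(
            f"span {span_bp} too small for the core genes ({core_bp} bp)"
        )

    # insert cargo genes into the 16 inter-core gaps while budget allows
    elements: list[_PlannedGene] = []
    cargo_n = 0
    lo_c, hi_c = config.cargo_genes_per_gap
    for i, gene in enumerate(core):
        elements.append(gene)
        if i == len(core) - 1:
            break
        for _ in range(int(rng.integers(lo_c, hi_c + 1))):
            length = int(rng.integers(80, 201))
            nt = 3 * (length + 1)
            if budget - (nt + min_gap) < 0:
                break
            cargo_n += 1
            elements.append(
                _PlannedGene(
                    f"{ice_tag}_cargo{cargo_n}",
                    "cargo",
                    random_protein(length, rng),
                )
            )
            budget -= nt + min_gap

    if strand == "-":
        elements = elements[::-1]

    # distribute the leftover budget over the inter-element spaces
    n_spaces = len(elements) - 1
    extra = np.zeros(n_spaces, dtype=int)
    if n_spaces > 0 and budget > 0:
        split = rng.multinomial(budget, np.full(n_spaces, 1.0 / n_spaces))
        extra = split
    placements = []
    offset = 0
    for i, gene in enumerate(elements):
        nt_len = len(back_translate(gene.protein))
        placements.append((gene, offset, offset + nt_len, strand))
        offset += nt_len
        if i < n_spaces:
            offset += min_gap + int(extra[i])
    assert offset == span_bp, (offset, span_bp)
    truth = {
        "family": family,
        "span_bp": span_bp,
        "strand": strand,
        "genes": {
            g.gene_id: {"role": g.role, "truncated": g.truncated}
            for g, *_ in placements
        },
        "n_cargo": cargo_n,
    }
    return placements, truth


@dataclass
class SyntheticDataset:
    config: SimConfig
    genomes: list[GenomeRecord]
    nucleotides: dict[str, str]  # genome_id -> contig sequence
    manifest: dict
    templates: TemplateSet
    plasmid_virb4: list[tuple[str, str]]  # labelled plasmid-origin set

    def write(self, out_dir: str | Path) -> None:
        """Write GenBank genomes, the plasmid VirB4 FASTA, and the
        truth manifest as JSON."""
        out = Path(out_dir)
        (out / "genomes").mkdir(parents=True, exist_ok=True)
        for genome in self.genomes:
            contig = genome.contigs[0]
            rec = SeqRecord(
                Seq(self.nucleotides[genome.genome_id]),
                id=contig.contig_id,
                name=contig.contig_id[:16],
                description="synthetic genome",
                annotations={"molecule_type": "DNA", "organism": genome.organism},
            )
            for g in contig.genes:
                loc = FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1)
                feat = SeqFeature(
                    loc,
                    type="CDS",
                    qualifiers={"locus_tag": [g.gene_id], "translation": [g.protein]},
                )
                rec.features.append(feat)
            SeqIO.write([rec], str(out / "genomes" / f"{genome.genome_id}.gbk"), "genbank")
        with open(out / "plasmid_virb4.faa", "w") as fh:
            for name, seq in self.plasmid_virb4:
                fh.write(f">{name}\n{seq}\n")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )


def _build_genome(
    genome_idx: int,
    templates: TemplateSet,
    config: SimConfig,
) -> tuple[GenomeRecord, str, dict]:
    rng = np.random.default_rng([config.seed, 1, genome_idx])
    gid = f"SYN{genome_idx:03d}"
    contig_id = f"{gid}_c1"

    counts = sorted(config.ices_per_genome)
    probs = [config.ices_per_genome[c] for c in counts]
    n_ices = int(rng.choice(counts, p=probs))
    n_decoys = int(rng.poisson(config.decoy_rate))

    items: list[dict] = []
    for i in range(n_ices):
        items.append({"kind": "ice", "ordinal": i + 1})
    for i in range(n_decoys):
        items.append({"kind": "decoy", "ordinal": i + 1})

    # item start positions spaced so that decoys sit > 100 kbp from any
    # planted ICE and from each other
    spacing = 140_000
    head = 60_000
    genes: list[GeneFeature] = []
    nt_parts: list[str] = []
    cursor = 0
    truth_ices = []
    truth_decoys = []

    def fill_to(pos: int) -> None:
        nonlocal cursor
        if pos > cursor:
            nt_parts.append(
                "".join(rng.choice(["A", "C", "G", "T"], size=pos - cursor))
            )
            cursor = pos

    # scatter a few background genes in the head region
    n_background = 8
    bpos = 5_000
    for b in range(n_background):
        prot = random_protein(int(rng.integers(100, 301)), rng)
        nt = back_translate(prot)
        fill_to(bpos)
        nt_parts.append(nt)
        genes.append(
            GeneFeature(f"{gid}_bg{b + 1}", contig_id, bpos, bpos + len(nt), "+", prot)
        )
        cursor = bpos + len(nt)
        bpos = cursor + int(rng.integers(500, 2_000))
        if bpos > head - 10_000:
            break

    for item_idx, item in enumerate(items):
        start = head + item_idx * spacing
        fill_to(start)
        if item["kind"] == "ice":
            family = int(rng.integers(config.n_families))
            lo, hi = config.core_span_bp
            # the span must fit the 17 core genes; the effective lower
            # bound is whichever is larger
            min_span = 0
            strand = "+" if rng.random() < 0.5 else "-"
            ice_tag = f"{gid}_ice{item['ordinal']}"
            for attempt in range(20):
                span = int(rng.integers(lo, hi + 1))
                try:
                    placements, truth = plant_ice(
                        templates, family, span, config, rng, strand, ice_tag
                    )
                    break
                except ValueError:
                    continue
            else:
                raise ValueError(
                    "core genes cannot fit the configured span range"
                )
            for gene, off_s, off_e, g_strand in placements:
                nt = back_translate(gene.protein)
                fill_to(start + off_s)
                nt_parts.append(nt if g_strand == "+" else str(Seq(nt).reverse_complement()))
                cursor = start + off_e
                genes.append(
                    GeneFeature(
                        gene.gene_id, contig_id, start + off_s, start + off_e,
                        g_strand, gene.protein,
                    )
                )
            fill_to(start + span)
            truth.update(
                {
                    "ice_tag": ice_tag,
                    "genome_id": gid,
                    "contig_id": contig_id,
                    "start": start,
                    "end": start + span,
                }
            )
            truth_ices.append(truth)
        else:
            role = str(rng.choice(["int", "mur", "virB4", "mobT", "tcpA"]))
            family = int(rng.integers(config.n_families))
            prot = mutate_protein(
                templates.families[family][role],
                config.within_family_divergence,
                rng,
            )
            nt = back_translate(prot)
            gene_id = f"{gid}_decoy{item['ordinal']}"
            nt_parts.append(nt)
            genes.append(
                GeneFeature(gene_id, contig_id, start, start + len(nt), "+", prot)
            )
            cursor = start + len(nt)
            truth_decoys.append(
                {
                    "gene_id": gene_id,
                    "genome_id": gid,
                    "category": ROLE_CATEGORY[role],
                    "start": start,
                }
            )

    tail = head + max(len(items), 1) * spacing + 20_000
    fill_to(tail)
    nt_seq = "".join(nt_parts)
    assert len(nt_seq) == cursor
    genome = GenomeRecord(
        gid,
        "Synthetica exempli",
        [Contig(contig_id, len(nt_seq), genes)],
    )
    truth = {"ices": truth_ices, "decoys": truth_decoys}
    return genome, nt_seq, truth


def make_plasmid_virb4(
    templates: TemplateSet, config: SimConfig
) -> list[tuple[str, str]]:
    """Labelled plasmid-origin VirB4 set: subgroup templates diverged from
    the ICE VirB4 root at the inter-origin rate, members at the
    within-family rate."""
    rng = np.random.default_rng([config.seed, 2])
    ice_root = templates.roots["virB4"]
    plasmid_root = mutate_protein(ice_root, config.inter_origin_divergence / 2.0, rng)
    subgroups = [
        mutate_protein(plasmid_root, 0.15, rng)
        for _ in range(config.n_plasmid_subgroups)
    ]
    out = []
    for i in range(config.n_plasmid_virb4):
        sub = i % config.n_plasmid_subgroups
        prot = mutate_protein(
            subgroups[sub], config.within_family_divergence, rng
        )
        out.append((f"P_virB4_{i + 1:02d}", prot))
    return out


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the full benchmark dataset for one configuration.

    Deterministic for a fixed config: all randomness flows from
    ``config.seed`` via named substreams.  Decoy isolation (no window
    around any decoy reaching 4 function categories) holds by
    construction and is asserted post-generation.
    """
    templates = make_templates(config.seed, config)
    genomes = []
    nucleotides = {}
    manifest: dict = {"config": {"seed": config.seed, "n_genomes": config.n_genomes,
                                 "n_families": config.n_families},
                      "genomes": {}}
    for gi in range(config.n_genomes):
        genome, nt, truth = _build_genome(gi, templates, config)
        genomes.append(genome)
        nucleotides[genome.genome_id] = nt
        manifest["genomes"][genome.genome_id] = truth
    _assert_decoy_isolation(manifest)
    plasmid = make_plasmid_virb4(templates, config)
    return SyntheticDataset(config, genomes, nucleotides, manifest, templates, plasmid)


def _assert_decoy_isolation(manifest: dict, window_bp: int = 100_000) -> None:
    for gid, truth in manifest["genomes"].items():
        anchors = [ice["start"] for ice in truth["ices"]] + [
            ice["end"] for ice in truth["ices"]
        ]
        decoys = [d["start"] for d in truth["decoys"]]
        for i, d in enumerate(decoys):
            near_ice = any(abs(d - a) <= window_bp for a in anchors)
            near_decoy = any(
                abs(d - other) <= window_bp for j, other in enumerate(decoys) if j != i
            )
            if near_ice or near_decoy:
                raise AssertionError(f"decoy isolation violated in {gid}")


def build_detection_hmms(
    templates: TemplateSet, cutoff_bits: float = 25.0
) -> dict[str, list[ProfileHMM]]:
    """Per-category detection profiles built from the family templates.

    The family templates are equal-length descendants of one root, so
    they already form an ungapped alignment.  The default 25-bit cutoff
    follows the magnitude of curated protein-family gathering cutoffs:
    genuine members score in the hundreds of bits, unrelated proteins
    near zero.
    """
    out: dict[str, list[ProfileHMM]] = {}
    for role, category in ROLE_CATEGORY.items():
        rows = [fam[role] for fam in templates.families]
        msa = Msa([f"fam{i}" for i in range(len(rows))], rows)
        hmm = build_profile(msa, name=f"det_{category}", cutoff_bits=cutoff_bits)
        out[category] = [hmm]
    return out
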