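"""Reading annotated genomes and writing pipeline outputs.

Genomes come in as GenBank flat files or GFF3 + FASTA pairs; internally
every gene lives in 0-based half-open coordinates on its contig, in
genomic order.  Translations are taken from the annotation (``translation``
qualifier in GenBank, or translated from the spliced CDS when absent and
a nucleotide sequence is available); ab-initio gene calling is out of
scope.  All on-disk formats keep their native 1-based inclusive
conventions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class GeneFeature:
    """A protein-coding gene: locus tag, location, strand, translation."""

    gene_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str  # '+' or '-'
    protein: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval for {self.gene_id}: [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        bad = set(self.protein.upper()) - _VALID_AA
        if bad:
            raise ValueError(f"{self.gene_id}: non-amino-acid characters {sorted(bad)}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class Contig:
    contig_id: str
    length_bp: int
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for g in self.genes:
            if g.end > self.length_bp:
                raise ValueError(
                    f"gene {g.gene_id} extends past contig {self.contig_id}"
                )


@dataclass
class GenomeRecord:
    genome_id: str
    organism: str
    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        ids = [c.contig_id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate contig ids in {self.genome_id}")

    def genes(self):
        for contig in self.contigs:
            yield from contig.genes

    def gene_index(self) -> dict[str, GeneFeature]:
        return {g.gene_id: g for g in self.genes()}


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_annotated_genome(
    path: str | Path,
    format: str = "genbank",
    fasta_path: str | Path | None = None,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Parse a GenBank file, or a GFF3 file plus its FASTA, into a genome.

    Every CDS that carries (or can be) translated becomes a
    :class:`GeneFeature`; coordinates are converted from the on-disk
    1-based inclusive convention to internal 0-based half-open.  A CDS
    without translation and without sequence to translate from is
    skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        return _read_genbank(path, genome_id)
    if format == "gff3+fasta":
        if fasta_path is None:
            raise ValueError("gff3+fasta format needs fasta_path")
        return _read_gff3(path, Path(fasta_path), genome_id)
    raise ValueError(f"unknown format {format!r}")


def _clean_protein(raw: str) -> str:
    p = raw.upper().rstrip("*")
    return "".join("X" if c not in _VALID_AA else c for c in p)


def _read_genbank(path: Path, genome_id: str | None) -> GenomeRecord:
    contigs = []
    organism = ""
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise ValueError(f"cannot parse {path} as GenBank: {exc}") from exc
    if not records:
        raise ValueError(f"cannot parse {path} as GenBank: no records found")
    for rec in records:
        organism = organism or rec.annotations.get("organism", "")
        genes = []
        n_anon = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            gid = quals.get("locus_tag", quals.get("gene", [None]))[0]
            if gid is None:
                n_anon += 1
                gid = f"{rec.id}_cds{n_anon}"
            protein = quals.get("translation", [""])[0]
            if not protein:
                try:
                    protein = str(feat.extract(rec.seq).translate(to_stop=True))
                except Exception:
                    protein = ""
                if not protein:
                    warnings.warn(f"skipping CDS {gid}: no translation available")
                    continue
            strand = "-" if feat.location.strand == -1 else "+"
            genes.append(
                GeneFeature(
                    gene_id=gid,
                    contig_id=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand=strand,
                    protein=_clean_protein(protein),
                )
            )
        contigs.append(Contig(rec.id, len(rec.seq), genes))
    return GenomeRecord(genome_id or path.stem, organism, contigs)


def _read_gff3(gff_path: Path, fasta_path: Path, genome_id: str | None) -> GenomeRecord:
    seqs = {rec.id: rec.seq for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {fasta_path}")
    genes_by_contig: dict[str, list[GeneFeature]] = {cid: [] for cid in seqs}
    for lineno, line in enumerate(gff_path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{gff_path}:{lineno}: not a 9-column GFF3 record")
        seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
        if ftype != "CDS":
            continue
        if seqid not in seqs:
            raise ValueError(f"{gff_path}:{lineno}: unknown contig {seqid}")
        attr = dict(
            kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
        )
        gid = attr.get("ID") or attr.get("locus_tag") or f"{seqid}_cds{lineno}"
        s0, e0 = int(start) - 1, int(end)  # 1-based inclusive -> half-open
        nt = seqs[seqid][s0:e0]
        if strand == "-":
            nt = nt.reverse_complement()
        protein = str(Seq(nt).translate(to_stop=True))
        if not protein:
            warnings.warn(f"skipping CDS {gid}: empty translation")
            continue
        genes_by_contig[seqid].append(
            GeneFeature(gid, seqid, s0, e0, strand, _clean_protein(protein))
        )
    contigs = [
        Contig(cid, len(seqs[cid]), genes_by_contig[cid]) for cid in seqs
    ]
    return GenomeRecord(genome_id or gff_path.stem, "", contigs)


def extract_proteome(genome: GenomeRecord) -> list[tuple[str, str]]:
    """(gene_id, protein) for every CDS with a non-empty translation,
    in genomic order; independent of strand."""
    return [(g.gene_id, g.protein) for g in genome.genes() if g.protein]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_gff3(candidates, path: str | Path) -> None:
    """ICE core regions as GFF3 ``mobile_genetic_element`` features
    (1-based inclusive on disk)."""
    lines = ["##gff-version 3"]
    for c in sorted(candidates, key=lambda c: c.ice_id):
        if c.region_start is None:
            continue
        attrs = (
            f"ID={c.ice_id};n_categories={c.n_categories};"
            f"orientation={c.orientation};synteny_ok={str(c.synteny_ok).lower()}"
        )
        strand = {"forward": "+", "reverse": "-"}.get(c.orientation, ".")
        lines.append(
            "\t".join(
                [
                    c.contig_id,
                    "ice-scout",
                    "mobile_genetic_element",
                    str(c.region_start + 1),
                    str(c.region_end),
                    ".",
                    strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(entries: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_tsv(rows: list[dict], columns: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_outputs(
    candidates,
    families,
    assignment,
    out_dir: str | Path,
    summary: dict | None = None,
) -> dict[str, Path]:
    """Write the standard result bundle: GFF3 regions, TSV tables, FASTA
    of core-family member proteins, and a JSON run summary.

    Outputs are byte-stable for identical inputs: all iteration orders
    are canonicalised before writing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["regions"] = out / "ice_regions.gff3"
    write_gff3(candidates, paths["regions"])

    cand_rows = []
    for c in sorted(candidates, key=lambda c: c.ice_id):
        cand_rows.append(
            {
                "ice_id": c.ice_id,
                "contig": c.contig_id,
                "seed_relaxase": c.seed_relaxase,
                "n_categories": c.n_categories,
                "region_start": "" if c.region_start is None else c.region_start,
                "region_end": "" if c.region_end is None else c.region_end,
                "region_length_bp": "" if c.region_length_bp is None else c.region_length_bp,
                "region_orf_count": "" if c.region_orf_count is None else c.region_orf_count,
                "orientation": c.orientation,
                "synteny_ok": c.synteny_ok,
            }
        )
    paths["candidates"] = out / "candidates.tsv"
    write_tsv(
        cand_rows,
        [
            "ice_id", "contig", "seed_relaxase", "n_categories", "region_start",
            "region_end", "region_length_bp", "region_orf_count", "orientation",
            "synteny_ok",
        ],
        paths["candidates"],
    )

    fam_rows = []
    fasta_entries = []
    for fam in sorted(families, key=lambda f: f.family_id):
        for ice_id in sorted(fam.members):
            member = fam.members[ice_id]
            fam_rows.append(
                {
                    "family_id": fam.family_id,
                    "ice_id": ice_id,
                    "gene": member.gene_id,
                    "identity_pct": f"{member.stats.identity_pct:.2f}",
                    "coverage_pct": f"{member.stats.coverage_pct:.2f}",
                    "truncated": member.truncated,
                }
            )
            fasta_entries.append(
                (f"{fam.family_id}|{ice_id}|{member.gene_id}", member.protein)
            )
    paths["families"] = out / "core_families.tsv"
    write_tsv(
        fam_rows,
        ["family_id", "ice_id", "gene", "identity_pct", "coverage_pct", "truncated"],
        paths["families"],
    )
    paths["core_proteins"] = out / "core_proteins.faa"
    write_fasta(fasta_entries, paths["core_proteins"])

    if assignment is not None:
        paths["families_json"] = out / "family_assignment.json"
        write_json(assignment.to_dict(), paths["families_json"])
    if summary is not None:
        paths["summary"] = out / "run_summary.json"
        write_json(summary, paths["summary"])
    return paths
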