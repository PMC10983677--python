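"""ICE family assignment from per-family clade labels.

Every detected ICE is summarised as a clade vector: for each retained
core-gene family, the clade its member fell into — or ``missing``,
``truncated``, ``outlier``.  Families of ICEs are then groups of
elements whose clade labels agree on a set of marker genes (the genes
whose clading is most coherent); two ICEs link when they share identical
clade labels on at least ``agreement_frac`` of the markers informative
in both, and single-linkage components become families numbered by
descending size.  Within a family, subfamilies are split by the modal
clade-set of the conjugation-module genes, which are observed to be
exchanged between elements as a block; ICEs matching two families'
modal marker labels are flagged as mixed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from ice_scout.clades import OUTLIER, CladeAssignment
from ice_scout.coregenes import CoreGeneFamily
from ice_scout.detect import CandidateICE

log = logging.getLogger(__name__)

MISSING = "missing"
TRUNCATED = "truncated"

#: default marker genes for family assignment (most coherent clading)
DEFAULT_MARKERS = ["L.ICE_CG3", "L.ICE_CG4", "L.ICE_CG5", "L.ICE_CG6", "tcpA", "mobT"]
#: conjugation-module genes whose clades are exchanged as a block
DEFAULT_SUBFAMILY_COLUMNS = ["L.ICE_CG9", "tcpE", "virB4", "L.ICE_CG10"]


@dataclass
class CladeVector:
    ice_id: str
    entries: dict[str, str]  # family_id -> clade label / missing / truncated / outlier


@dataclass
class FamilyAssignment:
    labels: dict[str, str]  # ice_id -> family label ("1", "2A", "unassigned", ...)
    mixed: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": dict(sorted(self.labels.items())),
            "mixed": dict(sorted(self.mixed.items())),
        }


def clade_matrix(
    ices: list[CandidateICE],
    core_families: list[CoreGeneFamily],
    assignments: dict[str, CladeAssignment],
) -> list[CladeVector]:
    """One clade vector per ICE over the retained core-gene families.

    Absent members map to ``missing``, truncation-flagged members to
    ``truncated``; clade outliers propagate as ``outlier``.
    """
    vectors = []
    for c in sorted(ices, key=lambda c: c.ice_id):
        entries = {}
        for fam in core_families:
            member = fam.members.get(c.ice_id)
            if member is None:
                entries[fam.family_id] = MISSING
            elif member.truncated:
                entries[fam.family_id] = TRUNCATED
            else:
                label = assignments[fam.family_id].labels.get(c.ice_id, OUTLIER)
                entries[fam.family_id] = label
        vectors.append(CladeVector(c.ice_id, entries))
    return vectors


def _informative(state: str) -> bool:
    return state not in (MISSING, TRUNCATED)


def assign_families(
    matrix: list[CladeVector],
    marker_genes: list[str] | None = None,
    agreement_frac: float = 0.6,
    subfamily_columns: list[str] | None = None,
) -> FamilyAssignment:
    """Group ICEs into families by marker-gene clade agreement.

    Two ICEs link when, over the marker genes informative in both
    (missing/truncated excluded from the denominator), the fraction with
    identical clade labels is at least ``agreement_frac``; single-linkage
    components become families labelled ``1``, ``2``, ... by descending
    size (ties by smallest member id).  Subfamily suffixes (``A``, ``B``)
    split a family by the clade-set of the conjugation-module columns.
    An ICE is flagged mixed when its marker labels match two different
    families' modal labels at two or more markers each.
    """
    if marker_genes is None:
        marker_genes = list(DEFAULT_MARKERS)
    if subfamily_columns is None:
        subfamily_columns = list(DEFAULT_SUBFAMILY_COLUMNS)
    if not matrix:
        return FamilyAssignment({}, {})
    columns = set(matrix[0].entries)
    markers = [m for m in marker_genes if m in columns]
    if not markers:
        raise ValueError(
            f"none of the marker genes {marker_genes} are matrix columns"
        )
    sub_cols = [s for s in subfamily_columns if s in columns]

    vectors = sorted(matrix, key=lambda v: v.ice_id)
    ids = [v.ice_id for v in vectors]
    by_id = {v.ice_id: v for v in vectors}

    def linked(a: CladeVector, b: CladeVector) -> bool:
        shared = [
            m
            for m in markers
            if _informative(a.entries[m]) and _informative(b.entries[m])
        ]
        if not shared:
            return False
        same = sum(1 for m in shared if a.entries[m] == b.entries[m])
        return same / len(shared) >= agreement_frac

    # single-linkage components via union-find
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if linked(by_id[a], by_id[b]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), g[0]))

    labels: dict[str, str] = {}
    modal_by_family: dict[int, dict[str, str]] = {}
    for fam_idx, group in enumerate(ordered, 1):
        # modal marker labels of the family, for the mixed-ICE check
        modal = {}
        for m in markers:
            states = [
                by_id[i].entries[m]
                for i in group
                if _informative(by_id[i].entries[m])
            ]
            if states:
                modal[m] = Counter(states).most_common(1)[0][0]
        modal_by_family[fam_idx] = modal

        # subfamily split by the conjugation-module clade-set; missing or
        # truncated entries are no evidence of a different module, so they
        # inherit the family's modal label for that column
        modal_sub = {}
        for s in sub_cols:
            states = [
                by_id[i].entries[s] for i in group if _informative(by_id[i].entries[s])
            ]
            modal_sub[s] = Counter(states).most_common(1)[0][0] if states else "?"
        suffix_of: dict[tuple, str] = {}
        signatures = {}
        for i in group:
            sig = tuple(
                by_id[i].entries[s]
                if _informative(by_id[i].entries[s])
                else modal_sub[s]
                for s in sub_cols
            )
            signatures[i] = sig
        distinct = sorted(
            Counter(signatures.values()).items(), key=lambda kv: (-kv[1], kv[0])
        )
        use_suffix = len(distinct) > 1 and sub_cols
        for rank, (sig, _count) in enumerate(distinct):
            suffix_of[sig] = chr(ord("A") + rank) if use_suffix else ""
        for i in group:
            labels[i] = f"{fam_idx}{suffix_of[signatures[i]]}"

    mixed: dict[str, bool] = {}
    for i in ids:
        hits_per_family = []
        for fam_idx, modal in modal_by_family.items():
            n = sum(
                1
                for m in markers
                if m in modal
                and _informative(by_id[i].entries[m])
                and by_id[i].entries[m] == modal[m]
            )
            hits_per_family.append(n)
        mixed[i] = sum(1 for n in hits_per_family if n >= 2) >= 2
    return FamilyAssignment(labels, mixed)


def family_report(
    assignment: FamilyAssignment,
    matrix: list[CladeVector],
    ices: list[CandidateICE] | None = None,
) -> dict:
    """Machine-readable summary: family sizes, per-ICE rows, two-ICE tally."""
    sizes: Counter = Counter(assignment.labels.values())
    rows = []
    for v in sorted(matrix, key=lambda v: v.ice_id):
        rows.append(
            {
                "ice_id": v.ice_id,
                "family": assignment.labels.get(v.ice_id, "unassigned"),
                "mixed": assignment.mixed.get(v.ice_id, False),
                "states": dict(sorted(v.entries.items())),
            }
        )
    report = {
        "family_sizes": dict(sorted(sizes.items())),
        "n_ices": len(matrix),
        "ices": rows,
    }
    if ices is not None:
        per_genome: Counter = Counter(c.genome_id for c in ices)
        report["genomes_with_two_ices"] = sum(1 for n in per_genome.values() if n >= 2)
    return report


def matrix_tsv_rows(matrix: list[CladeVector]) -> tuple[list[dict], list[str]]:
    """Rows + column order for writing the clade matrix as TSV."""
    if not matrix:
        return [], ["ice_id"]
    columns = ["ice_id"] + sorted(matrix[0].entries)
    rows = [
        {"ice_id": v.ice_id, **v.entries} for v in sorted(matrix, key=lambda v: v.ice_id)
    ]
    return rows, columns
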