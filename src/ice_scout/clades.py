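"""Phylogenetic clading of core-gene families and clade-HMM validation.

For each conserved core-gene family the members are aligned, an
uncorrected p-distance matrix is computed, a neighbor-joining tree is
built, and clades are cut algorithmically: internal branches much longer
than the tree's average internal branch separate groups.  Each clade of
two or more members then gets its own profile HMM, and the clade
structure is confirmed by requiring every member to score higher against
its own clade's HMM than any member of another clade does (by a
configurable bit margin) — the discriminating-HMM validation step.

Truncated family members are excluded from tree building and receive
their clade label post hoc from the best-scoring clade HMM.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ice_scout import msa as msa_mod
from ice_scout.phmm import Msa, ProfileHMM, build_profile, score_sequence

log = logging.getLogger(__name__)

OUTLIER = "outlier"


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")


@dataclass
class TreeNode:
    """Node of an (arbitrarily rooted) phylogenetic tree."""

    name: str
    length: float = 0.0  # branch length to the parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.length:.6f}"

    def edges(self):
        """Yield (parent, child) pairs over the whole tree."""
        for c in self.children:
            yield (self, c)
            yield from c.edges()


@dataclass
class CladeAssignment:
    family_id: str
    labels: dict[str, str]  # member id -> clade_k or "outlier"
    k: int

    def members_of(self, clade: str) -> list[str]:
        return sorted(m for m, c in self.labels.items() if c == clade)

    def clade_names(self) -> list[str]:
        return sorted({c for c in self.labels.values() if c != OUTLIER})


@dataclass
class CladeValidation:
    family_id: str
    scores: dict[tuple[str, str], float]  # (member, clade) -> bits
    per_clade: dict[str, dict]  # clade -> {min_within_bits, max_cross_bits, confirmed}

    @property
    def all_confirmed(self) -> bool:
        return all(v["confirmed"] for v in self.per_clade.values())


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def p_distance_matrix(msa: Msa) -> DistanceMatrix:
    """Uncorrected pairwise p-distances over mutually non-gap columns."""
    arr = np.array([list(r) for r in msa.rows])
    is_gap = (arr == "-") | (arr == ".")
    n = len(msa.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~is_gap[i] & ~is_gap[j]
            total = int(both.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]} and {msa.ids[j]}"
                )
            diff = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = diff / total
    return DistanceMatrix(list(msa.ids), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with canonical branch lengths.

    Deterministic: among ties in the Q criterion the lexicographically
    smallest label pair is joined.  Negative branch-length estimates are
    clamped to zero (logged).  The returned tree is rooted at the final
    three-way join, representing the unrooted NJ topology.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = {lab: TreeNode(lab) for lab in dm.labels}
    active = list(dm.labels)
    d = {
        (a, b): dm.d[i, j]
        for i, a in enumerate(dm.labels)
        for j, b in enumerate(dm.labels)
    }
    counter = itertools.count(1)
    clamped = False

    def dist(a: str, b: str) -> float:
        return d[(a, b)]

    while len(active) > 2:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best_pair = None
        best_q = math.inf
        for a, b in itertools.combinations(sorted(active), 2):
            q = (m - 2) * dist(a, b) - r[a] - r[b]
            if q < best_q - 1e-12:
                best_q = q
                best_pair = (a, b)
        a, b = best_pair
        la = 0.5 * dist(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = dist(a, b) - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        new_name = f"_nj{next(counter)}"
        node = TreeNode(new_name)
        nodes[a].length, nodes[b].length = la, lb
        node.children = [nodes[a], nodes[b]]
        nodes[new_name] = node
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
            d[(new_name, c)] = d[(c, new_name)] = duc
        d[(new_name, new_name)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new_name]

    a, b = active
    root = TreeNode("_root")
    half = max(dist(a, b), 0.0)
    # attach both remaining nodes under an arbitrary root splitting the branch
    nodes[a].length = half / 2
    nodes[b].length = half - half / 2
    root.children = [nodes[a], nodes[b]]
    if clamped:
        log.warning("negative NJ branch length estimates clamped to 0")
    return root


def tree_leaf_distance(tree: TreeNode, a: str, b: str) -> float:
    """Patristic distance between two leaves (for additive-data checks)."""

    def path(node: TreeNode, target: str, acc: list[TreeNode]) -> bool:
        acc.append(node)
        if node.is_leaf and node.name == target:
            return True
        for c in node.children:
            if path(c, target, acc):
                return True
        acc.pop()
        return False

    pa: list[TreeNode] = []
    pb: list[TreeNode] = []
    path(tree, a, pa)
    path(tree, b, pb)
    common = 0
    for x, y in zip(pa, pb):
        if x is y:
            common += 1
        else:
            break
    return sum(n.length for n in pa[common:]) + sum(n.length for n in pb[common:])


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as the smaller-side leaf sets) of the tree."""
    all_leaves = frozenset(tree.leaf_names())
    splits = set()
    for _parent, child in tree.edges():
        side = frozenset(child.leaf_names())
        if 1 < len(side) < len(all_leaves) - 1:
            other = all_leaves - side
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


# ---------------------------------------------------------------------------
# clade cutting
# ---------------------------------------------------------------------------

def cut_clades(
    tree: TreeNode,
    family_id: str = "",
    stretch_factor: float = 2.0,
    max_clades: int | None = None,
) -> CladeAssignment:
    """Cut long internal branches and label the leaf components as clades.

    An internal branch is removed when it is longer than
    ``stretch_factor`` times the mean length of the *other* internal
    branches (leave-one-out, so one stretched branch cannot inflate its
    own threshold).  Terminal branches reflect within-group divergence
    and stay out of the reference, except as a fallback scale when the
    tree has three or fewer internal branches and the leave-one-out
    criterion finds nothing (a pair of equally long separating branches
    in a tiny tree would otherwise shield each other).  The resulting
    connected leaf groups of size >= 2 become clades (numbered
    ``clade_1``.. in order of their smallest member label) and
    singletons become outliers.  When ``max_clades`` is given, exactly
    the ``max_clades - 1`` longest internal branches are cut instead.
    """
    all_edges = list(tree.edges())
    internal = [(parent, child) for parent, child in all_edges if not child.is_leaf]
    terminal_lengths = [child.length for _p, child in all_edges if child.is_leaf]

    if max_clades is not None:
        k_cuts = max(max_clades - 1, 0)
        ranked = sorted(
            internal, key=lambda e: (-e[1].length, sorted(e[1].leaf_names()))
        )
        cut_edges = set(id(child) for _p, child in ranked[:k_cuts])
    else:
        lengths = [child.length for _p, child in internal]
        total = sum(lengths)
        long_set = set()
        for i, l in enumerate(lengths):
            if len(lengths) > 1:
                reference = (total - l) / (len(lengths) - 1)
            else:
                reference = 0.0
            if reference > 0 and l > stretch_factor * reference:
                long_set.add(i)
        if not long_set and len(internal) <= 3 and terminal_lengths:
            reference = sum(terminal_lengths) / len(terminal_lengths)
            long_set = {
                i
                for i, l in enumerate(lengths)
                if reference > 0 and l > stretch_factor * reference
            }
        cut_edges = set(
            id(child) for i, (_p, child) in enumerate(internal) if i in long_set
        )

    # components: leaves grouped by the cut forest
    components: list[list[str]] = []

    def collect(node: TreeNode) -> list[str]:
        acc = [node.name] if node.is_leaf else []
        for c in node.children:
            if id(c) in cut_edges:
                components.append(collect(c))
            else:
                acc.extend(collect(c))
        return acc

    components.append(collect(tree))
    components = [sorted(c) for c in components if c]
    labels: dict[str, str] = {}
    clades = sorted((c for c in components if len(c) >= 2), key=lambda c: c[0])
    for i, comp in enumerate(clades, 1):
        for m in comp:
            labels[m] = f"clade_{i}"
    for comp in components:
        if len(comp) == 1:
            labels[comp[0]] = OUTLIER
    return CladeAssignment(family_id, labels, k=len(clades))


# ---------------------------------------------------------------------------
# clade HMMs and validation
# ---------------------------------------------------------------------------

def _clade_alignments(
    members: dict[str, str], assignment: CladeAssignment
) -> dict[str, Msa]:
    alignments = {}
    for clade in assignment.clade_names():
        ids = assignment.members_of(clade)
        if len(ids) < 2:
            raise RuntimeError(f"clade {clade} has fewer than 2 members")
        alignments[clade] = msa_mod.align_proteins([(i, members[i]) for i in ids])
    return alignments


def build_clade_hmms(
    members: dict[str, str],
    assignment: CladeAssignment,
    pseudocount_weight: float = 0.1,
    alignments: dict[str, Msa] | None = None,
) -> dict[str, ProfileHMM]:
    """One profile HMM per clade, from an alignment of the clade members."""
    alignments = alignments or _clade_alignments(members, assignment)
    hmms = {}
    for clade, aln in sorted(alignments.items()):
        hmms[clade] = build_profile(
            aln,
            name=f"{assignment.family_id}_{clade}" if assignment.family_id else clade,
            pseudocount_weight=pseudocount_weight,
        )
    return hmms


def validate_clades(
    members: dict[str, str],
    assignment: CladeAssignment,
    hmms: dict[str, ProfileHMM],
    margin_bits: float = 10.0,
    alignments: dict[str, Msa] | None = None,
) -> CladeValidation:
    """Score every member against every clade HMM and check separation.

    A clade is confirmed when its poorest within-clade score exceeds the
    best score any cross-clade member achieves against its HMM by at
    least ``margin_bits``.  To keep the comparison honest, within-clade
    scores are computed leave-one-out whenever the clade has at least 3
    members: each member is scored against a profile rebuilt from its
    clade alignment without that member's row, so a member can never
    certify a clade merely by matching its own contribution to the
    profile.  A single-clade family is trivially confirmed.
    """
    if alignments is None:
        alignments = _clade_alignments(members, assignment)
    scores: dict[tuple[str, str], float] = {}
    for member_id, protein in sorted(members.items()):
        for clade, hmm in sorted(hmms.items()):
            scores[(member_id, clade)] = score_sequence(
                hmm, protein, seq_id=member_id
            ).bit_score
    per_clade = {}
    for clade in sorted(hmms):
        ids = assignment.members_of(clade)
        aln = alignments.get(clade)
        within = []
        for m in ids:
            if aln is not None and len(ids) >= 3:
                rest_ids = [i for i in aln.ids if i != m]
                rest_rows = [r for i, r in zip(aln.ids, aln.rows) if i != m]
                loo = build_profile(Msa(rest_ids, rest_rows), name=f"{clade}_loo")
                within.append(score_sequence(loo, members[m]).bit_score)
            else:
                within.append(scores[(m, clade)])
        cross = [
            scores[(m, clade)]
            for m, lab in sorted(assignment.labels.items())
            if lab not in (clade, OUTLIER)
        ]
        min_within = min(within)
        max_cross = max(cross) if cross else -math.inf
        per_clade[clade] = {
            "min_within_bits": min_within,
            "max_cross_bits": max_cross,
            "confirmed": min_within >= max_cross + margin_bits,
        }
    return CladeValidation(assignment.family_id, scores, per_clade)


def build_and_validate_clade_hmms(
    members: dict[str, str],
    assignment: CladeAssignment,
    tree: TreeNode | None = None,
    margin_bits: float = 10.0,
    retry: bool = True,
) -> tuple[dict[str, ProfileHMM], CladeValidation, CladeAssignment]:
    """Build clade HMMs, validate, and optionally re-cut once on failure.

    If any clade fails the margin check and a tree is supplied, the tree
    is re-cut into one fewer clade and the HMMs rebuilt (a single retry);
    the better-validated assignment is returned.
    """
    alignments = _clade_alignments(members, assignment)
    hmms = build_clade_hmms(members, assignment, alignments=alignments)
    validation = validate_clades(members, assignment, hmms, margin_bits, alignments)
    if validation.all_confirmed or not retry or tree is None or assignment.k <= 1:
        return hmms, validation, assignment
    log.info(
        "family %s: %d clades failed validation; retrying with %d",
        assignment.family_id,
        sum(not v["confirmed"] for v in validation.per_clade.values()),
        assignment.k - 1,
    )
    retry_assignment = cut_clades(
        tree, family_id=assignment.family_id, max_clades=assignment.k - 1
    )
    if retry_assignment.k < 1 or retry_assignment.k >= assignment.k:
        return hmms, validation, assignment
    retry_alns = _clade_alignments(members, retry_assignment)
    retry_hmms = build_clade_hmms(members, retry_assignment, alignments=retry_alns)
    retry_validation = validate_clades(
        members, retry_assignment, retry_hmms, margin_bits, retry_alns
    )
    if retry_validation.all_confirmed:
        return retry_hmms, retry_validation, retry_assignment
    return hmms, validation, assignment


def clade_family(
    members: dict[str, str],
    family_id: str = "",
    truncated: set[str] | None = None,
    stretch_factor: float = 2.0,
    margin_bits: float = 10.0,
) -> tuple[CladeAssignment, CladeValidation | None, TreeNode | None, dict[str, ProfileHMM]]:
    """Full clading of one family: align, tree, cut, build + validate HMMs.

    ``truncated`` members are left out of the alignment and tree and are
    labelled afterwards by their best clade-HMM bit score.  Families with
    fewer than 3 full-length members form a single clade trivially.
    """
    truncated = truncated or set()
    full = {m: s for m, s in members.items() if m not in truncated}
    if len(full) < 3:
        labels = {m: "clade_1" for m in members}
        return CladeAssignment(family_id, labels, k=1), None, None, {}
    aln = msa_mod.align_proteins(sorted(full.items()))
    dm = p_distance_matrix(aln)
    tree = nj_tree(dm)
    assignment = cut_clades(tree, family_id=family_id, stretch_factor=stretch_factor)
    if assignment.k == 0:
        # every component was a singleton: degenerate; fall back to one clade
        assignment = CladeAssignment(
            family_id, {m: "clade_1" for m in full}, k=1
        )
    hmms, validation, assignment = build_and_validate_clade_hmms(
        full, assignment, tree=tree, margin_bits=margin_bits
    )
    # place truncated members post hoc by best clade HMM
    for m in sorted(truncated):
        if not hmms:
            assignment.labels[m] = "clade_1"
            continue
        best = max(
            sorted(hmms.items()),
            key=lambda kv: score_sequence(kv[1], members[m]).bit_score,
        )
        assignment.labels[m] = best[0]
    return assignment, validation, tree, hmms
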