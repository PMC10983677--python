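"""Profile hidden Markov models for protein homology detection.

This module is the scoring engine behind every detection step in the
package: reading curated profiles in the HMMER3 text format (e.g. PFAM
families with their gathering cutoffs), building new profiles from
multiple sequence alignments (clade HMMs, origin HMMs), scoring protein
sequences by local Viterbi log-odds, and calling presence against curated
bit-score thresholds.

Model conventions
-----------------
A profile of length ``M`` has match states 1..M, each with a 20-letter
emission distribution, an insert state per match state emitting a
background-like distribution, and delete states allowing match columns to
be skipped.  Scoring is local/local: an alignment may start at any match
state and any sequence position and end likewise, with entry and exit
free.  The bit score is the log2-odds of the best (Viterbi) path against
an i.i.d. background model, so a perfectly conserved single-residue model
scores ``log2(1 / background[residue])`` on its consensus letter.

Presence decisions use bit scores against curated cutoffs (the PFAM
"gathering cutoff" convention); E-values are available through an
explicit Gumbel calibration (`calibrate_gumbel_mu`) but never gate
detection.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

#: Amino-acid alphabet in the order used by HMMER3 profile files.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residues treated as background-emitting (score contribution zero).
AMBIGUOUS = set("BJZXUO*")

# Robinson & Robinson (1991) amino-acid frequencies, the standard null
# model for protein profile searches; normalised to sum exactly to 1.
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}
BACKGROUND = np.array([_RR[aa] for aa in AMINO_ACIDS])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

_EULER_GAMMA = 0.5772156649015329

#: Transition kinds, in HMMER3 file order.
TRANSITIONS = ("mm", "mi", "md", "im", "ii", "dm", "dd")


class ProfileParseError(ValueError):
    """Raised when a profile file violates the HMMER3 text format."""


class CutoffError(ValueError):
    """Raised when a presence call is requested without any bit cutoff."""


@dataclass
class ProfileHMM:
    """A protein profile HMM with optional curated presence cutoff.

    Attributes
    ----------
    name, accession:
        Identifier and optional database accession (e.g. ``PF12846``).
    match_emissions, insert_emissions:
        ``(M, 20)`` probability arrays over `AMINO_ACIDS`.
    transitions:
        ``(M, 7)`` probabilities in `TRANSITIONS` order; row ``k`` holds
        the outgoing transitions of node ``k+1``.
    background:
        20-vector null distribution.
    cutoff_bits:
        Curated presence threshold (PFAM GA line), or None.
    """

    name: str
    accession: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    cutoff_bits: float | None = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, float)
        self.insert_emissions = np.asarray(self.insert_emissions, float)
        self.transitions = np.asarray(self.transitions, float)
        self.background = np.asarray(self.background, float)
        if self.match_emissions.ndim != 2 or self.match_emissions.shape[1] != 20:
            raise ValueError("match_emissions must be (M, 20)")
        if self.match_emissions.shape[0] < 1:
            raise ValueError("profile needs at least one match state")
        self._cache: dict[str, np.ndarray] = {}

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, tol: float = 1e-9) -> None:
        """Check that all stored distributions are normalised."""
        for name, arr in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
            ("background", self.background.reshape(1, -1)),
        ):
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=tol * arr.shape[1] * 100, rtol=1e-6):
                raise ValueError(f"{name} rows do not sum to 1 (got {sums})")
        t = self.transitions
        for grp in ((0, 1, 2), (3, 4), (5, 6)):
            sums = t[:, grp].sum(axis=1)
            if not np.allclose(sums, 1.0, rtol=1e-6, atol=1e-6):
                raise ValueError(f"transition group {grp} does not sum to 1")

    # cached log-odds / log arrays used by the Viterbi scorer
    def _scoring_arrays(self):
        if "melo" not in self._cache:
            with np.errstate(divide="ignore"):
                melo = np.log2(self.match_emissions) - np.log2(self.background)
                ielo = np.log2(self.insert_emissions) - np.log2(self.background)
                tlog = np.log2(self.transitions)
            # forbidden transitions get a large finite penalty so that the
            # cumulative-sum trick for delete runs never forms inf - inf
            tlog = np.maximum(tlog, -1e9)
            # column 20: ambiguous residues emit background -> log-odds 0
            self._cache["melo"] = np.hstack([melo, np.zeros((self.M, 1))])
            self._cache["ielo"] = np.hstack([ielo, np.zeros((self.M, 1))])
            self._cache["tlog"] = tlog
        return self._cache["melo"], self._cache["ielo"], self._cache["tlog"]


@dataclass
class Msa:
    """A protein multiple sequence alignment (rows over AA + '-')."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows differ in width")

    @property
    def width(self) -> int:
        return len(self.rows[0])


@dataclass
class HmmHit:
    """A scored local match of a profile on one protein sequence."""

    seq_id: str
    hmm_name: str
    bit_score: float
    e_value: float
    env_start: int
    env_end: int


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a protein string to emission-column indices (20 = ambiguous)."""
    idx = np.empty(len(seq), dtype=np.intp)
    for i, ch in enumerate(seq.upper()):
        j = _AA_INDEX.get(ch)
        if j is None:
            if ch in AMBIGUOUS:
                j = 20
            else:
                raise ValueError(f"unexpected residue {ch!r} at position {i}")
        idx[i] = j
    return idx


# ---------------------------------------------------------------------------
# HMMER3 text format I/O
# ---------------------------------------------------------------------------

def parse_profile(text: str) -> ProfileHMM:
    """Parse one profile from HMMER3/f profile text.

    Emission and transition values are stored in the file as negative
    natural logs of probabilities ('*' meaning probability zero); they are
    exponentiated back here.  A GA line supplies ``cutoff_bits``.
    """
    lines = iter(text.splitlines())
    header: dict[str, str] = {}
    first = next(lines, "")
    while first.strip() == "":
        first = next(lines, None)
        if first is None:
            raise ProfileParseError("empty profile text")
    if not first.startswith("HMMER3"):
        raise ProfileParseError("missing HMMER3 format line")

    for line in lines:
        if line.split() and line.split()[0] == "HMM":
            break
        if not line.strip():
            continue
        key, _, value = line.partition(" ")
        header[key.strip()] = value.strip()
    else:
        raise ProfileParseError("missing HMM model section")

    for req in ("NAME", "LENG", "ALPH"):
        if req not in header:
            raise ProfileParseError(f"missing mandatory header field {req}")
    if header["ALPH"].lower() != "amino":
        raise ProfileParseError("only amino-acid profiles are supported")
    M = int(header["LENG"])
    cutoff = None
    if "GA" in header:
        cutoff = float(header["GA"].split()[0].rstrip(";"))

    next(lines)  # m->m m->i ... header line

    def decode(tok: str) -> float:
        return 0.0 if tok == "*" else math.exp(-float(tok))

    me = np.zeros((M, 20))
    ie = np.zeros((M, 20))
    tr = np.zeros((M, 7))
    node = 0
    rows = [ln.split() for ln in lines if ln.strip() and ln.strip() != "//"]
    pos = 0
    # optional COMPO line plus the node-0 insert/transition pair
    if rows and rows[0][0] == "COMPO":
        pos += 1
    pos += 2  # node-0 insert emissions and transitions (unused: entry is free)
    while node < M:
        if pos + 2 >= len(rows) + 1:
            raise ProfileParseError(f"truncated profile at node {node + 1}")
        mrow = rows[pos]
        if int(mrow[0]) != node + 1:
            raise ProfileParseError(f"unexpected node index {mrow[0]}")
        me[node] = [decode(t) for t in mrow[1:21]]
        ie[node] = [decode(t) for t in rows[pos + 1][:20]]
        tr[node] = [decode(t) for t in rows[pos + 2][:7]]
        node += 1
        pos += 3
    # final node: m->d has no successor; renormalise defensively
    for grp in ((0, 1, 2), (3, 4), (5, 6)):
        s = tr[:, grp].sum(axis=1)
        s[s == 0] = 1.0
        tr[:, grp] /= s[:, None]
    me /= me.sum(axis=1, keepdims=True)
    ie /= ie.sum(axis=1, keepdims=True)
    return ProfileHMM(
        name=header["NAME"],
        accession=header.get("ACC", ""),
        match_emissions=me,
        insert_emissions=ie,
        transitions=tr,
        cutoff_bits=cutoff,
    )


def parse_profiles(text: str) -> list[ProfileHMM]:
    """Parse a multi-profile HMMER3 file (profiles separated by ``//``)."""
    out = []
    for chunk in text.split("//"):
        if chunk.strip():
            out.append(parse_profile(chunk))
    return out


def write_profile(hmm: ProfileHMM) -> str:
    """Serialise a profile to HMMER3/f text (inverse of `parse_profile`)."""

    def enc(p: float) -> str:
        return "*" if p <= 0 else f"{-math.log(p):.5f}"

    buf = io.StringIO()
    buf.write("HMMER3/f [ice-scout profile]\n")
    buf.write(f"NAME  {hmm.name}\n")
    if hmm.accession:
        buf.write(f"ACC   {hmm.accession}\n")
    buf.write(f"LENG  {hmm.M}\n")
    buf.write("ALPH  amino\n")
    if hmm.cutoff_bits is not None:
        buf.write(f"GA    {hmm.cutoff_bits:.2f} {hmm.cutoff_bits:.2f};\n")
    def fmt(tokens: list[str]) -> str:
        return "  " + "  ".join(f"{t:>7s}" for t in tokens) + "\n"

    buf.write("HMM    " + fmt(list(AMINO_ACIDS))[2:])
    buf.write("        " + fmt(["m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d"])[2:])
    # node 0: insert emissions (background) and begin transitions; entry is
    # free in this package's scorer, values written for format compliance.
    buf.write("       " + fmt([enc(p) for p in hmm.background]))
    buf.write("       " + fmt([enc(0.9), enc(0.05), enc(0.05), enc(0.5), enc(0.5), "0.00000", "*"]))
    for k in range(hmm.M):
        trans = [enc(p) for p in hmm.transitions[k]]
        if k == hmm.M - 1:
            # the final node transitions to the end state only
            trans = ["0.00000", trans[1], "*", trans[3], trans[4], "0.00000", "*"]
        cons = AMINO_ACIDS[int(np.argmax(hmm.match_emissions[k]))]
        buf.write(
            f"{k + 1:7d}"
            + fmt([enc(p) for p in hmm.match_emissions[k]]).rstrip("\n")
            + f" {k + 1:6d} {cons} - - -\n"
        )
        buf.write("       " + fmt([enc(p) for p in hmm.insert_emissions[k]]))
        buf.write("       " + fmt(trans))
    buf.write("//\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Profile construction from alignments
# ---------------------------------------------------------------------------

GAP_CHARS = set("-.")


def build_profile(
    msa: Msa,
    name: str = "profile",
    match_gap_frac: float = 0.5,
    pseudocount_weight: float = 0.1,
    cutoff_bits: float | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a multiple sequence alignment.

    Columns whose gap fraction is below ``match_gap_frac`` become match
    states.  Match emissions use a background-mixture pseudocount:

        p(a) = (count_a + w * 20 * bg_a) / (n_obs + w * 20)

    with ``w = pseudocount_weight``.  Insert states emit the background.
    Transitions are counted from each row's state path through the
    alignment with the analogous pseudocount per option.

    Raises
    ------
    ValueError
        If no column qualifies as a match state.
    """
    n = len(msa.rows)
    cols = []
    for j in range(msa.width):
        gaps = sum(1 for r in msa.rows if r[j] in GAP_CHARS)
        if gaps / n < match_gap_frac:
            cols.append(j)
    if not cols:
        raise ValueError("no match states: every column exceeds the gap fraction")
    M = len(cols)
    match_col = {j: k for k, j in enumerate(cols)}

    w = pseudocount_weight
    counts = np.zeros((M, 20))
    nobs = np.zeros(M)
    # transition counts per node: mm mi md im ii dm dd
    tcounts = np.zeros((M, 7))

    for row in msa.rows:
        # state path: list of (kind, node) visited, kinds 'M','D','I'
        path: list[tuple[str, int]] = []
        for j, ch in enumerate(row):
            if j in match_col:
                k = match_col[j]
                if ch in GAP_CHARS:
                    path.append(("D", k))
                else:
                    path.append(("M", k))
                    if ch in _AA_INDEX:
                        counts[k, _AA_INDEX[ch]] += 1
                        nobs[k] += 1
                    elif ch in AMBIGUOUS:
                        counts[k] += BACKGROUND
                        nobs[k] += 1
            else:
                if ch not in GAP_CHARS:
                    node = match_col.get(max((c for c in cols if c < j), default=-1), -1)
                    path.append(("I", node))
        # collapse runs of I and count transitions between consecutive states
        for (k1, n1), (k2, n2) in zip(path, path[1:]):
            node = n1 if k1 != "I" else n1
            if node < 0:
                continue  # inserts before the first match column: free entry
            if k1 == "M":
                tcounts[node, {"M": 0, "I": 1, "D": 2}[k2]] += 1
            elif k1 == "I":
                # plan7 has no I->D; attribute an insert-then-delete row to I->M
                tcounts[node, 3 if k2 in ("M", "D") else 4] += 1
            elif k1 == "D":
                tcounts[node, 5 if k2 in ("M", "I") else 6] += 1

    me = (counts + w * 20 * BACKGROUND) / (nobs[:, None] + w * 20)
    ie = np.tile(BACKGROUND, (M, 1))
    tr = np.zeros((M, 7))
    for grp in ((0, 1, 2), (3, 4), (5, 6)):
        cnt = tcounts[:, grp]
        tr[:, grp] = (cnt + w) / (cnt.sum(axis=1, keepdims=True) + len(grp) * w)
    # last node: only exit is legal
    tr[-1] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]
    return ProfileHMM(
        name=name,
        accession="",
        match_emissions=me,
        insert_emissions=ie,
        transitions=tr,
        cutoff_bits=cutoff_bits,
    )


# ---------------------------------------------------------------------------
# Viterbi scoring
# ---------------------------------------------------------------------------

NEG_INF = -np.inf

try:  # numba accelerates the O(L*M) Viterbi recursion ~50x
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


@_njit(cache=False)
def _viterbi_kernel(idx, melo, ielo, tlog):  # pragma: no cover - exercised via score_sequence
    L = idx.shape[0]
    M = melo.shape[0]
    neg = -1e300
    pm = np.full(M, neg)
    pi = np.full(M, neg)
    pd = np.full(M, neg)
    sm = np.zeros(M, np.int64)
    si = np.zeros(M, np.int64)
    sd = np.zeros(M, np.int64)
    cm = np.empty(M)
    ci = np.empty(M)
    cd = np.empty(M)
    csm = np.zeros(M, np.int64)
    csi = np.zeros(M, np.int64)
    csd = np.zeros(M, np.int64)
    best = neg
    best_start = 0
    best_end = 1
    for i in range(L):
        c = idx[i]
        for k in range(M):
            # match state: free local entry or continuation
            bv = 0.0
            bs = i
            if k > 0:
                v = pm[k - 1] + tlog[k - 1, 0]
                if v > bv:
                    bv = v
                    bs = sm[k - 1]
                v = pi[k - 1] + tlog[k - 1, 3]
                if v > bv:
                    bv = v
                    bs = si[k - 1]
                v = pd[k - 1] + tlog[k - 1, 5]
                if v > bv:
                    bv = v
                    bs = sd[k - 1]
            cm[k] = melo[k, c] + bv
            csm[k] = bs
            # insert state
            va = pm[k] + tlog[k, 1]
            vb = pi[k] + tlog[k, 4]
            if va >= vb:
                ci[k] = ielo[k, c] + va
                csi[k] = sm[k]
            else:
                ci[k] = ielo[k, c] + vb
                csi[k] = si[k]
            # delete state (same row, needs cm[k-1] and cd[k-1])
            if k > 0:
                va = cm[k - 1] + tlog[k - 1, 2]
                vb = cd[k - 1] + tlog[k - 1, 6]
                if va >= vb:
                    cd[k] = va
                    csd[k] = csm[k - 1]
                else:
                    cd[k] = vb
                    csd[k] = csd[k - 1]
            else:
                cd[k] = neg
                csd[k] = 0
            if cm[k] > best:
                best = cm[k]
                best_start = csm[k]
                best_end = i + 1
        pm, cm = cm, pm
        pi, ci = ci, pi
        pd, cd = cd, pd
        sm, csm = csm, sm
        si, csi = csi, si
        sd, csd = csd, sd
    return best, best_start, best_end


def _provider_index(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Running max of ``values`` and, per position, the index providing it.

    Ties keep the earliest provider (deterministic).
    """
    running = np.maximum.accumulate(values)
    prev = np.concatenate(([NEG_INF], running[:-1]))
    idx = np.arange(len(values))
    is_new = values > prev
    provider = np.maximum.accumulate(np.where(is_new, idx, -1))
    return running, provider


def score_sequence(hmm: ProfileHMM, seq: str, seq_id: str = "query") -> HmmHit:
    """Best local Viterbi log2-odds of ``seq`` against ``hmm``.

    The alignment may use any contiguous run of model nodes entered and
    exited at match states, against any subsequence of ``seq``; entry and
    exit are free.  Returns the bit score with the envelope (0-based
    half-open sequence coordinates) of the optimal path.  The E-value
    field is NaN unless the profile carries a Gumbel calibration
    (see `calibrate_gumbel_mu` / `evalue`).
    """
    if not seq:
        raise ValueError("cannot score an empty sequence")
    idx = seq_to_indices(seq)
    melo, ielo, tlog = hmm._scoring_arrays()
    M = hmm.M
    L = len(idx)

    if _HAVE_NUMBA:
        best_v, bs, be = _viterbi_kernel(
            idx.astype(np.int64), melo, ielo, np.ascontiguousarray(tlog)
        )
        return _finish_hit(hmm, seq_id, float(best_v), int(bs), int(be))

    tmm, tmi, tmd = tlog[:, 0], tlog[:, 1], tlog[:, 2]
    tim, tii = tlog[:, 3], tlog[:, 4]
    tdm, tdd = tlog[:, 5], tlog[:, 6]
    # cum_dd[k] = sum of tdd over nodes 0..k-1, so a delete run j+1..k-1
    # contributes cum_dd[k] - cum_dd[j+1]
    cum_dd = np.concatenate(([0.0], np.cumsum(tdd)))

    prev_m = np.full(M, NEG_INF)
    prev_i = np.full(M, NEG_INF)
    prev_d = np.full(M, NEG_INF)
    start_m = np.zeros(M, dtype=np.intp)
    start_i = np.zeros(M, dtype=np.intp)
    start_d = np.zeros(M, dtype=np.intp)

    best = NEG_INF
    best_start = 0
    best_end = 1

    for i in range(L):
        em = melo[:, idx[i]]
        # candidates for M[i][k]: entry, M[i-1][k-1]+tmm, I[i-1][k-1]+tim, D[i-1][k-1]+tdm
        cand = np.full((4, M), NEG_INF)
        cand[0] = 0.0  # free local entry at any match state
        cand[1, 1:] = prev_m[:-1] + tmm[:-1]
        cand[2, 1:] = prev_i[:-1] + tim[:-1]
        cand[3, 1:] = prev_d[:-1] + tdm[:-1]
        choice = np.argmax(cand, axis=0)
        cur_m = em + np.take_along_axis(cand, choice[None, :], axis=0)[0]
        starts = np.vstack([
            np.full(M, i, dtype=np.intp),
            np.concatenate(([0], start_m[:-1])),
            np.concatenate(([0], start_i[:-1])),
            np.concatenate(([0], start_d[:-1])),
        ])
        cur_start_m = np.take_along_axis(starts, choice[None, :], axis=0)[0]

        # I[i][k]: from M[i-1][k]+tmi or I[i-1][k]+tii
        a = prev_m + tmi
        b = prev_i + tii
        use_a = a >= b
        cur_i = ielo[:, idx[i]] + np.where(use_a, a, b)
        cur_start_i = np.where(use_a, start_m, start_i)

        # D[i][k] = max_{j<k} M[i][j] + tmd[j] + sum(tdd over nodes j+1..k-1),
        # a running max of S[j] = M[i][j] + tmd[j] - cum_dd[j+1], plus cum_dd[k]
        cur_d = np.full(M, NEG_INF)
        cur_start_d = np.zeros(M, dtype=np.intp)
        if M > 1:
            s = cur_m + tmd - cum_dd[1 : M + 1]
            run, provider = _provider_index(s[: M - 1])
            cur_d[1:] = cum_dd[1:M] + run
            valid = provider >= 0
            cur_start_d[1:] = np.where(
                valid, cur_start_m[np.maximum(provider, 0)], 0
            )

        end_here = cur_m  # exit free from any match state
        k_best = int(np.argmax(end_here))
        if end_here[k_best] > best:
            best = float(end_here[k_best])
            best_start = int(cur_start_m[k_best])
            best_end = i + 1

        prev_m, prev_i, prev_d = cur_m, cur_i, cur_d
        start_m, start_i, start_d = cur_start_m, cur_start_i, cur_start_d

    return _finish_hit(hmm, seq_id, best, best_start, best_end)


def _finish_hit(
    hmm: ProfileHMM, seq_id: str, best: float, start: int, end: int
) -> HmmHit:
    e_val = float("nan")
    mu = getattr(hmm, "gumbel_mu", None)
    if mu is not None:
        e_val = evalue(best, mu, getattr(hmm, "gumbel_db_size", 1))
    return HmmHit(
        seq_id=seq_id,
        hmm_name=hmm.name,
        bit_score=best,
        e_value=e_val,
        env_start=start,
        env_end=end,
    )


def call_presence(hit: HmmHit, hmm: ProfileHMM, override_bits: float | None = None) -> bool:
    """True iff the hit's bit score reaches the presence cutoff (>= semantics)."""
    threshold = override_bits if override_bits is not None else hmm.cutoff_bits
    if threshold is None:
        raise CutoffError(f"no presence cutoff available for HMM {hmm.name!r}")
    return hit.bit_score >= threshold


# ---------------------------------------------------------------------------
# E-value calibration (Gumbel with fixed lambda = ln 2 on the bit scale)
# ---------------------------------------------------------------------------

def calibrate_gumbel_mu(
    hmm: ProfileHMM,
    queries: list[str],
    n_shuffles: int = 200,
    seed: int = 0,
    db_size: int = 1,
) -> float:
    """Fit the Gumbel location for ``hmm`` from shuffled decoy sequences.

    Each decoy is a residue permutation of one query (cycling through the
    query set until ``n_shuffles`` decoys exist), so decoys match the
    queries in length and composition.  With the scale fixed at
    λ = ln 2 per bit, the location is the method-of-moments estimate
    μ = mean(score) − γ/λ.  The fitted values are attached to the profile
    so subsequent `score_sequence` calls report E-values.
    """
    if not queries:
        raise ValueError("need at least one query sequence to calibrate")
    rng = np.random.default_rng(seed)
    scores = []
    for s in range(n_shuffles):
        q = queries[s % len(queries)]
        letters = np.array(list(q))
        rng.shuffle(letters)
        scores.append(score_sequence(hmm, "".join(letters)).bit_score)
    lam = math.log(2.0)
    mu = float(np.mean(scores)) - _EULER_GAMMA / lam
    hmm.gumbel_mu = mu
    hmm.gumbel_db_size = db_size
    return mu


def evalue(bit_score: float, mu: float, db_size: int = 1) -> float:
    """Gumbel tail probability times database size, λ fixed at ln 2."""
    lam = math.log(2.0)
    p = -math.expm1(-math.exp(-lam * (bit_score - mu)))
    return max(db_size * p, 5e-324)
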