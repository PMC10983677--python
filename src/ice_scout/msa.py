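"""Multiple sequence alignment via MAFFT.

Alignment is a commodity step here, not part of the method itself, so it
is delegated to MAFFT (deterministic in its default progressive mode).
Input order is preserved in the output alignment.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

from ice_scout.phmm import Msa


def align_proteins(named_seqs: list[tuple[str, str]]) -> Msa:
    """Align (id, protein) pairs with ``mafft --quiet`` and return an Msa.

    Sequences that are already equal-length and ungapped pass through
    unchanged (the aligner cannot improve a gapless rectangle and this
    keeps the fast path deterministic and cheap).
    """
    if len(named_seqs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    ids = [n for n, _ in named_seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    lengths = {len(s) for _, s in named_seqs}
    if len(lengths) == 1:
        return Msa(ids, [s for _, s in named_seqs])

    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fa"
        with open(fa, "w") as fh:
            for i, (_, seq) in enumerate(named_seqs):
                fh.write(f">s{i}\n{seq}\n")
        proc = subprocess.run(
            ["mafft", "--quiet", "--anysymbol", str(fa)],
            capture_output=True,
            text=True,
            check=True,
        )
    rows: dict[str, str] = {}
    current = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].strip()
            rows[current] = ""
        elif current is not None:
            rows[current] += line.strip()
    aligned = [rows[f"s{i}"].upper() for i in range(len(named_seqs))]
    return Msa(ids, aligned)
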