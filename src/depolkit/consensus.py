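"""Column-wise consensus sequence with BLOSUM62 tie resolution.

Per column the most frequent residue wins.  When several residues share the
top count, the winner is the candidate with the highest summed BLOSUM62
similarity to the column's (non-gap) residues; exact score ties fall back to
alphabetical order.  Columns whose most common character is the gap are left
out of the consensus protein but kept in the per-column audit table.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .errors import DataError
from .seqio import GAP, ProteinAlignment, ScoringMatrix, load_blosum62


@dataclass(frozen=True)
class ConsensusColumn:
    index: int  # 0-based alignment column
    counts: dict[str, int]  # residue -> count, gaps excluded
    gap_count: int
    winner: str | None  # None when the column is gap-majority or all-gap
    tie: bool
    tie_scores: dict[str, int]  # candidate -> summed BLOSUM62 score


@dataclass(frozen=True)
class ConsensusResult:
    sequence: str
    columns: tuple[ConsensusColumn, ...]


def _pick_winner(
    counts: Counter,
    column: str,
    matrix: ScoringMatrix,
    score_scope: str,
) -> tuple[str, bool, dict[str, int]]:
    top = max(counts.values())
    tied = sorted(r for r, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0], False, {}
    if score_scope == "column":
        context = [c for c in column if c != GAP]
    elif score_scope == "ties":
        context = [c for c in column if c in tied]
    else:
        raise DataError(f"unknown score_scope {score_scope!r}")
    scores = {r: matrix.score_against(r, context) for r in tied}
    best = max(scores.values())
    winners = sorted(r for r, s in scores.items() if s == best)
    return winners[0], True, scores


def consensus_sequence(
    aln: ProteinAlignment,
    gap_policy: str = "omit",
    matrix: ScoringMatrix | None = None,
    score_scope: str = "column",
) -> ConsensusResult:
    """Most-common-residue consensus of a non-empty alignment.

    ``gap_policy``: 'omit' drops gap-majority columns from the sequence,
    'dash' emits '-' for them.  ``score_scope`` controls whether tie-break
    scores are computed against the whole column or only the tied residues.
    """
    if aln.nrow == 0 or aln.ncol == 0:
        raise DataError("consensus of an empty alignment is undefined")
    if gap_policy not in ("omit", "dash"):
        raise DataError(f"unknown gap_policy {gap_policy!r}")
    if matrix is None:
        matrix = load_blosum62()
    chars: list[str] = []
    cols: list[ConsensusColumn] = []
    for j, column in enumerate(aln.columns()):
        counts = Counter(c for c in column if c != GAP)
        gap_count = sum(1 for c in column if c == GAP)
        if not counts:
            warnings.warn(f"column {j + 1} is entirely gaps; omitted")
            cols.append(ConsensusColumn(j, {}, gap_count, None, False, {}))
            continue
        top = max(counts.values())
        if gap_count > top:
            cols.append(
                ConsensusColumn(j, dict(counts), gap_count, None, False, {})
            )
            if gap_policy == "dash":
                chars.append(GAP)
            continue
        winner, tie, scores = _pick_winner(counts, column, matrix, score_scope)
        cols.append(
            ConsensusColumn(j, dict(counts), gap_count, winner, tie, scores)
        )
        chars.append(winner)
    return ConsensusResult("".join(chars), tuple(cols))


def write_consensus_table(result: ConsensusResult, path) -> None:
    """TSV audit table: column, winner, tie flag, counts, tie scores."""
    with open(path, "w") as fh:
        fh.write("column\twinner\ttie\tgap_count\tcounts\ttie_scores\n")
        for col in result.columns:
            counts = ",".join(
                f"{r}:{c}" for r, c in sorted(col.counts.items())
            )
            scores = ",".join(
                f"{r}:{s}" for r, s in sorted(col.tie_scores.items())
            )
            fh.write(
                f"{col.index + 1}\t{col.winner or '-'}\t"
                f"{int(col.tie)}\t{col.gap_count}\t{counts}\t{scores}\n"
            )
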