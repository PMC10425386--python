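"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own algorithms: microhomology is
counted by enumerating equal-length deletion placements, alignment by an
exhaustive affine-gap dynamic program that enumerates every optimal
path, and coverage by direct per-base counting.
"""

from __future__ import annotations

from editcall.align import AlignmentResult, events_from_alignment

NEG = float("-inf")


def mh_by_placement_count(reference: str, del_start: int, del_end: int) -> int:
    """Number of equal-length deletion placements with identical product, minus 1."""
    dl = del_end - del_start
    edited = reference[:del_start] + reference[del_end:]
    count = 0
    for t in range(0, len(reference) - dl + 1):
        if reference[:t] + reference[t + dl:] == edited:
            count += 1
    return count - 1


def affine_optimal(
    target: str,
    query: str,
    match: float = 2.0,
    mismatch: float = -2.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    max_paths: int = 5000,
):
    """Exhaustive global affine-gap alignment.

    Gap of length k costs gap_open + (k - 1) * gap_extend. Returns
    (score, set of canonical event tuples) where each member is one
    optimal alignment's left-normalized event list.
    """
    n, m = len(target), len(query)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query: deletion
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target: insertion
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if target[i - 1] == query[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    score = max(M[n][m], X[n][m], Y[n][m])

    paths: list[list[str]] = []

    def walk(i: int, j: int, state: str, acc: list[str]) -> None:
        if len(paths) >= max_paths:
            return
        if i == 0 and j == 0 and state == "M":
            paths.append(list(reversed(acc)))
            return
        if state == "M":
            if i == 0 or j == 0:
                return
            s = match if target[i - 1] == query[j - 1] else mismatch
            col = "match" if target[i - 1] == query[j - 1] else "mismatch"
            want = M[i][j] - s
            for prev, grid in (("M", M), ("X", X), ("Y", Y)):
                if grid[i - 1][j - 1] == want:
                    walk(i - 1, j - 1, prev, acc + [col])
        elif state == "X":
            if i == 0:
                return
            if i >= 1 and j == 0 and X[i][j] == gap_open + (i - 1) * gap_extend:
                paths.append(list(reversed(acc + ["del"] * i)))
                return
            if M[i - 1][j] + gap_open == X[i][j]:
                walk(i - 1, j, "M", acc + ["del"])
            if X[i - 1][j] + gap_extend == X[i][j]:
                walk(i - 1, j, "X", acc + ["del"])
            if Y[i - 1][j] + gap_open == X[i][j]:
                walk(i - 1, j, "Y", acc + ["del"])
        else:
            if j == 0:
                return
            if j >= 1 and i == 0 and Y[i][j] == gap_open + (j - 1) * gap_extend:
                paths.append(list(reversed(acc + ["ins"] * j)))
                return
            if M[i][j - 1] + gap_open == Y[i][j]:
                walk(i, j - 1, "M", acc + ["ins"])
            if Y[i][j - 1] + gap_extend == Y[i][j]:
                walk(i, j - 1, "Y", acc + ["ins"])
            if X[i][j - 1] + gap_open == Y[i][j]:
                walk(i, j - 1, "X", acc + ["ins"])

    for state, grid in (("M", M), ("X", X), ("Y", Y)):
        if grid[n][m] == score:
            walk(n, m, state, [])

    event_sets = set()
    for cols in paths:
        event_sets.add(_events_from_columns(cols, target, query))
    return score, event_sets


def _events_from_columns(cols: list[str], target: str, query: str):
    """Column labels -> run-length ops -> canonical normalized events."""
    ops: list[tuple[str, int, str]] = []
    ti = qi = 0
    for col in cols:
        qchar = ""
        if col in ("match", "mismatch"):
            qchar = query[qi]
            ti += 1
            qi += 1
        elif col == "ins":
            qchar = query[qi]
            qi += 1
        else:
            ti += 1
        if ops and ops[-1][0] == col:
            op, length, seq = ops[-1]
            ops[-1] = (op, length + 1, seq + (qchar if col in ("mismatch", "ins") else ""))
        else:
            ops.append((col, 1, qchar if col in ("mismatch", "ins") else ""))
    aln = AlignmentResult(allele_name="oracle", score=0.0, ops=ops, ref_span=(0, len(target)))
    events = events_from_alignment(aln, target, (0, len(target)))
    return tuple((e.etype.value, e.ref_start, e.length, e.inserted_seq) for e in events)


def canonical_events(aln: AlignmentResult, target: str):
    events = events_from_alignment(aln, target, (0, len(target)))
    return tuple((e.etype.value, e.ref_start, e.length, e.inserted_seq) for e in events)


def coverage_by_counting(alignments, amplicon_length: int):
    """Direct per-base counting of covered (non-deleted) positions."""
    depth = [0] * amplicon_length
    ids = set()
    for aln in alignments:
        ids.add(aln.read_id)
        for pos in range(max(aln.start, 0), min(aln.end, amplicon_length)):
            if any(s <= pos < e for s, e in aln.deletions):
                continue
            depth[pos] += 1
    return depth, len(ids)
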