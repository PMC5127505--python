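"""Independent oracles for the codon-unit aligner.

Two layers: :func:`enumerate_best_score` exhaustively walks every monotone
move path through the alignment lattice (no memoisation — literally every
alignment is visited), which is tractable only for references of about
three codons; :func:`recursive_best_score` is a memoised top-down
maximisation over the same move set, validated against the exhaustive
walker and then used as the oracle for larger references.  Both are coded
against the move definitions only and share nothing with the production
dynamic program.
"""

from __future__ import annotations

from functools import lru_cache


def recursive_best_score(refseq: str, core: str, match: int, mismatch: int,
                         indel: int) -> int:
    """Memoised top-down best alignment score over the three move classes."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == 0 and j == 0:
            return 0
        best = None
        if i >= 3 and i % 3 == 0 and j >= 3:
            sc = go(i - 3, j - 3) + (
                match if refseq[i - 3 : i] == core[j - 3 : j] else mismatch
            )
            best = sc
        for k in (1, 2, 3):
            if i >= k:
                sc = go(i - k, j) + indel
                best = sc if best is None else max(best, sc)
            if j >= k:
                sc = go(i, j - k) + indel
                best = sc if best is None else max(best, sc)
        assert best is not None
        return best

    return go(len(refseq), len(core))


def enumerate_best_score(refseq: str, core: str, match: int, mismatch: int,
                         indel: int) -> int:
    """Exhaustive depth-first enumeration of every alignment path."""
    R, n = len(refseq), len(core)
    best = [None]

    def walk(i: int, j: int, score: int) -> None:
        if i == R and j == n:
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i + 3 <= R and i % 3 == 0 and j + 3 <= n:
            walk(
                i + 3, j + 3,
                score + (match if refseq[i : i + 3] == core[j : j + 3] else mismatch),
            )
        for k in (1, 2, 3):
            if i + k <= R:
                walk(i + k, j, score + indel)
            if j + k <= n:
                walk(i, j + k, score + indel)

    walk(0, 0, 0)
    assert best[0] is not None
    return best[0]


def edit_case_grid(refseq: str, pair_stride: int = 20) -> list[str]:
    """Deterministic grid of cores derived from ``refseq`` by small edits.

    All single edits (three alternative codons per position, deletions and
    insertions of 1-3 nt at every offset) plus every ``pair_stride``-th
    ordered pair of them applied sequentially.
    """
    singles: list[str] = []
    n_codons = len(refseq) // 3
    for ci in range(n_codons):
        codon = refseq[3 * ci : 3 * ci + 3]
        for p in range(3):
            for b in "ACGT":
                if b != codon[p]:
                    alt = codon[:p] + b + codon[p + 1 :]
                    singles.append(refseq[: 3 * ci] + alt + refseq[3 * ci + 3 :])
                    break  # one substitute base per codon position
    for pos in range(len(refseq)):
        for length in (1, 2, 3):
            if pos + length <= len(refseq):
                singles.append(refseq[:pos] + refseq[pos + length :])
    for pos in range(len(refseq) + 1):
        for ins in ("A", "CT", "GAC"):
            singles.append(refseq[:pos] + ins + refseq[pos:])

    cases = list(dict.fromkeys(singles))
    pairs = []
    items = sorted(cases)
    for idx in range(0, len(items) * len(items), pair_stride):
        a, b = divmod(idx, len(items))
        if a >= len(items):
            break
        first = items[a]
        # apply edit b's delta crudely: splice a window of items[b]
        second = items[b]
        mid = min(len(first), len(second)) // 2
        pairs.append(first[:mid] + second[mid:])
    out = [c for c in cases + pairs if c and abs(len(c) - len(refseq)) <= 9]
    return list(dict.fromkeys(out))
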