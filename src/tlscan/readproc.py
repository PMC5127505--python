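"""Codon-aware variant calling from pooled amplicon reads.

The caller follows the screen's bespoke three-stage recipe:

1. :func:`merge_and_verify` — paired-end merging with perfect-flank
   verification: the mates must agree exactly in their overlap, and the
   flanking sequences must match the wild-type reference exactly; the core
   between the flanks is extracted.
2. :func:`codon_align` — a codon-unit dynamic-programming global alignment
   of the core against the reference coding region: an exact three-letter
   codon match earns a positive score, any mismatch within a codon a
   negative score, and an insertion or deletion of one, two or three
   nucleotides a constant negative score.
3. :func:`call_variant` — substituted codons are accepted only if they
   belong to the expected set programmed into the library (plus spike-ins);
   anything else — an unexpected codon (the signature of a sequencing
   error) or any indel — is rejected.

Accepted calls are tallied per sample into an :class:`AlleleCountTable`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .synthetic_data import (
    WT_ID,
    AmpliconReference,
    CODON_TO_AA,
    ExpectedVariantSet,
    reverse_complement,
)

__all__ = [
    "MergedRead",
    "ScoringScheme",
    "CodonSubstitution",
    "Insertion",
    "Deletion",
    "AlignmentResult",
    "Substitution",
    "VariantCall",
    "AlleleCountTable",
    "AlignmentBandError",
    "merge_and_verify",
    "codon_align",
    "call_variant",
    "call_core",
    "call_readset",
    "call_fastq_pair",
    "count_alleles",
]

REJECT_REASONS = (
    "flank_mismatch",
    "overlap_disagreement",
    "no_overlap",
    "unexpected_codon",
    "indel",
    "unalignable",
)


class AlignmentBandError(ValueError):
    """Core length deviates from the reference by more than the band."""


# --------------------------------------------------------------------------
# Paired-end merging with flank verification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    core_sequence: str | None = None
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.core_sequence is None) == (self.reject_reason is None):
            raise ValueError(
                "exactly one of core_sequence / reject_reason must be set"
            )


def merge_and_verify(
    read1: str,
    read2: str,
    ref: AmpliconReference,
    read_id: str = "",
    flank_len: int = 15,
    min_overlap: int = 10,
) -> MergedRead:
    """Merge an innie pair and extract the core between the WT flanks.

    Mate 2 is reverse-complemented, the merged length with an exactly
    agreeing overlap is found, and the configured flank keys (the
    ``flank_len`` reference nucleotides adjacent to the coding region on
    each side) must occur verbatim in the merged sequence.  Failures are
    encoded in ``reject_reason`` rather than raised.
    """
    if flank_len > len(ref.upstream_flank) or flank_len > len(ref.downstream_flank):
        raise ValueError("flank_len exceeds the reference flank length")
    r1, r2 = read1.upper(), reverse_complement(read2.upper())
    len1, len2 = len(r1), len(r2)
    merged = None
    overlap_seen = False
    # merged length L: r1 spans [0, len1), r2 spans [L - len2, L)
    for L in range(max(len1, len2), len1 + len2 - min_overlap + 1):
        start2 = L - len2
        lo, hi = max(0, start2), min(len1, L)
        if hi - lo < min_overlap:
            continue
        overlap_seen = True
        if r1[lo:hi] == r2[lo - start2 : hi - start2]:
            # mate 2 may extend past the start of mate 1 (start2 < 0)
            merged = (r1[:start2] + r2) if start2 > 0 else r2
            break
    if merged is None:
        reason = "overlap_disagreement" if overlap_seen else "no_overlap"
        return MergedRead(read_id, reject_reason=reason)

    up_key = ref.upstream_flank[-flank_len:]
    down_key = ref.downstream_flank[:flank_len]
    i = merged.find(up_key)
    if i < 0:
        return MergedRead(read_id, reject_reason="flank_mismatch")
    core_start = i + flank_len
    j = merged.find(down_key, core_start)
    if j < 0:
        return MergedRead(read_id, reject_reason="flank_mismatch")
    return MergedRead(read_id, core_sequence=merged[core_start:j])


# --------------------------------------------------------------------------
# Codon-unit dynamic-programming alignment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoringScheme:
    """Move scores of the codon-unit aligner.

    A codon match is positive, a codon containing at least one mismatched
    letter is negative, and an insertion or deletion of one, two or three
    letters costs the same constant negative score regardless of length.
    Defaults (+1, -1, -2) make a single codon substitution outscore any
    indel pair explaining the same core, keeping substitution calls
    canonical.
    """

    codon_match: int = 1
    codon_mismatch: int = -1
    indel: int = -2

    def __post_init__(self) -> None:
        if self.codon_match <= 0:
            raise ValueError("codon_match must be positive")
        if self.codon_mismatch >= 0 or self.indel >= 0:
            raise ValueError("codon_mismatch and indel must be negative")

    @property
    def max_fastpath_mismatches(self) -> int:
        """Largest mismatched-codon count for which the plain diagonal
        alignment of an equal-length core is guaranteed optimal.

        Equal lengths force any indel-bearing alignment to contain at least
        two indel moves, bounding its score by ``C*match + 2*indel``; the
        diagonal scores ``(C-m)*match + m*mismatch``.
        """
        return (2 * self.indel) // (self.codon_mismatch - self.codon_match)


@dataclass(frozen=True)
class CodonSubstitution:
    codon_index: int  # 1-based
    observed_codon: str


@dataclass(frozen=True)
class Insertion:
    position: int  # reference nt offset (0-based) before which nt are inserted
    length: int
    sequence: str = ""


@dataclass(frozen=True)
class Deletion:
    position: int  # reference nt offset (0-based) of the first deleted nt
    length: int


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    edits: tuple
    n_codon_matches: int


_NEG = -(10**9)


def codon_align(
    core: str,
    ref: AmpliconReference,
    scheme: ScoringScheme = ScoringScheme(),
    band: int = 9,
) -> AlignmentResult:
    """Maximum-score global alignment of a core against the codon sequence.

    The lattice is hybrid: the reference is consumed codon-wise on diagonal
    moves (3 nt at a time, only at codon boundaries) and nucleotide-wise on
    deletion moves; insertions consume 1-3 core nucleotides.  Ties are
    broken deterministically: codon substitution over indels, deletions
    over insertions, longer indels before shorter.

    Raises :class:`AlignmentBandError` when the core length deviates from
    the reference by more than ``band`` nucleotides.
    """
    if not core:
        raise ValueError("core sequence is empty")
    refseq = ref.coding_sequence
    R, n = len(refseq), len(core)
    if abs(n - R) > band:
        raise AlignmentBandError(
            f"core length {n} outside band {band} of reference length {R}"
        )

    # fast path: equal lengths, few mismatched codons -> diagonal is optimal
    if n == R:
        mismatched = [
            ci
            for ci in range(1, ref.n_codons + 1)
            if core[3 * ci - 3 : 3 * ci] != refseq[3 * ci - 3 : 3 * ci]
        ]
        if len(mismatched) <= scheme.max_fastpath_mismatches:
            edits = tuple(
                CodonSubstitution(ci, core[3 * ci - 3 : 3 * ci]) for ci in mismatched
            )
            n_match = ref.n_codons - len(mismatched)
            return AlignmentResult(
                score=n_match * scheme.codon_match
                + len(mismatched) * scheme.codon_mismatch,
                edits=edits,
                n_codon_matches=n_match,
            )

    match, mismatch, indel = scheme.codon_match, scheme.codon_mismatch, scheme.indel
    # move codes: 0 diagonal, 1/2/3 deletion of k, 4/5/6 insertion of k=code-3;
    # candidate order encodes the tie-break (diag > del, longer k first).
    trigram = [None, None, None] + [core[j - 3 : j] for j in range(3, n + 1)]
    refcodons = ref.codons
    S = [[_NEG] * (n + 1) for _ in range(R + 1)]
    move = [[-1] * (n + 1) for _ in range(R + 1)]
    S[0][0] = 0
    for i in range(R + 1):
        Si, Mi = S[i], move[i]
        diag = i >= 3 and i % 3 == 0
        if diag:
            S3 = S[i - 3]
            refc = refcodons[i // 3 - 1]
        rows_up = [(k, S[i - k]) for k in (3, 2, 1) if i >= k]
        for j in range(0 if i else 1, n + 1):
            best, bm = _NEG, -1
            if diag and j >= 3:
                best = S3[j - 3] + (match if refc == trigram[j] else mismatch)
                bm = 0
            for k, Sk in rows_up:
                sc = Sk[j] + indel
                if sc > best:
                    best, bm = sc, k
            for k in (3, 2, 1):
                if j >= k:
                    sc = Si[j - k] + indel
                    if sc > best:
                        best, bm = sc, k + 3
            Si[j] = best
            Mi[j] = bm

    i, j = R, n
    edits = []
    n_match = 0
    while i or j:
        m = move[i][j]
        if m < 0:  # pragma: no cover - lattice is always connected
            raise RuntimeError("alignment traceback failed")
        if m == 0:
            if refcodons[i // 3 - 1] == trigram[j]:
                n_match += 1
            else:
                edits.append(CodonSubstitution(i // 3, core[j - 3 : j]))
            i, j = i - 3, j - 3
        elif m <= 3:
            edits.append(Deletion(position=i - m, length=m))
            i -= m
        else:
            k = m - 3
            edits.append(Insertion(position=i, length=k, sequence=core[j - k : j]))
            j -= k
    edits.reverse()
    return AlignmentResult(score=S[R][n], edits=tuple(edits), n_codon_matches=n_match)


# --------------------------------------------------------------------------
# Variant identification against the expected codon set
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Substitution:
    codon_index: int
    wt_codon: str
    observed_codon: str
    wt_aa: str
    mutant_aa: str
    residue_number: int

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.residue_number}{self.mutant_aa}"


@dataclass(frozen=True)
class VariantCall:
    substitutions: tuple[Substitution, ...]
    status: str  # wildtype | single | multiple | rejected
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        if self.status == "rejected":
            if self.reject_reason is None or self.substitutions:
                raise ValueError("rejected calls carry a reason and no substitutions")
        elif self.reject_reason is not None:
            raise ValueError("only rejected calls carry a reject reason")
        elif self.status == "single" and len(self.substitutions) != 1:
            raise ValueError("status single requires exactly one substitution")
        elif self.status == "wildtype" and self.substitutions:
            raise ValueError("wildtype calls carry no substitutions")

    @property
    def variant_id(self) -> str:
        if self.status == "rejected":
            return f"rejected:{self.reject_reason}"
        if not self.substitutions:
            return WT_ID
        return ",".join(s.label for s in self.substitutions)


def call_variant(
    aln: AlignmentResult,
    ref: AmpliconReference,
    evs: ExpectedVariantSet,
) -> VariantCall:
    """Classify an alignment against the expected codon whitelist.

    Zero mismatched codons -> wildtype.  Every mismatched codon must be a
    programmed (or spike-in) codon at its position; any unexpected codon —
    the fingerprint of a sequencing error — or any indel rejects the read.
    """
    if any(isinstance(e, (Insertion, Deletion)) for e in aln.edits):
        return VariantCall((), "rejected", "indel")
    subs = []
    for e in aln.edits:
        assert isinstance(e, CodonSubstitution)
        if e.observed_codon not in evs.expected_codons(e.codon_index):
            return VariantCall((), "rejected", "unexpected_codon")
        subs.append(
            Substitution(
                codon_index=e.codon_index,
                wt_codon=ref.wt_codon(e.codon_index),
                observed_codon=e.observed_codon,
                wt_aa=ref.wt_aa(e.codon_index),
                mutant_aa=CODON_TO_AA[e.observed_codon],
                residue_number=ref.residue_of(e.codon_index),
            )
        )
    subs.sort(key=lambda s: s.codon_index)
    if not subs:
        return VariantCall((), "wildtype")
    status = "single" if len(subs) == 1 else "multiple"
    return VariantCall(tuple(subs), status)


def call_core(
    core: str,
    ref: AmpliconReference,
    evs: ExpectedVariantSet,
    scheme: ScoringScheme = ScoringScheme(),
    band: int = 9,
) -> VariantCall:
    """Align a merged core and call it; band overflows become ``unalignable``."""
    try:
        aln = codon_align(core, ref, scheme, band)
    except AlignmentBandError:
        return VariantCall((), "rejected", "unalignable")
    return call_variant(aln, ref, evs)


# --------------------------------------------------------------------------
# Counting
# --------------------------------------------------------------------------


@dataclass
class AlleleCountTable:
    """Accepted reads per variant per sample, plus rejection tallies.

    ``counts`` is variants x samples (integer; includes the WT row),
    ``rejected`` is reject-reason x samples, and ``samples`` is the sample
    sheet (sample, condition, replicate, role) indexed by sample name.
    Per-sample mapped totals are the accepted column sums.
    """

    counts: pd.DataFrame
    rejected: pd.DataFrame
    samples: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sample_for(self, condition: str, replicate: int) -> str:
        hit = self.samples[
            (self.samples["condition"] == condition)
            & (self.samples["replicate"] == replicate)
        ]
        if len(hit) != 1:
            raise KeyError(f"no unique sample for ({condition}, {replicate})")
        return str(hit.index[0])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    @property
    def replicates(self) -> list[int]:
        return sorted(self.samples["replicate"].unique())


class _CoreCallCache:
    """Memoises calls by core sequence across samples of one screen."""

    def __init__(self, ref, evs, scheme, band):
        self.ref, self.evs, self.scheme, self.band = ref, evs, scheme, band
        self._cache: dict[str, VariantCall] = {}

    def __call__(self, core: str) -> VariantCall:
        call = self._cache.get(core)
        if call is None:
            call = call_core(core, self.ref, self.evs, self.scheme, self.band)
            self._cache[core] = call
        return call


def _tally(pairs, ref, evs, scheme, band, flank_len, min_overlap, cache=None):
    """pairs: iterable of (read_id, read1, read2, multiplicity)."""
    call = cache if cache is not None else _CoreCallCache(ref, evs, scheme, band)
    accepted: Counter[str] = Counter()
    rejected: Counter[str] = Counter()
    for read_id, r1, r2, mult in pairs:
        merged = merge_and_verify(r1, r2, ref, read_id, flank_len, min_overlap)
        if merged.reject_reason is not None:
            rejected[merged.reject_reason] += mult
            continue
        vc = call(merged.core_sequence)
        if vc.status == "rejected":
            rejected[vc.reject_reason] += mult
        else:
            accepted[vc.variant_id] += mult
    return accepted, rejected


def call_readset(
    readset: Counter,
    ref: AmpliconReference,
    evs: ExpectedVariantSet,
    scheme: ScoringScheme = ScoringScheme(),
    band: int = 9,
    flank_len: int = 15,
    min_overlap: int = 10,
    cache: _CoreCallCache | None = None,
) -> tuple[Counter, Counter]:
    """Call a simulated amplicon multiset (each entry is one read pair)."""
    pairs = (
        (f"seq{i}", seq, reverse_complement(seq), mult)
        for i, (seq, mult) in enumerate(sorted(readset.items()))
    )
    return _tally(pairs, ref, evs, scheme, band, flank_len, min_overlap, cache)


def call_fastq_pair(
    fastq1,
    fastq2,
    ref: AmpliconReference,
    evs: ExpectedVariantSet,
    scheme: ScoringScheme = ScoringScheme(),
    band: int = 9,
    flank_len: int = 15,
    min_overlap: int = 10,
    cache: _CoreCallCache | None = None,
) -> tuple[Counter, Counter]:
    """Call a paired FASTQ sample; identical pairs are collapsed first."""
    pair_counts: Counter[tuple[str, str]] = Counter()
    with open(fastq1) as f1, open(fastq2) as f2:
        for (id1, s1, _), (id2, s2, _) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            pair_counts[(s1, s2)] += 1
    pairs = (
        (f"pair{i}", r1, r2, mult)
        for i, ((r1, r2), mult) in enumerate(sorted(pair_counts.items()))
    )
    return _tally(pairs, ref, evs, scheme, band, flank_len, min_overlap, cache)


def count_alleles(
    per_sample: dict[str, tuple[Counter, Counter]],
    sample_sheet: pd.DataFrame,
) -> AlleleCountTable:
    """Assemble per-sample (accepted, rejected) tallies into one table.

    Every tallied sample must appear in the sample sheet; unknown labels
    raise.  Conservation holds by construction: accepted + rejected column
    sums equal the number of input read pairs per sample.
    """
    sheet = sample_sheet.copy()
    if sheet.index.name != "sample":
        sheet = sheet.set_index("sample", drop=False)
    known = set(sheet.index)
    for sample in per_sample:
        if sample not in known:
            raise KeyError(f"unknown sample label {sample!r}")
    counts = pd.DataFrame(
        {s: pd.Series(acc, dtype=float) for s, (acc, _) in per_sample.items()}
    ).fillna(0).astype(int)
    rejected = pd.DataFrame(
        {s: pd.Series(rej, dtype=float) for s, (_, rej) in per_sample.items()}
    ).fillna(0).astype(int)
    if WT_ID not in counts.index:
        counts.loc[WT_ID] = 0
    counts = counts.sort_index()
    rejected = rejected.reindex(sorted(rejected.index)).fillna(0).astype(int)
    return AlleleCountTable(counts=counts, rejected=rejected, samples=sheet)
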