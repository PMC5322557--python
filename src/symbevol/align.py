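"""Pairwise local protein alignment engine behind the all-vs-all search.

Candidate pairs are pre-screened by shared k-mer seeds, scored with a local
BLOSUM62 affine-gap alignment, and converted to bit scores and e-values under
a Karlin–Altschul approximation with gapped BLOSUM62 parameters. Identical
sequences and exact substrings take a closed-form fast path: the optimal
local alignment of an exact substring is the full diagonal match (every
BLOSUM62 off-diagonal entry is below both diagonal entries, so no other
pairing can score higher).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

#: gapped Karlin–Altschul parameters for BLOSUM62 with open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041
LN2 = math.log(2.0)


@dataclass
class ScoringConfig:
    """Thresholds and seeding parameters for the all-vs-all search."""

    min_bitscore: float = 50.0
    max_evalue: float = 1e-5
    seed_k: int = 5
    min_shared_seeds: int = 2
    gap_open: float = -11.0
    gap_extend: float = -1.0


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_DIAG = {aa: _BLOSUM62[aa, aa] for aa in "ACDEFGHIKLMNPQRSTVWYX"}


def make_aligner(config: ScoringConfig, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    if mode == "global":
        # do not penalise terminal gaps: truncated CDSs should align to the
        # matching region of their full-length ortholog
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def bitscore(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / LN2


def evalue(raw_score: float, query_len: int, db_letters: int) -> float:
    """Karlin–Altschul expectation with effective search space
    query_len * db_letters."""
    return KA_K * query_len * db_letters * math.exp(-KA_LAMBDA * raw_score)


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


#: diagonal bucket width for seed consistency (tolerates small indel drift)
DIAG_BAND = 16
#: bit-score floor of the ungapped diagonal screen run before any DP
UNGAPPED_SCREEN_BITS = 25.0

_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_BLOSUM_ARRAY = None


def _blosum_array():
    global _BLOSUM_ARRAY
    if _BLOSUM_ARRAY is None:
        import numpy as np

        n = len(_ALPHABET)
        arr = np.zeros((n, n), dtype=np.int8)
        for i, a in enumerate(_ALPHABET):
            for j, b in enumerate(_ALPHABET):
                arr[i, j] = _BLOSUM62[a, b]
        _BLOSUM_ARRAY = arr
    return _BLOSUM_ARRAY


def encode_protein(seq: str):
    import numpy as np

    return np.frombuffer(
        bytes(_AA_INDEX.get(aa, _AA_INDEX["X"]) for aa in seq), dtype=np.uint8
    )


def seed_candidates(
    seqs: dict[str, str], k: int, min_shared: int
) -> dict[tuple[str, str], list[int]]:
    """Unordered candidate pairs sharing >= min_shared k-mer seeds on a
    consistent alignment diagonal.

    An inverted k-mer index maps each k-mer to its (sequence, position)
    occurrences; a pair qualifies when some diagonal band (query offset
    minus subject offset, bucketed to DIAG_BAND residues) collects at least
    ``min_shared`` distinct shared k-mers. The value is the sorted list of
    exact seed diagonals, which the ungapped screen then extends. Chance
    collisions between unrelated proteins land on scattered diagonals and
    are discarded here, before any dynamic programming.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for sid in sorted(seqs):
        seq = seqs[sid]
        seen: set[str] = set()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if km not in seen:  # first occurrence defines the seed position
                seen.add(km)
                index.setdefault(km, []).append((sid, i))
    banded: dict[tuple[str, str, int], int] = {}
    diagonals: dict[tuple[str, str], set[int]] = {}
    for occs in index.values():
        if len(occs) < 2:
            continue
        for x in range(len(occs)):
            sid_a, pos_a = occs[x]
            for y in range(x + 1, len(occs)):
                sid_b, pos_b = occs[y]
                diag = pos_a - pos_b
                key = (sid_a, sid_b, diag // DIAG_BAND)
                banded[key] = banded.get(key, 0) + 1
                diagonals.setdefault((sid_a, sid_b), set()).add(diag)
    out: dict[tuple[str, str], list[int]] = {}
    for (a, b, _), c in banded.items():
        if c >= min_shared and (a, b) not in out:
            out[(a, b)] = sorted(diagonals[(a, b)])
    return out


def best_ungapped_segment(
    enc_a, enc_b, diagonals: list[int]
) -> tuple[float, int, int, int]:
    """Best ungapped segment over the given diagonals (query offset minus
    subject offset), by a maximum-subarray scan of substitution scores.

    Returns (score, diagonal, start, end): 0-based half-open bounds of the
    segment along the query, with subject bounds implied by the diagonal.
    """
    import numpy as np

    mat = _blosum_array()
    la, lb = len(enc_a), len(enc_b)
    best = (0.0, 0, 0, 0)
    for d in diagonals:
        i0 = max(0, d)
        j0 = i0 - d
        n = min(la - i0, lb - j0)
        if n <= 0:
            continue
        scores = mat[enc_a[i0 : i0 + n], enc_b[j0 : j0 + n]].astype(np.int32)
        cum = np.cumsum(scores)
        prefix = np.concatenate(([0], cum[:-1]))
        running_min = np.minimum.accumulate(prefix)
        gains = cum - running_min
        end = int(gains.argmax())
        seg = float(gains[end])
        if seg > best[0]:
            # segment start = last position where the prefix sum touches
            # its running minimum before the segment end
            start = int(
                np.flatnonzero(prefix[: end + 1] == running_min[end])[-1]
            )
            best = (seg, d, i0 + start, i0 + end + 1)
    return best


def ungapped_diagonal_score(enc_a, enc_b, diagonals: list[int]) -> float:
    return best_ungapped_segment(enc_a, enc_b, diagonals)[0]


def segment_alignment(enc_a, enc_b, segment: tuple[float, int, int, int]) -> LocalAlignment:
    """LocalAlignment record for an ungapped segment (used when the gapped
    optimum coincides with the ungapped one)."""
    score, d, qs, qe = segment
    ss, se = qs - d, qe - d
    n = qe - qs
    identities = int((enc_a[qs:qe] == enc_b[ss:se]).sum())
    return LocalAlignment(
        score=score,
        qstart=qs + 1,
        qend=qe,
        sstart=ss + 1,
        send=se,
        aln_length=n,
        identities=identities,
        mismatches=n - identities,
        gap_opens=0,
    )


def diagonal_score(seq: str) -> float:
    return float(sum(_DIAG[aa] for aa in seq))


@dataclass
class LocalAlignment:
    """Coordinates are 1-based inclusive on query/subject."""

    score: float
    qstart: int
    qend: int
    sstart: int
    send: int
    aln_length: int
    identities: int
    mismatches: int
    gap_opens: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.aln_length if self.aln_length else 0.0


def _substring_fast_path(query: str, subject: str) -> Optional[LocalAlignment]:
    if len(query) <= len(subject):
        pos = subject.find(query)
        if pos >= 0:
            return LocalAlignment(
                score=diagonal_score(query),
                qstart=1,
                qend=len(query),
                sstart=pos + 1,
                send=pos + len(query),
                aln_length=len(query),
                identities=len(query),
                mismatches=0,
                gap_opens=0,
            )
    else:
        pos = query.find(subject)
        if pos >= 0:
            return LocalAlignment(
                score=diagonal_score(subject),
                qstart=pos + 1,
                qend=pos + len(subject),
                sstart=1,
                send=len(subject),
                aln_length=len(subject),
                identities=len(subject),
                mismatches=0,
                gap_opens=0,
            )
    return None


def local_score(
    query: str, subject: str, aligner: Align.PairwiseAligner
) -> float:
    fast = _substring_fast_path(query, subject)
    if fast is not None:
        return fast.score
    return aligner.score(query, subject)


def local_align(
    query: str, subject: str, aligner: Align.PairwiseAligner
) -> LocalAlignment:
    """Best local alignment with coordinates, identity and gap counts."""
    fast = _substring_fast_path(query, subject)
    if fast is not None:
        return fast
    alignment = aligner.align(query, subject)[0]
    qaln, saln = alignment[0], alignment[1]
    identities = mismatches = gap_opens = 0
    in_gap = False
    for a, b in zip(qaln, saln):
        if a == "-" or b == "-":
            if not in_gap:
                gap_opens += 1
                in_gap = True
        else:
            in_gap = False
            if a == b:
                identities += 1
            else:
                mismatches += 1
    qblocks = alignment.aligned[0]
    sblocks = alignment.aligned[1]
    return LocalAlignment(
        score=alignment.score,
        qstart=int(qblocks[0][0]) + 1,
        qend=int(qblocks[-1][1]),
        sstart=int(sblocks[0][0]) + 1,
        send=int(sblocks[-1][1]),
        aln_length=len(qaln),
        identities=identities,
        mismatches=mismatches,
        gap_opens=gap_opens,
    )
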