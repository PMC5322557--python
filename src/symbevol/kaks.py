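"""Pairwise Ka/Ks (dN/dS) by Nei–Gojobori pathway counting.

Two coding sequences are aligned at the protein level (BLOSUM62, affine
gaps, free end gaps), the alignment is back-mapped to codons, and columns
containing a gap, a stop codon, or an ambiguous base are dropped. Synonymous
and nonsynonymous site fractions are found by enumerating the nine possible
single-nucleotide changes of every codon (changes that create a stop codon
count as nonsynonymous); differences between codons separated by several
changes are averaged over all minimal substitution pathways with equal
weights. Proportions are corrected for multiple hits with the Jukes–Cantor
formula d = -(3/4) ln(1 - 4p/3). A dN/dS ratio below one is read as
purifying selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from .align import ScoringConfig, make_aligner
from .records import STOP_CODONS, translate_cds

BASES = "ACGT"

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11]  # bacterial; codon map = standard code
    for codon, aa in table.forward_table.items():
        _CODON_TABLE[codon] = aa
    for codon in table.stop_codons:
        _CODON_TABLE[codon] = "*"


_build_codon_table()


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each of the three positions contributes the fraction of its three
    possible changes that are synonymous; a change creating a stop codon is
    nonsynonymous. The two fractions always sum to 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if translate_codon(mutant) == aa:  # stops translate to '*', never equal
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Averaged over all orderings of the minimal substitution pathway; a step
    is synonymous iff it preserves the amino acid and involves no stop
    codon.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and translate_codon(cur) == translate_codon(nxt)
            ):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        syn_total += syn
        nonsyn_total += nonsyn
        n_paths += 1
    return syn_total / n_paths, nonsyn_total / n_paths


@dataclass
class CodonAlignment:
    """Paired codon columns, filtered of gaps, stops and ambiguous codons."""

    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("unequal codon counts after filtering")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


def _trim_cds(cds: str, label: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 == 0 and cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if len(cds) % 3 != 0:
        raise ValueError(
            f"{label}: CDS length {len(cds)} not divisible by 3 after stop trimming"
        )
    return cds


def codon_align(
    cds_a: str, cds_b: str, scoring: Optional[ScoringConfig] = None
) -> CodonAlignment:
    """Codon alignment of two CDSs via global protein alignment back-mapping.

    Internal stop codons (pseudogenes) are tolerated: they are translated as
    ``*`` for the protein alignment and their columns dropped afterwards,
    together with every column containing a gap or an N.
    """
    cds_a = _trim_cds(cds_a, "cds_a")
    cds_b = _trim_cds(cds_b, "cds_b")
    aa_a = translate_cds(cds_a, trim_stop=False)
    aa_b = translate_cds(cds_b, trim_stop=False)
    if aa_a == aa_b and len(aa_a) > 0:
        ali, bli = list(range(len(aa_a))), list(range(len(aa_b)))
    else:
        aligner = make_aligner(scoring or ScoringConfig(), mode="global")
        alignment = aligner.align(aa_a, aa_b)[0]
        ali, bli = [], []
        for (a0, a1), (b0, b1) in zip(*alignment.aligned):
            ali.extend(range(a0, a1))
            bli.extend(range(b0, b1))
    codons_a, codons_b = [], []
    for ia, ib in zip(ali, bli):
        ca = cds_a[3 * ia : 3 * ia + 3]
        cb = cds_b[3 * ib : 3 * ib + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS or "N" in ca or "N" in cb:
            continue
        codons_a.append(ca)
        codons_b.append(cb)
    return CodonAlignment(codons_a, codons_b)


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]
    ratio: Optional[float]
    valid: bool
    reason: str = ""

    def row(self) -> dict:
        return {
            "S": self.S,
            "N": self.N,
            "Sd": self.Sd,
            "Nd": self.Nd,
            "pS": self.pS,
            "pN": self.pN,
            "dS": self.dS,
            "dN": self.dN,
            "ratio": self.ratio,
            "valid": self.valid,
            "reason": self.reason,
        }


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 distance; None at saturation (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(aln: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori (pathway) counting with Jukes–Cantor correction.

    Site counts are averaged over the two sequences, so S + N equals three
    times the number of retained codon pairs. The result is symmetric in
    the two sequences.
    """
    if aln.n_codons == 0:
        raise ValueError("empty codon alignment")
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = codon_pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    if dS is None or dN is None:
        return KaKsResult(S, N, Sd, Nd, pS, pN, dS, dN, None, False, "saturation")
    if dS == 0.0:
        return KaKsResult(S, N, Sd, Nd, pS, pN, dS, dN, None, False, "zero_dS")
    return KaKsResult(S, N, Sd, Nd, pS, pN, dS, dN, dN / dS, True)


def purifying_verdict(result: KaKsResult, threshold: float = 1.0) -> str:
    """``purifying`` iff the ratio is defined and strictly below threshold."""
    if not result.valid or result.ratio is None:
        return "undefined"
    return "purifying" if result.ratio < threshold else "neutral_or_relaxed"


def kaks_pair(cds_a: str, cds_b: str) -> KaKsResult:
    """Convenience: codon-align two CDSs and run Nei–Gojobori."""
    return nei_gojobori(codon_align(cds_a, cds_b))
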