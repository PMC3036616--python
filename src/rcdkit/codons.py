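"""Codon-level sequence model: genetic code, NG86 site counting, pathway classification.

The Nei–Gojobori (1986) framework partitions each codon's 3 mutational positions
into fractional synonymous and nonsynonymous *sites* (by enumerating the 9
single-nucleotide neighbours), and classifies observed *differences* between two
codons by averaging over all minimal mutational pathways.  These primitives back
the divergence, polymorphism and McDonald–Kreitman modules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"
STOP = "*"

_table = unambiguous_dna_by_id[1]  # the standard genetic code
GENETIC_CODE: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    GENETIC_CODE[_stop] = STOP

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != STOP)
)

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


class UntranslatableCodonError(ValueError):
    """Codon contains a gap or ambiguity character, or is not a 3-mer."""


def is_unambiguous_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in NUCLEOTIDES for b in codon)


def translate_codon(codon: str) -> str:
    """Translate a codon under the standard code; returns ``'*'`` for a stop.

    Raises :class:`UntranslatableCodonError` on gaps/ambiguity characters.
    """
    codon = codon.upper()
    if not is_unambiguous_codon(codon):
        raise UntranslatableCodonError(f"cannot translate codon {codon!r}")
    return GENETIC_CODE[codon]


def is_transition(a: str, b: str) -> bool:
    return _TRANSITIONS.get(a) == b


@dataclass(frozen=True)
class CodonSiteCounts:
    """Fractional synonymous/nonsynonymous mutational-opportunity sites of one codon."""

    syn_sites: float
    nonsyn_sites: float

    def __add__(self, other: "CodonSiteCounts") -> "CodonSiteCounts":
        return CodonSiteCounts(
            self.syn_sites + other.syn_sites, self.nonsyn_sites + other.nonsyn_sites
        )


@lru_cache(maxsize=None)
def ng86_codon_sites(codon: str) -> CodonSiteCounts:
    """NG86 fractional site counts for a sense codon.

    Each position contributes a synonymous fraction equal to the share of its
    single-base changes that are synonymous, with changes creating a stop codon
    excluded from numerator and denominator.  The two counts always sum to 3.
    """
    codon = codon.upper()
    aa = translate_codon(codon)
    if aa == STOP:
        raise ValueError(f"stop codon {codon!r} has no NG86 site decomposition")
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_counted = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            neighbour = codon[:pos] + alt + codon[pos + 1 :]
            alt_aa = GENETIC_CODE[neighbour]
            if alt_aa == STOP:
                continue  # stop-exclusion rule
            n_counted += 1
            if alt_aa == aa:
                n_syn += 1
        if n_counted:
            syn += n_syn / n_counted
        # a position whose every change is a stop contributes 0 syn / 1 nonsyn;
        # no sense codon actually has such a position under the standard code
    return CodonSiteCounts(syn, 3.0 - syn)


@dataclass(frozen=True)
class CodonDifferenceCounts:
    """Pathway-averaged synonymous/nonsynonymous differences between two codons."""

    syn_diffs: float
    nonsyn_diffs: float

    def __add__(self, other: "CodonDifferenceCounts") -> "CodonDifferenceCounts":
        return CodonDifferenceCounts(
            self.syn_diffs + other.syn_diffs, self.nonsyn_diffs + other.nonsyn_diffs
        )


@lru_cache(maxsize=None)
def ng86_codon_differences(codon_x: str, codon_y: str) -> CodonDifferenceCounts:
    """Classify the nucleotide differences between two sense codons.

    For codons differing at d positions, every one of the d! orderings of the
    single-base steps is a minimal pathway.  Pathways whose intermediate codons
    are stops are excluded; each remaining pathway's steps are classified
    synonymous/nonsynonymous by translating before/after codons, and the
    per-step tallies are averaged with equal weight.  If every pathway passes
    through a stop (possible only for d >= 2), all pathways are used.
    """
    codon_x, codon_y = codon_x.upper(), codon_y.upper()
    for c in (codon_x, codon_y):
        if translate_codon(c) == STOP:
            raise ValueError(f"stop codon {c!r} in difference counting")
    diff_positions = [i for i in range(3) if codon_x[i] != codon_y[i]]
    if not diff_positions:
        return CodonDifferenceCounts(0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        syn = nonsyn = 0.0
        current = codon_x
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_y[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == STOP and nxt != codon_y:
                through_stop = True
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        return syn, nonsyn, through_stop

    results = [walk(order) for order in itertools.permutations(diff_positions)]
    valid = [r for r in results if not r[2]] or results
    syn = sum(r[0] for r in valid) / len(valid)
    nonsyn = sum(r[1] for r in valid) / len(valid)
    return CodonDifferenceCounts(syn, nonsyn)
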