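"""McDonald–Kreitman contingency tables and Fisher's exact two-tailed test.

The MK test contrasts fixed differences between two population samples with
polymorphisms segregating within them, split into synonymous and
nonsynonymous classes.  Conventions: polymorphism counts are pooled (summed
over both populations); a site fixed in one population but polymorphic in the
other counts as polymorphic; fractional pathway-averaged counts are resolved
to integers at the table level by largest-remainder rounding (the raw
fractional counts are kept alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .alignment import CodonAlignment
from .codons import ng86_codon_differences, translate_codon

FISHER_REL_TOL = 1e-7


def fisher_exact_two_tailed(FS: int, PS: int, FN: int, PN: int) -> float:
    """Exact two-tailed Fisher probability for the 2x2 table [[FS, FN], [PS, PN]].

    With margins fixed, the two-tailed p is the sum of hypergeometric point
    probabilities of all admissible tables whose probability is <= that of the
    observed table, the comparison made with relative tolerance 1e-7.  A zero
    row or column margin leaves no test to perform: returns NaN.
    """
    for v in (FS, PS, FN, PN):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    row_f, row_p = FS + FN, PS + PN
    col_s, col_n = FS + PS, FN + PN
    if 0 in (row_f, row_p, col_s, col_n):
        return math.nan
    N = row_f + row_p
    lo = max(0, row_f - col_n)
    hi = min(row_f, col_s)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, col_s, row_f)
    p_obs = hypergeom.pmf(FS, N, col_s, row_f)
    p = float(np.sum(pmf[pmf <= p_obs * (1.0 + FISHER_REL_TOL)]))
    return min(p, 1.0)


@dataclass
class MKTable:
    """Fixed/polymorphic x synonymous/nonsynonymous counts with Fisher's p.

    Integer counts come from largest-remainder rounding of the pathway-averaged
    fractional counts (kept in ``fractional``); ``p_two_tailed`` is NaN when a
    test margin is empty.
    """

    FS: int
    PS: int
    FN: int
    PN: int
    p_two_tailed: float
    fractional: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    gene_name: str = ""
    comparison: str = ""


def _largest_remainder(values: list[float]) -> list[int]:
    """Round to integers preserving the (integer) total by largest remainder."""
    floors = [math.floor(v) for v in values]
    total = round(sum(values))
    deficit = total - sum(floors)
    remainders = sorted(
        range(len(values)), key=lambda i: values[i] - floors[i], reverse=True
    )
    out = list(floors)
    for i in remainders[:deficit]:
        out[i] += 1
    return out


def _consensus_codon(codons: list[str]) -> str:
    """Per-position majority codon (ties broken alphabetically)."""
    out = []
    for pos in range(3):
        chars = [c[pos] for c in codons]
        vals, counts = np.unique(chars, return_counts=True)
        out.append(str(vals[np.argmax(counts)]))
    return "".join(out)


def _single_step_class(codon_from: str, codon_to: str) -> tuple[float, float]:
    """(syn, nonsyn) weight of a single-nucleotide change in codon context."""
    if translate_codon(codon_from) == translate_codon(codon_to):
        return 1.0, 0.0
    return 0.0, 1.0


def mk_table(
    pop1: CodonAlignment, pop2: CodonAlignment, gene_name: str = "", comparison: str = ""
) -> MKTable:
    """Build the MK 2x2 table for two population samples of the same gene.

    Per clean codon column (jointly unambiguous in both samples):

    * a site is a *fixed difference* when every allele in pop1 differs from
      every allele in pop2 there and neither population is polymorphic at it;
      fixed differences within a codon are classified jointly by NG86
      pathway averaging between the two population consensus codons with
      polymorphic positions equalized;
    * a site segregating within pop1 or pop2 is *polymorphic*; each population
      it segregates in contributes one count (pooled), classified by the
      single-base change against the population consensus codon (multi-allele
      sites average over the non-major alleles).
    """
    if pop1.length != pop2.length:
        raise ValueError("alignments must have equal length")
    joint_mask = pop1.clean_codon_mask() & pop2.clean_codon_mask()
    fs = ps = fn = pn = 0.0
    for k in np.flatnonzero(joint_mask):
        codons1 = [s[3 * k : 3 * k + 3] for s in pop1.sequences]
        codons2 = [s[3 * k : 3 * k + 3] for s in pop2.sequences]
        cons1 = _consensus_codon(codons1)
        cons2 = _consensus_codon(codons2)
        fixed_positions = []
        for pos in range(3):
            a1 = {c[pos] for c in codons1}
            a2 = {c[pos] for c in codons2}
            if len(a1) == 1 and len(a2) == 1 and a1 != a2:
                fixed_positions.append(pos)
            else:
                # polymorphic within either population (pooled, one count per pop)
                for alleles, cons in ((a1, cons1), (a2, cons2)):
                    if len(alleles) > 1:
                        if translate_codon(cons) == "*":
                            continue  # chimeric consensus hit a stop: skip context
                        major = cons[pos]
                        minors = sorted(alleles - {major}) or sorted(alleles)
                        w = 1.0 / len(minors)
                        for alt in minors:
                            alt_codon = cons[:pos] + alt + cons[pos + 1 :]
                            if translate_codon(alt_codon) == "*":
                                continue  # change to a stop: not countable
                            s, ns = _single_step_class(cons, alt_codon)
                            ps += w * s
                            pn += w * ns
        if fixed_positions:
            # equalize non-fixed positions so pathway averaging sees only the
            # fixed differences
            base = list(cons1)
            target = list(cons1)
            for pos in fixed_positions:
                target[pos] = cons2[pos]
            c_from, c_to = "".join(base), "".join(target)
            if translate_codon(c_from) != "*" and translate_codon(c_to) != "*":
                d = ng86_codon_differences(c_from, c_to)
                fs += d.syn_diffs
                fn += d.nonsyn_diffs
    frac = (fs, ps, fn, pn)
    FS, PS, FN, PN = _largest_remainder(list(frac))
    return MKTable(
        FS=FS,
        PS=PS,
        FN=FN,
        PN=PN,
        p_two_tailed=fisher_exact_two_tailed(FS, PS, FN, PN),
        fractional=frac,
        gene_name=gene_name or pop1.gene_name,
        comparison=comparison,
    )
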