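"""Per-population polymorphism summaries: S, Watterson's theta, pi by site class, Hudson F_ST.

All statistics are computed on the *clean codon region* of an alignment — codon
columns where every sequence is unambiguous ACGT — so that total and site-class
statistics share one denominator set (complete deletion at codon granularity).
Site-class pi uses the NG86 fractional site partition averaged over the whole
sample, and pathway-averaged difference classification per codon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import CodonAlignment
from .codons import ng86_codon_differences, ng86_codon_sites


def harmonic_a(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (Watterson's coefficient)."""
    return float(np.sum(1.0 / np.arange(1, n)))


def harmonic_b(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


@dataclass
class PolymorphismSummary:
    """Summary statistics for one gene x population sample (per-site scale)."""

    gene_name: str
    population: str
    n: int
    L: int
    S: int
    theta_w: float
    pi_total: float
    pi_syn: float
    pi_nonsyn: float


def _clean_matrix(alignment: CodonAlignment) -> np.ndarray:
    """(n, L_clean) byte matrix restricted to clean codon columns."""
    mask = alignment.clean_codon_mask()
    mats = []
    for seq in alignment.sequences:
        arr = np.frombuffer(seq.encode(), dtype="S1").reshape(-1, 3)
        mats.append(arr[mask].reshape(-1))
    return np.vstack(mats) if mats else np.empty((0, 0), dtype="S1")


def segregating_sites(alignment: CodonAlignment) -> int:
    """Number of clean columns with >= 2 observed states."""
    if alignment.n < 2:
        raise ValueError("segregating sites require n >= 2")
    mat = _clean_matrix(alignment)
    if mat.shape[1] == 0:
        return 0
    return int(np.sum((mat != mat[0]).any(axis=0)))


def sites_analyzed(alignment: CodonAlignment) -> int:
    """L: nucleotide columns in the clean codon region."""
    return int(alignment.clean_codon_mask().sum()) * 3


def watterson_theta(alignment: CodonAlignment) -> float:
    """Watterson's estimator theta_w = S / (a_n * L), per site."""
    if alignment.n < 2:
        raise ValueError("Watterson's theta requires n >= 2")
    L = sites_analyzed(alignment)
    if L == 0:
        raise ValueError("no analyzable sites")
    return segregating_sites(alignment) / (harmonic_a(alignment.n) * L)


def mean_pairwise_differences(alignment: CodonAlignment) -> float:
    """Mean raw nucleotide difference count over all unordered sequence pairs."""
    mat = _clean_matrix(alignment)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("pairwise differences require n >= 2")
    # column-wise allele counts give sum over pairs without the O(n^2) loop
    total = 0.0
    for col in range(mat.shape[1]):
        _, counts = np.unique(mat[:, col], return_counts=True)
        total += (n * (n - 1) - np.sum(counts * (counts - 1))) / 2.0
    return total / (n * (n - 1) / 2.0)


def _class_pairwise(alignment: CodonAlignment) -> tuple[float, float, float, float]:
    """(mean syn diffs, mean nonsyn diffs, mean syn sites, mean nonsyn sites)."""
    mask = alignment.clean_codon_mask()
    codon_idx = np.flatnonzero(mask)
    n = alignment.n
    syn_sites = np.zeros(n)
    nonsyn_sites = np.zeros(n)
    for i, seq in enumerate(alignment.sequences):
        for k in codon_idx:
            sc = ng86_codon_sites(seq[3 * k : 3 * k + 3])
            syn_sites[i] += sc.syn_sites
            nonsyn_sites[i] += sc.nonsyn_sites
    syn_d = nonsyn_d = 0.0
    n_pairs = n * (n - 1) // 2
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = alignment.sequences[i], alignment.sequences[j]
            for k in codon_idx:
                ci, cj = si[3 * k : 3 * k + 3], sj[3 * k : 3 * k + 3]
                if ci != cj:
                    d = ng86_codon_differences(ci, cj)
                    syn_d += d.syn_diffs
                    nonsyn_d += d.nonsyn_diffs
    return (
        syn_d / n_pairs,
        nonsyn_d / n_pairs,
        float(syn_sites.mean()),
        float(nonsyn_sites.mean()),
    )


def nucleotide_diversity(alignment: CodonAlignment, site_class: str = "all") -> float:
    """pi per (class) site; ``site_class`` in {'all', 'synonymous', 'nonsynonymous'}.

    Class-specific pi divides the mean pathway-classified pairwise differences by
    the NG86 class site count averaged over the whole sample.
    """
    if alignment.n < 2:
        raise ValueError("pi requires n >= 2")
    if site_class == "all":
        L = sites_analyzed(alignment)
        if L == 0:
            raise ValueError("no analyzable sites")
        return mean_pairwise_differences(alignment) / L
    syn_d, nonsyn_d, syn_sites, nonsyn_sites = _class_pairwise(alignment)
    if site_class == "synonymous":
        if syn_sites == 0:
            raise ValueError("zero synonymous sites")
        return syn_d / syn_sites
    if site_class == "nonsynonymous":
        if nonsyn_sites == 0:
            raise ValueError("zero nonsynonymous sites")
        return nonsyn_d / nonsyn_sites
    raise ValueError(f"unknown site class {site_class!r}")


def summarize(alignment: CodonAlignment, population: str = "") -> PolymorphismSummary:
    """Table-2-style summary for one gene x population sample."""
    syn_d, nonsyn_d, syn_sites, nonsyn_sites = _class_pairwise(alignment)
    L = sites_analyzed(alignment)
    return PolymorphismSummary(
        gene_name=alignment.gene_name,
        population=population or f"{alignment.context or '?'} Type {alignment.lineage or '?'}",
        n=alignment.n,
        L=L,
        S=segregating_sites(alignment),
        theta_w=watterson_theta(alignment),
        pi_total=nucleotide_diversity(alignment, "all"),
        pi_syn=syn_d / syn_sites if syn_sites else math.nan,
        pi_nonsyn=nonsyn_d / nonsyn_sites if nonsyn_sites else math.nan,
    )


def hudson_fst(pop1: CodonAlignment, pop2: CodonAlignment) -> float:
    """Hudson-style F_ST = 1 - mean(pi_within) / pi_between.

    pi_between is the mean per-site difference over all cross-population pairs;
    negative estimates are reported as computed, not truncated.  Both alignments
    are restricted to codon columns clean in *both* samples.
    """
    if pop1.length != pop2.length:
        raise ValueError("alignments must have equal length")
    joint_mask = pop1.clean_codon_mask() & pop2.clean_codon_mask()
    L = int(joint_mask.sum()) * 3
    if L == 0:
        raise ValueError("no jointly analyzable sites")

    def restrict(aln: CodonAlignment) -> np.ndarray:
        mats = []
        for seq in aln.sequences:
            arr = np.frombuffer(seq.encode(), dtype="S1").reshape(-1, 3)
            mats.append(arr[joint_mask].reshape(-1))
        return np.vstack(mats)

    m1, m2 = restrict(pop1), restrict(pop2)

    def mean_within(m: np.ndarray) -> float:
        n = m.shape[0]
        if n < 2:
            return 0.0
        total = 0.0
        for i in range(n):
            total += float(np.sum(m[i + 1 :] != m[i]))
        return total / (n * (n - 1) / 2.0)

    pi_w = 0.5 * (mean_within(m1) + mean_within(m2)) / L
    between = 0.0
    for i in range(m1.shape[0]):
        between += float(np.sum(m2 != m1[i]))
    pi_b = between / (m1.shape[0] * m2.shape[0]) / L
    if pi_b == 0:
        raise ValueError("pi_between = 0: F_ST undefined")
    return 1.0 - pi_w / pi_b
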