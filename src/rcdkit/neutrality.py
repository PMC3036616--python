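"""Frequency-spectrum neutrality statistics: Tajima's D, Fu & Li's D*/F*, Fay & Wu's H.

All statistics are functions of the sample size n, the segregating sites and
their allele (or derived-allele) counts.  Alignment-facing wrappers extract
those inputs from the clean codon region of a :class:`CodonAlignment`; the
low-level ``*_from_*`` functions are shared with the coalescent simulator,
which produces derived-allele counts directly.

Coefficient sources: Tajima (1989) for D; Fu & Li (1993) star statistics with
the published corrected variance coefficients (Simonsen et al. 1995 appendix,
as used by the DnaSP/libsequence lineage of software); Fay & Wu (2000) for
theta_H and H, with the Zeng et al. (2006) variance normalization for the
normalized form.  Statistics are reported as NaN ("NA") when S = 0 or n < 4.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import CodonAlignment
from .polymorphism import (
    _clean_matrix,
    harmonic_a,
    harmonic_b,
    mean_pairwise_differences,
)


# ---------------------------------------------------------------------------
# coefficients (functions of n only)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralityCoefficients:
    """Variance coefficients for D, D* and F* at sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    c_n: float
    d_n: float
    u_d_star: float
    v_d_star: float
    u_f_star: float
    v_f_star: float


def neutrality_coefficients(n: int) -> NeutralityCoefficients:
    if n < 4:
        raise ValueError("coefficients defined for n >= 4")
    nf = float(n)
    a1 = harmonic_a(n)            # sum_{1}^{n-1} 1/i
    a2 = harmonic_b(n)            # sum_{1}^{n-1} 1/i^2
    # Tajima (1989)
    b1 = (nf + 1.0) / (3.0 * (nf - 1.0))
    b2 = 2.0 * (nf * nf + nf + 3.0) / (9.0 * nf * (nf - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (nf + 2.0) / (a1 * nf) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    # Fu & Li (1993) star statistics, corrected coefficients
    a1_np1 = a1 + 1.0 / nf        # a_{n+1}
    c_n = 2.0 * (nf * a1 - 2.0 * (nf - 1.0)) / ((nf - 1.0) * (nf - 2.0))
    d_n = (
        c_n
        + (nf - 2.0) / ((nf - 1.0) ** 2)
        + (2.0 / (nf - 1.0))
        * (1.5 - (2.0 * a1_np1 - 3.0) / (nf - 2.0) - 1.0 / nf)
    )
    v_d_star = (
        (nf / (nf - 1.0)) ** 2 * a2
        + a1 * a1 * d_n
        - 2.0 * nf * a1 * (a1 + 1.0) / ((nf - 1.0) ** 2)
    ) / (a1 * a1 + a2)
    u_d_star = (nf / (nf - 1.0)) * (a1 - nf / (nf - 1.0)) - v_d_star
    v_f_star = (
        d_n
        + 2.0 * (nf * nf + nf + 3.0) / (9.0 * nf * (nf - 1.0))
        - (2.0 / (nf - 1.0)) * (4.0 * a2 - 6.0 + 8.0 / nf)
    ) / (a1 * a1 + a2)
    u_f_star = (
        nf / (nf - 1.0)
        + (nf + 1.0) / (3.0 * (nf - 1.0))
        - 4.0 / (nf * (nf - 1.0))
        + 2.0 * ((nf + 1.0) / (nf - 1.0) ** 2) * (a1_np1 - 2.0 * nf / (nf + 1.0))
    ) / a1 - v_f_star
    return NeutralityCoefficients(
        n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2,
        c_n=c_n, d_n=d_n,
        u_d_star=u_d_star, v_d_star=v_d_star,
        u_f_star=u_f_star, v_f_star=v_f_star,
    )


# ---------------------------------------------------------------------------
# statistics from summaries / counts
# ---------------------------------------------------------------------------

def tajimas_d_from_summary(n: int, S: int, pi_gene: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs."""
    if S == 0:
        return math.nan
    if n < 4:
        warnings.warn("Tajima's D requires n >= 4; returning NA")
        return math.nan
    coef = neutrality_coefficients(n)
    var = coef.e1 * S + coef.e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_gene - S / coef.a1) / math.sqrt(var)


def fu_li_star_from_summary(
    n: int, S: int, eta_s: int, pi_gene: float
) -> tuple[float, float]:
    """Fu & Li's outgroup-free (D*, F*) from S, singleton count and pi."""
    if S == 0:
        return math.nan, math.nan
    if n < 4:
        warnings.warn("Fu & Li's D*/F* require n >= 4; returning NA")
        return math.nan, math.nan
    coef = neutrality_coefficients(n)
    nf = float(n)
    var_d = coef.u_d_star * S + coef.v_d_star * S * S
    var_f = coef.u_f_star * S + coef.v_f_star * S * S
    d_star = ((nf / (nf - 1.0)) * S - coef.a1 * eta_s) / math.sqrt(var_d)
    f_star = (pi_gene - ((nf - 1.0) / nf) * eta_s) / math.sqrt(var_f)
    return d_star, f_star


def theta_h_from_counts(n: int, derived_counts: np.ndarray) -> float:
    """Fay & Wu's homozygosity-weighted estimator theta_H = sum 2 i^2 S_i / (n(n-1))."""
    i = np.asarray(derived_counts, dtype=float)
    return float(np.sum(2.0 * i * i) / (n * (n - 1)))


def pi_from_derived_counts(n: int, derived_counts: np.ndarray) -> float:
    i = np.asarray(derived_counts, dtype=float)
    return float(np.sum(2.0 * i * (n - i)) / (n * (n - 1)))


def fay_wu_h_from_counts(n: int, derived_counts: np.ndarray) -> tuple[float, float]:
    """Raw and normalized Fay & Wu's H from derived-allele counts (1..n-1).

    Raw H = pi - theta_H.  The normalized form follows Zeng et al. (2006):
    H_norm = (pi - theta_L)/sqrt(Var), theta_L = sum i S_i / (n-1), with theta
    and theta^2 estimated from S via Watterson moments.  Note pi - theta_H =
    2 (pi - theta_L).
    """
    counts = np.asarray(derived_counts, dtype=float)
    S = counts.size
    if S == 0 or n < 4:
        return math.nan, math.nan
    pi = pi_from_derived_counts(n, counts)
    theta_h = theta_h_from_counts(n, counts)
    h_raw = pi - theta_h
    theta_l = float(np.sum(counts) / (n - 1))
    a_n = harmonic_a(n)
    b_n = harmonic_b(n)
    b_np1 = b_n + 1.0 / (n * n)   # sum_{i=1}^{n} 1/i^2
    theta_w = S / a_n
    theta_sq = S * (S - 1.0) / (a_n * a_n + b_n)
    nf = float(n)
    var = (
        (nf - 2.0) / (6.0 * (nf - 1.0)) * theta_w
        + (
            18.0 * nf * nf * (3.0 * nf + 2.0) * b_np1
            - (88.0 * nf**3 + 9.0 * nf * nf - 13.0 * nf + 6.0)
        )
        / (9.0 * nf * (nf - 1.0) ** 2)
        * theta_sq
    )
    h_norm = (pi - theta_l) / math.sqrt(var) if var > 0 else math.nan
    return h_raw, h_norm


# ---------------------------------------------------------------------------
# alignment-facing wrappers
# ---------------------------------------------------------------------------

def _segregating_columns(mat: np.ndarray) -> list[np.ndarray]:
    """Columns (as byte arrays) with >= 2 observed states."""
    seg = (mat != mat[0]).any(axis=0)
    return [mat[:, j] for j in np.flatnonzero(seg)]


def singleton_count(alignment: CodonAlignment) -> int:
    """eta_s: alleles observed in exactly one sequence, summed over segregating sites."""
    mat = _clean_matrix(alignment)
    eta_s = 0
    for col in _segregating_columns(mat):
        _, counts = np.unique(col, return_counts=True)
        eta_s += int(np.sum(counts == 1))
    return eta_s


def tajimas_d(alignment: CodonAlignment) -> float:
    mat = _clean_matrix(alignment)
    S = len(_segregating_columns(mat))
    if S == 0:
        return math.nan
    return tajimas_d_from_summary(
        alignment.n, S, mean_pairwise_differences(alignment)
    )


def fu_li_star(alignment: CodonAlignment) -> tuple[float, float]:
    mat = _clean_matrix(alignment)
    S = len(_segregating_columns(mat))
    if S == 0:
        return math.nan, math.nan
    return fu_li_star_from_summary(
        alignment.n, S, singleton_count(alignment),
        mean_pairwise_differences(alignment),
    )


@dataclass
class NeutralityStats:
    """Per-population neutrality test statistics (NaN = NA)."""

    n: int
    S: int
    D: float
    D_star: float
    F_star: float
    H: float
    H_normalized: float
    theta_H: float
    eta_s: int
    polarizable_sites: int


def polarized_derived_counts(alignment: CodonAlignment, outgroup: str) -> np.ndarray:
    """Derived-allele counts at segregating sites polarizable by the outgroup.

    Sites where the outgroup character is ambiguous/gapped or its allele is
    absent from the sample are unpolarizable and excluded.
    """
    if len(outgroup) != alignment.length:
        raise ValueError("outgroup length must match the alignment")
    mask = alignment.clean_codon_mask()
    out_arr = np.frombuffer(outgroup.upper().encode(), dtype="S1").reshape(-1, 3)
    out_clean = out_arr[mask].reshape(-1)
    mat = _clean_matrix(alignment)
    n = alignment.n
    derived_counts = []
    for j in np.flatnonzero((mat != mat[0]).any(axis=0)):
        anc = out_clean[j]
        if anc not in (b"A", b"C", b"G", b"T"):
            continue
        col = mat[:, j]
        if anc not in col:
            continue  # outgroup allele absent from the sample: unpolarizable
        derived = int(np.sum(col != anc))
        if 0 < derived < n:
            derived_counts.append(derived)
    return np.array(derived_counts, dtype=int)


def fay_wu_h(alignment: CodonAlignment, outgroup: str) -> tuple[float, float]:
    """Fay & Wu's (H, normalized H) polarized by an outgroup sequence.

    The outgroup (here: the consensus of the other lineage) resolves the
    ancestral state per segregating site; unpolarizable sites are excluded
    from both pi and theta_H for this statistic.
    """
    counts = polarized_derived_counts(alignment, outgroup)
    if counts.size == 0:
        return math.nan, math.nan
    return fay_wu_h_from_counts(alignment.n, counts)


def consensus_sequence(alignment: CodonAlignment) -> str:
    """Column-majority consensus (ties broken alphabetically, missing ignored)."""
    n_cols = alignment.length
    cols = np.vstack(
        [np.frombuffer(s.encode(), dtype="S1") for s in alignment.sequences]
    )
    out = []
    for j in range(n_cols):
        col = cols[:, j]
        col = col[np.isin(col, [b"A", b"C", b"G", b"T"])]
        if col.size == 0:
            out.append("N")
            continue
        vals, counts = np.unique(col, return_counts=True)
        out.append(vals[np.argmax(counts)].decode())
    return "".join(out)


def neutrality_stats(
    alignment: CodonAlignment, outgroup: str | None = None
) -> NeutralityStats:
    """All four statistics for one sample; H is NA without an outgroup."""
    mat = _clean_matrix(alignment)
    seg = _segregating_columns(mat)
    S = len(seg)
    pi_gene = mean_pairwise_differences(alignment) if alignment.n >= 2 else math.nan
    eta_s = singleton_count(alignment)
    D = tajimas_d_from_summary(alignment.n, S, pi_gene) if S else math.nan
    d_star, f_star = (
        fu_li_star_from_summary(alignment.n, S, eta_s, pi_gene)
        if S
        else (math.nan, math.nan)
    )
    h_raw = h_norm = theta_h = math.nan
    n_polarizable = 0
    if outgroup is not None and S:
        counts = polarized_derived_counts(alignment, outgroup)
        n_polarizable = int(counts.size)
        if n_polarizable:
            h_raw, h_norm = fay_wu_h_from_counts(alignment.n, counts)
            theta_h = theta_h_from_counts(alignment.n, counts)
    return NeutralityStats(
        n=alignment.n,
        S=S,
        D=D,
        D_star=d_star,
        F_star=f_star,
        H=h_raw,
        H_normalized=h_norm,
        theta_H=theta_h,
        eta_s=eta_s,
        polarizable_sites=n_polarizable,
    )
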