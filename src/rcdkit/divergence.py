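"""Pairwise and cross-type dN/dS (NG86 with Jukes–Cantor correction).

Implements the divergence screen: NG86 counting between single sequences,
averaging over the four Type A x Type B combinations of a 2+2 divergence
panel, the omega > 0.5 candidate rule, and the one-tailed Mann–Whitney
comparison of candidate gamete-recognition genes against controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .alignment import CodonAlignment
from .codons import (
    CodonDifferenceCounts,
    CodonSiteCounts,
    is_unambiguous_codon,
    ng86_codon_differences,
    ng86_codon_sites,
)

JC_SATURATION = 0.75


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3); undefined for p >= 3/4."""
    if p >= JC_SATURATION:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class PairwiseDivergence:
    """NG86 divergence between two coding sequences (or a cross-type average).

    ``omega`` is ``None`` when undefined (dS = 0), which is distinct from 0.
    ``saturated`` flags pN or pS >= 3/4, where the JC correction diverges; the
    raw proportions remain available in ``pN``/``pS``.
    """

    dN: float
    dS: float
    omega: float | None
    pN: float
    pS: float
    syn_sites: float = math.nan
    nonsyn_sites: float = math.nan
    syn_diffs: float = math.nan
    nonsyn_diffs: float = math.nan
    saturated: bool = False
    n_pairs: int = 1
    n_undefined_omega: int = 0


def ng86_pairwise(seq_x: str, seq_y: str) -> PairwiseDivergence:
    """NG86 dN, dS and omega for two equal-length in-frame coding sequences.

    Site counts are averaged between the two sequences; differences are
    pathway-averaged per codon; codons containing a gap or ambiguity in either
    sequence are skipped entirely (pairwise deletion at codon granularity);
    Jukes–Cantor correction is applied to pN and pS separately.
    """
    seq_x, seq_y = seq_x.upper(), seq_y.upper()
    if len(seq_x) != len(seq_y):
        raise ValueError("sequences must have equal length")
    if len(seq_x) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    sites_x = CodonSiteCounts(0.0, 0.0)
    sites_y = CodonSiteCounts(0.0, 0.0)
    diffs = CodonDifferenceCounts(0.0, 0.0)
    for k in range(0, len(seq_x), 3):
        cx, cy = seq_x[k : k + 3], seq_y[k : k + 3]
        if not (is_unambiguous_codon(cx) and is_unambiguous_codon(cy)):
            continue
        sites_x = sites_x + ng86_codon_sites(cx)
        sites_y = sites_y + ng86_codon_sites(cy)
        diffs = diffs + ng86_codon_differences(cx, cy)
    syn_sites = 0.5 * (sites_x.syn_sites + sites_y.syn_sites)
    nonsyn_sites = 0.5 * (sites_x.nonsyn_sites + sites_y.nonsyn_sites)
    if syn_sites == 0 or nonsyn_sites == 0:
        raise ValueError("no analyzable codons shared by the two sequences")
    pS = diffs.syn_diffs / syn_sites
    pN = diffs.nonsyn_diffs / nonsyn_sites
    saturated = pS >= JC_SATURATION or pN >= JC_SATURATION
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega: float | None
    if saturated or math.isnan(dS) or dS == 0.0:
        omega = None
    else:
        omega = dN / dS
    return PairwiseDivergence(
        dN=dN,
        dS=dS,
        omega=omega,
        pN=pN,
        pS=pS,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_diffs=diffs.syn_diffs,
        nonsyn_diffs=diffs.nonsyn_diffs,
        saturated=saturated,
        n_undefined_omega=int(omega is None),
    )


def mean_cross_type_omega(
    typeA_panel: Sequence[str] | CodonAlignment,
    typeB_panel: Sequence[str] | CodonAlignment,
) -> PairwiseDivergence:
    """Average NG86 divergence over every Type A x Type B sequence pair.

    Returns the arithmetic mean of dN, dS, and of the *defined* per-pair omega
    values (not the ratio of mean dN to mean dS); the number of pairs with
    undefined omega is recorded.  All pairs undefined -> averaged omega ``None``.
    """
    seqs_a = typeA_panel.sequences if isinstance(typeA_panel, CodonAlignment) else list(typeA_panel)
    seqs_b = typeB_panel.sequences if isinstance(typeB_panel, CodonAlignment) else list(typeB_panel)
    if not seqs_a or not seqs_b:
        raise ValueError("both panels must be non-empty")
    pairs = [ng86_pairwise(a, b) for a in seqs_a for b in seqs_b]
    omegas = [p.omega for p in pairs if p.omega is not None]
    return PairwiseDivergence(
        dN=float(np.mean([p.dN for p in pairs])),
        dS=float(np.mean([p.dS for p in pairs])),
        omega=float(np.mean(omegas)) if omegas else None,
        pN=float(np.mean([p.pN for p in pairs])),
        pS=float(np.mean([p.pS for p in pairs])),
        saturated=any(p.saturated for p in pairs),
        n_pairs=len(pairs),
        n_undefined_omega=sum(p.n_undefined_omega for p in pairs),
    )


def classify_candidate(omega_mean: float | None) -> bool:
    """Positive-selection candidate screen: strictly omega > 0.5.

    An undefined omega is not classifiable and raises ``ValueError``.
    """
    if omega_mean is None or math.isnan(omega_mean):
        raise ValueError("omega undefined: candidate status not classifiable")
    return omega_mean > 0.5


def mann_whitney_one_tailed(
    group_grp: Iterable[float], group_control: Iterable[float]
) -> tuple[float, float]:
    """One-tailed Mann–Whitney U test, alternative: GRP group stochastically greater.

    Exact enumeration when the combined sample size is <= 12 and tie-free,
    tie-corrected normal approximation otherwise.  Fully tied data yield p = 1
    with a warning.
    """
    x = np.asarray(list(group_grp), dtype=float)
    y = np.asarray(list(group_control), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p set to 1")
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)
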