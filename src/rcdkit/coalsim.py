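"""Neutral Hudson coalescent with recombination and simulation-based null distributions.

The simulator runs the ancestral recombination graph backwards in time over a
continuous unit interval: lineages coalesce at rate k(k-1)/2, recombine at rate
(rho/2) x (their breakable ancestral span), and accumulate infinite-sites
mutations at rate (theta/2) x (their ancestral material length).  Each mutation
is tagged with the sample set that carries it, so derived-allele counts are
exact from the topology.  Null distributions, 95% CIs, empirical p-values and
the sympatric/allopatric CI-overlap decision rule are layered on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class CoalescentConfig:
    """Parameters of one gene x population null simulation.

    theta_gene and rho_gene are the per-gene (not per-site) scaled mutation and
    recombination rates; L only sets the per-site scale of derived statistics.
    """

    n: int
    theta_gene: float
    rho_gene: float = 0.0
    L: int = 1000
    reps: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n >= 2 required")
        if self.theta_gene < 0 or self.rho_gene < 0:
            raise ValueError("theta and rho must be >= 0")
        if self.reps < 1:
            raise ValueError("reps >= 1 required")


@dataclass
class SimulatedSample:
    """One simulated haplotype set: binary genotypes with known ancestral states."""

    n: int
    L: int
    positions: np.ndarray          # continuous mutation positions in [0, 1)
    genotypes: np.ndarray          # (n, S) bool; True = derived

    @property
    def S(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def derived_counts(self) -> np.ndarray:
        return self.genotypes.sum(axis=0)

    @property
    def pi_gene(self) -> float:
        i = self.derived_counts.astype(float)
        n = self.n
        return float(np.sum(2.0 * i * (n - i)) / (n * (n - 1)))


# ---------------------------------------------------------------------------
# ARG simulation
# ---------------------------------------------------------------------------

class _Lineage:
    """Ancestral material of one lineage: disjoint segments carrying sample sets."""

    __slots__ = ("segments",)

    def __init__(self, segments: list[tuple[float, float, frozenset]]):
        self.segments = segments  # sorted, non-overlapping (left, right, samples)

    @property
    def material(self) -> float:
        return sum(r - l for l, r, _ in self.segments)

    @property
    def span(self) -> float:
        return self.segments[-1][1] - self.segments[0][0]

    @property
    def left(self) -> float:
        return self.segments[0][0]


def _merge_segments(
    a: list[tuple[float, float, frozenset]],
    b: list[tuple[float, float, frozenset]],
    full: frozenset,
) -> list[tuple[float, float, frozenset]]:
    """Union of two segment lists; overlapping stretches union their sample sets.

    Stretches whose union covers the full sample have found their MRCA and are
    dropped.
    """
    bounds = sorted(
        {x for l, r, _ in a for x in (l, r)} | {x for l, r, _ in b for x in (l, r)}
    )
    out: list[tuple[float, float, frozenset]] = []

    def carrier(segs, mid):
        for l, r, s in segs:
            if l <= mid < r:
                return s
        return None

    for l, r in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (l + r)
        sa, sb = carrier(a, mid), carrier(b, mid)
        if sa is None and sb is None:
            continue
        s = (sa or frozenset()) | (sb or frozenset())
        if s == full:
            continue  # MRCA reached for this stretch
        if out and out[-1][1] == l and out[-1][2] == s:
            out[-1] = (out[-1][0], r, s)
        else:
            out.append((l, r, s))
    return out


def simulate_sample(
    config: CoalescentConfig, rng: np.random.Generator | None = None
) -> SimulatedSample:
    """One draw from the neutral coalescent with recombination (infinite sites)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n
    full = frozenset(range(n))
    lineages = [_Lineage([(0.0, 1.0, frozenset([i]))]) for i in range(n)]
    mutations: list[tuple[float, frozenset]] = []
    theta2 = config.theta_gene / 2.0
    rho2 = config.rho_gene / 2.0
    while lineages:
        k = len(lineages)
        materials = np.array([lin.material for lin in lineages])
        spans = np.array([lin.span for lin in lineages])
        rate_coal = k * (k - 1) / 2.0
        rate_rec = rho2 * float(spans.sum())
        rate_mut = theta2 * float(materials.sum())
        total = rate_coal + rate_rec + rate_mut
        if total == 0:
            break
        u = rng.random() * total
        if u < rate_mut:
            # mutation: lineage proportional to material, position uniform in it
            idx = int(rng.choice(k, p=materials / materials.sum()))
            lin = lineages[idx]
            x = rng.random() * lin.material
            acc = 0.0
            for l, r, s in lin.segments:
                if x < acc + (r - l):
                    mutations.append((l + (x - acc), s))
                    break
                acc += r - l
        elif u < rate_mut + rate_rec:
            # recombination: breakpoint uniform within the lineage's span
            idx = int(rng.choice(k, p=spans / spans.sum()))
            lin = lineages[idx]
            bp = lin.left + rng.random() * lin.span
            left_segs, right_segs = [], []
            for l, r, s in lin.segments:
                if r <= bp:
                    left_segs.append((l, r, s))
                elif l >= bp:
                    right_segs.append((l, r, s))
                else:
                    left_segs.append((l, bp, s))
                    right_segs.append((bp, r, s))
            if left_segs and right_segs:
                lineages[idx] = _Lineage(left_segs)
                lineages.append(_Lineage(right_segs))
            # breakpoint outside material at an end: no-op (cannot happen with
            # span-uniform breakpoints except at exact boundaries)
        else:
            i, j = rng.choice(k, size=2, replace=False)
            i, j = int(min(i, j)), int(max(i, j))
            merged = _merge_segments(
                lineages[i].segments, lineages[j].segments, full
            )
            lineages.pop(j)
            if merged:
                lineages[i] = _Lineage(merged)
            else:
                lineages.pop(i)
    mutations.sort(key=lambda m: m[0])
    S = len(mutations)
    genotypes = np.zeros((n, S), dtype=bool)
    positions = np.empty(S)
    for col, (pos, carriers) in enumerate(mutations):
        positions[col] = pos
        genotypes[list(carriers), col] = True
    return SimulatedSample(n=n, L=config.L, positions=positions, genotypes=genotypes)


def simulate_replicates(
    config: CoalescentConfig, rng: np.random.Generator | None = None
) -> list[SimulatedSample]:
    """``config.reps`` seeded replicates (deterministic for a given config+seed)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return [simulate_sample(config, rng) for _ in range(config.reps)]


# ---------------------------------------------------------------------------
# null distributions and the CI-overlap rule
# ---------------------------------------------------------------------------

@dataclass
class NullSummary:
    """Simulated null of one statistic with the observed value's empirical p."""

    stat_name: str
    observed: float
    null_mean: float
    ci_low: float
    ci_high: float
    p_value: float
    n_valid: int
    n_na: int


def null_distribution(
    stat: Callable[[SimulatedSample], float],
    observed: float,
    config: CoalescentConfig,
    stat_name: str = "stat",
    rng: np.random.Generator | None = None,
) -> NullSummary:
    """Empirical null for a statistic evaluator over ``config.reps`` replicates.

    NA replicates (typically S = 0) are dropped and counted; more than 50% NA
    is refused.  The 95% CI is the 2.5/97.5 percentile band.  The p-value is
    one-tailed on the side of the observed deviation from the null median,
    counting replicates as or more extreme, floored at 1/(reps+1).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    values = []
    n_na = 0
    for _ in range(config.reps):
        v = stat(simulate_sample(config, rng))
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_na += 1
        else:
            values.append(float(v))
    if n_na > config.reps / 2:
        raise RuntimeError(
            f"{stat_name}: {n_na}/{config.reps} null replicates NA; null unusable"
        )
    arr = np.array(values)
    median = float(np.median(arr))
    if observed >= median:
        extreme = int(np.sum(arr >= observed))
    else:
        extreme = int(np.sum(arr <= observed))
    p = max(extreme / arr.size, 1.0 / (config.reps + 1))
    return NullSummary(
        stat_name=stat_name,
        observed=observed,
        null_mean=float(arr.mean()),
        ci_low=float(np.percentile(arr, 2.5)),
        ci_high=float(np.percentile(arr, 97.5)),
        p_value=min(p, 1.0),
        n_valid=arr.size,
        n_na=n_na,
    )


def ci_overlap_test(sym: NullSummary, allo: NullSummary) -> bool:
    """Sympatric vs allopatric significance by the two-way CI-exclusion rule.

    Significant only if the sympatric 95% CI excludes the allopatric observed
    value AND the allopatric CI excludes the sympatric observed value (the
    conjunction of both directions).  NA statistics are not evaluable.
    """
    if sym.stat_name != allo.stat_name:
        raise ValueError("summaries compare different statistics")
    for s in (sym, allo):
        if math.isnan(s.observed):
            raise ValueError("NA statistic: CI-overlap test not evaluable")
    sym_excludes = not (sym.ci_low <= allo.observed <= sym.ci_high)
    allo_excludes = not (allo.ci_low <= sym.observed <= allo.ci_high)
    return sym_excludes and allo_excludes


# -- statistic evaluators over simulated samples ----------------------------

def sim_tajimas_d(sample: SimulatedSample) -> float:
    from .neutrality import tajimas_d_from_summary

    return tajimas_d_from_summary(sample.n, sample.S, sample.pi_gene)


def sim_fu_li_d_star(sample: SimulatedSample) -> float:
    from .neutrality import fu_li_star_from_summary

    counts = sample.derived_counts
    eta_s = int(np.sum((counts == 1) | (counts == sample.n - 1)))
    return fu_li_star_from_summary(sample.n, sample.S, eta_s, sample.pi_gene)[0]


def sim_fu_li_f_star(sample: SimulatedSample) -> float:
    from .neutrality import fu_li_star_from_summary

    counts = sample.derived_counts
    eta_s = int(np.sum((counts == 1) | (counts == sample.n - 1)))
    return fu_li_star_from_summary(sample.n, sample.S, eta_s, sample.pi_gene)[1]


def sim_fay_wu_h(sample: SimulatedSample) -> float:
    from .neutrality import fay_wu_h_from_counts

    counts = sample.derived_counts
    counts = counts[(counts > 0) & (counts < sample.n)]
    return fay_wu_h_from_counts(sample.n, counts)[0]


SIM_STATISTICS: dict[str, Callable[[SimulatedSample], float]] = {
    "D": sim_tajimas_d,
    "D*": sim_fu_li_d_star,
    "F*": sim_fu_li_f_star,
    "H": sim_fay_wu_h,
}
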