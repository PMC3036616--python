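"""Bayesian constant-omega inference from a population sample of coding haplotypes.

The model is a pairwise composite likelihood: every unordered haplotype pair is
treated as two sequences separated by a coalescent divergence time t drawn from
an Exponential(1) density scaled by mu, evolving under an NY98-style codon
substitution model (kappa-weighted transitions, omega-weighted nonsynonymous
changes, empirical codon frequencies).  The t-integral is evaluated by fixed
Gauss-Laguerre quadrature, and the per-pair log-likelihoods are summed.

Priors for (mu, kappa, omega) are reciprocal densities (proportional to 1/x)
truncated to [1e-6, 1e3].  Sampling is Metropolis-Hastings with log-scale
Gaussian random-walk proposals; with a reciprocal prior the prior ratio and the
log-normal proposal's Hastings ratio cancel exactly, so moves are accepted on
the likelihood ratio alone (within the truncation bounds).

The comparison between two populations pairs posterior omega draws at random
and summarizes the difference distribution by its mean and equal-tailed 95%
credible interval; an interval containing zero means "not significantly
different".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment
from .codons import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP,
    is_transition,
    is_unambiguous_codon,
)

PRIOR_LOW = 1e-6
PRIOR_HIGH = 1e3

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_N_CODONS = len(SENSE_CODONS)


def _exchangeability_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-step masks over sense-codon pairs: (any, transition, nonsynonymous)."""
    single = np.zeros((_N_CODONS, _N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            p = diffs[0]
            transition[i, j] = is_transition(ci[p], cj[p])
            nonsyn[i, j] = GENETIC_CODE[ci] != GENETIC_CODE[cj]
    return single, transition, nonsyn

_SINGLE, _TRANSITION, _NONSYN = _exchangeability_masks()


def empirical_codon_frequencies(alignment: CodonAlignment, pseudocount: float = 0.5) -> np.ndarray:
    """Sense-codon frequencies observed in the sample, with a small pseudocount."""
    counts = np.full(_N_CODONS, pseudocount)
    for seq in alignment.sequences:
        for k in range(0, len(seq), 3):
            codon = seq[k : k + 3]
            idx = _CODON_INDEX.get(codon)
            if idx is not None:
                counts[idx] += 1.0
    return counts / counts.sum()


def codon_rate_matrix(kappa: float, omega: float, freqs: np.ndarray) -> np.ndarray:
    """NY98 constant-omega generator, normalized to one expected substitution/unit time."""
    Q = np.where(_SINGLE, np.where(_TRANSITION, kappa, 1.0), 0.0)
    Q = Q * np.where(_NONSYN, omega, 1.0)
    Q = Q * freqs[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(np.sum(freqs * np.diag(Q)))
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / scale


@dataclass
class _PairPatterns:
    """Sparse codon-pair pattern counts for one unordered haplotype pair."""

    i: np.ndarray
    j: np.ndarray
    counts: np.ndarray
    weight: float  # multiplicity of this haplotype pair in the sample


def _haplotype_patterns(alignment: CodonAlignment) -> list[_PairPatterns]:
    """Collapse the sample to distinct haplotypes and build per-pair patterns."""
    seq_to_count: dict[str, int] = {}
    for s in alignment.sequences:
        seq_to_count[s] = seq_to_count.get(s, 0) + 1
    haps = list(seq_to_count)
    idx_seqs = []
    for s in haps:
        codons = [
            _CODON_INDEX.get(s[k : k + 3]) for k in range(0, len(s), 3)
        ]
        idx_seqs.append(codons)
    out: list[_PairPatterns] = []
    for a in range(len(haps)):
        for b in range(a, len(haps)):
            ca, cb = seq_to_count[haps[a]], seq_to_count[haps[b]]
            weight = ca * (ca - 1) / 2.0 if a == b else float(ca * cb)
            if weight == 0:
                continue
            patt: dict[tuple[int, int], int] = {}
            for ia, ib in zip(idx_seqs[a], idx_seqs[b]):
                if ia is None or ib is None:
                    continue  # ambiguity: codon skipped
                key = (min(ia, ib), max(ia, ib))  # joint matrix is symmetric
                patt[key] = patt.get(key, 0) + 1
            keys = np.array(list(patt), dtype=int).reshape(-1, 2)
            out.append(
                _PairPatterns(
                    i=keys[:, 0],
                    j=keys[:, 1],
                    counts=np.array(list(patt.values()), dtype=float),
                    weight=weight,
                )
            )
    return out


class CompositeLikelihood:
    """Pairwise composite log-likelihood of a sample under the constant-omega model.

    With ``calibrate=True`` (default) the summed pair log-likelihood is rescaled
    by a_n/C(n,2), a_n = sum_{i<n} 1/i: an unweighted sum over all pairs counts
    every mutation O(n) times and yields spuriously sharp posteriors, whereas
    the mutation count of a coalescent sample — the raw information about rates
    — grows only like theta*a_n, i.e. a_n effective pairs.  The rescaling
    leaves the surface's shape (and so point estimates) unchanged but restores
    credible-interval magnitudes usable for interval-based decisions.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        quadrature_nodes: int = 16,
        calibrate: bool = True,
    ):
        if quadrature_nodes < 2:
            raise ValueError("need >= 2 quadrature nodes")
        self.freqs = empirical_codon_frequencies(alignment)
        self.pairs = _haplotype_patterns(alignment)
        total_weight = sum(p.weight for p in self.pairs)
        a_n = float(sum(1.0 / i for i in range(1, alignment.n)))
        self.scale = (
            a_n / total_weight if calibrate and total_weight > 0 else 1.0
        )
        nodes, weights = np.polynomial.laguerre.laggauss(quadrature_nodes)
        self._nodes = nodes          # Exponential(1) support points
        self._log_weights = np.log(weights)
        self._sqrt_f = np.sqrt(self.freqs)
        self._cache_key: tuple[float, float] | None = None
        self._eig = None
        # union of observed codon-pair patterns: logs are taken only there
        seen: dict[tuple[int, int], int] = {}
        for pair in self.pairs:
            for a, b in zip(pair.i, pair.j):
                seen.setdefault((int(a), int(b)), len(seen))
        self._union_i = np.array([k[0] for k in seen], dtype=int)
        self._union_j = np.array([k[1] for k in seen], dtype=int)
        self._pair_pos = [
            np.array([seen[(int(a), int(b))] for a, b in zip(p.i, p.j)], dtype=int)
            for p in self.pairs
        ]

    def _eigen(self, kappa: float, omega: float):
        if self._cache_key == (kappa, omega):
            return self._eig
        Q = codon_rate_matrix(kappa, omega, self.freqs)
        # reversible: symmetrize with sqrt(pi) and use the symmetric eigensolver
        B = (self._sqrt_f[:, None] * Q) / self._sqrt_f[None, :]
        B = 0.5 * (B + B.T)
        lam, U = np.linalg.eigh(B)
        self._cache_key = (kappa, omega)
        self._eig = (lam, U)
        return self._eig

    def __call__(self, mu: float, kappa: float, omega: float) -> float:
        """Composite log-likelihood; -inf outside the parameter support."""
        for v in (mu, kappa, omega):
            if not (PRIOR_LOW <= v <= PRIOR_HIGH) or not math.isfinite(v):
                return -math.inf
        lam, U = self._eigen(kappa, omega)
        t = mu * self._nodes
        # joint pair-probability matrix J(t) = diag(pi) P(t); symmetric under
        # reversibility: J = D^{1/2} U exp(lam t) U' D^{1/2}
        W = U * self._sqrt_f[:, None]  # rows scaled
        # J(t)[i,j] evaluated only at observed patterns, for every node:
        # J_ij = sum_k W_ik exp(lam_k t) W_jk
        prod = W[self._union_i] * W[self._union_j]           # (U, 61)
        expt = np.exp(np.outer(t, lam))                      # (q, 61)
        vals = expt @ prod.T                                 # (q, U)
        np.clip(vals, 1e-300, None, out=vals)
        logvals = np.log(vals)
        total = 0.0
        for pair, pos in zip(self.pairs, self._pair_pos):
            ll_q = logvals[:, pos] @ pair.counts + self._log_weights
            m = ll_q.max()
            total += pair.weight * (m + math.log(np.sum(np.exp(ll_q - m))))
        return float(self.scale * total)


def composite_loglik(
    alignment: CodonAlignment,
    mu: float,
    kappa: float,
    omega: float,
    quadrature_nodes: int = 16,
    calibrate: bool = True,
) -> float:
    """One-shot composite log-likelihood (builds pattern tables each call)."""
    return CompositeLikelihood(alignment, quadrature_nodes, calibrate)(mu, kappa, omega)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Metropolis-Hastings settings for the constant-omega model."""

    iterations: int = 250_000
    thinning: int = 1000
    burn_in_fraction: float = 0.2
    init_mu: float = 0.1
    init_kappa: float = 3.0
    init_omega: float = 0.5
    proposal_sd: float = 0.4
    prior_low: float = PRIOR_LOW
    prior_high: float = PRIOR_HIGH
    quadrature_nodes: int = 16
    use_likelihood: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.iterations // self.thinning < 50:
            raise ValueError("iterations/thinning must retain >= 50 draws")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction in [0, 1)")


@dataclass
class PosteriorSample:
    """Retained MCMC draws of (mu, kappa, omega) with run diagnostics."""

    mu: np.ndarray
    kappa: np.ndarray
    omega: np.ndarray
    run_id: str = ""
    acceptance_rates: dict = field(default_factory=dict)
    na_reason: str | None = None

    @property
    def is_na(self) -> bool:
        return self.na_reason is not None

    def summary(self) -> dict:
        out = {}
        for name in ("mu", "kappa", "omega"):
            draws = getattr(self, name)
            out[name] = {
                "mean": float(np.mean(draws)),
                "cri_low": float(np.percentile(draws, 2.5)),
                "cri_high": float(np.percentile(draws, 97.5)),
                "sd": float(np.std(draws)),
            }
        return out


MIN_SEGREGATING_SITES = 2


def _enough_variation(alignment: CodonAlignment) -> bool:
    """Whether the sample can inform omega at all.

    Requires >= 2 segregating sites and at least one synonymous pairwise
    difference: with no synonymous variation the synonymous rate — the
    denominator of omega — is unidentified and the posterior ratio diverges.
    """
    from .polymorphism import _class_pairwise, segregating_sites

    if len(set(alignment.sequences)) < 2 or alignment.n < 2:
        return False
    if segregating_sites(alignment) < MIN_SEGREGATING_SITES:
        return False
    syn_d, _, _, _ = _class_pairwise(alignment)
    return syn_d > 0


def run_mcmc(
    alignment: CodonAlignment, config: MCMCConfig, run_id: str = "run"
) -> PosteriorSample:
    """Sample the posterior of (mu, kappa, omega) for one population sample.

    Degenerate data — monomorphic samples, fewer than 2 segregating sites, or
    no synonymous variation (omega's denominator unidentified) — yield an
    NA-flagged sample ("Not enough variation"): omega is then prior- or
    boundary-dominated and unreliable.
    """
    rng = np.random.default_rng(config.seed)
    na_reason = None
    if not _enough_variation(alignment):
        na_reason = "Not enough variation"
    loglik = (
        CompositeLikelihood(alignment, config.quadrature_nodes)
        if config.use_likelihood
        else None
    )
    params = np.array([config.init_mu, config.init_kappa, config.init_omega])
    names = ("mu", "kappa", "omega")
    current_ll = loglik(*params) if loglik else 0.0
    accepts = np.zeros(3)
    proposals = np.zeros(3)
    kept = {name: [] for name in names}
    lo, hi = config.prior_low, config.prior_high
    for it in range(1, config.iterations + 1):
        for p in range(3):
            proposals[p] += 1
            proposal = params.copy()
            proposal[p] = params[p] * math.exp(config.proposal_sd * rng.standard_normal())
            if not (lo <= proposal[p] <= hi):
                continue  # outside truncated prior support: reject
            new_ll = loglik(*proposal) if loglik else 0.0
            # reciprocal prior x log-normal RW: prior and Hastings terms cancel
            if math.log(rng.random()) < new_ll - current_ll:
                params = proposal
                current_ll = new_ll
                accepts[p] += 1
        if it % config.thinning == 0:
            for p, name in enumerate(names):
                kept[name].append(params[p])
    n_kept = len(kept["mu"])
    burn = int(math.floor(n_kept * config.burn_in_fraction))
    return PosteriorSample(
        mu=np.array(kept["mu"][burn:]),
        kappa=np.array(kept["kappa"][burn:]),
        omega=np.array(kept["omega"][burn:]),
        run_id=run_id,
        acceptance_rates={
            name: float(accepts[p] / max(proposals[p], 1))
            for p, name in enumerate(names)
        },
        na_reason=na_reason,
    )


@dataclass
class CombineResult:
    ok: bool
    sample: PosteriorSample | None
    diagnostics: dict


def combine_runs(
    run1: PosteriorSample, run2: PosteriorSample, tolerance: float = 0.5
) -> CombineResult:
    """Concatenate two independent runs if their summaries match closely.

    For every parameter the run means must agree within ``tolerance`` pooled
    posterior SDs and the 95% CrI endpoints likewise; otherwise the runs are
    flagged for more iterations and no combined sample is returned.
    """
    diagnostics = {}
    ok = True
    for name in ("mu", "kappa", "omega"):
        d1, d2 = getattr(run1, name), getattr(run2, name)
        pooled_sd = math.sqrt(0.5 * (np.var(d1) + np.var(d2)))
        limit = tolerance * pooled_sd
        mean_gap = abs(float(np.mean(d1) - np.mean(d2)))
        lo_gap = abs(float(np.percentile(d1, 2.5) - np.percentile(d2, 2.5)))
        hi_gap = abs(float(np.percentile(d1, 97.5) - np.percentile(d2, 97.5)))
        param_ok = (
            (mean_gap <= limit and lo_gap <= limit and hi_gap <= limit)
            if pooled_sd > 0
            else (mean_gap == 0.0)
        )
        diagnostics[name] = {
            "mean_gap": mean_gap,
            "ci_low_gap": lo_gap,
            "ci_high_gap": hi_gap,
            "limit": limit,
            "ok": param_ok,
        }
        ok = ok and param_ok
    if not ok:
        return CombineResult(False, None, diagnostics)
    combined = PosteriorSample(
        mu=np.concatenate([run1.mu, run2.mu]),
        kappa=np.concatenate([run1.kappa, run2.kappa]),
        omega=np.concatenate([run1.omega, run2.omega]),
        run_id=f"{run1.run_id}+{run2.run_id}",
        acceptance_rates={
            "run1": run1.acceptance_rates,
            "run2": run2.acceptance_rates,
        },
        na_reason=run1.na_reason or run2.na_reason,
    )
    return CombineResult(True, combined, diagnostics)


@dataclass
class OmegaComparison:
    """Posterior difference of omega between two populations (pop1 - pop2)."""

    mean_diff: float
    cri_low: float
    cri_high: float
    contains_zero: bool
    na_reason: str | None = None

    @property
    def is_na(self) -> bool:
        return self.na_reason is not None


def posterior_difference(
    sample_pop1: PosteriorSample,
    sample_pop2: PosteriorSample,
    draws_B: int | None = None,
    seed: int | None = None,
) -> OmegaComparison:
    """Difference distribution of omega by random pairing of posterior draws.

    B draws of omega are resampled with replacement from each posterior and
    differenced (pop1 - pop2); the mean and equal-tailed 95% credible interval
    summarize the distribution.  Either sample NA-flagged makes the comparison
    NA, mirroring insufficient-variation verdicts.
    """
    for s, label in ((sample_pop1, "pop1"), (sample_pop2, "pop2")):
        if s.is_na:
            return OmegaComparison(
                math.nan, math.nan, math.nan, False,
                na_reason=f"NA ({s.na_reason} in {label})",
            )
        if s.omega.size == 0:
            raise ValueError("empty posterior sample")
    rng = np.random.default_rng(seed)
    B = draws_B or max(sample_pop1.omega.size, sample_pop2.omega.size)
    d = rng.choice(sample_pop1.omega, B, replace=True) - rng.choice(
        sample_pop2.omega, B, replace=True
    )
    lo, hi = float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5))
    return OmegaComparison(
        mean_diff=float(np.mean(d)),
        cri_low=lo,
        cri_high=hi,
        contains_zero=bool(lo <= 0.0 <= hi),
    )
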