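"""Synthetic two-lineage codon data with the study's sampling structure.

Emulates the statistical design the analysis assumes: two deeply diverged
lineages (Type A and Type B) each sampled in a sympatric and an allopatric
population, gene classes with elevated (candidate GRP) versus low (control)
nonsynonymous acceptance, plus a 2+2 cross-type divergence panel per gene.
Genealogies come from a structured coalescent (msprime); mutation is a
codon-aware process of this package: attempts are dropped at rate theta/2 on
branches, placed in random codon positions with kappa-favoured transitions,
stops rejected, and nonsynonymous changes retained with probability
omega_class — so the realized dN/dS has a known truth near omega_class.

Default calibration targets the study's observed ranges: within-population
diversity pi ~ 0.002-0.05 per site and between-type p-distance ~ 0.035-0.124.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np

from .alignment import CodonAlignment
from .codons import GENETIC_CODE, NUCLEOTIDES, SENSE_CODONS, STOP, translate_codon

POPULATIONS = ("sympatric_A", "allopatric_A", "sympatric_B", "allopatric_B")

OMEGA_GRP_DEFAULT = 0.6
OMEGA_CONTROL_DEFAULT = 0.1


@dataclass
class SyntheticConfig:
    """Truth parameters of one synthetic gene.

    tau is the Type A/B split time and tau_pop the sympatric/allopatric deme
    split within each type, both in coalescent units; theta values are per-gene
    attempted-mutation rates; m_sym is the A<->B migration rate inside the
    sympatric pair.  omega_class multiplies the retention probability of
    nonsynonymous mutations (GRP default 0.6, control default 0.1).
    """

    tau: float = 4.5
    tau_pop: float = 0.5
    theta_A: float = 10.0
    theta_B: float = 10.0
    m_sym: float = 0.0
    omega_grp: float = OMEGA_GRP_DEFAULT
    omega_control: float = OMEGA_CONTROL_DEFAULT
    n_individuals: int = 10
    L_codons: int = 150
    kappa_true: float = 3.0
    haploid: bool = False  # mtDNA-like: one allele per individual
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals >= 2")
        if min(self.tau, self.tau_pop, self.theta_A, self.theta_B, self.m_sym) < 0:
            raise ValueError("rates and times must be >= 0")
        if self.omega_grp <= 0 or self.omega_control <= 0:
            raise ValueError("omega_class must be > 0")

    def omega_for_class(self, gene_class: str) -> float:
        if gene_class == "GRP":
            return self.omega_grp
        if gene_class == "control":
            return self.omega_control
        raise ValueError(f"unknown gene class {gene_class!r}")


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """Stop-free codon sequence drawn uniformly over the 61 sense codons."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _mutate_once(
    seq: list[str],
    kappa: float,
    omega_class: float,
    rng: np.random.Generator,
    rejected_stops: list[int],
) -> None:
    """Attempt one mutation in place; stop codons redrawn, nonsyn filtered."""
    L = len(seq) * 3
    while True:
        site = int(rng.integers(0, L))
        codon_i, pos = divmod(site, 3)
        codon = seq[codon_i]
        base = codon[pos]
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
        others = [b for b in NUCLEOTIDES if b != base]
        weights = np.array([kappa if b == transitions[base] else 1.0 for b in others])
        alt = others[int(rng.choice(3, p=weights / weights.sum()))]
        new_codon = codon[:pos] + alt + codon[pos + 1 :]
        if GENETIC_CODE[new_codon] == STOP:
            rejected_stops[0] += 1
            continue  # redraw
        if GENETIC_CODE[new_codon] != GENETIC_CODE[codon]:
            if rng.random() >= omega_class:
                return  # nonsynonymous mutation not accepted
        seq[codon_i] = new_codon
        return


def _demography(config: SyntheticConfig) -> msprime.Demography:
    dem = msprime.Demography()
    # ploidy 1 with size 1 puts branch lengths in standard coalescent units
    # (pairwise coalescence rate 1 within a deme)
    for name in POPULATIONS:
        dem.add_population(name=name, initial_size=1.0)
    dem.add_population(name="anc_A", initial_size=1.0)
    dem.add_population(name="anc_B", initial_size=1.0)
    dem.add_population(name="root", initial_size=1.0)
    if config.m_sym > 0:
        dem.set_symmetric_migration_rate(
            ["sympatric_A", "sympatric_B"], config.m_sym
        )
    # zero times are clamped to a negligible epsilon (split events must be
    # strictly ordered and positive)
    eps = 1e-9
    t_pop = max(config.tau_pop, eps)
    t_split = max(config.tau, t_pop + eps)
    dem.add_population_split(
        time=t_pop, derived=["sympatric_A", "allopatric_A"], ancestral="anc_A"
    )
    dem.add_population_split(
        time=t_pop, derived=["sympatric_B", "allopatric_B"], ancestral="anc_B"
    )
    dem.add_population_split(
        time=t_split, derived=["anc_A", "anc_B"], ancestral="root"
    )
    dem.sort_events()
    return dem


def _simulate_tree(config: SyntheticConfig, seed: int):
    n_haps = config.n_individuals if config.haploid else 2 * config.n_individuals
    samples = {name: n_haps for name in POPULATIONS}
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=_demography(config),
        ploidy=1,
        sequence_length=1,
        random_seed=seed,
    )
    return ts.first(), n_haps


def _evolve_sequences(
    tree, config: SyntheticConfig, theta: dict[int, float], omega_class: float,
    rng: np.random.Generator,
) -> tuple[dict[int, str], int]:
    """Drop codon-aware mutations down the genealogy; returns leaf sequences."""
    root_seq = list(
        random_coding_sequence(config.L_codons, rng)[i : i + 3]
        for i in range(0, 3 * config.L_codons, 3)
    )
    rejected = [0]
    leaf_seqs: dict[int, str] = {}
    # preorder walk carrying the evolving sequence
    stack = [(r, root_seq) for r in tree.roots]
    while stack:
        node, seq = stack.pop()
        branch = tree.branch_length(node)
        if branch > 0:
            seq = list(seq)
            rate = theta.get(node, config.theta_A) / 2.0
            n_mut = rng.poisson(branch * rate)
            for _ in range(n_mut):
                _mutate_once(seq, config.kappa_true, omega_class, rng, rejected)
        children = tree.children(node)
        if not children:
            leaf_seqs[node] = "".join(seq)
        else:
            for child in children:
                stack.append((child, seq))
    return leaf_seqs, rejected[0]


@dataclass
class GeneDataset:
    """One synthetic gene: four population samples plus the divergence panel."""

    gene_name: str
    gene_class: str
    populations: dict[str, CodonAlignment]
    divergence_panel_A: CodonAlignment
    divergence_panel_B: CodonAlignment
    omega_true: float
    rejected_stop_redraws: int = 0


def generate_gene_dataset(
    config: SyntheticConfig,
    gene_class: str = "GRP",
    seed: int | None = None,
    gene_name: str = "gene",
) -> GeneDataset:
    """Simulate one gene's alignments for the four populations and the 2+2 panel.

    The divergence panel reuses the first two allopatric haplotypes of each
    type (the study sequenced its divergence panel from allopatric
    individuals).
    """
    seed = seed if seed is not None else (config.seed or 1)
    rng = np.random.default_rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    tree, n_haps = _simulate_tree(config, ms_seed)
    ts_tree = tree
    omega_class = config.omega_for_class(gene_class)
    # per-node theta: lineage-A nodes use theta_A, B nodes theta_B; internal
    # nodes above the split use the mean (only matters when theta_A != theta_B)
    theta_mean = 0.5 * (config.theta_A + config.theta_B)
    pop_of_node = {}
    tseq = ts_tree.tree_sequence
    for node in tseq.nodes():
        pop_name = (
            tseq.population(node.population).metadata.get("name", "")
            if node.population >= 0
            else ""
        )
        if pop_name.endswith("_A") or pop_name == "anc_A":
            pop_of_node[node.id] = config.theta_A
        elif pop_name.endswith("_B") or pop_name == "anc_B":
            pop_of_node[node.id] = config.theta_B
        else:
            pop_of_node[node.id] = theta_mean
    leaf_seqs, rejected = _evolve_sequences(
        ts_tree, config, pop_of_node, omega_class, rng
    )
    # map leaves back to populations in sampling order
    pops: dict[str, CodonAlignment] = {}
    samples_by_pop = {name: [] for name in POPULATIONS}
    for leaf in tseq.samples():
        name = tseq.population(tseq.node(leaf).population).metadata["name"]
        samples_by_pop[name].append(leaf)
    for name in POPULATIONS:
        leaves = samples_by_pop[name]
        lineage = "A" if name.endswith("A") else "B"
        context = "sympatric" if name.startswith("sym") else "allopatric"
        pops[name] = CodonAlignment(
            gene_name=gene_name,
            sequences=[leaf_seqs[l] for l in leaves],
            ids=[f"{name}_h{i}" for i in range(len(leaves))],
            lineage=lineage,
            context=context,
        )
    panel_A = CodonAlignment(
        gene_name=gene_name,
        sequences=pops["allopatric_A"].sequences[:2],
        ids=["panelA_1", "panelA_2"],
        lineage="A",
        context="divergence_panel",
    )
    panel_B = CodonAlignment(
        gene_name=gene_name,
        sequences=pops["allopatric_B"].sequences[:2],
        ids=["panelB_1", "panelB_2"],
        lineage="B",
        context="divergence_panel",
    )
    return GeneDataset(
        gene_name=gene_name,
        gene_class=gene_class,
        populations=pops,
        divergence_panel_A=panel_A,
        divergence_panel_B=panel_B,
        omega_true=omega_class,
        rejected_stop_redraws=rejected,
    )


def generate_population_sample(
    theta: float,
    omega_class: float,
    n_haplotypes: int = 10,
    L_codons: int = 300,
    kappa: float = 3.0,
    seed: int | None = None,
    gene_name: str = "gene",
) -> CodonAlignment:
    """One panmictic population sample with known omega truth.

    A single-deme coalescent genealogy (msprime) with codon-aware mutation:
    the within-population analogue of :func:`generate_gene_dataset`, used for
    estimator parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n_haplotypes, ploidy=1, population_size=1.0,
        sequence_length=1, random_seed=ms_seed,
    )
    tree = ts.first()
    cfg = SyntheticConfig(
        theta_A=theta, theta_B=theta, L_codons=L_codons, kappa_true=kappa
    )
    theta_by_node = {node.id: theta for node in ts.nodes()}
    leaf_seqs, _ = _evolve_sequences(tree, cfg, theta_by_node, omega_class, rng)
    leaves = list(ts.samples())
    return CodonAlignment(
        gene_name=gene_name,
        sequences=[leaf_seqs[l] for l in leaves],
        ids=[f"h{i}" for i in range(len(leaves))],
    )


CLONE_MISS_PROB = 0.5 ** 7  # both alleles identical in 8 sampled clones


@dataclass
class Individual:
    individual_id: str
    allele_1: str
    allele_2: str
    called_homozygous: bool = False


def diploid_packaging(
    haplotypes: list[str],
    n_individuals: int,
    clone_sampling: bool = False,
    rng: np.random.Generator | None = None,
) -> list[Individual]:
    """Pair consecutive haplotypes into diploid individuals.

    With ``clone_sampling`` on, the 8-clone allele-discovery protocol is
    emulated: a heterozygote's second allele is missed (and the individual
    miscalled homozygous) with probability (1/2)^7 under fair clone sampling.
    """
    if len(haplotypes) != 2 * n_individuals:
        raise ValueError("need exactly 2 * n_individuals haplotypes")
    rng = rng if rng is not None else np.random.default_rng()
    individuals = []
    for i in range(n_individuals):
        h1, h2 = haplotypes[2 * i], haplotypes[2 * i + 1]
        miscalled = False
        if clone_sampling and h1 != h2 and rng.random() < CLONE_MISS_PROB:
            h2 = h1
            miscalled = True
        individuals.append(
            Individual(f"ind{i}", h1, h2, called_homozygous=miscalled)
        )
    return individuals
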