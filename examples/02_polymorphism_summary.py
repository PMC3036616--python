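"""Per-population polymorphism summaries for one gene.

Prints sample size, sites analyzed, segregating sites, Watterson's theta and
nucleotide diversity (total and by NG86 site class) for the four populations,
plus Hudson's F_ST between the sympatric Type A and Type B demes.
"""

from rcdkit import polymorphism
from rcdkit.synthetic import SyntheticConfig, generate_gene_dataset

g = generate_gene_dataset(SyntheticConfig(), "GRP", seed=11, gene_name="demo")

print(f"{'population':<14} {'n':>3} {'L':>5} {'S':>3} {'theta_w':>8} "
      f"{'pi':>7} {'pi_syn':>7} {'pi_non':>7}")
for name, aln in g.populations.items():
    s = polymorphism.summarize(aln, population=name)
    print(f"{name:<14} {s.n:>3} {s.L:>5} {s.S:>3} {s.theta_w:>8.4f} "
          f"{s.pi_total:>7.4f} {s.pi_syn:>7.4f} {s.pi_nonsyn:>7.4f}")

fst = polymorphism.hudson_fst(
    g.populations["sympatric_A"], g.populations["sympatric_B"]
)
print(f"\nHudson F_ST sympatric A vs B: {fst:.3f}")
print(
    "theta_w and pi are per analyzed site; pi_syn > pi_non reflects purifying "
    "pressure on amino-acid changes. F_ST near 1 shows the two lineages are "
    "strongly differentiated even in sympatry."
)
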