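#!/usr/bin/env python
"""Generate the synthetic study datasets every downstream step analyses.

Writes, under results/data/:
  * an episodic-burst codon alignment: a 500-codon gene evolved on a
    6-taxon tree with dN/dS = 6 on one internal branch over a purifying
    (omega = 0.2) background, plus the generating tree and the true
    per-branch substitution counts;
  * a dimorphic population sample: 16 diploid individuals whose phased
    haplotypes fall into two deeply diverged allele clades with complete
    linkage between the coding and 3'-noncoding blocks;
  * a neutral coalescent sample (n = 20, theta = 5) for calibrating the
    frequency-spectrum statistics.
"""

from pathlib import Path

from codonburst import seqio, simulate

SEED = 20140601
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
BURST_TREE = "((A:0.02,B:0.02)x:0.02,(C:0.02,D:0.02)y:0.02,(E:0.02,F:0.02)z:0.02)r;"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    tree = seqio.read_newick(BURST_TREE)
    sim = simulate.simulate_codon_tree(
        simulate.SimulationConfig(
            tree=tree, n_codons=500, omega_map={"x": 6.0},
            default_omega=0.2, seed=SEED,
        )
    )
    seqio.write_fasta_alignment(sim.alignment, OUT / "burst_alignment.fasta")
    (OUT / "burst_tree.nwk").write_text(BURST_TREE + "\n")
    with open(OUT / "burst_true_counts.tsv", "w") as fh:
        fh.write("branch\tns\ts\n")
        for branch, (ns, s) in sorted(sim.branch_counts.items()):
            fh.write(f"{branch}\t{ns}\t{s}\n")
    ns, s = sim.branch_counts["r->x"]
    print(f"burst gene: true counts on the accelerated branch ns={ns}, s={s}")

    pop = simulate.simulate_dimorphic_population(
        simulate.PopulationSimConfig(recombination_prob=0.0, seed=SEED)
    )
    seqio.write_fasta_alignment(pop.sample.alignment, OUT / "dimorphic_haplotypes.fasta")
    with open(OUT / "dimorphic_population.tsv", "w") as fh:
        fh.write("individual_id\tphase\tsequence_id\tpopulation\ttrue_clade\n")
        for ind, ph, sid, clade in zip(
            pop.sample.individuals, pop.sample.phases,
            pop.sample.sequence_ids, pop.true_clades,
        ):
            fh.write(f"{ind}\t{ph}\t{sid}\tsim\t{clade}\n")
    with open(OUT / "dimorphic_diagnostics.tsv", "w") as fh:
        fh.write("site\tstate_I\tstate_II\n")
        for site, sI, sII in pop.diagnostic_sites:
            fh.write(f"{site}\t{sI}\t{sII}\n")
    n_I = pop.true_clades.count("I")
    print(
        f"dimorphic sample: {pop.sample.n_individuals} individuals, "
        f"clade I/II haplotypes {n_I}/{len(pop.true_clades) - n_I}"
    )

    haps = simulate.simulate_neutral_sample(20, 5.0, 2000, seed=SEED)
    with open(OUT / "neutral_sample.fasta", "w") as fh:
        for i, h in enumerate(haps):
            fh.write(f">hap{i + 1}\n{h}\n")
    print(f"neutral sample: {len(haps)} haplotypes of {len(haps[0])} sites")


if __name__ == "__main__":
    main()
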