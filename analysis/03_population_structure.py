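#!/usr/bin/env python
"""Intrapopulation analysis of the dimorphic haplotype sample: sliding-window
pi and Tajima's D, coding-vs-3' linkage disequilibrium, Hardy-Weinberg
equilibrium of the clade genotypes, clade assignment, and the haplotype
network with inferred intermediates.

Writes results/windows.tsv, results/ld_hwe.tsv and results/network.dot.
"""

import csv
from collections import Counter
from pathlib import Path

from codonburst import popgen, seqio

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    aln = seqio.read_fasta_alignment(ROOT / "data" / "dimorphic_haplotypes.fasta")
    diagnostics = []
    with open(ROOT / "data" / "dimorphic_diagnostics.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            diagnostics.append((int(row["site"]), row["state_I"], row["state_II"]))
    coding = (0, 900)
    flank3 = (900, 1500)
    haps = aln.sequences

    windows = popgen.sliding_windows(haps, window=100, step=25)
    with open(ROOT / "windows.tsv", "w") as fh:
        fh.write("start\tend\tpi\ttajima_D\tS\n")
        for w in windows:
            d = w.stats.tajima_D
            fh.write(
                f"{w.start + 1}\t{w.end}\t{w.stats.pi:.6g}\t"
                f"{'NA' if d is None else f'{d:.4f}'}\t{w.stats.S}\n"
            )
    peak = max(windows, key=lambda w: w.stats.pi)
    print(
        f"peak diversity window [{peak.start + 1}, {peak.end}]: "
        f"pi={peak.stats.pi:.4g}, Tajima's D={peak.stats.tajima_D:.3f}"
    )

    coding_clades = popgen.assign_clades([h[slice(*coding)] for h in haps],
                                         diagnostics).labels
    # diagnose the flank block from its own fixed differences
    flank_states = [h[slice(*flank3)] for h in haps]
    flank_diag = []
    for i in range(len(flank_states[0])):
        counts = Counter(s[i] for s in flank_states)
        if len(counts) == 2 and min(counts.values()) >= 10:
            # polarize consistently: state_I is the first haplotype's state
            a = flank_states[0][i]
            b = next(x for x in counts if x != a)
            flank_diag.append((i, a, b))
    flank_clades = popgen.assign_clades(flank_states, flank_diag).labels
    ld = popgen.ld_two_loci(coding_clades, flank_clades, "coding", "flank3")

    counts = Counter(
        tuple(sorted((coding_clades[i], coding_clades[i + 1])))
        for i in range(0, len(coding_clades), 2)
    )
    n_II = counts.get(("I", "I"), 0)
    n_ID = counts.get(("I", "II"), 0)
    n_DD = counts.get(("II", "II"), 0)
    hwe_p = popgen.hwe_test(n_II, n_ID, n_DD)

    with open(ROOT / "ld_hwe.tsv", "w") as fh:
        fh.write("statistic\tvalue\n")
        fh.write(f"D\t{ld.D:.4f}\nD_prime\t{ld.D_prime:.4f}\n")
        fh.write(f"ld_p_two_tailed\t{ld.p_two_tailed:.4g}\n")
        fh.write(f"hwe_genotypes_II_ID_DD\t{n_II}/{n_ID}/{n_DD}\n")
        fh.write(f"hwe_exact_p\t{hwe_p:.4g}\n")
    print(
        f"coding vs 3' linkage: D'={ld.D_prime:.3f} (p={ld.p_two_tailed:.2g}); "
        f"HWE exact p={hwe_p:.3f} on genotypes {n_II}/{n_ID}/{n_DD}"
    )

    alleles: dict[str, str] = {}
    freqs: dict[str, int] = {}
    for taxon, seq in zip(aln.taxa, haps):
        for aid, aseq in alleles.items():
            if aseq == seq:
                freqs[aid] += 1
                break
        else:
            alleles[taxon] = seq
            freqs[taxon] = 1
    net = popgen.build_network(alleles, freqs, connection_limit="parsimony95")
    (ROOT / "network.dot").write_text(popgen.network_to_dot(net) + "\n")
    n_obs = sum(1 for a in net.nodes.values() if not a["inferred"])
    n_inf = len(net.nodes) - n_obs
    print(
        f"haplotype network: {n_obs} observed alleles, {n_inf} inferred "
        f"connectors, {len(net.components())} component(s) at the "
        f"{net.connection_limit}-step 95% connection limit"
    )


if __name__ == "__main__":
    main()
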