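"""Synthetic-data generators reproducing the statistical structure the
analysis assumes: codon sequences evolved on a tree with branch-specific
omega (episodic bursts over a purifying background), dimorphic population
samples with two divergent allele clades tightly linked across a coding and
a 3'-noncoding block, and neutral coalescent samples for calibrating the
frequency-spectrum statistics.

All generators are pure functions of (config, seed): the same seed and
configuration give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_code import BASES, SENSE_CODONS, STANDARD_CODE, is_stop, is_transition
from .seqio import CodonAlignment, PhyloTree, PopulationSample


@dataclass
class SimulationConfig:
    """Codon evolution along a fixed tree.

    Branch lengths are expected candidate mutations per nucleotide site on
    the neutral scale; ``omega_map`` assigns a dN/dS to each branch
    (child-node id), with ``default_omega`` elsewhere. Nonsynonymous
    candidates fix with probability omega/max(1, omega) and synonymous ones
    with 1/max(1, omega), which preserves the omega ratio of fixation
    probabilities for any omega >= 0 and reduces to accepting synonymous
    changes always when omega <= 1. Changes to stop codons are rejected.
    """

    tree: PhyloTree
    n_codons: int = 300
    omega_map: dict[str, float] = field(default_factory=dict)
    default_omega: float = 0.2
    kappa: float = 2.0
    root_sequence: str | None = None
    seed: int = 0

    def omega_of(self, child_id: str) -> float:
        return self.omega_map.get(child_id, self.default_omega)


@dataclass
class CodonSimResult:
    alignment: CodonAlignment  # leaves only
    ancestral_sequences: dict[str, str]  # every node id, root included
    branch_counts: dict[str, tuple[int, int]]  # branch id -> (ns, s)
    events: dict[str, list[tuple[int, str, str, bool]]]  # (site, from, to, syn)


def _random_root(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _mutate_base(base: str, kappa: float, rng: np.random.Generator) -> str:
    others = [b for b in BASES if b != base]
    weights = np.array([kappa if is_transition(base, b) else 1.0 for b in others])
    return others[rng.choice(3, p=weights / weights.sum())]


def simulate_codon_tree(config: SimulationConfig) -> CodonSimResult:
    """Gillespie-style codon evolution along each branch of the tree.

    Candidate single-base changes arrive as a Poisson process at the
    branch's neutral expectation (length x nucleotide sites), targets drawn
    with kappa-weighted probabilities; selection acts through the fixation
    probabilities described on :class:`SimulationConfig`. True substitution
    events are recorded per branch.
    """
    rng = np.random.default_rng(config.seed)
    L = 3 * config.n_codons
    root = config.root_sequence or _random_root(config.n_codons, rng)
    if len(root) != L:
        raise ValueError("root sequence length does not match n_codons")
    for i in range(0, L, 3):
        if is_stop(root[i : i + 3]):
            raise ValueError("root sequence contains a stop codon")

    tree = config.tree
    sequences: dict[str, str] = {}
    branch_counts: dict[str, tuple[int, int]] = {}
    events: dict[str, list[tuple[int, str, str, bool]]] = {}

    for node in tree.preorder():
        node_id = PhyloTree.node_id(node)
        if node.parent_node is None:
            sequences[node_id] = root
            continue
        parent_id = PhyloTree.node_id(node.parent_node)
        branch_id = f"{parent_id}->{node_id}"
        omega = config.omega_of(node_id)
        seq = list(sequences[parent_id])
        ns = s = 0
        ev: list[tuple[int, str, str, bool]] = []
        n_candidates = rng.poisson(node.edge.length * L)
        p_nonsyn = omega / max(1.0, omega)
        p_syn = 1.0 / max(1.0, omega)
        for _ in range(n_candidates):
            site = int(rng.integers(0, L))
            old = seq[site]
            new = _mutate_base(old, config.kappa, rng)
            codon_start = 3 * (site // 3)
            codon = seq[codon_start : codon_start + 3]
            mutant = codon.copy()
            mutant[site - codon_start] = new
            if is_stop("".join(mutant)):
                continue
            synonymous = STANDARD_CODE["".join(codon)] == STANDARD_CODE["".join(mutant)]
            accept_p = p_syn if synonymous else p_nonsyn
            if rng.random() >= accept_p:
                continue
            seq[site] = new
            ev.append((site, old, new, synonymous))
            if synonymous:
                s += 1
            else:
                ns += 1
        sequences[node_id] = "".join(seq)
        branch_counts[branch_id] = (ns, s)
        events[branch_id] = ev

    leaf_labels = tree.leaf_labels
    alignment = CodonAlignment(
        taxa=leaf_labels, sequences=[sequences[t] for t in leaf_labels], frame_offset=0
    )
    return CodonSimResult(alignment, sequences, branch_counts, events)


# ---------------------------------------------------------------------------
# dimorphic population sample


@dataclass
class PopulationSimConfig:
    """Two divergent allele clades segregating in one population.

    Defaults mirror a receptor-locus sample: 16 diploid individuals, a
    900-bp coding block tightly linked to a 600-bp 3'-noncoding block, deep
    fixed divergence between the clade cores in both blocks, sparse private
    mutations within clades, rare inter-block recombination, and
    Hardy–Weinberg pairing of haplotypes into individuals.
    """

    n_individuals: int = 16
    coding_length: int = 900
    flank3_length: int = 600
    divergence_coding: int = 10
    divergence_flank: int = 8
    clade_frequency: float = 0.5
    within_clade_mutations: float = 0.5  # Poisson mean per haplotype
    recombination_prob: float = 0.0
    seed: int = 0


@dataclass
class DimorphicSample:
    sample: PopulationSample
    true_clades: list[str]  # per haplotype, clade of the *coding* block
    true_flank_clades: list[str]
    diagnostic_sites: list[tuple[int, str, str]]  # coding-block diagnostics


def simulate_dimorphic_population(config: PopulationSimConfig) -> DimorphicSample:
    """Draw 2n phased haplotypes from a deeply dimorphic locus.

    Two core haplotypes separated by the configured fixed differences in
    the coding and 3' blocks; haplotypes drawn at the clade frequency,
    recombined between blocks with the configured probability, sprinkled
    with private mutations, and paired into individuals under
    Hardy–Weinberg proportions (sequential random pairing).
    """
    if not 0.0 <= config.clade_frequency <= 1.0:
        raise ValueError("clade frequency must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    L = config.coding_length + config.flank3_length
    core_I = "".join(BASES[i] for i in rng.integers(0, 4, size=L))

    def mutate_at(seq: str, sites: np.ndarray) -> str:
        s = list(seq)
        for site in sites:
            s[site] = _mutate_base(s[site], 1.0, rng)
        return "".join(s)

    coding_sites = rng.choice(config.coding_length, size=config.divergence_coding, replace=False)
    flank_sites = config.coding_length + rng.choice(
        config.flank3_length, size=config.divergence_flank, replace=False
    )
    core_II = mutate_at(core_I, np.concatenate([coding_sites, flank_sites]))

    diagnostic = sorted(
        (int(site), core_I[site], core_II[site]) for site in coding_sites
    )

    n_hap = 2 * config.n_individuals
    is_II = rng.random(n_hap) < config.clade_frequency
    recomb = rng.random(n_hap) < config.recombination_prob
    cut = config.coding_length

    seqs, coding_clades, flank_clades = [], [], []
    for i in range(n_hap):
        coding_core = core_II if is_II[i] else core_I
        flank_from_II = bool(is_II[i]) ^ bool(recomb[i])
        flank_core = core_II if flank_from_II else core_I
        hap = coding_core[:cut] + flank_core[cut:]
        n_private = rng.poisson(config.within_clade_mutations)
        if n_private:
            sites = rng.choice(L, size=min(n_private, L), replace=False)
            hap = mutate_at(hap, sites)
        seqs.append(hap)
        coding_clades.append("II" if is_II[i] else "I")
        flank_clades.append("II" if flank_from_II else "I")

    taxa = [f"ind{i // 2 + 1}_h{i % 2 + 1}" for i in range(n_hap)]
    alignment = CodonAlignment(taxa=taxa, sequences=seqs, frame_offset=0)
    sample = PopulationSample(
        alignment=alignment,
        individuals=[f"ind{i // 2 + 1}" for i in range(n_hap)],
        phases=[i % 2 + 1 for i in range(n_hap)],
        sequence_ids=taxa,
        populations=["sim"] * n_hap,
        region_map={"coding": (0, cut), "flank3": (cut, L)},
    )
    return DimorphicSample(sample, coding_clades, flank_clades, diagnostic)


# ---------------------------------------------------------------------------
# neutral coalescent


def simulate_neutral_sample(
    n: int, theta: float, length: int, seed: int = 0
) -> list[str]:
    """Standard neutral coalescent sample of n haplotypes.

    Exponential coalescence times (rate k(k-1)/2 in units of 2N
    generations), Poisson mutations at rate theta/2 per lineage per unit
    time, infinite-sites placement onto distinct positions of a length-L
    background sequence. E[pairwise differences] = theta and
    E[S] = theta * sum(1/i).
    """
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    rng = np.random.default_rng(seed)

    # genealogy bookkeeping: leaf indices carried below each node
    active = list(range(n))
    branch_of: dict[int, float] = {i: 0.0 for i in range(n)}
    nodes_members: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    while len(active) > 1:
        k = len(active)
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        for a in active:
            branch_of[a] += t
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        nodes_members[next_id] = nodes_members[a] + nodes_members[b]
        branch_of[next_id] = 0.0
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = active[0]

    # mutations: Poisson(theta/2 * branch length) per branch, distinct sites
    background = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    haplotypes = [list(background) for _ in range(n)]
    carriers_per_branch = [
        (node, branch_of[node]) for node in branch_of if node != root
    ]
    total_mut = 0
    site_pool = rng.permutation(length)
    for node, blen in carriers_per_branch:
        n_mut = rng.poisson(theta / 2.0 * blen)
        for _ in range(n_mut):
            if total_mut >= length:
                raise ValueError(
                    "infinite-sites violation: more mutations than sites; "
                    "increase length"
                )
            site = int(site_pool[total_mut])
            total_mut += 1
            derived = _mutate_base(background[site], 1.0, rng)
            for leaf in nodes_members[node]:
                haplotypes[leaf][site] = derived
    return ["".join(h) for h in haplotypes]
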