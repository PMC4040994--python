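"""Intrapopulation statistics over phased haplotypes: nucleotide diversity,
Tajima's D (global and sliding-window), linkage disequilibrium D', exact
Hardy–Weinberg tests, allele-clade assignment, and minimum-spanning
haplotype networks with inferred intermediates.

Gap handling is complete deletion within the analysed region (columns
containing any gap/N are dropped before counting), with the removed column
count logged. Tajima's D is undefined (not 0) when there are no segregating
sites.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, fisher_exact

logger = logging.getLogger(__name__)

_CLEAN = set("ACGT")


@dataclass
class DiversityStats:
    n: int
    S: int
    k_hat: float
    pi: float
    tajima_D: float | None
    counted_length: int


@dataclass
class WindowStats:
    start: int
    end: int
    stats: DiversityStats
    defined: bool


@dataclass
class LDResult:
    locus_a: str
    locus_b: str
    D: float
    D_prime: float
    p_two_tailed: float
    counts: tuple[int, int, int, int]  # AB, Ab, aB, ab


@dataclass
class CladeAssignment:
    labels: list[str]  # "I" | "II" | "unassigned"
    diagnostic_sites: list[tuple[int, str, str]]


@dataclass
class HaplotypeNetwork:
    """Observed alleles plus inferred single-step connectors.

    node ids: observed allele identifiers, or ``h1, h2, ...`` for inferred
    intermediates. Every edge spans exactly one mutational step.
    """

    nodes: dict[str, dict] = field(default_factory=dict)  # id -> {sequence, freq, inferred}
    edges: list[tuple[str, str]] = field(default_factory=list)
    connection_limit: int = 0

    def degree(self, node: str) -> int:
        return sum(1 for u, v in self.edges if node in (u, v))

    def components(self) -> list[set[str]]:
        parent = {n: n for n in self.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in self.edges:
            parent[find(u)] = find(v)
        comps: dict[str, set[str]] = {}
        for n in self.nodes:
            comps.setdefault(find(n), set()).add(n)
        return list(comps.values())


# ---------------------------------------------------------------------------
# diversity and Tajima's D


def complete_deletion(haplotypes: list[str]) -> tuple[list[str], int]:
    """Drop columns containing any gap/ambiguity; return cleaned rows and
    the number of removed columns."""
    if not haplotypes:
        return [], 0
    cols = [
        i
        for i in range(len(haplotypes[0]))
        if all(h[i] in _CLEAN for h in haplotypes)
    ]
    removed = len(haplotypes[0]) - len(cols)
    if removed:
        logger.info("complete deletion removed %d columns", removed)
    return ["".join(h[i] for i in cols) for h in haplotypes], removed


def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1,a2,b1,b2,c1,c2,e1,e2 constants for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def diversity(haplotypes: list[str], region: tuple[int, int] | None = None) -> DiversityStats:
    """Mean pairwise differences, per-site pi, segregating sites and
    Tajima's D for a haplotype sample (complete deletion of gap/N columns)."""
    n = len(haplotypes)
    if n < 2:
        raise ValueError("diversity needs at least 2 haplotypes")
    if region is not None:
        start, end = region
        haplotypes = [h[start:end] for h in haplotypes]
    clean, _removed = complete_deletion(haplotypes)
    L = len(clean[0]) if clean else 0

    arr = np.frombuffer("".join(clean).encode(), dtype="S1").reshape(n, L) if L else np.empty((n, 0), dtype="S1")
    S = 0
    k_sum = 0
    for j in range(L):
        col = arr[:, j]
        counts = Counter(col.tobytes().decode())
        if len(counts) > 1:
            S += 1
            # pairwise differences contributed by this column
            same = sum(c * (c - 1) // 2 for c in counts.values())
            k_sum += n * (n - 1) // 2 - same
    pairs = n * (n - 1) / 2
    k_hat = k_sum / pairs
    pi = k_hat / L if L else 0.0

    if S == 0:
        D = None
    else:
        c = tajima_constants(n)
        var = c["e1"] * S + c["e2"] * S * (S - 1)
        D = (k_hat - S / c["a1"]) / math.sqrt(var) if var > 0 else None
    return DiversityStats(n=n, S=S, k_hat=k_hat, pi=pi, tajima_D=D, counted_length=L)


def sliding_windows(
    haplotypes: list[str], window: int = 100, step: int = 25
) -> list[WindowStats]:
    """Tile the alignment with fixed-step windows and compute per-window
    diversity; windows keeping < 3 sites after deletion are flagged
    undefined."""
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    L = len(haplotypes[0])
    if window > L:
        logger.warning("window %d exceeds alignment length %d; using one window", window, L)
        window = L
    out = []
    start = 0
    while start < L:
        end = min(start + window, L)
        stats = diversity(haplotypes, region=(start, end))
        out.append(WindowStats(start, end, stats, defined=stats.counted_length >= 3))
        if end == L:
            break
        start += step
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_from_counts(n_AB: int, n_Ab: int, n_aB: int, n_ab: int,
                   locus_a: str = "A", locus_b: str = "B") -> LDResult:
    """Lewontin's D and D' plus a two-tailed Fisher exact p from the four
    haplotype counts."""
    n = n_AB + n_Ab + n_aB + n_ab
    if n == 0:
        raise ValueError("empty haplotype table")
    pA = (n_AB + n_Ab) / n
    pB = (n_AB + n_aB) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus: D' undefined")
    D = n_AB / n - pA * pB
    if D > 0:
        Dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        Dmax = min(pA * pB, (1 - pA) * (1 - pB))
    Dp = abs(D) / Dmax if Dmax > 0 else 0.0
    _odds, p = fisher_exact([[n_AB, n_Ab], [n_aB, n_ab]], alternative="two-sided")
    return LDResult(locus_a, locus_b, D, Dp, float(p), (n_AB, n_Ab, n_aB, n_ab))


def ld_two_loci(labels_a: list[str], labels_b: list[str],
                locus_a: str = "A", locus_b: str = "B") -> LDResult:
    """D/D' between two biallelic loci given per-haplotype allele labels.

    A locus may be a nucleotide site (labels = bases) or a region-dimorphism
    locus (labels = clade assignments of the region's sub-haplotype). The
    reference allele at each locus is the most frequent (lexicographic on
    ties), so D's sign is the association between the two majority alleles.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label lists differ in length")
    pairs = [(a, b) for a, b in zip(labels_a, labels_b)]

    def major(labels):
        counts = Counter(labels)
        if len(counts) != 2:
            raise ValueError(f"locus not biallelic: alleles {sorted(counts)}")
        return sorted(counts, key=lambda a: (-counts[a], a))

    A, a = major([p[0] for p in pairs])
    B, b = major([p[1] for p in pairs])
    c = Counter(pairs)
    return ld_from_counts(c[(A, B)], c[(A, b)], c[(a, B)], c[(a, b)], locus_a, locus_b)


# ---------------------------------------------------------------------------
# Hardy–Weinberg


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "exact") -> float:
    """Hardy–Weinberg test from genotype counts.

    Default is the exact conditional test: enumerate every heterozygote
    count compatible with the observed allele counts and sum the
    probabilities of configurations no more probable than the observed one.
    ``method="chi2"`` gives the 1-df chi-square approximation.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype counts")
    N = n_AA + n_Aa + n_aa
    if N < 1:
        raise ValueError("empty sample")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0

    if method == "chi2":
        p = nA / (2 * N)
        exp = [N * p * p, 2 * N * p * (1 - p), N * (1 - p) * (1 - p)]
        stat = sum(
            (o - e) ** 2 / e for o, e in zip((n_AA, n_Aa, n_aa), exp) if e > 0
        )
        return float(chi2.sf(stat, df=1))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    def log_prob(het: int) -> float:
        hom_A = (nA - het) // 2
        hom_a = (na - het) // 2
        return (
            math.lgamma(N + 1)
            - math.lgamma(hom_A + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_a + 1)
            + het * math.log(2.0)
            + math.lgamma(nA + 1)
            + math.lgamma(na + 1)
            - math.lgamma(2 * N + 1)
        )

    hets = range(nA % 2, min(nA, na) + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    obs = logs[n_Aa]
    total = sum(math.exp(lp) for lp in logs.values())
    p_val = sum(math.exp(lp) for lp in logs.values() if lp <= obs + 1e-12) / total
    return min(1.0, p_val)


# ---------------------------------------------------------------------------
# clade assignment


def assign_clades(
    haplotypes: list[str],
    diagnostic_sites: list[tuple[int, str, str]],
    threshold: float = 0.9,
) -> CladeAssignment:
    """Label each haplotype clade I or II by its states at diagnostic sites.

    A haplotype is labelled I (II) when at least ``threshold`` of the
    diagnostic sites carry the clade-I (clade-II) state; mixtures are
    flagged ``unassigned`` (candidate recombinants).
    """
    if not diagnostic_sites:
        raise ValueError("empty diagnostic site set")
    labels = []
    for h in haplotypes:
        match_I = sum(1 for site, sI, _ in diagnostic_sites if h[site] == sI)
        match_II = sum(1 for site, _, sII in diagnostic_sites if h[site] == sII)
        m = len(diagnostic_sites)
        if match_I / m >= threshold:
            labels.append("I")
        elif match_II / m >= threshold:
            labels.append("II")
        else:
            labels.append("unassigned")
    return CladeAssignment(labels=labels, diagnostic_sites=list(diagnostic_sites))


# ---------------------------------------------------------------------------
# haplotype network


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def parsimony95_limit(length: int) -> int:
    """Approximate 95% statistical-parsimony connection limit.

    Uses the birthday-problem approximation for the probability that m
    observed differences arose without superimposed change at any site,
    exp(-m(m-1)/(2L)) >= 0.95; the limit is the largest such m. A
    documented simplification of the full pinned-haplotype machinery.
    """
    m = 1
    while math.exp(-m * (m + 1) / (2.0 * length)) >= 0.95:
        m += 1
    return m


def build_network(
    alleles: dict[str, str],
    frequencies: dict[str, int] | None = None,
    connection_limit: int | str = "parsimony95",
) -> HaplotypeNetwork:
    """Minimum-spanning haplotype network with single-step edges.

    Edges are added in increasing Hamming distance; within one distance
    class every edge joining components that were distinct *before* the
    class is kept, so equal-length alternatives survive as reticulations.
    Multi-step edges are expanded with inferred intermediate haplotypes
    (sites mutated in increasing coordinate order). Pairs beyond the
    connection limit stay in separate components.
    """
    if len(alleles) < 2:
        raise ValueError("need at least 2 distinct alleles")
    ids = list(alleles)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate allele identifiers")
    freqs = frequencies or {i: 1 for i in ids}
    seqs = alleles
    limit = (
        parsimony95_limit(len(next(iter(seqs.values()))))
        if connection_limit == "parsimony95"
        else int(connection_limit)
    )

    net = HaplotypeNetwork(connection_limit=limit)
    for i in ids:
        net.nodes[i] = {"sequence": seqs[i], "freq": freqs.get(i, 1), "inferred": False}

    dists = sorted(
        (( _hamming(seqs[u], seqs[v]), u, v) for u, v in itertools.combinations(ids, 2)),
        key=lambda t: (t[0], t[1], t[2]),
    )

    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    inferred_count = 0
    for d, group in itertools.groupby(dists, key=lambda t: t[0]):
        if d == 0 or d > limit:
            continue
        group = list(group)
        # connectivity frozen at the start of the distance class: ties kept
        comp_before = {i: find(i) for i in ids}
        added = []
        for _, u, v in group:
            if comp_before[u] != comp_before[v]:
                added.append((u, v))
        for u, v in added:
            if d == 1:
                net.edges.append((u, v))
            else:
                prev = u
                current = seqs[u]
                target = seqs[v]
                diff_sites = [i for i in range(len(current)) if current[i] != target[i]]
                for site in diff_sites[:-1]:
                    current = current[:site] + target[site] + current[site + 1 :]
                    inferred_count += 1
                    hid = f"h{inferred_count}"
                    net.nodes[hid] = {"sequence": current, "freq": 0, "inferred": True}
                    net.edges.append((prev, hid))
                    prev = hid
                net.edges.append((prev, v))
            parent[find(u)] = find(v)
    return net


def network_to_dot(net: HaplotypeNetwork) -> str:
    """GraphViz DOT export; observed alleles sized by frequency."""
    lines = ["graph haplotypes {"]
    for nid, attrs in net.nodes.items():
        if attrs["inferred"]:
            lines.append(f'  "{nid}" [shape=point, label=""];')
        else:
            lines.append(f'  "{nid}" [label="{nid} ({attrs["freq"]})"];')
    for u, v in net.edges:
        lines.append(f'  "{u}" -- "{v}";')
    lines.append("}")
    return "\n".join(lines)
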