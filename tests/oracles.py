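"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: everything is direct
enumeration over the standard genetic code or closed-form combinatorics.
"""

from __future__ import annotations

import itertools
import math

BASES = "ACGT"
_AA_TABLE = {}
_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
_AAS = (
    "KNKNTTTTRSRSIIMI"
    "QHQHPPPPRRRRLLLL"
    "EDEDAAAAGGGGVVVV"
    "*Y*YSSSS*CWCLFLF"
)
for _c, _a in zip(_CODONS, _AAS):
    _AA_TABLE[_c] = _a


def oracle_translate(codon: str) -> str:
    return _AA_TABLE[codon]


def oracle_potential_sites(codon: str) -> tuple[float, float]:
    """Enumerate all 9 single-base mutants; renormalize per position over
    non-stop changes."""
    s_total = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _AA_TABLE[mut] == "*":
                continue
            valid += 1
            if _AA_TABLE[mut] == _AA_TABLE[codon]:
                syn += 1
        if valid:
            s_total += syn / valid
    return s_total, 3.0 - s_total


def oracle_pathway_differences(a: str, b: str) -> tuple[float, float]:
    """Average syn/nonsyn step counts over all stop-free orderings of the
    differing positions; per-position fallback when none is stop-free."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, syn, non, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _AA_TABLE[nxt] == "*":
                ok = False
                break
            if _AA_TABLE[nxt] == _AA_TABLE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            paths.append((syn, non))
    if paths:
        return (
            sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths),
        )
    syn = non = 0
    for pos in diff:
        mut = a[:pos] + b[pos] + a[pos + 1 :]
        if _AA_TABLE[mut] != "*" and _AA_TABLE[mut] == _AA_TABLE[a]:
            syn += 1
        else:
            non += 1
    return float(syn), float(non)


def oracle_fisher_tail(ns: int, s: int, N: int, S: int) -> float:
    """One-tailed Fisher p by explicit summation over all more-extreme
    tables at fixed margins, with exact rational combinatorics."""
    k = ns + s
    denom = math.comb(N + S, k)
    total = 0
    for x in range(ns, min(N, k) + 1):
        if k - x <= S:
            total += math.comb(N, x) * math.comb(S, k - x)
    return total / denom


def oracle_hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by full enumeration of heterozygote counts with exact
    rational probabilities (conditioned on allele counts)."""
    N = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0

    def weight(het: int):
        homA = (nA - het) // 2
        homa = (na - het) // 2
        return (
            math.factorial(N)
            * 2**het
            // (math.factorial(homA) * math.factorial(het) * math.factorial(homa))
        )

    hets = list(range(nA % 2, min(nA, na) + 1, 2))
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= obs) / total


def parsimony_length(leaf_seqs: dict[str, str], children: dict[str, list[str]], root: str) -> int:
    """Exact minimum number of state changes (small parsimony, unit costs)
    of an alignment on a rooted tree, by Sankoff dynamic programming.

    children maps internal node id -> child ids; leaves appear only as
    keys of leaf_seqs.
    """
    INF = float("inf")
    L = len(next(iter(leaf_seqs.values())))
    states = sorted({c for s in leaf_seqs.values() for c in s})
    total = 0
    for site in range(L):

        def cost(node) -> dict[str, float]:
            if node in leaf_seqs:
                obs = leaf_seqs[node][site]
                return {s: (0 if s == obs else INF) for s in states}
            kid_costs = [cost(k) for k in children[node]]
            out = {}
            for s in states:
                c = 0.0
                for kc in kid_costs:
                    c += min(kc[t] + (0 if t == s else 1) for t in states)
                out[s] = c
            return out

        total += int(min(cost(root).values()))
    return total
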