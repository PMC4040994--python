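"""Per-branch test of episodic positive selection: excess of nonsynonymous
over synonymous substitutions against the potential-site background, with a
one-tailed small-sample Fisher exact probability.

The 2x2 table tested is ``[[ns, s], [N_sites - ns, S_sites - s]]`` where the
fractional site totals are rounded to the nearest integer (Fisher's test
requires integers; the table actually tested is always carried in the
result) and fractional pathway-averaged substitution counts are rounded
half-up. The tail is one-sided toward nonsynonymous excess, matching the
question of whether dN/dS exceeds 1. No multiple-testing correction is
applied by default (per-branch p-values are reported raw); Bonferroni and
Benjamini–Hochberg are available as options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from . import ancestral, codon_model
from .codon_model import DnDsEstimate, SiteCounts
from .seqio import CodonAlignment, PhyloTree


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class BranchSelectionResult:
    """One row of the per-branch selection report."""

    branch: str
    ns: int
    s: int
    N_sites: float
    S_sites: float
    dN: float
    dS: float
    omega: float
    omega_defined: bool
    p_one_tailed: float
    significant: bool
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_positive_selection(ns: int, s: int, N_sites: float, S_sites: float) -> float:
    """One-tailed Fisher exact probability of at least this nonsynonymous
    excess, by hypergeometric tail summation.

    The table is [[ns, s], [round(N)-ns, round(S)-s]]; the tail collects
    tables at least as extreme toward nonsynonymous excess (ns larger at
    fixed margins).
    """
    if ns < 0 or s < 0:
        raise ValueError("counts must be non-negative")
    if N_sites <= 0 or S_sites <= 0:
        raise ValueError("site totals must be positive")
    N = _round_half_up(N_sites)
    S = _round_half_up(S_sites)
    if ns > N or s > S:
        raise ValueError(f"counts exceed site totals: ns={ns}>{N} or s={s}>{S}")
    if ns + s < 1:
        return 1.0
    # X ~ Hypergeom(population N+S, successes N, draws ns+s); tail P(X >= ns)
    return float(hypergeom.sf(ns - 1, N + S, N, ns + s))


def branch_dnds(ns: float, s: float, N_sites: float, S_sites: float) -> DnDsEstimate:
    """Branch dN/dS from substitution counts and potential-site totals.

    When s = 0 with ns > 0, omega is the +inf sentinel with dS = 0 (the
    report rows where no synonymous change anchors the denominator).
    """
    if N_sites <= 0 or S_sites <= 0:
        raise ValueError("site totals must be positive")
    pN = ns / N_sites
    pS = s / S_sites
    dN = codon_model.jukes_cantor_correct(pN)
    dS = codon_model.jukes_cantor_correct(pS)
    if dS > 0:
        return DnDsEstimate(pN, pS, dN, dS, dN / dS, True)
    if dN > 0:
        return DnDsEstimate(pN, pS, dN, dS, math.inf, True)
    return DnDsEstimate(pN, pS, dN, dS, math.nan, False)


def sequence_site_counts(seq: str, frame_offset: int = 0, kappa: float = 1.0) -> SiteCounts:
    """Potential-site totals of one sequence, skipping uncountable codons."""
    total = SiteCounts(0.0, 0.0)
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon_model.codon_is_countable(codon):
            total = total + codon_model.weighted_sites(codon, kappa)
    return total


def _adjust(pvals: list[float], method: str | None) -> list[float]:
    m = len(pvals)
    if method is None or m == 0:
        return pvals
    if method == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    if method == "bh":
        order = sorted(range(m), key=lambda i: pvals[i])
        adj = [0.0] * m
        prev = 1.0
        for rank_from_end, idx in enumerate(reversed(order)):
            rank = m - rank_from_end
            prev = min(prev, pvals[idx] * m / rank)
            adj[idx] = prev
        return adj
    raise ValueError(f"unknown correction {method!r}")


def scan_branches(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model: str = "JC",
    kappa_sites: float = 1.0,
    alpha: float = 0.05,
    branches: list[str] | None = None,
    correction: str | None = None,
) -> list[BranchSelectionResult]:
    """Run the full per-branch test: ancestral reconstruction, substitution
    mapping, site counting, Fisher exact test; results sorted by p.

    Site totals for a branch are the average of the parent- and child-node
    sequence totals (symmetric, standard). ``branches`` restricts the scan
    to named ``parent->child`` ids. ``kappa_sites`` optionally weights
    transitions in the site counting (1 = unweighted default).
    """
    recon = ancestral.reconstruct_marginal(alignment, tree, model=model)
    subs = ancestral.map_branch_substitutions(recon, tree, alignment.frame_offset)
    site_cache: dict[str, SiteCounts] = {}

    def sites_of(node_id: str) -> SiteCounts:
        if node_id not in site_cache:
            site_cache[node_id] = sequence_site_counts(
                recon.sequences[node_id], alignment.frame_offset, kappa_sites
            )
        return site_cache[node_id]

    results = []
    for bs in subs:
        if branches is not None and bs.branch_id not in branches:
            continue
        sp = sites_of(bs.parent)
        sc = sites_of(bs.child)
        N = (sp.N_sites + sc.N_sites) / 2.0
        S = (sp.S_sites + sc.S_sites) / 2.0
        ns_i = _round_half_up(bs.ns)
        s_i = _round_half_up(bs.s)
        if N <= 0 or S <= 0:
            continue
        p = fisher_positive_selection(ns_i, s_i, N, S)
        est = branch_dnds(bs.ns, bs.s, N, S)
        Ni, Si = _round_half_up(N), _round_half_up(S)
        results.append(
            BranchSelectionResult(
                branch=bs.branch_id,
                ns=ns_i,
                s=s_i,
                N_sites=N,
                S_sites=S,
                dN=est.dN,
                dS=est.dS,
                omega=est.omega,
                omega_defined=est.omega_defined,
                p_one_tailed=p,
                significant=False,
                table=((ns_i, s_i), (Ni - ns_i, Si - s_i)),
            )
        )
    adjusted = _adjust([r.p_one_tailed for r in results], correction)
    for r, p_adj in zip(results, adjusted):
        r.significant = p_adj < alpha
    results.sort(key=lambda r: (r.p_one_tailed, r.branch))
    return results


def results_table(results: list[BranchSelectionResult]) -> pd.DataFrame:
    """Report mirroring the per-branch selection table: branch, ns, s, p,
    omega, significance stars, and the exact 2x2 table tested."""

    def stars(p: float) -> str:
        return "**" if p < 0.01 else "*" if p < 0.05 else ""

    return pd.DataFrame(
        {
            "branch": [r.branch for r in results],
            "ns": [r.ns for r in results],
            "s": [r.s for r in results],
            "N_sites": [round(r.N_sites, 2) for r in results],
            "S_sites": [round(r.S_sites, 2) for r in results],
            "omega": [
                (round(r.omega, 4) if math.isfinite(r.omega) else ("inf" if r.omega_defined else "NA"))
                for r in results
            ],
            "p_one_tailed": [r.p_one_tailed for r in results],
            "significance": [stars(r.p_one_tailed) for r in results],
            "table_tested": [str(r.table) for r in results],
        }
    )
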