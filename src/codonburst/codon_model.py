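"""Nei–Gojobori codon counting: potential synonymous/nonsynonymous sites,
pathway-averaged substitution counting, and corrected dN/dS.

Fractional sites are kept as reals throughout; any rounding to integers
happens only where a discrete test requires it (see :mod:`episodic_test`).
Changes that would create a stop codon are excluded and the per-position
synonymous fraction is renormalized over the remaining valid changes,
matching the convention of the distance-based tool family this module
re-implements. Gap handling is pairwise complete deletion at codon
granularity: deterministic and symmetric.
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
from dataclasses import dataclass

from .genetic_code import BASES, STANDARD_CODE, is_stop, is_transition

logger = logging.getLogger(__name__)

_VALID = set(BASES)


class StopCodonError(ValueError):
    """A stop codon where a sense codon is required."""


class SaturationError(ValueError):
    """Proportion of differences >= 3/4: the distance correction is undefined."""


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous (S) and nonsynonymous (N) site totals."""

    S_sites: float
    N_sites: float

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.S_sites + other.S_sites, self.N_sites + other.N_sites)


@dataclass(frozen=True)
class DiffCounts:
    """Fractional synonymous (Sd) and nonsynonymous (Nd) differences."""

    Sd: float
    Nd: float

    def __add__(self, other: "DiffCounts") -> "DiffCounts":
        return DiffCounts(self.Sd + other.Sd, self.Nd + other.Nd)


@dataclass(frozen=True)
class DnDsEstimate:
    """Proportions (pN, pS), corrected distances (dN, dS) and omega.

    ``omega`` is ``math.inf`` when dN > 0 with dS = 0 and ``math.nan``
    (flagged ``omega_defined = False``) when both distances are zero.
    """

    pN: float
    pS: float
    dN: float
    dS: float
    omega: float
    omega_defined: bool


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= _VALID:
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if is_stop(codon):
        raise StopCodonError(f"stop codon {codon} has no defined site counts")
    return codon


def codon_is_countable(codon: str) -> bool:
    """True when the codon is an unambiguous sense codon (no gap/N/stop)."""
    codon = codon.upper()
    return len(codon) == 3 and set(codon) <= _VALID and not is_stop(codon)


def potential_sites(codon: str) -> SiteCounts:
    """Fractional synonymous/nonsynonymous site counts of a sense codon.

    Each of the three positions contributes one site, split by the fraction
    of its single-base changes that are synonymous, after excluding (and
    renormalizing over) changes that would create a stop codon.
    """
    return weighted_sites(codon, kappa=1.0)


@functools.lru_cache(maxsize=65536)
def weighted_sites(codon: str, kappa: float = 1.0) -> SiteCounts:
    """Site counts with transitions weighted ``kappa`` : 1 over transversions.

    ``kappa = 1`` reduces exactly to the unweighted Nei–Gojobori counting.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    codon = _check_codon(codon)
    aa = STANDARD_CODE[codon]
    s_total = 0.0
    for pos in range(3):
        w_valid = 0.0
        w_syn = 0.0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            w = kappa if is_transition(codon[pos], base) else 1.0
            w_valid += w
            if STANDARD_CODE[mutant] == aa:
                w_syn += w
        if w_valid > 0:
            s_total += w_syn / w_valid
        # all three changes hit stops cannot occur under the standard code
    return SiteCounts(S_sites=s_total, N_sites=3.0 - s_total)


@functools.lru_cache(maxsize=65536)
def pathway_differences(codon_a: str, codon_b: str) -> DiffCounts:
    """Synonymous/nonsynonymous differences between two sense codons,
    averaged over all orderings of the differing positions.

    Pathways passing through a stop codon are excluded from the average;
    if every pathway does, falls back to classifying each differing
    position independently (with a logged warning).
    """
    codon_a = _check_codon(codon_a)
    codon_b = _check_codon(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return DiffCounts(0.0, 0.0)

    pathways: list[tuple[int, int]] = []  # (syn, nonsyn) per valid pathway
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if STANDARD_CODE[nxt] == STANDARD_CODE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            pathways.append((syn, nonsyn))

    if pathways:
        n = len(pathways)
        return DiffCounts(
            Sd=sum(p[0] for p in pathways) / n,
            Nd=sum(p[1] for p in pathways) / n,
        )

    logger.warning(
        "all mutational pathways %s->%s pass through stop codons; "
        "falling back to per-position classification",
        codon_a,
        codon_b,
    )
    syn = nonsyn = 0
    for pos in diff_pos:
        mutant = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1 :]
        if not is_stop(mutant) and STANDARD_CODE[mutant] == STANDARD_CODE[codon_a]:
            syn += 1
        else:
            nonsyn += 1
    return DiffCounts(Sd=float(syn), Nd=float(nonsyn))


def jukes_cantor_correct(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"p = {p} >= 3/4: corrected distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _iter_codon_pairs(seq_a: str, seq_b: str):
    for i in range(0, len(seq_a), 3):
        yield seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()


def nei_gojobori(seq_a: str, seq_b: str, kappa: float = 1.0) -> DnDsEstimate:
    """Nei–Gojobori dN/dS between two aligned in-frame sequences.

    Codons containing gaps, ambiguity codes or stops in either sequence are
    excluded pairwise. Site counts are averaged over the two sequences;
    proportions are corrected with the Jukes–Cantor-style formula.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be divisible by 3")

    sites_a = SiteCounts(0.0, 0.0)
    sites_b = SiteCounts(0.0, 0.0)
    diffs = DiffCounts(0.0, 0.0)
    skipped = 0
    for ca, cb in _iter_codon_pairs(seq_a, seq_b):
        if not (codon_is_countable(ca) and codon_is_countable(cb)):
            skipped += 1
            continue
        sites_a = sites_a + weighted_sites(ca, kappa)
        sites_b = sites_b + weighted_sites(cb, kappa)
        diffs = diffs + pathway_differences(ca, cb)
    if skipped:
        logger.info("pairwise deletion removed %d codons", skipped)

    S = (sites_a.S_sites + sites_b.S_sites) / 2.0
    N = (sites_a.N_sites + sites_b.N_sites) / 2.0
    if S <= 0 and N <= 0:
        raise ValueError("no countable codons shared by the pair")
    pS = diffs.Sd / S if S > 0 else 0.0
    pN = diffs.Nd / N if N > 0 else 0.0
    dS = jukes_cantor_correct(pS)
    dN = jukes_cantor_correct(pN)
    if dS > 0:
        return DnDsEstimate(pN, pS, dN, dS, dN / dS, True)
    if dN > 0:
        return DnDsEstimate(pN, pS, dN, dS, math.inf, True)
    return DnDsEstimate(pN, pS, dN, dS, math.nan, False)
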