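"""Silent-rate calibration and divergence-time estimation.

"Silent" divergence pools synonymous coding differences with noncoding
differences, weighted per site, since both are assumed near-neutral. A
strict clock is used; the uncertainty carried is the min/max range over the
calibration points, not a sampling CI.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import codon_model


@dataclass
class RateCalibration:
    """A calibrated silent substitution rate (subs/site/year) from a dated
    split: rate = divergence / (2 * time)."""

    name: str
    divergence: float
    split_time_years: float
    rate: float


@dataclass
class DivergenceTimeEstimate:
    divergence: float
    rate_low: float
    rate_high: float
    time_low_years: float
    time_high_years: float


def calibrate_rate(divergence: float, split_time_years: float, name: str = "") -> RateCalibration:
    """Rate from a dated split; divergence is per silent site between the
    two sides of the split."""
    if divergence <= 0 or split_time_years <= 0:
        raise ValueError("divergence and split time must be positive")
    return RateCalibration(
        name=name,
        divergence=divergence,
        split_time_years=split_time_years,
        rate=divergence / (2.0 * split_time_years),
    )


def estimate_divergence_time(
    silent_divergence: float, rate_range: tuple[float, float]
) -> DivergenceTimeEstimate:
    """Time range (years) implied by a silent divergence under the
    calibrated rate range: (d/(2*r_hi), d/(2*r_lo))."""
    r_lo, r_hi = rate_range
    if r_lo <= 0 or r_hi < r_lo:
        raise ValueError("need 0 < r_lo <= r_hi")
    if silent_divergence < 0:
        raise ValueError("divergence must be >= 0")
    return DivergenceTimeEstimate(
        divergence=silent_divergence,
        rate_low=r_lo,
        rate_high=r_hi,
        time_low_years=silent_divergence / (2.0 * r_hi),
        time_high_years=silent_divergence / (2.0 * r_lo),
    )


def silent_divergence(
    coding_a: str,
    coding_b: str,
    noncoding_a: str = "",
    noncoding_b: str = "",
) -> float:
    """Per-site silent divergence between two sequences: synonymous
    differences over synonymous sites pooled (site-weighted) with noncoding
    differences over noncoding sites."""
    syn_diffs = syn_sites = 0.0
    if coding_a:
        est = codon_model.nei_gojobori(coding_a, coding_b)
        # recover pooled numerator/denominator from proportions
        sites_a = sites_b = codon_model.SiteCounts(0.0, 0.0)
        for i in range(0, len(coding_a), 3):
            ca, cb = coding_a[i : i + 3].upper(), coding_b[i : i + 3].upper()
            if codon_model.codon_is_countable(ca) and codon_model.codon_is_countable(cb):
                sites_a = sites_a + codon_model.potential_sites(ca)
                sites_b = sites_b + codon_model.potential_sites(cb)
        syn_sites = (sites_a.S_sites + sites_b.S_sites) / 2.0
        syn_diffs = est.pS * syn_sites

    nc_diffs = nc_sites = 0.0
    for x, y in zip(noncoding_a.upper(), noncoding_b.upper()):
        if x in "ACGT" and y in "ACGT":
            nc_sites += 1
            if x != y:
                nc_diffs += 1

    total_sites = syn_sites + nc_sites
    if total_sites <= 0:
        raise ValueError("no silent sites to compare")
    return (syn_diffs + nc_diffs) / total_sites
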