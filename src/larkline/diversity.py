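"""Diversity statistics from the SFS, plus scalar population calculators.

π and Watterson's θ are computed per site from a spectrum that includes
the invariant (zero) class, so both are directly comparable across
datasets. The calculators cover the standard conversions used when
interpreting diversity in a conservation context: Θ = 4Ne·μ effective
size, drift retention of heterozygosity, divergence-to-coalescence time,
generation time from life-history rates, and island-area extrapolation of
an ancestral census size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sfs import SiteFrequencySpectrum


@dataclass
class ScalingConfig:
    """Mutation rate and generation time used for all natural-unit conversions.

    Defaults are a passerine (collared flycatcher) per-generation mutation
    rate and the study species' generation time from age at first breeding
    plus inverse mean annual mortality.
    """

    mu: float = 4.6e-9  # per site per generation
    generation_time_years: float = 6.5

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.generation_time_years <= 0:
            raise ValueError("mu and generation time must be > 0")


@dataclass
class DiversityStats:
    pi: float
    theta_w: float
    tajimas_d: float
    S: float
    L: float


def _class_weights(sfs: SiteFrequencySpectrum) -> np.ndarray:
    """Per-class pairwise-difference weight 2 i (n - i) / (n (n - 1)).

    Works identically on folded and unfolded spectra because the weight of
    class i equals that of class n - i.
    """
    n = sfs.n_haploid
    i = np.arange(len(sfs.counts))
    return 2.0 * i * (n - i) / (n * (n - 1.0))


def pi_from_sfs(sfs: SiteFrequencySpectrum) -> float:
    """Per-site nucleotide diversity from the spectrum.

    π = [Σ_i η_i · 2 i (n−i) / (n (n−1))] / n_sites; the invariant class
    contributes only to the denominator.
    """
    if sfs.n_sites <= 0:
        raise ValueError("empty SFS")
    if sfs.n_haploid < 2:
        raise ValueError("need n_haploid >= 2")
    return float((sfs.counts * _class_weights(sfs)).sum() / sfs.n_sites)


def watterson_theta(sfs: SiteFrequencySpectrum) -> float:
    """Watterson's estimator θ_W = S / (a_n · L), a_n = Σ_{k=1}^{n−1} 1/k."""
    if sfs.n_sites <= 0:
        raise ValueError("empty SFS")
    n = sfs.n_haploid
    a_n = np.sum(1.0 / np.arange(1, n))
    return float(sfs.n_segregating / (a_n * sfs.n_sites))


def tajimas_d(sfs: SiteFrequencySpectrum) -> float:
    """Tajima's D with the original 1989 constants.

    Negative D indicates an excess of rare variants (e.g. after expansion);
    undefined (raises) when there are no segregating sites.
    """
    n = sfs.n_haploid
    S = sfs.n_segregating
    if S <= 0:
        raise ValueError("Tajima's D undefined with no segregating sites")
    L = sfs.n_sites
    pi_total = pi_from_sfs(sfs) * L
    k = np.arange(1, n)
    a1 = np.sum(1.0 / k)
    a2 = np.sum(1.0 / k**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((pi_total - S / a1) / math.sqrt(var))


def stats_from_sfs(sfs: SiteFrequencySpectrum) -> DiversityStats:
    """Bundle π, θ_W, Tajima's D, S and L for one spectrum."""
    S = sfs.n_segregating
    d = tajimas_d(sfs) if S > 0 else float("nan")
    return DiversityStats(
        pi=pi_from_sfs(sfs),
        theta_w=watterson_theta(sfs),
        tajimas_d=d,
        S=S,
        L=sfs.n_sites,
    )


# ---------------------------------------------------------------------------
# scalar calculators
# ---------------------------------------------------------------------------

def round_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    mag = math.floor(math.log10(abs(x)))
    return round(x, -mag + sig - 1)


def ne_from_pi(pi: float, scaling: ScalingConfig = ScalingConfig()) -> float:
    """Equilibrium effective size from Θ = 4 Ne μ, i.e. Ne = π / (4 μ)."""
    if pi < 0:
        raise ValueError("pi must be >= 0")
    return pi / (4.0 * scaling.mu)


def drift_retention(ne: float, g: float) -> float:
    """Fraction of ancestral heterozygosity retained after g generations.

    Each generation a population of effective size Ne loses a fraction
    1/(2 Ne) of its heterozygosity to drift, so retention = (1 − 1/(2Ne))^g.
    """
    if ne < 1:
        raise ValueError("ne must be >= 1")
    if g < 0:
        raise ValueError("g must be >= 0")
    return (1.0 - 1.0 / (2.0 * ne)) ** g


def coalescence_generations(divergence: float, scaling: ScalingConfig = ScalingConfig()) -> float:
    """Generations to coalescence implied by per-site sequence divergence.

    Two sequences diverging at rate μ each accumulate differences at 2μ per
    generation jointly: T = d / (2 μ).
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    return divergence / (2.0 * scaling.mu)


def generation_time(age_first_breeding: float, mean_annual_mortality: float) -> float:
    """Mean parental age: age at first breeding + 1 / mean annual mortality."""
    if not (0 < mean_annual_mortality <= 1):
        raise ValueError("mortality must be in (0, 1]")
    return age_first_breeding + 1.0 / mean_annual_mortality


def years_to_generations(years: float, scaling: ScalingConfig = ScalingConfig()) -> float:
    """Convert calendar years to generations at the configured generation time."""
    return years / scaling.generation_time_years


def area_extrapolation(
    areas_km2: list[float], current_area_km2: float, current_census: float
) -> tuple[float, float, float]:
    """Extrapolate an ancestral census size from a species' former range.

    Returns (total range km² including the current area, fold expansion
    relative to the current area, predicted ancestral census rounded to two
    significant figures).
    """
    if current_area_km2 <= 0 or any(a <= 0 for a in areas_km2):
        raise ValueError("areas must be > 0")
    total = float(sum(areas_km2) + current_area_km2)
    fold = total / current_area_km2
    predicted = round_sig(current_census * fold, 2)
    return total, fold, predicted
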