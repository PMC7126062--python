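"""Pairwise relatedness screening for low-coverage genotype data.

A depth-aware moment estimator in the GRM family. Because sequencing
reads sample a genotype's two alleles binomially, the error-corrected
read-ratio dosage (2 x alt-read fraction, rescaled for the per-read
miscall rate) is conditionally *unbiased* for the true dosage at any
depth — unlike hard calls or posterior means, whose shrinkage
attenuates pairwise products at low coverage. Off-diagonal relatedness
is therefore a ratio-of-sums GRM over read-ratio dosages, restricted
per pair to SNPs covered in both samples.

Two diagnostics guard against the artifacts this estimator is used to
screen for here: (i) a per-SNP Hardy-Weinberg-disequilibrium filter
(default window [0, 0.1]) strips loci where apparent heterozygosity is
structurally inflated (e.g. collapsed sex-linked gametologues, which
look like obligate-heterozygote SNPs with D = -0.25); (ii) self-
relatedness on the diagonal is computed with a cross-read split — reads
at each site are divided into two halves whose expected dosages are
multiplied — so shared read noise cannot inflate it, and values near 1
indicate a well-calibrated SNP set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gtio import MISSING, GenotypeLikelihoodMatrix, GenotypeMatrix

logger = logging.getLogger("larkline")


@dataclass
class RelatednessResult:
    r: np.ndarray  # (n_samples, n_samples), diagonal = self-relatedness diagnostic
    samples: list[str]
    n_snps: int
    filter_report: dict

    def to_pairs(self) -> pd.DataFrame:
        """Long-format pair list sorted by descending relatedness."""
        rows = []
        for i in range(len(self.samples)):
            for j in range(i + 1, len(self.samples)):
                rows.append({"id1": self.samples[i], "id2": self.samples[j],
                             "r": self.r[i, j]})
        return pd.DataFrame(rows).sort_values("r", ascending=False).reset_index(drop=True)


def hw_disequilibrium(gm: GenotypeMatrix) -> np.ndarray:
    """Per-SNP Hardy-Weinberg disequilibrium D.

    D = observed frequency of reference homozygotes - p^2 with p the
    reference-allele frequency among non-missing calls. NaN where fewer
    than two genotypes are called. D = 0 at exact HWE; obligate-
    heterozygote loci (collapsed gametologues) give D = -0.25.
    """
    d = gm.dosage
    called = d != MISSING
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ((d == 0).sum(axis=1) + 0.5 * (d == 1).sum(axis=1)) / n
        hom_ref = (d == 0).sum(axis=1) / n
        out = hom_ref - p**2
    out[n < 2] = np.nan
    return out


def _posterior_mean_dosage(gl: np.ndarray, p: np.ndarray) -> np.ndarray:
    """E[dosage | GL, HWE prior binomial(2, 1-p_ref)] per site x sample.

    ``p`` is the reference-allele frequency per site; the prior over alt
    dosage g is C(2,g) (1-p)^g p^(2-g). Used for allele-frequency
    estimation (shrinkage is harmless there), not for the GRM products.
    """
    q = 1.0 - p  # alt-allele frequency
    prior = np.stack([p**2, 2 * p * q, q**2], axis=-1)  # (sites, 3)
    w = gl * prior[:, None, :]
    tot = w.sum(axis=2)
    tot[tot == 0] = 1.0
    return (w[:, :, 1] + 2.0 * w[:, :, 2]) / tot


def _read_ratio_dosage(ad: np.ndarray, error_rate: float) -> np.ndarray:
    """Error-corrected read-ratio dosage, NaN where depth is 0.

    x = 2 (n_alt/d - e) / (1 - 2e): conditionally unbiased for the true
    alt dosage because reads draw alleles binomially from the genotype.
    """
    d = ad.sum(axis=-1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = ad[..., 1] / d
    x = 2.0 * (frac - error_rate) / (1.0 - 2.0 * error_rate)
    x[d == 0] = np.nan
    return x


def relatedness_matrix(
    glm: GenotypeLikelihoodMatrix,
    allele_freqs: np.ndarray | None = None,
    hw_bounds: tuple[float, float] = (0.0, 0.1),
    min_total_reads: int = 0,
    error_rate: float = 0.002,
    seed: int | None = None,
) -> RelatednessResult:
    """Pairwise relatedness with low-depth handling and HW filtering.

    SNPs are kept when their HW disequilibrium lies in ``hw_bounds`` and
    their panel-wide read count reaches ``min_total_reads``; monomorphic
    SNPs (p in {0, 1}) are excluded. Off-diagonal entries are the
    ratio-of-sums GRM

        r_ij = sum_S (x_i - 2q)(x_j - 2q) / sum_S 2 p q

    over the SNPs S covered by >= 1 read in both samples, with x the
    error-corrected read-ratio dosage and q the alt-allele frequency
    (estimated from posterior mean dosages, iterated once, unless
    ``allele_freqs`` are supplied). The diagonal splits each SNP's reads
    into two halves and multiplies their centered dosages, so read-
    sampling noise (shared within a read stack, independent between
    halves) cannot inflate self-relatedness; values near 1 indicate a
    well-calibrated SNP set. ``error_rate`` is the per-read miscall rate
    assumed by the dosage correction. Allelic depths (AD) are required;
    without them a posterior-mean fallback is used and flagged, which
    understates relatedness at low depth.
    """
    if glm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    rng = np.random.default_rng(seed)
    report = {"n_input": glm.n_sites}

    keep = np.ones(glm.n_sites, dtype=bool)
    if min_total_reads > 0:
        keep &= glm.depth.sum(axis=1) >= min_total_reads
    report["removed_total_reads"] = int(glm.n_sites - keep.sum())

    # variant sites only
    keep &= (glm.sites["alt"] != ".").to_numpy()

    work = glm.subset_sites(keep)
    # hard calls (argmax, any depth) for the HW filter
    best = work.gl.argmax(axis=2).astype(np.int8)
    ties = (np.sort(work.gl, axis=2)[:, :, 2] == np.sort(work.gl, axis=2)[:, :, 1])
    best[ties | (work.depth == 0)] = MISSING
    D = hw_disequilibrium(GenotypeMatrix(work.sites, work.samples, best))
    hw_ok = ~np.isnan(D) & (D >= hw_bounds[0]) & (D <= hw_bounds[1])
    report["removed_hw_disequilibrium"] = int((~hw_ok).sum())
    work = work.subset_sites(hw_ok)

    # allele frequencies from posterior mean dosages, iterated once
    if allele_freqs is None:
        x0 = _posterior_mean_dosage(work.gl, np.full(work.n_sites, 0.5))
        q = x0.mean(axis=1) / 2.0
        x1 = _posterior_mean_dosage(work.gl, 1.0 - q)
        q = x1.mean(axis=1) / 2.0
    else:
        af = np.asarray(allele_freqs, dtype=float)
        if len(af) != glm.n_sites:
            raise ValueError("allele_freqs must have one entry per input site")
        q = af[keep][hw_ok]
    poly = (q > 0) & (q < 1)
    report["removed_monomorphic"] = int((~poly).sum())
    work = work.subset_sites(poly)
    q = q[poly]
    n_snps = work.n_sites
    report["n_retained"] = n_snps
    if n_snps < 100:
        logger.warning("relatedness_matrix: only %d SNPs survive filtering", n_snps)
    if n_snps == 0:
        raise ValueError("no SNPs survive filtering")

    p = 1.0 - q
    denom = 2.0 * p * q
    if work.ad is not None:
        x = _read_ratio_dosage(work.ad, error_rate)
    else:
        logger.warning(
            "relatedness_matrix: no allelic depths; falling back to posterior-"
            "mean dosages, which attenuate relatedness at low depth"
        )
        x = _posterior_mean_dosage(work.gl, p)
        x[work.depth == 0] = np.nan
    observed = ~np.isnan(x)
    n_samp = work.n_samples
    denom = 2.0 * p * q

    def _grm(y1: np.ndarray, y2: np.ndarray, m1: np.ndarray, m2: np.ndarray):
        """Ratio-of-sums GRM between centered dosage sets, pairwise over
        SNPs observed in both members."""
        c1 = np.where(m1, y1 - 2.0 * q[:, None], 0.0)
        c2 = np.where(m2, y2 - 2.0 * q[:, None], 0.0)
        num = c1.T @ c2
        den = m1.T.astype(float) @ (denom[:, None] * m2)
        den[den == 0] = np.nan
        return num / den

    r = _grm(x, x, observed, observed)

    # Allele frequencies estimated from the panel itself shift every
    # off-diagonal down by O(1/N) (the centering projection), material
    # for small panels. The absolute level is not identifiable from the
    # matrix alone, so the background is anchored: the median off-
    # diagonal entry — the typical unrelated pair in a screening panel —
    # is subtracted. With mostly related panels this anchor would be
    # wrong; the screening use case assumes relatives are the exception.
    off = r[~np.eye(n_samp, dtype=bool)]
    shift = float(np.nanmedian(off))
    r = r - shift

    # diagonal: cross-read split (read noise is independent between the
    # two halves of a read stack, so their product estimates 1 + F
    # without the sampling-noise inflation of a squared noisy dosage);
    # reported unshifted, as an absolute calibration diagnostic
    if work.ad is not None:
        ref_a = rng.binomial(work.ad[..., 0], 0.5)
        alt_a = rng.binomial(work.ad[..., 1], 0.5)
        ad_a = np.stack([ref_a, alt_a], axis=-1)
        xa = _read_ratio_dosage(ad_a, error_rate)
        xb = _read_ratio_dosage(work.ad - ad_a, error_rate)
        oa, ob = ~np.isnan(xa), ~np.isnan(xb)
        D = np.diag(_grm(xa, xb, oa, ob)).copy()
        np.fill_diagonal(r, D)
    else:
        logger.warning(
            "relatedness_matrix: no allelic depths; self-relatedness "
            "diagnostic unavailable (diagonal set to NaN)"
        )
        np.fill_diagonal(r, np.nan)
    return RelatednessResult(r=(r + r.T) / 2.0, samples=list(work.samples),
                             n_snps=n_snps, filter_report=report)
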