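"""Synthetic data with the statistical structure the pipeline assumes.

Generates coalescent genealogies under piecewise-constant demographies
(exponential waiting times with time-rescaling across epochs), drops
infinite-sites mutations on the branches, and samples RAD-like
low-coverage reads into genotype likelihoods. A neo-sex-chromosome
emulator builds panels with female-specific heterozygosity elevation
(undiverged gametologues) next to a haploid ancestral-Z signal, with
ground-truth intervals for recovery tests. A small pedigree overlay
provides known-relatedness panels.

RAD loci are short and far apart, so loci are simulated as independent
genealogies with no intra-locus recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import DemographicModel
from .gtio import GenotypeLikelihoodMatrix, GenotypeMatrix


@dataclass
class SimConfig:
    """Simulation parameters.

    theta_site is the scaled mutation rate 4*N_anc*mu per site; mean_depth
    is the expected reads per site per sample (Poisson); error_rate the
    per-base miscall probability. Identical (config, seed) pairs give
    bit-identical output.
    """

    n_diploids: int = 10
    loci: int = 1000
    locus_length_bp: int = 100
    theta_site: float = 0.005
    mean_depth: float = 2.8
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_diploids, self.loci, self.locus_length_bp) < 1:
            raise ValueError("counts must be >= 1")
        if self.theta_site < 0:
            raise ValueError("theta_site must be >= 0")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class SexRegionSpec:
    """One genomic region of a sex-chromosome panel.

    neo_suppressed regions make females obligate heterozygotes at a
    fraction ``gametologue_divergence`` of sites (fixed W/Z differences) on
    top of background variation; ancestral_Z regions are haploid in
    females (all reads from a single haplotype, so true heterozygosity is
    zero); autosomal regions are diploid in both sexes.
    """

    region_kind: str  # autosomal | ancestral_Z | neo_suppressed
    length_bp: int
    gametologue_divergence: float = 0.0115
    background_pi: float = 0.001

    def __post_init__(self) -> None:
        if self.region_kind not in ("autosomal", "ancestral_Z", "neo_suppressed"):
            raise ValueError(f"unknown region_kind {self.region_kind!r}")
        if not (0 <= self.gametologue_divergence <= 1):
            raise ValueError("gametologue_divergence must be in [0, 1]")
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")


# ---------------------------------------------------------------------------
# coalescent machinery
# ---------------------------------------------------------------------------

def _simulate_tree(n_hap: int, model: DemographicModel, rng: np.random.Generator):
    """One coalescent genealogy: returns (leafsets, lengths).

    leafsets is a boolean array (n_branches, n_hap); lengths the matching
    branch lengths in units of 2*N_anc generations. Waiting times are
    exponential with rate C(k,2) on the rescaled time axis and mapped back
    to real time through the piecewise-linear inverse intensity.
    """
    active_sets = [np.eye(1, n_hap, i, dtype=bool)[0] for i in range(n_hap)]
    start = np.zeros(n_hap)
    leafsets, lengths = [], []
    tau = 0.0
    k = n_hap
    while k > 1:
        tau += rng.exponential(2.0 / (k * (k - 1)))
        t = float(model.real_from_scaled(tau))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        for idx in (i, j):
            leafsets.append(active_sets[idx])
            lengths.append(t - start[idx])
        merged = active_sets[i] | active_sets[j]
        active_sets[i] = merged
        start[i] = t
        active_sets.pop(j)
        start = np.delete(start, j)
        k -= 1
    return np.array(leafsets), np.array(lengths)


def _mutate_locus(
    leafsets: np.ndarray,
    lengths: np.ndarray,
    locus_length_bp: int,
    theta_site: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson infinite-sites mutations on a genealogy.

    Returns (positions within locus, haplotype matrix n_var x n_hap). Each
    mutation lands on a branch (probability proportional to length) at a
    distinct uniform position; mutation rate is theta/2 per site per unit
    of 2N-generations time.
    """
    total = lengths.sum()
    n_mut = rng.poisson(0.5 * theta_site * locus_length_bp * total)
    n_mut = min(n_mut, locus_length_bp)  # infinite sites within a finite locus
    if n_mut == 0:
        return np.empty(0, dtype=int), np.empty((0, leafsets.shape[1]), dtype=bool)
    positions = rng.choice(locus_length_bp, size=n_mut, replace=False)
    branch = rng.choice(len(lengths), size=n_mut, p=lengths / total)
    order = np.argsort(positions)
    return positions[order], leafsets[branch[order]]


def _haplotypes_to_dosage(hap: np.ndarray) -> np.ndarray:
    """(n_var, 2D) haplotypes -> (n_var, D) dosage."""
    return hap[:, 0::2].astype(np.int8) + hap[:, 1::2].astype(np.int8)


def _site_table(scaffold: str, offset: int, locus_id: int, length: int,
                var_pos: np.ndarray) -> pd.DataFrame:
    pos = np.arange(length) + offset
    alt = np.full(length, ".", dtype=object)
    alt[var_pos] = "T"
    return pd.DataFrame({
        "scaffold": scaffold,
        "pos": pos,
        "ref": "A",
        "alt": alt,
        "qual": np.nan,
        "locus": locus_id,
    })


def simulate_genotypes(
    model: DemographicModel, cfg: SimConfig
) -> GenotypeMatrix:
    """True genotypes for a panel under a piecewise-constant demography.

    Simulates ``cfg.loci`` independent genealogies of 2*n_diploids
    chromosomes, drops mutations, and returns a dosage matrix whose site
    table covers every base of every locus (invariant sites included, alt
    '.'), with locus ids for block bootstraps.
    """
    rng = np.random.default_rng(cfg.seed)
    n_hap = 2 * cfg.n_diploids
    if n_hap < 2:
        raise ValueError("need at least one diploid")
    tables, dosages = [], []
    for lid in range(cfg.loci):
        leafsets, lengths = _simulate_tree(n_hap, model, rng)
        var_pos, hap = _mutate_locus(leafsets, lengths, cfg.locus_length_bp,
                                     cfg.theta_site, rng)
        dos = np.zeros((cfg.locus_length_bp, cfg.n_diploids), dtype=np.int8)
        if len(var_pos):
            dos[var_pos] = _haplotypes_to_dosage(hap)
        dosages.append(dos)
        tables.append(_site_table("scaf_1", lid * cfg.locus_length_bp, lid,
                                  cfg.locus_length_bp, var_pos))
    sites = pd.concat(tables, ignore_index=True)
    samples = [f"ind_{i:03d}" for i in range(cfg.n_diploids)]
    return GenotypeMatrix(sites, samples, np.concatenate(dosages))


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def simulate_reads(
    genotypes: GenotypeMatrix,
    mean_depth: float,
    error_rate: float,
    seed: int | None = None,
) -> GenotypeLikelihoodMatrix:
    """Sample RAD-like reads from true genotypes into genotype likelihoods.

    Depth is Poisson(mean_depth) per site x sample; each read reports the
    alt allele with probability error_rate, 0.5 or 1-error_rate for dosage
    0, 1 or 2. Likelihood triplets are the standard independent-reads
    biallelic model, max-normalized; depth-0 entries are uninformative
    (1, 1, 1). Allelic depths are recorded for read-split diagnostics.
    """
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    dos = genotypes.dosage
    if np.any(dos < 0) or np.any(dos > 2):
        raise ValueError("dosages must be in {0, 1, 2}")
    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, size=dos.shape)
    p_alt_true = np.array([error_rate, 0.5, 1.0 - error_rate])[dos]
    n_alt = rng.binomial(depth, p_alt_true)
    n_ref = depth - n_alt
    # likelihoods of the three genotypes given read counts
    p_alt_g = np.array([error_rate, 0.5, 1.0 - error_rate])
    gl = np.empty(dos.shape + (3,))
    for g in range(3):
        gl[..., g] = np.power(p_alt_g[g], n_alt) * np.power(1.0 - p_alt_g[g], n_ref)
    mx = gl.max(axis=2, keepdims=True)
    mx[mx == 0] = 1.0
    gl /= mx
    ad = np.stack([n_ref, n_alt], axis=-1)
    return GenotypeLikelihoodMatrix(
        sites=genotypes.sites, samples=genotypes.samples,
        gl=gl, depth=depth, ad=ad,
    )


# ---------------------------------------------------------------------------
# neo-sex-chromosome panel
# ---------------------------------------------------------------------------

def simulate_sex_chromosome_panel(
    spec_list: list[SexRegionSpec],
    sexes: list[str],
    cfg: SimConfig,
    model: DemographicModel | None = None,
    locus_spacing_bp: int = 25_000,
    scaffold_per_region: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Panel of males and females across autosomal / ancestral-Z /
    neo-suppressed regions.

    Regions are laid end to end (one scaffold, or one per region when
    ``scaffold_per_region``), with RAD loci of ``cfg.locus_length_bp``
    every ``locus_spacing_bp``. Returns (genotypes, truth intervals with
    columns scaffold/start/end/region_kind, sample metadata).

    Ancestral-Z female dosage is twice the allele of a single haplotype —
    all reads derive from one chromosome copy, reproducing the haploid
    zero-heterozygosity signal.
    """
    if model is None:
        model = DemographicModel.constant()
    sexes = list(sexes)
    if not set(sexes) <= {"F", "M"}:
        raise ValueError("sexes must be 'F' or 'M'")
    if "F" not in sexes or "M" not in sexes:
        raise ValueError("panel needs at least one female and one male")
    if len(sexes) != cfg.n_diploids:
        raise ValueError("len(sexes) must equal cfg.n_diploids")
    rng = np.random.default_rng(cfg.seed)
    n_hap = 2 * cfg.n_diploids
    is_f = np.array([s == "F" for s in sexes])

    tables, dosages, truth = [], [], []
    offset = 0
    locus_id = 0
    for ridx, spec in enumerate(spec_list):
        scaffold = f"chr_{ridx + 1}" if scaffold_per_region else "chr_1"
        if scaffold_per_region:
            offset = 0
        n_loci = max(1, spec.length_bp // locus_spacing_bp)
        truth.append({"scaffold": scaffold, "start": offset,
                      "end": offset + spec.length_bp, "region_kind": spec.region_kind})
        for l in range(n_loci):
            lstart = offset + l * locus_spacing_bp
            leafsets, lengths = _simulate_tree(n_hap, model, rng)
            var_pos, hap = _mutate_locus(leafsets, lengths, cfg.locus_length_bp,
                                         spec.background_pi, rng)
            dos = np.zeros((cfg.locus_length_bp, cfg.n_diploids), dtype=np.int8)
            if len(var_pos):
                if spec.region_kind == "ancestral_Z":
                    full = _haplotypes_to_dosage(hap)
                    # females: single chromosome copy (first haplotype), observed
                    # as homozygous; males keep both copies
                    hapF = 2 * hap[:, 0::2].astype(np.int8)
                    full[:, is_f] = hapF[:, is_f]
                    dos[var_pos] = full
                else:
                    dos[var_pos] = _haplotypes_to_dosage(hap)
            if spec.region_kind == "neo_suppressed" and spec.gametologue_divergence > 0:
                n_fix = rng.binomial(cfg.locus_length_bp, spec.gametologue_divergence)
                if n_fix:
                    taken = set(var_pos.tolist())
                    free = np.array([p for p in range(cfg.locus_length_bp)
                                     if p not in taken])
                    n_fix = min(n_fix, len(free))
                    fix_pos = rng.choice(free, size=n_fix, replace=False)
                    dos[fix_pos[:, None], np.flatnonzero(is_f)[None, :]] = 1
                    var_pos = np.sort(np.concatenate([var_pos, fix_pos]))
            dosages.append(dos)
            tables.append(_site_table(scaffold, lstart, locus_id,
                                      cfg.locus_length_bp, var_pos))
            locus_id += 1
        if not scaffold_per_region:
            offset += spec.length_bp
    sites = pd.concat(tables, ignore_index=True)
    samples = [f"{s}{i:03d}" for i, s in enumerate(sexes)]
    meta = pd.DataFrame({"id": samples, "population": "sim", "sex": sexes})
    gm = GenotypeMatrix(sites, samples, np.concatenate(dosages))
    return gm, pd.DataFrame(truth), meta


# ---------------------------------------------------------------------------
# pedigree overlay
# ---------------------------------------------------------------------------

def simulate_pedigree_genotypes(
    n_snps: int,
    n_founder_pairs: int = 2,
    n_unrelated: int = 4,
    seed: int | None = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Founders in Hardy-Weinberg equilibrium plus one offspring per
    founder pair; for relatedness-estimator validation.

    Returns (genotypes, truth pair table with columns id1/id2/relationship
    in {parent_offspring, unrelated}). Allele frequencies are drawn
    uniformly on ``maf_range`` per SNP.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf_range, size=n_snps)
    n_founders = 2 * n_founder_pairs + n_unrelated
    hap_f = (rng.random((n_snps, 2 * n_founders)) < p[:, None])
    samples = [f"fnd_{i:02d}" for i in range(n_founders)]
    cols = [hap_f]
    truth = []
    for k in range(n_founder_pairs):
        pa, ma = 2 * k, 2 * k + 1
        pick_pa = rng.integers(0, 2, n_snps)
        pick_ma = rng.integers(0, 2, n_snps)
        child = np.stack([
            hap_f[np.arange(n_snps), 2 * pa + pick_pa],
            hap_f[np.arange(n_snps), 2 * ma + pick_ma],
        ], axis=1)
        cols.append(child)
        cid = f"off_{k:02d}"
        samples.append(cid)
        truth.append({"id1": samples[pa], "id2": cid, "relationship": "parent_offspring"})
        truth.append({"id1": samples[ma], "id2": cid, "relationship": "parent_offspring"})
    hap = np.concatenate(cols, axis=1)
    dosage = _haplotypes_to_dosage(hap)
    for i in range(2 * n_founder_pairs, n_founders):
        for j in range(i + 1, n_founders):
            truth.append({"id1": samples[i], "id2": samples[j], "relationship": "unrelated"})
    sites = pd.DataFrame({
        "scaffold": "ped_1", "pos": np.arange(n_snps), "ref": "A", "alt": "T",
        "qual": np.nan, "locus": np.arange(n_snps),
    })
    return GenotypeMatrix(sites, samples, dosage), pd.DataFrame(truth)
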