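"""Site frequency spectrum estimation from genotype likelihoods.

Implements the two-step low-coverage approach: per-site likelihoods of
every possible total allele count (a dynamic-programming convolution over
individuals), followed by maximum-likelihood estimation of the spectrum by
EM over sites (the realSFS-style estimator). Bootstrap and drop-one-out
replicates are provided for robustness analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .gtio import GenotypeLikelihoodMatrix


@dataclass
class SiteFrequencySpectrum:
    """Counts of sites per allele-frequency class.

    Unfolded: ``counts[i]`` = number of sites where the derived (alt)
    allele is carried by ``i`` of ``n_haploid`` chromosomes, i = 0..n.
    Folded: classes are minor-allele counts 0..n//2. ``counts[0]`` is the
    invariant class and enters diversity denominators.
    """

    counts: np.ndarray
    n_haploid: int
    folded: bool = False
    em_converged: bool = True
    em_iterations: int = 0
    em_last_change: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = self.n_haploid // 2 + 1 if self.folded else self.n_haploid + 1
        if len(self.counts) != expected:
            raise ValueError(
                f"SFS length {len(self.counts)} != expected {expected} "
                f"(n={self.n_haploid}, folded={self.folded})"
            )
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("SFS counts must be finite and >= 0")
        if self.n_haploid % 2:
            raise ValueError("n_haploid must be even (diploid samples)")

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())

    @property
    def n_segregating(self) -> float:
        """Segregating sites: all classes except invariant (and, unfolded, fixed)."""
        poly = self.counts[1:] if self.folded else self.counts[1:-1]
        return float(poly.sum())

    def normalized(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def to_file(self, path) -> None:
        """Write as single-line whitespace-separated counts with a header comment."""
        with open(path, "w") as fh:
            fh.write(f"# larkline SFS n_haploid={self.n_haploid} folded={int(self.folded)}\n")
            fh.write(" ".join(f"{c:.6f}" for c in self.counts) + "\n")

    @classmethod
    def from_file(cls, path) -> "SiteFrequencySpectrum":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("SFS file must start with a header comment")
            kv = dict(tok.split("=") for tok in header.split() if "=" in tok)
            counts = np.array([float(x) for x in fh.readline().split()])
        return cls(counts, int(kv["n_haploid"]), folded=bool(int(kv["folded"])))


@dataclass
class SfsReplicateSet:
    replicates: list[SiteFrequencySpectrum]
    kind: str  # "bootstrap" | "drop_one_out"
    seed: int | None = None


def fold(sfs: SiteFrequencySpectrum) -> SiteFrequencySpectrum:
    """Fold an unfolded spectrum: class i merges with class n-i."""
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    n = sfs.n_haploid
    half = n // 2
    folded = sfs.counts[: half + 1].copy()
    folded[:half] += sfs.counts[n : half : -1]
    return SiteFrequencySpectrum(folded, n, folded=True)


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def site_count_likelihoods(glm: GenotypeLikelihoodMatrix) -> np.ndarray:
    """Likelihood of each total alt-allele count at every site.

    For D diploids (n = 2D haplotypes),

        L_s(j) = C(n,j)^-1 * sum over genotype vectors g with sum(g)=j of
                 prod_d C(2, g_d) * GL_d(g_d)

    computed by convolving individuals one at a time. Under the exchangeable
    (hypergeometric) sampling of alleles into genotypes this is the
    probability of the data given j alt alleles among the 2D chromosomes.
    Uninformative triplets (1,1,1) for every sample give L(j) = 1 for all
    j (the combinatorial weights cancel against C(n,j)). Rows are only
    rescaled when they underflow (per-site constants do not affect the
    downstream EM).

    Returns array of shape (n_sites, n + 1).
    """
    D = glm.n_samples
    n = 2 * D
    weights = np.array([1.0, 2.0, 1.0])  # C(2, g)
    acc = np.ones((glm.n_sites, 1))
    for d in range(D):
        w = glm.gl[:, d, :] * weights  # (sites, 3)
        cur = acc.shape[1]
        nxt = np.zeros((glm.n_sites, cur + 2))
        for g in range(3):
            nxt[:, g : g + cur] += acc * w[:, g][:, None]
        acc = nxt
        # underflow guard for large low-likelihood panels
        mx = acc.max(axis=1)
        tiny = mx < 1e-200
        if tiny.any():
            acc[tiny] /= np.where(mx[tiny] == 0, 1.0, mx[tiny])[:, None]
    return acc / np.exp(_log_binom(n, np.arange(n + 1)))[None, :]


def _fold_count_likelihoods(L: np.ndarray) -> np.ndarray:
    """Merge count-likelihood columns j and n-j (minor-allele classes)."""
    n = L.shape[1] - 1
    half = n // 2
    out = L[:, : half + 1].copy()
    out[:, :half] += L[:, n : half : -1]
    return out


def _run_em(
    L: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, bool, int, float, float]:
    """EM for the mixture proportions p over allele-count classes.

    E-step: per-site posterior over classes; M-step: mean posterior.
    The log-likelihood sum_s log(p . L_s) is concave in p, so EM converges
    to the global maximum. Returns (p, converged, n_iter, last_rel_change,
    final log-likelihood).
    """
    n_sites, n_classes = L.shape
    p = np.full(n_classes, 1.0 / n_classes)
    ll_prev = -np.inf
    converged = False
    it = 0
    rel = np.inf
    for it in range(1, max_iter + 1):
        mix = L @ p  # (sites,)
        ll = float(np.log(mix).sum())
        post = L * p[None, :] / mix[:, None]
        p = post.mean(axis=0)
        rel = abs(ll - ll_prev) / (abs(ll) + 1e-300)
        if rel < tol:
            converged = True
            break
        ll_prev = ll
    ll = float(np.log(L @ p).sum())
    return p, converged, it, rel, ll


def estimate_sfs_em(
    glm: GenotypeLikelihoodMatrix,
    folded: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
    _count_likelihoods: np.ndarray | None = None,
) -> SiteFrequencySpectrum:
    """Maximum-likelihood SFS from genotype likelihoods by EM.

    Maximizes ``sum_s log sum_j p_j L_s(j)`` over the probability vector p
    and returns p scaled by the number of sites. When ``folded``, classes j
    and n-j of the count likelihoods are summed before the EM. Capped at
    ``max_iter`` iterations (non-convergence is flagged on the result, not
    raised).
    """
    if glm.n_sites < 1:
        raise ValueError("need at least one site")
    L = _count_likelihoods if _count_likelihoods is not None else site_count_likelihoods(glm)
    if folded:
        L = _fold_count_likelihoods(L)
    p, converged, it, rel, _ = _run_em(L, max_iter=max_iter, tol=tol)
    out = SiteFrequencySpectrum(
        p * glm.n_sites,
        glm.n_haploid,
        folded=folded,
        em_converged=converged,
        em_iterations=it,
        em_last_change=rel,
    )
    return out


def bootstrap_sfs(
    glm: GenotypeLikelihoodMatrix,
    n_boot: int = 20,
    unit: str = "site",
    seed: int | None = None,
    folded: bool = True,
    max_iter: int = 100,
) -> SfsReplicateSet:
    """Bootstrap the SFS by resampling sites (or whole RAD loci).

    Each replicate resamples units with replacement to the original count
    and re-runs the EM; n_sites is preserved. ``unit="locus"`` resamples
    locus blocks (sites within a RAD locus are linked) using the ``locus``
    column of the site table.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if unit not in ("site", "locus"):
        raise ValueError("unit must be 'site' or 'locus'")
    rng = np.random.default_rng(seed)
    L = site_count_likelihoods(glm)
    if folded:
        L = _fold_count_likelihoods(L)
    reps = []
    if unit == "locus":
        loci = glm.sites["locus"].to_numpy()
        if np.all(loci < 0):
            raise ValueError("locus ids unavailable for unit='locus'")
        uniq = np.unique(loci)
        groups = [np.flatnonzero(loci == u) for u in uniq]
    for _ in range(n_boot):
        if unit == "site":
            idx = rng.integers(0, glm.n_sites, size=glm.n_sites)
        else:
            chosen = rng.integers(0, len(groups), size=len(groups))
            idx = np.concatenate([groups[c] for c in chosen])
        p, conv, it, rel, _ = _run_em(L[idx], max_iter=max_iter, tol=1e-8)
        reps.append(
            SiteFrequencySpectrum(
                p * len(idx), glm.n_haploid, folded=folded,
                em_converged=conv, em_iterations=it, em_last_change=rel,
            )
        )
    return SfsReplicateSet(reps, kind="bootstrap", seed=seed)


def drop_one_out_spectra(
    glm: GenotypeLikelihoodMatrix,
    folded: bool = True,
    max_iter: int = 100,
) -> SfsReplicateSet:
    """Re-estimate the SFS excluding one individual at a time.

    Replicate d drops individual d and re-runs the EM with n reduced by 2;
    used to show a spectral feature is not driven by any single sample.
    """
    if glm.n_samples < 2:
        raise ValueError("drop-one-out needs >= 2 individuals")
    reps = []
    for d in range(glm.n_samples):
        keep = [i for i in range(glm.n_samples) if i != d]
        reps.append(estimate_sfs_em(glm.subset_samples(keep), folded=folded, max_iter=max_iter))
    return SfsReplicateSet(reps, kind="drop_one_out")
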