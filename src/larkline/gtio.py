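"""Genotype-likelihood data model and I/O.

The central container is :class:`GenotypeLikelihoodMatrix`: per-site,
per-sample biallelic genotype likelihood triplets (hom-ref, het, hom-alt)
plus read depths, as produced by low-coverage pipelines (ANGSD/GATK style).
Likelihood triplets are stored max-normalized (the largest entry of each
triplet is 1), the phred-free analogue of the VCF PL convention.

Coordinates are 0-based half-open internally; VCF import/export converts
to/from the 1-based convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("larkline")

MISSING = -1  # dosage code for missing genotype

SITE_COLUMNS = ["scaffold", "pos", "ref", "alt", "qual", "locus"]


def _as_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Normalize a site table to the canonical columns and dtypes."""
    out = sites.copy().reset_index(drop=True)
    if "qual" not in out:
        out["qual"] = np.nan
    if "locus" not in out:
        out["locus"] = -1
    out = out[SITE_COLUMNS]
    out["pos"] = out["pos"].astype(np.int64)
    out["locus"] = out["locus"].astype(np.int64)
    return out


@dataclass
class GenotypeLikelihoodMatrix:
    """Biallelic genotype likelihoods for a panel of diploid samples.

    Parameters
    ----------
    sites
        Table with columns ``scaffold, pos, ref, alt, qual, locus``;
        ``pos`` is 0-based, positions strictly increasing within scaffold.
        ``alt == "."`` marks an invariant (monomorphic) site.
    samples
        Ordered sample identifiers.
    gl
        Array ``(n_sites, n_samples, 3)``: likelihoods of genotypes
        (hom-ref, het, hom-alt), max-normalized per triplet.
    depth
        Array ``(n_sites, n_samples)`` of read counts.
    ad
        Optional ``(n_sites, n_samples, 2)`` allelic depths (ref, alt
        read counts); required for the read-split self-relatedness
        diagnostic.
    """

    sites: pd.DataFrame
    samples: list[str]
    gl: np.ndarray
    depth: np.ndarray
    ad: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = _as_site_table(self.sites)
        self.samples = list(self.samples)
        self.gl = np.asarray(self.gl, dtype=float)
        self.depth = np.asarray(self.depth)
        if self.gl.shape != (self.n_sites, self.n_samples, 3):
            raise ValueError(
                f"gl shape {self.gl.shape} inconsistent with "
                f"{self.n_sites} sites x {self.n_samples} samples"
            )
        if self.depth.shape != (self.n_sites, self.n_samples):
            raise ValueError("depth shape inconsistent with sites x samples")
        if self.ad is not None:
            self.ad = np.asarray(self.ad)
            if self.ad.shape != (self.n_sites, self.n_samples, 2):
                raise ValueError("ad shape inconsistent with sites x samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haploid(self) -> int:
        return 2 * self.n_samples

    def validate(self) -> None:
        """Check container invariants; raise ``ValueError`` on violation."""
        if not np.all(np.isfinite(self.gl)) or np.any(self.gl < 0):
            raise ValueError("genotype likelihoods must be finite and >= 0")
        mx = self.gl.max(axis=2)
        if not np.allclose(mx, 1.0):
            raise ValueError("triplets must be max-normalized (max == 1)")
        for _, grp in self.sites.groupby("scaffold", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError("positions must strictly increase within scaffold")

    def subset_sites(self, index: np.ndarray) -> "GenotypeLikelihoodMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeLikelihoodMatrix(
            sites=self.sites.iloc[index],
            samples=self.samples,
            gl=self.gl[index],
            depth=self.depth[index],
            ad=self.ad[index] if self.ad is not None else None,
        )

    def subset_samples(self, which: Sequence[int] | Sequence[str]) -> "GenotypeLikelihoodMatrix":
        if len(which) and isinstance(which[0], str):
            idx = [self.samples.index(s) for s in which]
        else:
            idx = list(which)
        return GenotypeLikelihoodMatrix(
            sites=self.sites,
            samples=[self.samples[i] for i in idx],
            gl=self.gl[:, idx],
            depth=self.depth[:, idx],
            ad=self.ad[:, idx] if self.ad is not None else None,
        )


@dataclass
class GenotypeMatrix:
    """Hard genotype calls: alt-allele dosage in {0, 1, 2} or MISSING (-1)."""

    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray  # (n_sites, n_samples) int8

    def __post_init__(self) -> None:
        self.sites = _as_site_table(self.sites)
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage shape inconsistent with sites x samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(self.sites.iloc[index], self.samples, self.dosage[index])

    def subset_samples(self, which: Sequence[int] | Sequence[str]) -> "GenotypeMatrix":
        if len(which) and isinstance(which[0], str):
            idx = [self.samples.index(s) for s in which]
        else:
            idx = list(which)
        return GenotypeMatrix(self.sites, [self.samples[i] for i in idx], self.dosage[:, idx])


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns id, population, sex."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "population", "sex"}
    if not required.issubset(meta.columns):
        raise ValueError(f"sample metadata must have columns {sorted(required)}")
    if meta["id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    bad = ~meta["sex"].isin(["F", "M", "unknown"])
    if bad.any():
        raise ValueError(f"sex must be F/M/unknown; got {meta.loc[bad, 'sex'].unique()}")
    return meta


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[GenotypeLikelihoodMatrix, GenotypeMatrix | None]:
    """Read a VCF 4.x into the data model.

    FORMAT must contain GL or PL (hard-call-only VCFs with GT are accepted
    with degenerate likelihoods). Multiallelic and non-SNP records are
    skipped with a logged count. Returns the likelihood matrix and, when GT
    is present, the matching hard-call matrix.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    nsamp = len(samples)

    rows, gls, depths, ads, gts = [], [], [], [], []
    n_skipped = 0
    has_gt = None
    for var in vcf:
        alts = [a for a in var.ALT if a not in (".",)]
        invariant = len(alts) == 0
        if len(alts) > 1:
            n_skipped += 1
            continue
        alt = alts[0] if alts else "."
        if len(var.REF) != 1 or (alt != "." and len(alt) != 1):
            n_skipped += 1
            continue

        tri = _likelihood_triplets(var, nsamp)
        if tri is None:
            raise ValueError("VCF record lacks GL, PL and GT FORMAT fields")
        gls.append(tri)

        dp = _format_or_none(var, "DP")
        depths.append(
            np.nan_to_num(dp.astype(float), nan=0.0).reshape(nsamp).astype(int)
            if dp is not None
            else np.zeros(nsamp, dtype=int)
        )
        adf = _format_or_none(var, "AD")
        ads.append(adf.reshape(nsamp, -1)[:, :2].astype(int) if adf is not None else None)

        gt_present = var.gt_types is not None and "GT" in (var.FORMAT or [])
        if has_gt is None:
            has_gt = gt_present
        if gt_present:
            # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            g = np.array(var.gt_types)
            dosage = np.select([g == 0, g == 1, g == 3], [0, 1, 2], default=MISSING)
            gts.append(dosage.astype(np.int8))
        rows.append(
            {
                "scaffold": var.CHROM,
                "pos": var.POS - 1,
                "ref": var.REF,
                "alt": alt,
                "qual": var.QUAL if var.QUAL is not None else np.nan,
                "locus": -1,
            }
        )
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError("no usable biallelic SNP records in VCF")

    sites = pd.DataFrame(rows)
    ad_arr = None
    if all(a is not None for a in ads):
        ad_arr = np.stack(ads)
    glm = GenotypeLikelihoodMatrix(
        sites=sites,
        samples=samples,
        gl=np.stack(gls),
        depth=np.stack(depths),
        ad=ad_arr,
    )
    gm = GenotypeMatrix(sites, samples, np.stack(gts)) if gts else None
    return glm, gm


def _format_or_none(var, tag: str):
    """FORMAT field array, or None when the tag is absent (cyvcf2 raises
    KeyError for tags missing from the header)."""
    try:
        return var.format(tag)
    except KeyError:
        return None


def _likelihood_triplets(var, nsamp: int) -> np.ndarray | None:
    gl = _format_or_none(var, "GL")
    if gl is not None:
        tri = np.power(10.0, gl.astype(float).reshape(nsamp, 3))
    else:
        pl = _format_or_none(var, "PL")
        if pl is not None:
            tri = np.power(10.0, -pl.astype(float).reshape(nsamp, 3) / 10.0)
        elif var.gt_types is not None:
            g = np.array(var.gt_types)
            tri = np.full((nsamp, 3), 1.0)
            for code, dos in ((0, 0), (1, 1), (3, 2)):
                mask = g == code
                tri[mask] = 0.0
                tri[mask, dos] = 1.0
        else:
            return None
    mx = tri.max(axis=1, keepdims=True)
    mx[mx == 0] = 1.0
    return tri / mx


def write_vcf(glm: GenotypeLikelihoodMatrix, path, genotypes: GenotypeMatrix | None = None) -> None:
    """Write the data model as a VCF 4.2 text file (GL, DP and optional AD/GT)."""
    scaffolds = glm.sites["scaffold"].unique()
    contig_len = {
        s: int(glm.sites.loc[glm.sites["scaffold"] == s, "pos"].max()) + 2 for s in scaffolds
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=larkline\n")
        for s in scaffolds:
            fh.write(f"##contig=<ID={s},length={contig_len[s]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GL,Number=G,Type=Float,Description="Genotype likelihoods, log10">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(glm.samples)
            + "\n"
        )
        fmt = "GT:GL:DP" + (":AD" if glm.ad is not None else "")
        dosage = genotypes.dosage if genotypes is not None else None
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with np.errstate(divide="ignore"):
            log_gl = np.log10(glm.gl)
        for i in range(glm.n_sites):
            row = glm.sites.iloc[i]
            qual = "." if pd.isna(row["qual"]) else f"{row['qual']:g}"
            fields = [
                row["scaffold"],
                str(int(row["pos"]) + 1),
                ".",
                row["ref"],
                row["alt"],
                qual,
                "PASS",
                ".",
                fmt,
            ]
            for j in range(glm.n_samples):
                gt = gt_str[int(dosage[i, j])] if dosage is not None else "./."
                gl_txt = ",".join(
                    "-500" if not np.isfinite(v) else f"{v:.6g}" for v in log_gl[i, j]
                )
                cell = f"{gt}:{gl_txt}:{int(glm.depth[i, j])}"
                if glm.ad is not None:
                    cell += f":{int(glm.ad[i, j, 0])},{int(glm.ad[i, j, 1])}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# genotype calling and site filters
# ---------------------------------------------------------------------------

def call_genotypes(glm: GenotypeLikelihoodMatrix, min_depth: int = 5) -> GenotypeMatrix:
    """Call hard genotypes from likelihoods.

    Dosage is the argmax of the likelihood triplet; a call is missing when
    the sample's depth is below ``min_depth`` or the two best likelihoods
    are exactly tied (ties are never broken arbitrarily, to avoid biasing
    heterozygosity scans).
    """
    order = np.argsort(glm.gl, axis=2)
    best = order[:, :, 2]
    second = order[:, :, 1]
    top = np.take_along_axis(glm.gl, best[:, :, None], axis=2)[:, :, 0]
    runner = np.take_along_axis(glm.gl, second[:, :, None], axis=2)[:, :, 0]
    dosage = best.astype(np.int8)
    dosage[top == runner] = MISSING
    dosage[glm.depth < min_depth] = MISSING
    return GenotypeMatrix(glm.sites, glm.samples, dosage)


def filter_sites(
    glm: GenotypeLikelihoodMatrix,
    min_snp_qual: float = 20.0,
    min_total_reads: int = 0,
) -> tuple[GenotypeLikelihoodMatrix, dict[str, int]]:
    """Drop sites failing quality / total-read-count thresholds.

    ``min_snp_qual`` applies only to sites that carry a quality score;
    ``min_total_reads`` is the panel-wide read count threshold. Returns the
    filtered matrix and a per-rule removal report.
    """
    if min_snp_qual < 0 or min_total_reads < 0:
        raise ValueError("filter thresholds must be >= 0")
    qual = glm.sites["qual"].to_numpy(dtype=float)
    fail_qual = np.zeros(glm.n_sites, dtype=bool)
    if min_snp_qual > 0:
        fail_qual = ~np.isnan(qual) & (qual < min_snp_qual)
    fail_reads = np.zeros(glm.n_sites, dtype=bool)
    if min_total_reads > 0:
        fail_reads = glm.depth.sum(axis=1) < min_total_reads
    keep = ~(fail_qual | fail_reads)
    report = {
        "n_input": glm.n_sites,
        "removed_snp_qual": int(fail_qual.sum()),
        "removed_total_reads": int(fail_reads.sum()),
        "n_retained": int(keep.sum()),
    }
    logger.info("filter_sites: %s", report)
    return glm.subset_sites(keep), report
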