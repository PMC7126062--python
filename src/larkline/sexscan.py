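"""Neo-sex-chromosome detection from per-individual heterozygosity.

Females of a ZW species carry a single Z, so windows on the ancestral Z
show near-zero heterozygous genotype calls in females. A formerly
autosomal region recruited into sex linkage (a neo-sex chromosome) shows
the opposite signal while its gametologues are still young: suppressed
recombination lets the neo-W and neo-Z retain distinct alleles, and
reads from both map to the same reference scaffold, so females appear as
obligate heterozygotes at every fixed W/Z difference. The scan computes
the proportion of heterozygous calls per individual in fixed windows,
smooths it with a tricube local linear regression over a fixed genomic
span, and calls contiguous runs of windows with a strong female/male
contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gtio import MISSING, GenotypeMatrix

logger = logging.getLogger("larkline")

TRACK_COLUMNS = ["individual", "scaffold", "start", "end", "n_sites", "prop_het", "smoothed"]


def window_heterozygosity(
    gm: GenotypeMatrix, window_size: int = 250_000, min_sites: int = 100
) -> pd.DataFrame:
    """Per-individual proportion of heterozygous calls in fixed windows.

    Windows are [k*W, (k+1)*W) per scaffold; prop_het = heterozygous calls
    / non-missing calls. Windows with fewer than ``min_sites`` genotyped
    sites for an individual emit no row for that individual. Returns a
    long-format track table (columns ``TRACK_COLUMNS``, smoothed = NaN).
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    pos = gm.sites["pos"].to_numpy()
    scaf = gm.sites["scaffold"].to_numpy()
    win = pos // window_size
    rows = []
    for s in pd.unique(scaf):
        sel = np.flatnonzero(scaf == s)
        for w in np.unique(win[sel]):
            idx = sel[win[sel] == w]
            d = gm.dosage[idx]
            n_called = (d != MISSING).sum(axis=0)
            n_het = (d == 1).sum(axis=0)
            for j, ind in enumerate(gm.samples):
                if n_called[j] < min_sites:
                    continue
                rows.append((ind, s, int(w) * window_size, (int(w) + 1) * window_size,
                             int(n_called[j]), n_het[j] / n_called[j], np.nan))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def _loess_bp(x: np.ndarray, y: np.ndarray, span_bp: float) -> np.ndarray:
    """Tricube-weighted local linear regression with a fixed genomic span.

    The smoothing window is centered on each point with half-width
    span_bp/2 of genomic distance (not a fraction of points). Local linear
    fits reproduce straight-line trends exactly.
    """
    half = span_bp / 2.0
    out = np.empty_like(y, dtype=float)
    for i, xi in enumerate(x):
        d = np.abs(x - xi)
        w = np.zeros_like(d, dtype=float)
        inside = d < half
        w[inside] = (1.0 - (d[inside] / half) ** 3) ** 3
        sw = w.sum()
        xc = x - xi
        sx = np.sum(w * xc)
        sxx = np.sum(w * xc * xc)
        sy = np.sum(w * y)
        sxy = np.sum(w * xc * y)
        denom = sw * sxx - sx * sx
        if denom <= 1e-12 * max(sxx, 1.0) * max(sw, 1.0):
            out[i] = sy / sw  # degenerate design: weighted mean
        else:
            out[i] = (sxx * sy - sx * sxy) / denom  # intercept at xc = 0
    return out


def smooth_track(track: pd.DataFrame, span_bp: float = 10_000_000) -> pd.DataFrame:
    """Fill the ``smoothed`` column of a heterozygosity track.

    Smoothing runs per individual per scaffold over window midpoints;
    excluded windows are absent from the table and neither contribute nor
    get imputed. A scaffold with a single valued window keeps its raw
    value (logged).
    """
    track = track.copy()
    for (ind, scaf), idx in track.groupby(["individual", "scaffold"]).groups.items():
        sub = track.loc[idx]
        x = ((sub["start"] + sub["end"]) / 2.0).to_numpy(dtype=float)
        y = sub["prop_het"].to_numpy(dtype=float)
        if len(x) < 2:
            logger.info("smooth_track: single window on %s for %s; smoothed = raw", scaf, ind)
            track.loc[idx, "smoothed"] = y
            continue
        track.loc[idx, "smoothed"] = _loess_bp(x, y, span_bp)
    return track


def infer_sex(
    tracks: pd.DataFrame,
    z_scaffolds: set[str],
    min_windows: int = 10,
    f_threshold: float = 0.25,
    m_threshold: float = 0.6,
) -> pd.DataFrame:
    """Sex from the ratio of Z-linked to autosomal heterozygosity.

    r = median Z-window prop_het / median autosomal prop_het; an
    individual is female when r < f_threshold (single Z, so near-zero
    heterozygosity), male when r > m_threshold, otherwise unknown. Fewer
    than ``min_windows`` valued Z windows gives unknown. Returns a table
    (individual, z_het, autosomal_het, ratio, sex).
    """
    rows = []
    for ind, sub in tracks.groupby("individual"):
        on_z = sub["scaffold"].isin(z_scaffolds)
        z = sub.loc[on_z, "prop_het"]
        a = sub.loc[~on_z, "prop_het"]
        if len(z) < min_windows or len(a) == 0 or a.median() == 0:
            rows.append((ind, z.median(), a.median(), np.nan, "unknown"))
            continue
        r = z.median() / a.median()
        sex = "F" if r < f_threshold else ("M" if r > m_threshold else "unknown")
        rows.append((ind, z.median(), a.median(), r, sex))
    return pd.DataFrame(rows, columns=["individual", "z_het", "autosomal_het", "ratio", "sex"])


def _runs(flags: np.ndarray, min_run: int, max_gap: int) -> list[tuple[int, int]]:
    """Maximal runs of flagged windows, bridging gaps of <= max_gap."""
    idx = np.flatnonzero(flags)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    # min_run counts flagged windows inside the run
    out = []
    for a, b in runs:
        if flags[a : b + 1].sum() >= min_run:
            out.append((a, b))
    return out


def call_suppressed_regions(
    tracks: pd.DataFrame,
    sexes: pd.DataFrame,
    fold_threshold: float = 3.0,
    min_female_het: float = 0.002,
    min_run_windows: int = 8,
    max_gap_windows: int = 2,
    z_ratio_threshold: float = 0.25,
) -> pd.DataFrame:
    """Call regions of suppressed recombination from smoothed tracks.

    A window is neo-flagged when the female median smoothed heterozygosity
    is at least ``fold_threshold`` times the male median and at least
    ``min_female_het`` in absolute terms; maximal runs of >=
    ``min_run_windows`` flagged windows (gaps <= ``max_gap_windows``
    bridged) become neo_suppressed calls. The mirrored rule (female median
    < ``z_ratio_threshold`` x male median, male median >=
    ``min_female_het``) yields ancestral_Z calls. Run-length filtering
    ignores isolated single-window peaks (collapsed-repeat artifacts).

    The two classes carry very different signal strengths, and the caller
    exploits that. Neo-suppressed windows show a strong absolute
    elevation (obligate-heterozygote gametologue sites), so candidate
    runs come from the *raw* per-window signal pooled across individuals
    of each sex (total heterozygous calls / total called sites), which
    keeps boundaries at window resolution; a candidate must overlap at
    least one smoothed-flagged window, so isolated raw noise (collapsed
    repeats) cannot seed a call. The ancestral-Z contrast, by comparison,
    is a *reduction* of an already small female rate toward the
    error-driven heterozygous-call floor, and per-window raw tests sit at
    that floor's noise level — so ancestral runs are taken from the
    smoothed medians, which average the floor out; their boundaries are
    only accurate to the smoothing scale.

    ``sexes`` needs columns individual/sex with >= 1 F and >= 1 M.
    Returns a BED-like table (scaffold, start, end, region_class,
    female_med, male_med, female_raw, male_raw, n_windows) where the
    med columns are medians of smoothed values and the raw columns are
    pooled raw rates within the call.
    """
    sex_of = dict(zip(sexes["individual"], sexes["sex"]))
    females = [i for i, s in sex_of.items() if s == "F"]
    males = [i for i, s in sex_of.items() if s == "M"]
    if not females or not males:
        raise ValueError("need at least one female and one male with tracks")
    if tracks["smoothed"].isna().all():
        raise ValueError("tracks must be smoothed first (smooth_track)")

    calls = []
    for scaf, sub in tracks.groupby("scaffold"):
        piv = sub.pivot_table(index="start", columns="individual", values="smoothed")
        nsit = sub.pivot_table(index="start", columns="individual", values="n_sites")
        prop = sub.pivot_table(index="start", columns="individual", values="prop_het")
        het = prop * nsit
        starts = piv.index.to_numpy()
        fcols = [c for c in piv.columns if c in females]
        mcols = [c for c in piv.columns if c in males]
        fmed = piv[fcols].median(axis=1).to_numpy()
        mmed = piv[mcols].median(axis=1).to_numpy()
        fn = nsit[fcols].sum(axis=1).to_numpy()
        mn = nsit[mcols].sum(axis=1).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            fraw = het[fcols].sum(axis=1).to_numpy() / fn
            mraw = het[mcols].sum(axis=1).to_numpy() / mn
        width = int(np.median(sub["end"] - sub["start"]))
        ok = ~(np.isnan(fmed) | np.isnan(mmed))
        okr = ~(np.isnan(fraw) | np.isnan(mraw))

        def neo_rule(f, m, valid):
            return valid & (f >= fold_threshold * m) & (f >= min_female_het)

        def anc_rule(f, m, valid):
            # mirrored contrast; m = 0 windows fail the strict inequality
            return valid & (f < z_ratio_threshold * m)

        for rule, klass in ((neo_rule, "neo_suppressed"), (anc_rule, "ancestral_Z")):
            smoothed_flags = rule(fmed, mmed, ok)
            raw_flags = rule(fraw, mraw, okr)
            if klass == "neo_suppressed":
                candidates = [
                    (a, b) for a, b in _runs(raw_flags, min_run_windows, max_gap_windows)
                    if smoothed_flags[a : b + 1].any()
                ]
            else:
                candidates = _runs(smoothed_flags, min_run_windows, max_gap_windows)
            for a2, b2 in candidates:
                f_tot, m_tot = fn[a2 : b2 + 1].sum(), mn[a2 : b2 + 1].sum()
                calls.append({
                    "scaffold": scaf,
                    "start": int(starts[a2]),
                    "end": int(starts[b2]) + width,
                    "region_class": klass,
                    "female_med": float(np.median(fmed[a2 : b2 + 1])),
                    "male_med": float(np.median(mmed[a2 : b2 + 1])),
                    "female_raw": float((fraw * fn)[a2 : b2 + 1].sum() / f_tot),
                    "male_raw": float((mraw * mn)[a2 : b2 + 1].sum() / m_tot),
                    "n_windows": int(b2 - a2 + 1),
                })
    return pd.DataFrame(
        calls, columns=["scaffold", "start", "end", "region_class",
                        "female_med", "male_med", "female_raw",
                        "male_raw", "n_windows"],
    )


def gametologue_divergence(
    gm: GenotypeMatrix, region: pd.Series | dict, female_ids: list[str]
) -> float:
    """Neo-W/neo-Z divergence as heterozygous differences per 100 bp.

    Mean per-site heterozygous-call density across females within a called
    neo_suppressed region, scaled to differences per 100 bp; the
    denominator is each female's genotyped sites (variant and invariant)
    in the region.
    """
    if region["region_class"] != "neo_suppressed":
        raise ValueError("region must be a neo_suppressed call")
    if not female_ids:
        raise ValueError("need at least one female")
    mask = (
        (gm.sites["scaffold"] == region["scaffold"]).to_numpy()
        & (gm.sites["pos"].to_numpy() >= region["start"])
        & (gm.sites["pos"].to_numpy() < region["end"])
    )
    cols = [gm.samples.index(f) for f in female_ids]
    d = gm.dosage[np.ix_(np.flatnonzero(mask), cols)]
    n_called = (d != MISSING).sum(axis=0)
    if np.any(n_called == 0) or len(d) == 0:
        raise ValueError("zero genotyped sites in region for some female")
    dens = (d == 1).sum(axis=0) / n_called
    return float(dens.mean() * 100.0)


def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, sep="\t", index=False)


def write_region_bed(calls: pd.DataFrame, path) -> None:
    """Region calls as BED with the class in the name field."""
    with open(path, "w") as fh:
        for _, r in calls.iterrows():
            fh.write(f"{r['scaffold']}\t{r['start']}\t{r['end']}\t{r['region_class']}\n")


def read_region_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            rows.append({"scaffold": f[0], "start": int(f[1]), "end": int(f[2]),
                         "region_class": f[3] if len(f) > 3 else "region"})
    return pd.DataFrame(rows)
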