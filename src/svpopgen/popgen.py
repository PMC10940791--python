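"""Differentiation and genome-landscape statistics for two populations.

Implements the Weir & Cockerham (1984) variance-component FST estimator
for two populations and biallelic variants: per variant, the
among-population (a), among-individual-within-population (b) and
within-individual (c) components are computed from per-population sample
sizes, allele frequencies and observed heterozygosities; the per-variant
estimate is a/(a+b+c) and any aggregate (window, chromosome, genome) is
the weighted ratio of sums sum(a)/sum(a+b+c).

Also provides: sliding-window FST tracks (100-kb windows, 10-kb steps),
per-window variant density and base-pairs-covered tracks (non-overlapping
100-kb windows), genotype PCA on a frequency-normalized covariance
matrix, correlation between window tracks, and linkage-disequilibrium
decay as binned mean r^2 against physical distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GT_MISSING, GenotypeMatrix, require_two_populations

__all__ = [
    "FstComponents", "wc_fst_components", "wc_fst_per_variant", "weighted_fst",
    "sliding_window_fst", "variant_density_per_window", "bp_covered_per_window",
    "pca", "PCAResult", "window_track_correlation", "ld_decay",
]

WINDOW_SIZE = 100_000
WINDOW_STEP = 10_000


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

@dataclass
class FstComponents:
    """Per-variant variance components; fst = a / (a + b + c).

    ``defined`` is False where a population has fewer than two non-missing
    genotypes (the estimator is undefined) and the components are NaN.
    ``fst`` is NaN where undefined and 0 where the variant is monomorphic
    across both populations (a = b = c = 0).
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    fst: np.ndarray
    defined: np.ndarray
    monomorphic: np.ndarray


def wc_fst_components(matrix: np.ndarray, labels: Sequence[str]) -> FstComponents:
    """Vectorized two-population Weir-Cockerham components per variant.

    ``matrix`` is (n_samples, n_variants) alt-allele dosage with -1 for
    missing; missing individuals are excluded per variant.
    """
    labels = np.asarray(labels)
    pop_a, pop_b = require_two_populations(labels)
    g = np.asarray(matrix)
    out_shape = g.shape[1]

    def pop_stats(mask: np.ndarray):
        gp = g[mask]
        called = gp != GT_MISSING
        n = called.sum(axis=0).astype(float)                # individuals
        alt = np.where(called, gp, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
            h = np.where(called, gp == 1, False).sum(axis=0) / n
        return n, p, h

    n1, p1, h1 = pop_stats(labels == pop_a)
    n2, p2, h2 = pop_stats(labels == pop_b)

    defined = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)      # (r-1) = 1 divisor
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r
                                     - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0

    a = np.where(defined, a, np.nan)
    b = np.where(defined, b, np.nan)
    c = np.where(defined, c, np.nan)
    denom = a + b + c
    monomorphic = defined & (denom == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / denom
    fst = np.where(monomorphic, 0.0, fst)
    # components are zero for monomorphic sites; keep them that way
    a = np.where(monomorphic, 0.0, a)
    b = np.where(monomorphic, 0.0, b)
    c = np.where(monomorphic, 0.0, c)
    assert a.shape[0] == out_shape
    return FstComponents(a=a, b=b, c=c, fst=fst, defined=defined,
                         monomorphic=monomorphic)


def wc_fst_per_variant(genotypes: Sequence[int], labels: Sequence[str],
                       ) -> tuple[float, float, float, float]:
    """Single-variant convenience wrapper; returns (a, b, c, fst)."""
    g = np.asarray(genotypes).reshape(-1, 1)
    comp = wc_fst_components(g, labels)
    return float(comp.a[0]), float(comp.b[0]), float(comp.c[0]), float(comp.fst[0])


def weighted_fst(gm: GenotypeMatrix | None = None,
                 components: FstComponents | None = None,
                 mask: np.ndarray | None = None) -> float:
    """Ratio-of-sums FST over a scope (genome, chromosome or window).

    Pass either a GenotypeMatrix (components are computed) or precomputed
    components; ``mask`` restricts the scope.  Undefined variants are
    excluded; NaN is returned for an empty scope.
    """
    if components is None:
        if gm is None:
            raise ValueError("need a GenotypeMatrix or precomputed components")
        components = wc_fst_components(gm.matrix, gm.populations)
    use = components.defined.copy()
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)
    if not use.any():
        return float("nan")
    num = np.nansum(components.a[use])
    den = np.nansum((components.a + components.b + components.c)[use])
    return float("nan") if den == 0 else float(num / den)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def _window_starts(chrom_len: int, window: int, step: int) -> np.ndarray:
    n = max(1, -(-max(chrom_len - window, 0) // step) + 1)
    return np.arange(n) * step


def sliding_window_fst(gm: GenotypeMatrix,
                       window: int = WINDOW_SIZE, step: int = WINDOW_STEP,
                       chrom_lengths: Mapping[str, int] | None = None,
                       components: FstComponents | None = None) -> pd.DataFrame:
    """Weighted FST in sliding windows along each chromosome.

    Windows are [start, start+window) on 0-based coordinates; a variant at
    VCF position ``pos`` belongs to every window containing ``pos - 1``.
    Windows without variants are emitted with NaN FST.
    """
    import warnings
    if step > window:
        warnings.warn("step > window leaves gaps between windows")
    if components is None:
        components = wc_fst_components(gm.matrix, gm.populations)
    d = components.a + components.b + components.c
    pos0 = gm.variants["pos"].to_numpy() - 1
    chroms = gm.variants["chrom"].to_numpy()

    rows = []
    for chrom in pd.unique(chroms):
        cmask = chroms == chrom
        clen = (chrom_lengths[chrom] if chrom_lengths is not None
                else int(pos0[cmask].max()) + 1)
        for start in _window_starts(clen, window, step):
            wmask = cmask & (pos0 >= start) & (pos0 < start + window)
            use = wmask & components.defined
            num = np.nansum(components.a[use])
            den = np.nansum(d[use])
            rows.append({
                "chrom": chrom, "start": int(start), "end": int(start + window),
                "n_variants": int(wmask.sum()),
                "fst_num": num, "fst_den": den,
                "fst": num / den if den > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def variant_density_per_window(variants: pd.DataFrame, window: int = WINDOW_SIZE,
                               chrom_lengths: Mapping[str, int] | None = None,
                               ) -> pd.DataFrame:
    """Variant count per non-overlapping window (chrom/start/end/n_variants)."""
    pos0 = variants["pos"].to_numpy() - 1
    chroms = variants["chrom"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        cmask = chroms == chrom
        clen = (chrom_lengths[chrom] if chrom_lengths is not None
                else int(pos0[cmask].max()) + 1)
        idx = pos0[cmask] // window
        counts = np.bincount(idx.astype(int), minlength=-(-clen // window))
        for w, n in enumerate(counts):
            rows.append({"chrom": chrom, "start": w * window,
                         "end": (w + 1) * window, "n_variants": int(n)})
    return pd.DataFrame(rows)


def bp_covered_per_window(variants: pd.DataFrame, window: int = WINDOW_SIZE,
                          chrom_lengths: Mapping[str, int] | None = None,
                          overlap_union: bool = False) -> pd.DataFrame:
    """Base pairs covered by variants per non-overlapping window.

    Span variants (DEL/DUP/INV, or anything whose end exceeds its pos)
    contribute the intersection of their reference footprint with each
    window; point variants (INS, SNPs, point indels) contribute their full
    length to the window containing their position.  Contributions are
    summed by default; ``overlap_union=True`` instead unions the span
    footprints so overlapping variants are not double counted (point
    lengths are still added).  The per-window proportion is capped at 1.

    ``variants`` needs chrom/pos/length columns; ``end`` and ``svtype``
    are used when present.
    """
    chroms = variants["chrom"].to_numpy()
    pos0 = variants["pos"].to_numpy() - 1
    length = variants["length"].to_numpy()
    end = (variants["end"].to_numpy() if "end" in variants
           else variants["pos"].to_numpy())
    svtype = (variants["svtype"].to_numpy() if "svtype" in variants
              else np.array([None] * len(variants), dtype=object))
    is_span = np.array([t in ("DEL", "DUP", "INV") or (t is None and e > p)
                        for t, e, p in zip(svtype, end, variants["pos"].to_numpy())])

    rows = []
    for chrom in pd.unique(chroms):
        cmask = chroms == chrom
        clen = (chrom_lengths[chrom] if chrom_lengths is not None
                else int(end[cmask].max()))
        n_windows = -(-clen // window)
        covered = np.zeros(n_windows, dtype=float)
        span_intervals: dict[int, list[tuple[int, int]]] = {}
        for j in np.flatnonzero(cmask):
            if is_span[j]:
                s, e = int(pos0[j]), int(end[j])        # 0-based half-open
                w0, w1 = s // window, min((e - 1) // window, n_windows - 1)
                for w in range(w0, w1 + 1):
                    lo = max(s, w * window)
                    hi = min(e, (w + 1) * window)
                    if overlap_union:
                        span_intervals.setdefault(w, []).append((lo, hi))
                    else:
                        covered[w] += hi - lo
            else:
                w = min(int(pos0[j]) // window, n_windows - 1)
                covered[w] += float(length[j])
        if overlap_union:
            for w, ivals in span_intervals.items():
                ivals.sort()
                total, cur_lo, cur_hi = 0, *ivals[0]
                for lo, hi in ivals[1:]:
                    if lo > cur_hi:
                        total += cur_hi - cur_lo
                        cur_lo, cur_hi = lo, hi
                    else:
                        cur_hi = max(cur_hi, hi)
                total += cur_hi - cur_lo
                covered[w] += total
        for w in range(n_windows):
            rows.append({
                "chrom": chrom, "start": w * window, "end": (w + 1) * window,
                "bp_covered": covered[w],
                "bp_covered_fraction": min(covered[w] / window, 1.0),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray            # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray      # (n_samples, n_components), unit columns


def pca(gm: GenotypeMatrix | np.ndarray, n_components: int | None = None,
        ) -> PCAResult:
    """PCA of individuals on the frequency-normalized genotype covariance.

    Missing entries are mean-imputed per variant; columns are centered and
    scaled by sqrt(p(1-p)) where p is half the mean dosage (zero-variance
    columns dropped); the individual x individual covariance matrix is
    eigendecomposed.  Scores are eigenvectors scaled by sqrt(eigenvalue),
    with the deterministic sign convention that each eigenvector's first
    nonzero entry is positive.
    """
    g = gm.matrix if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    if g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("need >= 2 individuals and >= 2 variants")
    x = g.astype(float)
    x[x == GT_MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    # all-missing columns have no information at all
    keep = ~np.isnan(col_mean)
    x, col_mean = x[:, keep], col_mean[keep]
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    p_hat = col_mean / 2.0
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    keep = scale > 0
    if not keep.any():
        raise ValueError("all variant columns have zero variance")
    x = (x[:, keep] - col_mean[keep]) / scale[keep]
    cov = x @ x.T / x.shape[1]

    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    if n_components is None:
        n_components = min(g.shape) - 1
    eigvals, eigvecs = eigvals[:n_components], eigvecs[:, :n_components]
    for k in range(eigvecs.shape[1]):
        nz = np.flatnonzero(np.abs(eigvecs[:, k]) > 1e-12)
        if nz.size and eigvecs[nz[0], k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    total = np.clip(np.linalg.eigvalsh(cov), 0.0, None).sum()
    ratio = eigvals / total if total > 0 else np.zeros_like(eigvals)
    scores = eigvecs * np.sqrt(eigvals)[None, :]
    return PCAResult(scores=scores, explained_variance_ratio=ratio,
                     eigenvalues=eigvals, eigenvectors=eigvecs)


# ---------------------------------------------------------------------------
# track correlation and LD decay
# ---------------------------------------------------------------------------

def window_track_correlation(track_a: np.ndarray, track_b: np.ndarray,
                             ) -> tuple[float, float]:
    """Squared Pearson correlation between two aligned window tracks.

    Windows where either value is undefined (NaN) are dropped; fewer than
    three shared windows leaves the statistic undefined (NaN, NaN).
    The p-value is the usual t-transform of r.
    """
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must share the window grid")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a[ok], b[ok])
    return float(r ** 2), float(p)


def ld_decay(gm: GenotypeMatrix, max_dist: int = 1_000,
             bin_edges: Sequence[int] | None = None) -> pd.DataFrame:
    """Mean genotype-correlation r^2 binned by pairwise distance.

    All variant pairs on the same chromosome within ``max_dist`` bp are
    scored; r^2 is the squared Pearson correlation of dosages over
    individuals non-missing at both sites.  Pairs monomorphic in the
    shared individuals are skipped.
    """
    if bin_edges is None:
        bin_edges = np.linspace(0, max_dist, 11)
    bin_edges = np.asarray(bin_edges, dtype=float)
    sums = np.zeros(len(bin_edges) - 1)
    counts = np.zeros(len(bin_edges) - 1, dtype=int)

    chroms = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    g = gm.matrix
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        p = pos[idx]
        for ii, i in enumerate(idx):
            for jj in range(ii + 1, idx.size):
                j = idx[jj]
                d = p[jj] - p[ii]
                if d > max_dist:
                    break
                gi, gj = g[:, i].astype(float), g[:, j].astype(float)
                ok = (gi != GT_MISSING) & (gj != GT_MISSING)
                if ok.sum() < 3:
                    continue
                vi, vj = gi[ok], gj[ok]
                if vi.std() == 0 or vj.std() == 0:
                    continue
                r = np.corrcoef(vi, vj)[0, 1]
                k = np.searchsorted(bin_edges, d, side="right") - 1
                if 0 <= k < counts.size:
                    sums[k] += r ** 2
                    counts[k] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_lo": bin_edges[:-1], "bin_hi": bin_edges[1:],
        "mean_r2": mean_r2, "n_pairs": counts,
    })
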