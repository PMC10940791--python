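"""Outlier and candidate detection for two-population differentiation.

Two complementary scans per variant class:

* *outliers of differentiation* - variants simultaneously in the top 3%
  of the per-variant FST distribution (at or above the type-7 97th
  percentile) and with a Benjamini-Hochberg q-value below 0.01 in a
  two-sided Fisher exact test on per-population allelic counts;
* *RDA candidates* - variants whose loading on the single constrained
  axis of a redundancy analysis (genotypes regressed on the population
  factor) lies more than three standard deviations from the mean loading,
  capturing covarying small-effect loci that single-locus scans miss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GT_MISSING, GenotypeMatrix, require_two_populations
from .popgen import wc_fst_components

__all__ = [
    "fisher_allelic_test", "allele_count_table", "fisher_tests", "bh_adjust",
    "intersection_outliers", "rda_candidates", "RDAResult", "outlier_table",
]


def allele_count_table(genotypes: np.ndarray, labels: np.ndarray,
                       ) -> np.ndarray:
    """2x2 [[alt1, ref1], [alt2, ref2]] allele counts at one variant.

    Allele counts are twice the non-missing genotyped individuals,
    adjusted for missing data per population.
    """
    pop_a, pop_b = require_two_populations(labels)
    table = np.zeros((2, 2), dtype=np.int64)
    for row, pop in enumerate((pop_a, pop_b)):
        g = np.asarray(genotypes)[np.asarray(labels) == pop]
        g = g[g != GT_MISSING]
        alt = int(g.sum())
        table[row] = (alt, 2 * g.size - alt)
    return table


def fisher_allelic_test(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 allelic count table.

    Two-sided by summing hypergeometric probabilities not exceeding that
    of the observed table.  An empty margin (no alleles observed, or an
    allele absent everywhere) carries no information and yields p = 1.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fisher_tests(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant two-sided Fisher exact p over population allele counts."""
    return np.array([
        fisher_allelic_test(allele_count_table(gm.matrix[:, j], gm.populations))
        for j in range(gm.n_variants)
    ])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1, order preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def intersection_outliers(fst: np.ndarray, fisher_q: np.ndarray,
                          fst_quantile: float = 0.97,
                          q_thresh: float = 0.01) -> pd.DataFrame:
    """Flag FST-quantile outliers, Fisher outliers and their intersection.

    The FST cut is the linear-interpolation (type-7) sample quantile of
    the defined per-variant values; a variant is an FST outlier when its
    value is at or above that cut, a Fisher outlier when q < q_thresh, and
    an intersection outlier when both hold.
    """
    fst = np.asarray(fst, dtype=float)
    fisher_q = np.asarray(fisher_q, dtype=float)
    if fst.shape != fisher_q.shape:
        raise ValueError("fst and fisher_q must align")
    finite = np.isfinite(fst)
    cut = np.quantile(fst[finite], fst_quantile) if finite.any() else np.nan
    fst_outlier = finite & (fst >= cut)
    fisher_outlier = fisher_q < q_thresh
    return pd.DataFrame({
        "fst": fst, "fisher_q": fisher_q,
        "fst_outlier": fst_outlier,
        "fisher_outlier": fisher_outlier,
        "intersection_outlier": fst_outlier & fisher_outlier,
    })


@dataclass
class RDAResult:
    loadings: np.ndarray       # unit right-singular-vector weights per variant
    candidate: np.ndarray      # |loading - mean| > sd_mult * sd
    axis_scores: np.ndarray    # individual scores on the constrained axis
    sd_mult: float


def rda_candidates(gm: GenotypeMatrix, sd_mult: float = 3.0) -> RDAResult:
    """Single-factor redundancy analysis with the population as predictor.

    Missing genotypes are mean-imputed per variant and columns centered;
    the explanatory design is the centered population indicator; fitted
    values X (X'X)^-1 X' Y are decomposed by SVD and variant loadings are
    the weights of the single constrained axis (sign fixed so the
    largest-magnitude loading is positive).  Candidates are loadings more
    than ``sd_mult`` standard deviations from the mean loading.
    """
    pop_a, pop_b = require_two_populations(gm.populations)
    for pop in (pop_a, pop_b):
        if (gm.populations == pop).sum() < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
    y = gm.matrix.astype(float)
    y[y == GT_MISSING] = np.nan
    col_mean = np.nanmean(y, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(y))
    y[inds] = col_mean[inds[1]]
    y = y - y.mean(axis=0)

    x = (gm.populations == pop_b).astype(float)
    x = (x - x.mean()).reshape(-1, 1)
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    fitted = x @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    loadings = vt[0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
        u[:, 0] = -u[:, 0]
    axis_scores = u[:, 0] * s[0]
    dev = np.abs(loadings - loadings.mean())
    candidate = dev > sd_mult * loadings.std()
    return RDAResult(loadings=loadings, candidate=candidate,
                     axis_scores=axis_scores, sd_mult=sd_mult)


def outlier_table(gm: GenotypeMatrix, fst_quantile: float = 0.97,
                  q_thresh: float = 0.01, sd_mult: float = 3.0) -> pd.DataFrame:
    """Full per-variant outlier table: FST, Fisher p/q, RDA loading, flags.

    The quantile cut is taken within the supplied matrix, so run this
    separately per variant class to match per-class outlier counting.
    """
    comp = wc_fst_components(gm.matrix, gm.populations)
    p = fisher_tests(gm)
    q = bh_adjust(p)
    flags = intersection_outliers(comp.fst, q, fst_quantile, q_thresh)
    rda = rda_candidates(gm, sd_mult)
    out = gm.variants[["chrom", "pos", "id", "vclass"]].copy()
    out["fst"] = comp.fst
    out["fisher_p"] = p
    out["fisher_q"] = q
    out["rda_loading"] = rda.loadings
    out["fst_outlier"] = flags["fst_outlier"].to_numpy()
    out["fisher_outlier"] = flags["fisher_outlier"].to_numpy()
    out["intersection_outlier"] = flags["intersection_outlier"].to_numpy()
    out["rda_candidate"] = rda.candidate
    return out
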