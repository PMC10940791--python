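"""Gene proximity, feature overlap and GO enrichment.

Links variants of interest to nearby gene models (within a 10-kb gap,
either side, overlap included), counts overlap of SV sets with arbitrary
feature tracks (repeats, syntenic regions) within a 100-bp window, and
tests GO-term over-representation of the resulting gene sets against a
background gene list with a one-sided hypergeometric test and
Benjamini-Hochberg correction (significant: corrected p < 0.1, biological
process terms only).

Distances are measured between 1-based closed coordinate spans: a variant
ending at position e and a gene starting at position s are "within w" when
s - e <= w, matching the window semantics of the usual BED tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .io_formats import GeneModel
from .outliers import bh_adjust

__all__ = [
    "variant_span", "genes_near_variants", "feature_overlap_fractions",
    "go_enrichment", "propagate_go",
]


def variant_span(variant) -> tuple[str, int, int]:
    """0-based half-open footprint of a variant-like object.

    DEL/DUP/INV use their full reference span; insertions, SNPs and
    anything without an extent use the single anchor base.  Accepts
    SVCall/MergedSV-like objects (chrom/pos/end/svtype attributes) or
    mapping rows with those keys.
    """
    get = variant.get if hasattr(variant, "get") else lambda k, d=None: getattr(variant, k, d)
    chrom = get("chrom")
    pos = int(get("pos"))
    end = get("end")
    svtype = get("svtype")
    if svtype == "INS" or end is None or int(end) <= pos:
        return chrom, pos - 1, pos
    return chrom, pos - 1, int(end)


def _gap_le(a: tuple[int, int], b: tuple[int, int], w: int) -> bool:
    """True when two 0-based half-open spans overlap or sit within w bp."""
    return a[0] < b[1] + w and b[0] < a[1] + w


def genes_near_variants(variants: Iterable, genes: Sequence[GeneModel],
                        window: int = 10_000,
                        ) -> tuple[set[str], list[tuple[int, str]]]:
    """Genes within ``window`` bp of any variant (overlap counts as 0).

    Returns the de-duplicated gene-id set and (variant index, gene_id)
    pairs.  Uses an interval index; equivalent to the all-pairs scan.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - window, g.end + window, g.gene_id)
    gene_set: set[str] = set()
    pairs: list[tuple[int, str]] = []
    for i, v in enumerate(variants):
        chrom, start, stop = variant_span(v)
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(start, stop):
            gene_set.add(hit.data)
            pairs.append((i, hit.data))
    return gene_set, pairs


def feature_overlap_fractions(sv_sets: Mapping[str, Sequence],
                              tracks: Mapping[str, Sequence[tuple[str, int, int]]],
                              window: int = 100) -> pd.DataFrame:
    """Fraction of each SV set overlapping each feature track (gap <= window).

    ``tracks`` holds BED-style (chrom, start, end) intervals, 0-based
    half-open.  With two or more tracks an ``all`` column reports the
    fraction overlapping every track at once.  Typical use compares
    retained vs filtered-out SVs against repeat and syntenic tracks.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for tname, ivals in tracks.items():
        per_chrom: dict[str, IntervalTree] = {}
        for chrom, start, end in ivals:
            per_chrom.setdefault(chrom, IntervalTree()).addi(
                start - window, end + window)
        trees[tname] = per_chrom

    rows = {}
    track_names = list(tracks)
    for sname, svs in sv_sets.items():
        svs = list(svs)
        hits = {t: 0 for t in track_names}
        hits_all = 0
        for v in svs:
            chrom, start, stop = variant_span(v)
            v_hits = []
            for t in track_names:
                tree = trees[t].get(chrom)
                hit = bool(tree is not None and tree.overlap(start, stop))
                v_hits.append(hit)
                hits[t] += hit
            hits_all += all(v_hits)
        n = len(svs)
        row = {t: (hits[t] / n if n else 0.0) for t in track_names}
        if len(track_names) > 1:
            row["all"] = hits_all / n if n else 0.0
        rows[sname] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def go_enrichment(study_genes: Iterable[str], background_genes: Iterable[str],
                  gene2go: Mapping[str, set[str]],
                  go_namespace: Mapping[str, str] | None = None,
                  alpha: float = 0.1,
                  namespace: str = "biological_process") -> pd.DataFrame:
    """GO over-representation of a study gene set against a background.

    Per GO term with at least one study gene, the one-sided hypergeometric
    upper-tail p of drawing that many term genes in the study set;
    Benjamini-Hochberg across tested terms; a term is significant when its
    corrected p falls below ``alpha`` and its namespace matches (terms
    with no recorded namespace default to biological_process).
    """
    study = set(study_genes)
    background = set(background_genes)
    offenders = study - background
    if offenders:
        raise ValueError(f"study genes not in background: {sorted(offenders)[:10]}")

    term_background: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        for term in gene2go.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    n_bg, n_study = len(background), len(study)
    rows = []
    for term, k in sorted(term_study.items()):
        big_k = term_background[term]
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_study))
        rows.append({
            "go_id": term,
            "namespace": (go_namespace or {}).get(term, "biological_process"),
            "study_count": k, "study_size": n_study,
            "background_count": big_k, "background_size": n_bg,
            "fold_enrichment": (k / n_study) / (big_k / n_bg),
            "p": p,
        })
    result = pd.DataFrame(rows)
    if result.empty:
        result["q"] = []
        result["significant"] = []
        return result
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = (result["q"] < alpha) & (result["namespace"] == namespace)
    return result.sort_values("p", kind="stable").reset_index(drop=True)


def propagate_go(gene2go: Mapping[str, set[str]],
                 parents: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Optionally propagate annotations up a child -> parents term map."""
    def ancestors(term: str) -> set[str]:
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for p in parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    return {gene: set(terms) | set().union(*(ancestors(t) for t in terms))
            for gene, terms in gene2go.items()}
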