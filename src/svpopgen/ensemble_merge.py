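"""Ensemble merging of structural-variant callsets.

Multiple callers (and, downstream, two sequencing platforms) emit partially
overlapping SV calls with jittered breakpoints and lengths.  This module
clusters calls that refer to the same underlying event using a
minimum-spanning-forest procedure over a mutual size-scaled distance, then
applies the support (>= 2 tools) and length (>= 50 bp) filters that define
the retained union callset.

The distance between two calls is Euclidean in (start, length) space, and
two calls may only join when that distance is at most
``max(min_dist_floor, max_dist_linear * min(len_a, len_b))`` - the *mutual*
rule: the smaller variant's threshold must be satisfied, so both variants'
constraints hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import PLATFORMS, SVTYPES, SVCall

__all__ = [
    "MergeParams", "MergedSV", "pair_distance", "mergeable", "merge_callsets",
    "filter_merged", "cross_platform_merge", "platform_table",
    "summarize_platform_fractions", "support_table",
]


@dataclass(frozen=True)
class MergeParams:
    """Tuning knobs for the mutual-distance merge.

    ``max_dist_linear`` scales the allowed distance with the smaller
    variant's length; ``min_dist_floor`` keeps the threshold from collapsing
    to ~0 bp for tiny SVs.  ``normalize_type`` lets duplications match
    insertions (used at the cross-platform step, where the two platforms
    report the same event under different types).  ``strict_mutual``
    additionally requires every cross-component pair to satisfy the
    criterion before a union-find join.
    """

    max_dist_linear: float = 0.25
    min_dist_floor: float = 30.0
    allow_intrasample: bool = False
    normalize_type: bool = False
    strict_mutual: bool = False
    min_support: int = 2
    min_length: int = 50

    def __post_init__(self) -> None:
        if self.max_dist_linear <= 0:
            raise ValueError("max_dist_linear must be > 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass
class MergedSV:
    """A cluster of SVCalls judged to describe one underlying SV."""

    chrom: str
    pos: int
    end: int
    svtype: str
    length: int
    members: list[SVCall]
    support_callers: set[str]
    support_platforms: set[str]

    @property
    def n_supporting_tools(self) -> int:
        return len(self.support_callers)

    @property
    def platform_label(self) -> str:
        return "+".join(p for p in PLATFORMS if p in self.support_platforms)


def pair_distance(a: SVCall, b: SVCall) -> float:
    """Euclidean distance in (start position, length) space; same chrom only."""
    if a.chrom != b.chrom:
        raise ValueError("pair_distance requires calls on the same chromosome")
    return math.hypot(a.pos - b.pos, a.length - b.length)


def _type_key(svtype: str, normalize: bool) -> str:
    return "INS" if (normalize and svtype == "DUP") else svtype


def _threshold(a: SVCall, b: SVCall, params: MergeParams) -> float:
    return max(params.min_dist_floor,
               params.max_dist_linear * min(a.length, b.length))


def mergeable(a: SVCall, b: SVCall, params: MergeParams) -> bool:
    """True iff a and b may be clustered under the mutual-distance rule."""
    if a.chrom != b.chrom:
        return False
    if _type_key(a.svtype, params.normalize_type) != _type_key(b.svtype, params.normalize_type):
        return False
    return pair_distance(a, b) <= _threshold(a, b, params)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _call_sort_key(c: SVCall) -> tuple:
    return (c.chrom, c.pos, c.caller_id, c.sample_id or "", c.length, c.svtype)


def merge_callsets(callsets: Sequence[Sequence[SVCall]],
                   params: MergeParams | None = None) -> list[MergedSV]:
    """Cluster calls across callsets by the minimum-spanning-forest procedure.

    All mergeable pairs are enumerated, sorted by ascending distance (ties
    broken on the calls' own sort keys so the result is independent of input
    ordering), and joined with union-find unless the two components already
    share a caller (or a sample, when ``allow_intrasample`` is off), or -
    with ``strict_mutual`` - some cross-component pair violates the
    criterion.
    """
    if params is None:
        params = MergeParams()
    calls: list[SVCall] = [c for cs in callsets for c in cs]
    order = sorted(range(len(calls)), key=lambda i: _call_sort_key(calls[i]))
    calls = [calls[i] for i in order]
    n = len(calls)

    # candidate pairs per (chrom, normalized type), pruned by position
    groups: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(calls):
        groups.setdefault((c.chrom, _type_key(c.svtype, params.normalize_type)), []).append(i)

    edges: list[tuple[float, tuple, tuple, int, int]] = []
    for idxs in groups.values():
        idxs = sorted(idxs, key=lambda i: calls[i].pos)
        for a_rank, i in enumerate(idxs):
            ci = calls[i]
            bound = max(params.min_dist_floor, params.max_dist_linear * ci.length)
            for j in idxs[a_rank + 1:]:
                cj = calls[j]
                if cj.pos - ci.pos > bound:
                    break
                if mergeable(ci, cj, params):
                    ka, kb = sorted((_call_sort_key(ci), _call_sort_key(cj)))
                    edges.append((pair_distance(ci, cj), ka, kb, i, j))
    edges.sort(key=lambda e: e[:3])

    uf = _UnionFind(n)
    callers: list[set[str]] = [{c.caller_id} for c in calls]
    samples: list[set[str]] = [{c.sample_id} if c.sample_id else set() for c in calls]
    members: list[list[int]] = [[i] for i in range(n)]
    for _, _, _, i, j in edges:
        ri, rj = uf.find(i), uf.find(j)
        if ri == rj:
            continue
        if callers[ri] & callers[rj]:
            continue
        if not params.allow_intrasample and samples[ri] & samples[rj]:
            continue
        if params.strict_mutual and not all(
                mergeable(calls[a], calls[b], params)
                for a in members[ri] for b in members[rj]):
            continue
        uf.union(ri, rj)
        root = uf.find(ri)
        other = rj if root == ri else ri
        callers[root] = callers[ri] | callers[rj]
        samples[root] = samples[ri] | samples[rj]
        members[root] = members[ri] + members[rj]

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)

    merged = [_make_merged([calls[i] for i in idxs]) for idxs in clusters.values()]
    merged.sort(key=lambda m: (m.chrom, m.pos, m.svtype, m.length))
    return merged


def _make_merged(group: list[SVCall]) -> MergedSV:
    if len(group) == 1:
        rep = group[0]
    else:
        # medoid: minimum summed distance; ties -> smallest (pos, caller_id)
        best = None
        for c in group:
            total = sum(pair_distance(c, o) for o in group)
            key = (total, c.pos, c.caller_id)
            if best is None or key < best[0]:
                best = (key, c)
        rep = best[1]
    return MergedSV(
        chrom=rep.chrom, pos=rep.pos, end=rep.end, svtype=rep.svtype,
        length=rep.length, members=list(group),
        support_callers={c.caller_id for c in group},
        support_platforms={c.platform for c in group},
    )


def filter_merged(merged: Iterable[MergedSV], params: MergeParams | None = None,
                  ) -> tuple[list[MergedSV], pd.DataFrame]:
    """Apply the >=min_support tools and >=min_length bp filters.

    Returns the retained clusters plus a caller-combination x SV-type
    contingency table of the retained set (rows: sorted "A+B" caller
    combinations; columns: DEL/DUP/INS/INV plus a total).
    """
    if params is None:
        params = MergeParams()
    kept = [m for m in merged
            if m.n_supporting_tools >= params.min_support
            and m.length >= params.min_length]
    return kept, support_table(kept)


def support_table(merged: Iterable[MergedSV]) -> pd.DataFrame:
    rows: dict[str, dict[str, int]] = {}
    for m in merged:
        combo = "+".join(sorted(m.support_callers))
        row = rows.setdefault(combo, {t: 0 for t in SVTYPES})
        row[m.svtype] += 1
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(SVTYPES)).fillna(0).astype(int)
    table = table.sort_index()
    table["total"] = table.sum(axis=1)
    return table


def _as_call(m: MergedSV, platform: str) -> SVCall:
    """Re-wrap a platform-level cluster as a pseudo-call for the final merge."""
    return SVCall(chrom=m.chrom, pos=m.pos, end=m.end, svtype=m.svtype,
                  length=m.length, caller_id=platform, platform=platform)


def cross_platform_merge(sr_merged: Sequence[MergedSV],
                         lr_merged: Sequence[MergedSV],
                         params: MergeParams | None = None) -> list[MergedSV]:
    """Combine the filtered SR and LR sets into one union callset.

    Runs the same spanning-forest procedure with type normalization on
    (DUP matches INS), treating each platform set as one pseudo-caller so
    that two clusters from the same platform never merge with each other.
    Output clusters carry SR / LR / SR+LR provenance labels.
    """
    if params is None:
        params = MergeParams()
    params = MergeParams(
        max_dist_linear=params.max_dist_linear,
        min_dist_floor=params.min_dist_floor,
        allow_intrasample=params.allow_intrasample,
        normalize_type=True,
        strict_mutual=params.strict_mutual,
        min_support=1,
        min_length=params.min_length,
    )
    sr_calls = [_as_call(m, "SR") for m in sr_merged]
    lr_calls = [_as_call(m, "LR") for m in lr_merged]
    return merge_callsets([sr_calls, lr_calls], params)


def platform_table(merged: Iterable[MergedSV]) -> pd.DataFrame:
    """Counts by platform provenance x SV type (SR / LR / SR+LR rows)."""
    rows = {label: {t: 0 for t in SVTYPES} for label in ("SR", "LR", "SR+LR")}
    for m in merged:
        rows[m.platform_label][m.svtype] += 1
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(SVTYPES))
    table["total"] = table.sum(axis=1)
    return table


def summarize_platform_fractions(table: pd.DataFrame,
                                 decimals: int | None = 1,
                                 ) -> dict[str, float | None]:
    """Summary fractions of a platform-provenance count table.

    Expects rows SR, LR, SR+LR and columns per SV type plus ``total``.
    Returns percentages (rounded to ``decimals``, or unrounded when None):
    share of the union that is LR-only / SR-only / both, the per-type
    platform-exclusivity percentages, and the fraction of the SR set also
    supported by LR (SR+LR divided by SR set size).  Zero denominators
    yield None rather than NaN.
    """

    def pct(num: float, den: float) -> float | None:
        if den == 0:
            return None
        value = 100.0 * num / den
        return value if decimals is None else round(value, decimals)

    union = float(table["total"].sum())
    out: dict[str, float | None] = {
        "lr_only_pct": pct(table.at["LR", "total"], union),
        "sr_only_pct": pct(table.at["SR", "total"], union),
        "sr_lr_pct": pct(table.at["SR+LR", "total"], union),
    }
    sr_set = table.at["SR", "total"] + table.at["SR+LR", "total"]
    out["sr_supported_by_lr_pct"] = pct(table.at["SR+LR", "total"], sr_set)
    for t in SVTYPES:
        col_total = float(table[t].sum())
        out[f"{t.lower()}_lr_only_pct"] = pct(table.at["LR", t], col_total)
        out[f"{t.lower()}_sr_only_pct"] = pct(table.at["SR", t], col_total)
    return out
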