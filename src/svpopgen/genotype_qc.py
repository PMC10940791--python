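"""Genotype quality control, SV matching and genotype concordance.

Three stages between raw genotyped VCFs and the analysis-ready matrix:

1. per-sample genotype masking - a genotype becomes missing ("./.") when
   it lacks read support (DP < 4), has low quality (GQ < 5), implausibly
   high depth (DP >= 80, five times the expected coverage) or carries the
   caller's sentinel quality value (GQ = 127 for the SNP/indel caller,
   GQ = 256 for the graph genotyper), which flags degenerate calls;
2. population-level filters - keep variants with alt-allele frequency in
   [0.05, 0.95] and at most 50% missing genotypes;
3. bookkeeping that the genotyping step loses - matching genotyped SVs
   back to the putative merged SVs they came from (to recover type,
   length and platform provenance), and measuring concordance between a
   consensus of per-caller genotypes and the graph genotypes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .ensemble_merge import MergedSV
from .io_formats import GT_MISSING, VariantRecord

__all__ = [
    "QCParams", "ConcordanceRecord", "mask_genotypes", "population_filter",
    "match_genotyped_to_putative", "MatchResult", "genotype_concordance",
]

#: sentinel GQ values that flag degenerate calls, per genotype source
DEFAULT_SENTINELS = {"snp_caller": 127, "graph": 256}


@dataclass(frozen=True)
class QCParams:
    min_dp: int = 4
    min_gq: int = 5
    max_dp: int = 80
    sentinel_gq: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SENTINELS))
    maf_min: float = 0.05
    maf_max: float = 0.95
    max_missing_frac: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < self.maf_max <= 1.0:
            raise ValueError("require 0 <= maf_min < maf_max <= 1")


def mask_genotypes(records: Sequence[VariantRecord], params: QCParams | None = None,
                   source: str = "graph",
                   ) -> tuple[list[VariantRecord], dict[str, int]]:
    """Set genotypes to missing where DP/GQ fail the per-sample criteria.

    A genotype is masked iff DP < min_dp, GQ < min_gq, DP >= max_dp, or GQ
    equals the source's sentinel value.  Absent DP/GQ (coded -1) fail the
    minima and therefore mask.  Input records are not modified; masking is
    idempotent.  Returns (masked records, per-reason mask counts).
    """
    if params is None:
        params = QCParams()
    if source not in params.sentinel_gq:
        raise ValueError(f"unknown genotype source {source!r}; "
                         f"known: {sorted(params.sentinel_gq)}")
    sentinel = params.sentinel_gq[source]
    report = Counter(low_dp=0, low_gq=0, high_dp=0, sentinel_gq=0, masked=0)
    out = []
    for r in records:
        r = r.copy()
        called = r.genotypes != GT_MISSING
        low_dp = r.dp < params.min_dp
        low_gq = r.gq < params.min_gq
        high_dp = r.dp >= params.max_dp
        sent = r.gq == sentinel
        fail = low_dp | low_gq | high_dp | sent
        report["low_dp"] += int((called & low_dp).sum())
        report["low_gq"] += int((called & low_gq).sum())
        report["high_dp"] += int((called & high_dp).sum())
        report["sentinel_gq"] += int((called & sent).sum())
        report["masked"] += int((called & fail).sum())
        r.genotypes = np.where(fail, GT_MISSING, r.genotypes).astype(np.int8)
        out.append(r)
    return out, dict(report)


def population_filter(records: Sequence[VariantRecord],
                      params: QCParams | None = None,
                      ) -> tuple[list[VariantRecord], dict[str, int]]:
    """Keep variants with MAF in [maf_min, maf_max] and tolerable missingness.

    The alt-allele frequency is computed over non-missing genotypes only; a
    variant where every genotype is missing counts as a missingness
    failure (its frequency is undefined, which is not an error).  The
    removal tallies plus the kept count always sum to the input count.
    """
    if params is None:
        params = QCParams()
    kept: list[VariantRecord] = []
    report = Counter(kept=0, maf_fail=0, missing_fail=0, both_fail=0)
    for r in records:
        called = r.genotypes != GT_MISSING
        n_called = int(called.sum())
        missing_frac = 1.0 - n_called / r.genotypes.size
        miss_fail = missing_frac > params.max_missing_frac
        if n_called == 0:
            maf_fail = False       # frequency undefined; removed via missingness
        else:
            freq = float(r.genotypes[called].sum()) / (2.0 * n_called)
            maf_fail = not (params.maf_min <= freq <= params.maf_max)
        if maf_fail and miss_fail:
            report["both_fail"] += 1
        elif maf_fail:
            report["maf_fail"] += 1
        elif miss_fail:
            report["missing_fail"] += 1
        else:
            report["kept"] += 1
            kept.append(r)
    return kept, dict(report)


# ---------------------------------------------------------------------------
# matching genotyped SVs back to putative merged SVs
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    matches: list[tuple[int, int, float]]      # (genotyped idx, putative idx, distance)
    unmatched_genotyped: list[int]
    unmatched_putative: list[int]


def match_genotyped_to_putative(genotyped: Sequence[VariantRecord],
                                putative: Sequence[MergedSV],
                                pos_tol: int = 50,
                                len_tol_frac: float = 0.25) -> MatchResult:
    """Greedy best matching of genotyped SVs to known putative SVs.

    Candidates share a chromosome, differ in position by at most
    ``pos_tol`` bp and in allele length by at most ``len_tol_frac``
    relative to the longer of the two.  Candidate pairs are consumed in
    ascending (position, length) Euclidean distance; each putative SV and
    each genotyped record is used at most once.
    """
    candidates: list[tuple[float, int, int]] = []
    by_chrom: dict[str, list[int]] = {}
    for j, m in enumerate(putative):
        by_chrom.setdefault(m.chrom, []).append(j)
    for i, r in enumerate(genotyped):
        glen = r.length or 1
        for j in by_chrom.get(r.chrom, ()):
            m = putative[j]
            dpos = abs(r.pos - m.pos)
            if dpos > pos_tol:
                continue
            if abs(glen - m.length) > len_tol_frac * max(glen, m.length):
                continue
            candidates.append((math.hypot(dpos, glen - m.length), i, j))
    candidates.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for d, i, j in candidates:
        if i in used_g or j in used_p:
            continue
        used_g.add(i)
        used_p.add(j)
        matches.append((i, j, d))
    return MatchResult(
        matches=matches,
        unmatched_genotyped=[i for i in range(len(genotyped)) if i not in used_g],
        unmatched_putative=[j for j in range(len(putative)) if j not in used_p],
    )


# ---------------------------------------------------------------------------
# genotype concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceRecord:
    sv_id: str
    sample_id: str
    caller_genotypes: tuple[int, ...]
    consensus: int | None
    graph_genotype: int
    label: str       # concordant / discordant / no_consensus / not_evaluable


def _consensus(votes: list[int]) -> int | None:
    """Modal genotype if shared by >= 2 non-missing votes, else None."""
    counts = Counter(v for v in votes if v != GT_MISSING)
    if not counts:
        return None
    top, n = counts.most_common(1)[0]
    return top if n >= 2 else None


def genotype_concordance(caller_tables: Mapping[str, pd.DataFrame],
                         graph_table: pd.DataFrame,
                         samples: Sequence[str] | None = None,
                         sv_platform: Mapping[str, str] | None = None,
                         ) -> tuple[list[ConcordanceRecord], dict[str, float | None]]:
    """Compare consensus caller genotypes against graph genotypes.

    ``caller_tables`` maps caller name -> DataFrame indexed by sv_id with
    sample columns holding genotype codes (0/1/2, -1 missing); the graph
    table has the same layout.  A missing caller genotype does not vote,
    and a sample absent from a caller's table means the caller abstains.
    The consensus exists when >= 2 non-missing votes agree.  A record is
    not evaluable when the graph genotype is missing.

    Returns all records plus summary concordance rates (concordant over
    concordant+discordant), overall and per platform when ``sv_platform``
    labels each SV.
    """
    if len(caller_tables) < 2:
        raise ValueError("need >= 2 caller genotype tables")
    if samples is None:
        samples = list(graph_table.columns)
    records: list[ConcordanceRecord] = []
    for sv_id in graph_table.index:
        for sample in samples:
            votes = []
            for table in caller_tables.values():
                if sv_id in table.index and sample in table.columns:
                    votes.append(int(table.at[sv_id, sample]))
                else:
                    votes.append(GT_MISSING)
            graph_gt = (int(graph_table.at[sv_id, sample])
                        if sample in graph_table.columns else GT_MISSING)
            cons = _consensus(votes)
            if graph_gt == GT_MISSING:
                label = "not_evaluable"
            elif cons is None:
                label = "no_consensus"
            elif cons == graph_gt:
                label = "concordant"
            else:
                label = "discordant"
            records.append(ConcordanceRecord(
                sv_id=str(sv_id), sample_id=str(sample),
                caller_genotypes=tuple(votes), consensus=cons,
                graph_genotype=graph_gt, label=label))

    def rate(recs: list[ConcordanceRecord]) -> float | None:
        conc = sum(r.label == "concordant" for r in recs)
        disc = sum(r.label == "discordant" for r in recs)
        return None if conc + disc == 0 else conc / (conc + disc)

    summary: dict[str, float | None] = {"overall": rate(records)}
    if sv_platform is not None:
        for plat in sorted(set(sv_platform.values())):
            summary[plat] = rate([r for r in records
                                  if sv_platform.get(r.sv_id) == plat])
    return records, summary
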