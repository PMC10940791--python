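"""Readers, writers and coordinate conventions shared by the whole pipeline.

Variants live in VCF files (1-based, inclusive END); gene models and
feature tracks live in BED files (0-based, half-open).  Everything
downstream of the parsers works with the types defined here: py:`SVCall`
for raw per-caller structural-variant records, :py:`VariantRecord` for
genotyped multi-sample records, and :py:`GeneModel` for annotation
intervals.

Conventions
-----------
* ``SVCall.pos``/``SVCall.end`` keep the VCF convention (1-based,
  inclusive); for insertions ``end == pos`` because the event occupies a
  single reference anchor point.
* Internally, interval arithmetic is done on 0-based half-open spans via
  :func:`vcf_to_interval` / :func:`interval_to_vcf`, which are mutually
  inverse.
* Variant classes partition by allele-length difference: 0 -> SNP,
  1..49 -> small indel, >= 50 -> SV.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

SVTYPES = ("DEL", "DUP", "INS", "INV")
PLATFORMS = ("SR", "LR")

#: genotype codes used everywhere: number of alt alleles, -1 for missing
GT_MISSING = -1
SV_MIN_LENGTH = 50  # smaller events are small indels, not SVs


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def vcf_to_interval(pos: int, end: int) -> tuple[int, int]:
    """1-based inclusive [pos, end] -> 0-based half-open [start, stop)."""
    return pos - 1, end


def interval_to_vcf(start: int, stop: int) -> tuple[int, int]:
    """0-based half-open [start, stop) -> 1-based inclusive [pos, end]."""
    return start + 1, stop


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVCall:
    """A single structural-variant call from one caller on one platform."""

    chrom: str
    pos: int            # 1-based start (VCF convention)
    end: int            # 1-based inclusive end; == pos for INS
    svtype: str         # DEL / DUP / INS / INV
    length: int         # bp; inserted length for INS, span length otherwise
    caller_id: str
    platform: str       # SR or LR
    alt_seq: str | None = None
    sample_id: str | None = None
    precise: bool = True

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.svtype != "INS" and self.end < self.pos:
            raise ValueError(f"end {self.end} < pos {self.pos} for {self.svtype}")

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference footprint (a point for INS)."""
        if self.svtype == "INS":
            return self.pos - 1, self.pos
        return vcf_to_interval(self.pos, self.end)


@dataclass
class VariantRecord:
    """One multi-sample genotyped variant (SV, SNP or small indel)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str                      # SV / SNP / INDEL
    genotypes: np.ndarray                   # int8, alt-allele dose, -1 missing
    dp: np.ndarray                          # per-sample read depth, -1 missing
    gq: np.ndarray                          # per-sample genotype quality, -1 missing
    id: str | None = None
    length: int | None = None               # allele length (|SVLEN| for SVs)
    end: int | None = None
    svtype: str | None = None

    def copy(self) -> "VariantRecord":
        return replace(
            self,
            genotypes=self.genotypes.copy(),
            dp=self.dp.copy(),
            gq=self.gq.copy(),
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (0-based half-open) with optional GO annotations."""

    chrom: str
    start: int
    end: int
    gene_id: str
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


def classify_variant(ref: str, alt: str) -> str:
    """SNP / INDEL / SV partition by allele-length difference."""
    diff = abs(len(alt) - len(ref))
    if diff == 0:
        if len(ref) == 1:
            return "SNP"
        raise ValueError(f"cannot classify equal-length alleles {ref!r}/{alt!r}")
    return "INDEL" if diff < SV_MIN_LENGTH else "SV"


# ---------------------------------------------------------------------------
# SV VCF reading / writing
# ---------------------------------------------------------------------------

@dataclass
class SVReadResult:
    """Calls read from one VCF plus bookkeeping on records dropped."""

    calls: list[SVCall]
    n_dropped_type: int = 0     # SVTYPE outside DEL/DUP/INS/INV (e.g. BND)
    n_skipped: int = 0          # length not reconstructable

    def __iter__(self) -> Iterator[SVCall]:
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def read_sv_vcf(path: str | Path, caller_id: str, platform: str) -> SVReadResult:
    """Read one caller's SV VCF into :class:`SVCall` records.

    Records whose SVTYPE is outside the four-type alphabet (e.g. BND) are
    dropped and counted.  Length is taken from |SVLEN| when present, else
    from explicit alleles, else from END - POS + 1; records where none of
    those work are skipped with a warning.
    """
    result = SVReadResult(calls=[])
    for v in VCF(str(path)):
        svtype = v.INFO.get("SVTYPE")
        alt = v.ALT[0] if v.ALT else ""
        symbolic = alt.startswith("<")
        if svtype is None and not symbolic and alt:
            diff = abs(len(alt) - len(v.REF))
            if diff >= 1:
                svtype = "INS" if len(alt) > len(v.REF) else "DEL"
        if svtype not in SVTYPES:
            result.n_dropped_type += 1
            continue

        svlen = v.INFO.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        length: int | None = None
        if svlen is not None:
            length = abs(int(svlen))
        elif not symbolic and alt:
            length = abs(len(alt) - len(v.REF))
        else:
            info_end = v.INFO.get("END")
            if info_end is not None:
                length = int(info_end) - v.POS + 1
        if length is None or length < 1:
            result.n_skipped += 1
            logger.warning("skipping %s:%s (%s): no reconstructable length",
                           v.CHROM, v.POS, caller_id)
            continue

        if svtype == "INS":
            end = v.POS
        else:
            info_end = v.INFO.get("END")
            end = int(info_end) if info_end is not None else v.POS + length - 1

        seq = v.INFO.get("SEQ")
        if seq is None and not symbolic and len(alt) > len(v.REF):
            seq = alt[len(v.REF):]
        result.calls.append(SVCall(
            chrom=v.CHROM, pos=v.POS, end=end, svtype=svtype, length=length,
            caller_id=caller_id, platform=platform, alt_seq=seq,
            sample_id=v.INFO.get("SAMPLE"),
            precise="IMPRECISE" not in dict(v.INFO),
        ))
    if result.n_dropped_type:
        logger.info("%s: dropped %d records with unsupported SVTYPE",
                    path, result.n_dropped_type)
    return result


def _sv_info_fields(obj) -> list[str]:
    """INFO column for an SVCall or MergedSV-like object."""
    fields = [f"SVTYPE={obj.svtype}"]
    svlen = -obj.length if obj.svtype == "DEL" else obj.length
    fields.append(f"SVLEN={svlen}")
    if obj.svtype != "INS":
        fields.append(f"END={obj.end}")
    callers = getattr(obj, "support_callers", None)
    if callers is not None:
        fields.append("SUPP_CALLERS=" + ",".join(sorted(callers)))
        fields.append("PLATFORMS=" + ",".join(sorted(obj.support_platforms)))
        fields.append(f"N_TOOLS={len(callers)}")
    else:
        fields.append(f"CALLER={obj.caller_id}")
        fields.append(f"PLATFORM={obj.platform}")
        if obj.sample_id is not None:
            fields.append(f"SAMPLE={obj.sample_id}")
        if not obj.precise:
            fields.append("IMPRECISE")
    if getattr(obj, "alt_seq", None):
        fields.append(f"SEQ={obj.alt_seq}")
    return fields


_SV_VCF_HEADER_INFO = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">',
    '##INFO=<ID=CALLER,Number=1,Type=String,Description="Source caller">',
    '##INFO=<ID=PLATFORM,Number=1,Type=String,Description="Sequencing platform (SR/LR)">',
    '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Source sample">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">',
    '##INFO=<ID=SEQ,Number=1,Type=String,Description="Explicit alternate sequence">',
    '##INFO=<ID=SUPP_CALLERS,Number=.,Type=String,Description="Supporting callers">',
    '##INFO=<ID=PLATFORMS,Number=.,Type=String,Description="Supporting platforms">',
    '##INFO=<ID=N_TOOLS,Number=1,Type=Integer,Description="Number of supporting tools">',
]


def write_sv_vcf(calls: Sequence, path: str | Path,
                 contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write SVCall or MergedSV records to a sites-only VCF.

    Calls must already be sorted by (chrom, pos); IDs are assigned
    sequentially.  Round-trips through :func:`read_sv_vcf` reproduce all
    typed fields of plain :class:`SVCall` inputs.
    """
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos)")
    if contig_lengths is None:
        contig_lengths = {}
        for c in calls:
            contig_lengths[c.chrom] = max(contig_lengths.get(c.chrom, 0),
                                          c.end + 1000)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={name},length={length}>"
              for name, length in contig_lengths.items()]
    lines += _SV_VCF_HEADER_INFO
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, c in enumerate(calls):
        info = ";".join(_sv_info_fields(c))
        lines.append(f"{c.chrom}\t{c.pos}\tsv{i:06d}\tN\t<{c.svtype}>\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotyped multi-sample VCFs
# ---------------------------------------------------------------------------

# cyvcf2 gt_types: 0=hom_ref 1=het 2=unknown 3=hom_alt
_CYVCF2_GT_MAP = np.array([0, 1, GT_MISSING, 2], dtype=np.int8)


def read_genotyped_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a multi-sample genotyped VCF into VariantRecords.

    Returns (records, sample names).  DP/GQ default to -1 when the FORMAT
    field is absent, which downstream QC treats as failing.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    records: list[VariantRecord] = []
    for v in vcf:
        gts = _CYVCF2_GT_MAP[np.asarray(v.gt_types, dtype=np.int64)]
        dp = v.format("DP")
        dp = (np.full(n, -1, dtype=np.int32) if dp is None
              else np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32))
        gq = v.format("GQ")
        gq = (np.full(n, -1, dtype=np.int32) if gq is None
              else np.where(gq[:, 0] < 0, -1, gq[:, 0]).astype(np.int32))
        alt = v.ALT[0] if v.ALT else ""
        svtype = v.INFO.get("SVTYPE")
        if svtype in SVTYPES:
            vclass = "SV"
            svlen = v.INFO.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            length = abs(int(svlen)) if svlen is not None else None
            info_end = v.INFO.get("END")
            end = int(info_end) if info_end is not None else v.POS
        else:
            vclass = classify_variant(v.REF, alt)
            length = max(abs(len(alt) - len(v.REF)), 1)
            end = v.POS + max(len(v.REF) - 1, 0)
            svtype = None
        records.append(VariantRecord(
            chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
            variant_class=vclass, genotypes=gts, dp=dp, gq=gq,
            id=v.ID, length=length, end=end, svtype=svtype,
        ))
    return records, samples


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", GT_MISSING: "./."}


def write_genotyped_vcf(records: Sequence[VariantRecord], samples: Sequence[str],
                        path: str | Path,
                        contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write VariantRecords as a multi-sample VCF with GT:DP:GQ."""
    if contig_lengths is None:
        contig_lengths = {}
        for r in records:
            stop = r.end if r.end is not None else r.pos
            contig_lengths[r.chrom] = max(contig_lengths.get(r.chrom, 0), stop + 1000)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={name},length={length}>"
              for name, length in contig_lengths.items()]
    lines += [
        _SV_VCF_HEADER_INFO[0], _SV_VCF_HEADER_INFO[1], _SV_VCF_HEADER_INFO[2],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for i, r in enumerate(records):
        if r.svtype is not None:
            svlen = -r.length if r.svtype == "DEL" else r.length
            info = f"SVTYPE={r.svtype};SVLEN={svlen}"
            if r.svtype != "INS" and r.end is not None:
                info += f";END={r.end}"
        else:
            info = "."
        cells = []
        for g, d, q in zip(r.genotypes, r.dp, r.gq):
            ds = "." if d < 0 else str(int(d))
            qs = "." if q < 0 else str(int(q))
            cells.append(f"{_GT_STRINGS[int(g)]}:{ds}:{qs}")
        vid = r.id or f"var{i:07d}"
        lines.append(f"{r.chrom}\t{r.pos}\t{vid}\t{r.ref}\t{r.alt}\t.\tPASS\t{info}"
                     f"\tGT:DP:GQ\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# population map, gene models, GO map
# ---------------------------------------------------------------------------

def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> population TSV.

    Any number of populations is accepted here; the differentiation
    operations require exactly two and enforce that themselves.  A sample
    listed twice with conflicting labels is a fatal error.
    """
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed population-map line: {line!r}")
        sample, pop = parts[0], parts[1]
        if sample in mapping and mapping[sample] != pop:
            raise ValueError(f"sample {sample!r} has conflicting labels "
                             f"{mapping[sample]!r} and {pop!r}")
        mapping[sample] = pop
    counts = Counter(mapping.values())
    logger.info("population map: %s", dict(counts))
    return mapping


def require_two_populations(labels: Iterable[str]) -> tuple[str, str]:
    """Return the two population labels (sorted) or raise."""
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two populations required, got {uniq}")
    return uniq[0], uniq[1]


def read_gene_bed(path: str | Path,
                  go_map: Mapping[str, frozenset[str]] | None = None) -> list[GeneModel]:
    """Read genes from BED (chrom, start, end, gene_id); 0-based half-open."""
    genes = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end, gene_id = line.split("\t")[:4]
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        terms = frozenset(go_map.get(gene_id, frozenset())) if go_map else frozenset()
        genes.append(GeneModel(chrom, int(start), int(end), gene_id, terms))
    return genes


def read_go_map(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a gene -> GO mapping TSV (gene_id, go_id, namespace).

    Returns (gene_id -> set of GO ids, go_id -> namespace).
    """
    gene2go: dict[str, set[str]] = {}
    go2ns: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        gene, go_id = parts[0], parts[1]
        ns = parts[2] if len(parts) > 2 else "biological_process"
        gene2go.setdefault(gene, set()).add(go_id)
        go2ns[go_id] = ns
    return gene2go, go2ns


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a plain BED3 feature track (0-based half-open)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append((chrom, int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# genotype matrix container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x variants alt-allele dosage matrix with metadata.

    ``matrix[i, j]`` is the number of alt alleles (0/1/2) carried by sample
    ``samples[i]`` at variant ``j``, or -1 for a missing genotype.
    ``variants`` carries per-variant chrom/pos/class/length columns aligned
    with matrix columns.
    """

    samples: list[str]
    populations: np.ndarray          # per-sample labels, aligned with samples
    matrix: np.ndarray               # (n_samples, n_variants) int8
    variants: pd.DataFrame           # chrom, pos, id, vclass, length, end, svtype

    def __post_init__(self) -> None:
        if len(self.variants) != self.matrix.shape[1]:
            raise ValueError("variant metadata length != number of variants")
        if len(self.samples) != self.matrix.shape[0]:
            raise ValueError("sample list length != number of rows")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_records(cls, records: Sequence[VariantRecord], samples: Sequence[str],
                     popmap: Mapping[str, str]) -> "GenotypeMatrix":
        mat = (np.stack([r.genotypes for r in records], axis=1).astype(np.int8)
               if records else np.zeros((len(samples), 0), dtype=np.int8))
        meta = pd.DataFrame({
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "id": [r.id for r in records],
            "vclass": [r.variant_class for r in records],
            "length": [r.length if r.length is not None else 1 for r in records],
            "end": [r.end if r.end is not None else r.pos for r in records],
            "svtype": [r.svtype for r in records],
        })
        pops = np.array([popmap[s] for s in samples])
        return cls(list(samples), pops, mat, meta)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypeMatrix(self.samples, self.populations,
                              self.matrix[:, idx],
                              self.variants.iloc[idx].reset_index(drop=True))


def write_manifest(path: str | Path, **entries) -> None:
    """Write a small JSON run manifest (seed, counts, file names...)."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
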