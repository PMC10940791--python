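"""Synthetic two-population datasets with known truth.

Generates every input the downstream analysis consumes - per-caller SV
callsets on two platforms, multi-sample genotyped VCFs for SVs, SNPs and
small indels, and a population map - from an explicit truth table, so that
merging, QC and population-genetic statistics can all be tested by
parameter recovery.

Model
-----
* Two populations (defaults 29 "RO" + 31 "PU" individuals).  Neutral
  per-population allele frequencies follow the Balding-Nichols model:
  ``p_k ~ Beta(p0 (1-theta)/theta, (1-p0)(1-theta)/theta)`` independently
  per population, which targets a genome-wide FST of ``theta`` directly.
  A configurable fraction of loci is instead planted at a fixed strong
  frequency contrast (default 0.9 vs 0.1) to emulate divergent selection.
* Genotypes are Hardy-Weinberg draws ``Binomial(2, p_k)`` per individual;
  read depth is Poisson (default mean 16, the study-scale short-read
  coverage), genotype quality a clipped normal, and genotypes go missing
  with a configurable rate, independently of correctness.
* Each true SV is emitted by caller ``c`` with probability
  ``sensitivity(c, svtype)``; emitted breakpoints and lengths are jittered
  with caller-specific normal noise, and false positives are placed
  uniformly with the caller's own type mix.

Loci are independent by default (no linkage); an AR(1) haplotype
generator is provided separately for linkage-decay tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (GT_MISSING, SVTYPES, GenotypeMatrix, SVCall,
                         VariantRecord, write_genotyped_vcf, write_manifest)

__all__ = [
    "CallerProfile", "SimConfig", "TruthTable", "SimulatedGenotypes",
    "simulate_frequencies", "simulate_genotypes", "simulate_callsets",
    "simulate_linked_genotypes", "default_caller_profiles",
    "write_simulated_dataset",
]

#: SV type mix of the default generator, matching the union-callset
#: composition of a mixed-platform study (DEL-dominated, many INS, few
#: DUP/INV).
DEFAULT_SV_TYPE_MIX = {"DEL": 0.591, "INS": 0.383, "DUP": 0.022, "INV": 0.004}


@dataclass(frozen=True)
class CallerProfile:
    """Detection behavior of one emulated SV caller."""

    name: str
    platform: str
    sensitivity: Mapping[str, float]     # svtype -> detection probability
    fp_rate: float = 0.1                 # expected false calls per true SV
    fp_type_mix: Mapping[str, float] | None = None
    pos_jitter_sd: float = 3.0
    len_jitter_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.pos_jitter_sd < 0 or self.len_jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        for t, s in self.sensitivity.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"sensitivity[{t}] outside [0,1]")


def default_caller_profiles() -> list[CallerProfile]:
    """Three short-read and three long-read caller profiles.

    Qualitative behavior mirrors the tools the profiles are named after:
    short-read callers are deletion-biased and nearly blind to insertions
    (one of them entirely so), long-read callers are sensitive across
    types, with larger breakpoint jitter.
    """
    sr_mix = {"DEL": 0.85, "DUP": 0.05, "INS": 0.02, "INV": 0.08}
    lr_mix = {"DEL": 0.5, "DUP": 0.05, "INS": 0.42, "INV": 0.03}
    return [
        CallerProfile("delly", "SR",
                      {"DEL": 0.75, "DUP": 0.55, "INS": 0.15, "INV": 0.65},
                      fp_rate=0.10, fp_type_mix=sr_mix,
                      pos_jitter_sd=3.0, len_jitter_sd=3.0),
        CallerProfile("manta", "SR",
                      {"DEL": 0.80, "DUP": 0.60, "INS": 0.35, "INV": 0.70},
                      fp_rate=0.15, fp_type_mix=sr_mix,
                      pos_jitter_sd=3.0, len_jitter_sd=3.0),
        CallerProfile("smoove", "SR",
                      {"DEL": 0.65, "DUP": 0.35, "INS": 0.0, "INV": 0.40},
                      fp_rate=0.05, fp_type_mix={"DEL": 0.95, "DUP": 0.02,
                                                 "INS": 0.0, "INV": 0.03},
                      pos_jitter_sd=3.0, len_jitter_sd=3.0),
        CallerProfile("sniffles", "LR",
                      {"DEL": 0.90, "DUP": 0.50, "INS": 0.90, "INV": 0.60},
                      fp_rate=0.10, fp_type_mix=lr_mix,
                      pos_jitter_sd=8.0, len_jitter_sd=8.0),
        CallerProfile("svim", "LR",
                      {"DEL": 0.92, "DUP": 0.65, "INS": 0.92, "INV": 0.55},
                      fp_rate=0.20, fp_type_mix=lr_mix,
                      pos_jitter_sd=8.0, len_jitter_sd=8.0),
        CallerProfile("nanovar", "LR",
                      {"DEL": 0.80, "DUP": 0.70, "INS": 0.75, "INV": 0.65},
                      fp_rate=0.10, fp_type_mix=lr_mix,
                      pos_jitter_sd=8.0, len_jitter_sd=8.0),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic dataset; the seed determines
    every random draw."""

    seed: int
    n_pop1: int = 29                  # "RO"
    n_pop2: int = 31                  # "PU"
    pop1: str = "RO"
    pop2: str = "PU"
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000,
                                 "chr3": 5_000_000, "chr4": 5_000_000})
    n_snps: int = 20_000
    n_indels: int = 2_000
    n_svs: int = 1_000
    theta_fst: float = 0.05           # Balding-Nichols divergence
    divergent_frac: float = 0.02      # fraction of loci planted divergent
    divergent_contrast: tuple[float, float] = (0.9, 0.1)
    p0_range: tuple[float, float] = (0.05, 0.95)
    sv_type_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SV_TYPE_MIX))
    sv_length_log_mean: float = 5.3   # lognormal; median ~200 bp
    sv_length_log_sd: float = 1.0
    sv_length_min: int = 50
    sv_length_max: int = 10_000
    dp_mean: float = 16.0             # Poisson read depth
    gq_mean: float = 60.0
    gq_sd: float = 20.0
    missing_rate: float = 0.10
    caller_profiles: Sequence[CallerProfile] = field(
        default_factory=default_caller_profiles)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_fst < 1.0:
            raise ValueError("theta_fst must lie in (0, 1)")
        for name, value in (("divergent_frac", self.divergent_frac),
                            ("missing_rate", self.missing_rate)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        platforms = {p.platform for p in self.caller_profiles}
        for plat in platforms:
            if sum(p.platform == plat for p in self.caller_profiles) < 2:
                raise ValueError(f"need >= 2 caller profiles for platform {plat}")


@dataclass
class TruthTable:
    """Ground truth behind one synthetic dataset.

    ``loci`` has one row per variant (SNP, indel or SV) with ancestral and
    per-population frequencies and the divergent flag; ``svs`` has one row
    per true SV with its exact breakpoints and, after
    :func:`simulate_callsets`, the set of callers that emitted it.
    """

    loci: pd.DataFrame
    svs: pd.DataFrame


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, config: SimConfig, n: int,
                    ) -> tuple[np.ndarray, np.ndarray]:
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    pos = np.empty(n, dtype=np.int64)
    for i, c in enumerate(chroms):
        mask = chrom_idx == i
        pos[mask] = rng.integers(1, config.chrom_lengths[c], size=mask.sum())
    order = np.lexsort((pos, chrom_idx))
    return np.array(chroms, dtype=object)[chrom_idx[order]], pos[order]


def simulate_frequencies(config: SimConfig) -> TruthTable:
    """Draw per-locus truth: positions, classes, frequencies, SV geometry."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_snps + config.n_indels + config.n_svs

    chroms, pos = _draw_positions(rng, config, n_total)
    vclass = np.array(["SNP"] * config.n_snps + ["INDEL"] * config.n_indels
                      + ["SV"] * config.n_svs, dtype=object)
    rng.shuffle(vclass)

    lo, hi = config.p0_range
    p0 = rng.uniform(lo, hi, size=n_total)
    theta = config.theta_fst
    scale = (1.0 - theta) / theta
    p1 = rng.beta(np.maximum(p0 * scale, 1e-9),
                  np.maximum((1.0 - p0) * scale, 1e-9))
    p2 = rng.beta(np.maximum(p0 * scale, 1e-9),
                  np.maximum((1.0 - p0) * scale, 1e-9))

    n_div = int(round(config.divergent_frac * n_total))
    divergent = np.zeros(n_total, dtype=bool)
    if n_div:
        idx = rng.choice(n_total, size=n_div, replace=False)
        divergent[idx] = True
        hi_p, lo_p = config.divergent_contrast
        p1[idx], p2[idx] = hi_p, lo_p

    # SV geometry: types and lengths for the SV-class loci
    sv_rows = np.flatnonzero(vclass == "SV")
    types = np.array(list(config.sv_type_mix), dtype=object)
    probs = np.array([config.sv_type_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    svtype = rng.choice(types, size=sv_rows.size, p=probs)
    lengths = np.exp(rng.normal(config.sv_length_log_mean,
                                config.sv_length_log_sd, size=sv_rows.size))
    lengths = np.clip(np.round(lengths), config.sv_length_min,
                      config.sv_length_max).astype(np.int64)

    indel_rows = np.flatnonzero(vclass == "INDEL")
    indel_len = rng.integers(1, 50, size=indel_rows.size)

    length = np.ones(n_total, dtype=np.int64)
    length[sv_rows] = lengths
    length[indel_rows] = indel_len

    loci = pd.DataFrame({
        "locus_id": [f"L{i:07d}" for i in range(n_total)],
        "chrom": chroms, "pos": pos, "vclass": vclass, "length": length,
        "p0": p0, "p1": p1, "p2": p2, "divergent": divergent,
    })

    end = pos[sv_rows].copy()
    span = svtype != "INS"
    end[span] = pos[sv_rows][span] + lengths[span] - 1
    svs = pd.DataFrame({
        "sv_id": [f"SV{i:05d}" for i in range(sv_rows.size)],
        "locus_id": loci["locus_id"].to_numpy()[sv_rows],
        "chrom": chroms[sv_rows], "pos": pos[sv_rows], "end": end,
        "svtype": svtype, "length": lengths,
    })
    return TruthTable(loci=loci, svs=svs)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _ref_alt_for(vclass: str, svtype, length: int, rng: np.random.Generator,
                 ) -> tuple[str, str]:
    bases = "ACGT"
    if vclass == "SNP":
        i = int(rng.integers(0, 4))
        return bases[i], bases[(i + 1 + int(rng.integers(0, 3))) % 4]
    if vclass == "INDEL":
        anchor = bases[int(rng.integers(0, 4))]
        fill = "".join(bases[int(b)] for b in rng.integers(0, 4, size=length))
        if rng.random() < 0.5:
            return anchor + fill, anchor      # deletion-type indel
        return anchor, anchor + fill          # insertion-type indel
    return "N", f"<{svtype}>"


@dataclass
class SimulatedGenotypes:
    """Per-class genotyped records plus sample/population bookkeeping."""

    records: dict[str, list[VariantRecord]]   # keys SV / SNP / INDEL
    samples: list[str]
    popmap: dict[str, str]

    def matrix(self, vclass: str) -> GenotypeMatrix:
        return GenotypeMatrix.from_records(self.records[vclass],
                                           self.samples, self.popmap)


def simulate_genotypes(truth: TruthTable, config: SimConfig) -> SimulatedGenotypes:
    """HWE genotypes with DP/GQ/missingness noise for every truth locus.

    All randomness descends from ``config.seed`` (offset so the draws are
    independent of :func:`simulate_frequencies`), so output is
    deterministic: re-running with the same config yields byte-identical
    VCFs.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    samples = ([f"{config.pop1}_{i:02d}" for i in range(1, config.n_pop1 + 1)]
               + [f"{config.pop2}_{i:02d}" for i in range(1, config.n_pop2 + 1)])
    popmap = {s: (config.pop1 if i < config.n_pop1 else config.pop2)
              for i, s in enumerate(samples)}

    loci = truth.loci
    n_loci = len(loci)
    n_samples = len(samples)
    p1 = loci["p1"].to_numpy()
    p2 = loci["p2"].to_numpy()

    geno = np.empty((n_samples, n_loci), dtype=np.int8)
    geno[:config.n_pop1] = rng.binomial(
        2, p1[None, :], size=(config.n_pop1, n_loci)).astype(np.int8)
    geno[config.n_pop1:] = rng.binomial(
        2, p2[None, :], size=(config.n_pop2, n_loci)).astype(np.int8)

    dp = rng.poisson(config.dp_mean, size=(n_samples, n_loci)).astype(np.int32)
    gq = np.clip(np.round(rng.normal(config.gq_mean, config.gq_sd,
                                     size=(n_samples, n_loci))), 0, 99).astype(np.int32)
    missing = rng.random((n_samples, n_loci)) < config.missing_rate
    geno[missing] = GT_MISSING

    sv_type = dict(zip(truth.svs["locus_id"], truth.svs["svtype"]))
    sv_end = dict(zip(truth.svs["locus_id"], truth.svs["end"]))
    chrom_arr = loci["chrom"].to_numpy()
    pos_arr = loci["pos"].to_numpy()
    len_arr = loci["length"].to_numpy()
    id_arr = loci["locus_id"].to_numpy()
    class_arr = loci["vclass"].to_numpy()
    by_class: dict[str, list[VariantRecord]] = {}
    for vclass in ("SV", "SNP", "INDEL"):
        idx = np.flatnonzero(class_arr == vclass)
        records = []
        for j in idx:
            locus_id = id_arr[j]
            svtype = sv_type.get(locus_id) if vclass == "SV" else None
            end = int(sv_end[locus_id]) if vclass == "SV" else int(pos_arr[j])
            ref, alt = _ref_alt_for(vclass, svtype, int(len_arr[j]), rng)
            records.append(VariantRecord(
                chrom=chrom_arr[j], pos=int(pos_arr[j]), ref=ref, alt=alt,
                variant_class=vclass, genotypes=geno[:, j], dp=dp[:, j],
                gq=gq[:, j], id=locus_id, length=int(len_arr[j]),
                end=end, svtype=svtype,
            ))
        by_class[vclass] = records
    return SimulatedGenotypes(records=by_class, samples=samples, popmap=popmap)


# ---------------------------------------------------------------------------
# callsets
# ---------------------------------------------------------------------------

def simulate_callsets(truth: TruthTable, config: SimConfig,
                      ) -> dict[tuple[str, str], list[SVCall]]:
    """Emulated per-caller SV callsets with jitter and false positives.

    Mutates ``truth.svs`` to add a ``callers`` column (the set of caller
    names that emitted each true SV).  Keys of the returned dict are
    ``(caller_name, platform)``.
    """
    rng = np.random.default_rng(config.seed + 2_000_003)
    svs = truth.svs
    emitted: list[set[str]] = [set() for _ in range(len(svs))]
    callsets: dict[tuple[str, str], list[SVCall]] = {}

    for profile in config.caller_profiles:
        calls: list[SVCall] = []
        for i, row in enumerate(svs.itertuples(index=False)):
            sens = profile.sensitivity.get(row.svtype, 0.0)
            if rng.random() >= sens:
                continue
            emitted[i].add(profile.name)
            pos = max(1, int(round(row.pos + rng.normal(0, profile.pos_jitter_sd)))
                      ) if profile.pos_jitter_sd > 0 else int(row.pos)
            length = int(row.length)
            if profile.len_jitter_sd > 0:
                length = max(1, int(round(length + rng.normal(0, profile.len_jitter_sd))))
            end = pos if row.svtype == "INS" else pos + length - 1
            calls.append(SVCall(chrom=row.chrom, pos=pos, end=end,
                                svtype=row.svtype, length=length,
                                caller_id=profile.name, platform=profile.platform))
        # false positives, uniform along the genome
        n_fp = rng.poisson(profile.fp_rate * len(svs))
        mix = profile.fp_type_mix or config.sv_type_mix
        types = [t for t in mix if mix[t] > 0]
        probs = np.array([mix[t] for t in types], dtype=float)
        probs /= probs.sum()
        fp_chroms, fp_pos = _draw_positions(rng, config, n_fp)
        fp_types = rng.choice(np.array(types, dtype=object), size=n_fp, p=probs)
        fp_len = np.clip(np.round(np.exp(rng.normal(
            config.sv_length_log_mean, config.sv_length_log_sd, size=n_fp))),
            config.sv_length_min, config.sv_length_max).astype(np.int64)
        for c, p, t, ln in zip(fp_chroms, fp_pos, fp_types, fp_len):
            end = int(p) if t == "INS" else int(p) + int(ln) - 1
            calls.append(SVCall(chrom=str(c), pos=int(p), end=end, svtype=str(t),
                                length=int(ln), caller_id=profile.name,
                                platform=profile.platform))
        calls.sort(key=lambda c: (c.chrom, c.pos))
        callsets[(profile.name, profile.platform)] = calls

    svs["callers"] = [frozenset(s) for s in emitted]
    return callsets


# ---------------------------------------------------------------------------
# linked genotypes (for LD decay only)
# ---------------------------------------------------------------------------

def simulate_linked_genotypes(n_individuals: int, positions: np.ndarray,
                              p: np.ndarray, decay_bp: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Genotypes with AR(1) linkage decaying with physical distance.

    Each of the ``2 n`` haplotypes is a thresholded Gaussian AR(1) process:
    adjacent loci at distance ``d`` have latent correlation
    ``exp(-d / decay_bp)``, so pairwise r^2 decays monotonically with
    distance.  Marginal allele frequencies equal ``p``.
    """
    from scipy.stats import norm

    positions = np.asarray(positions, dtype=float)
    m = positions.size
    rho = np.exp(-np.diff(positions) / decay_bp)
    z = np.empty((2 * n_individuals, m))
    z[:, 0] = rng.standard_normal(2 * n_individuals)
    for j in range(1, m):
        eps = rng.standard_normal(2 * n_individuals)
        z[:, j] = rho[j - 1] * z[:, j - 1] + np.sqrt(1 - rho[j - 1] ** 2) * eps
    thresholds = norm.ppf(p)
    haplotypes = (z < thresholds[None, :]).astype(np.int8)
    return haplotypes[0::2] + haplotypes[1::2]


# ---------------------------------------------------------------------------
# full dataset on disk
# ---------------------------------------------------------------------------

def write_simulated_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a complete dataset: VCFs, callsets, truth, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_frequencies(config)
    sim = simulate_genotypes(truth, config)
    popmap = sim.popmap
    callsets = simulate_callsets(truth, config)

    files: dict[str, Path] = {}
    from .io_formats import write_sv_vcf  # local to avoid cycle at import time

    for vclass, records in sim.records.items():
        path = out / f"genotyped_{vclass.lower()}s.vcf"
        write_genotyped_vcf(records, sim.samples, path,
                            contig_lengths=config.chrom_lengths)
        files[f"genotyped_{vclass.lower()}s"] = path

    for (caller, platform), calls in callsets.items():
        path = out / f"calls_{platform}_{caller}.vcf"
        write_sv_vcf(sorted(calls, key=lambda c: (c.chrom, c.pos)), path,
                     contig_lengths=config.chrom_lengths)
        files[f"calls_{platform}_{caller}"] = path

    popmap_path = out / "population_map.tsv"
    popmap_path.write_text("".join(f"{s}\t{p}\n" for s, p in popmap.items()))
    files["population_map"] = popmap_path

    truth.loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
    svs = truth.svs.copy()
    svs["callers"] = [",".join(sorted(c)) for c in svs["callers"]]
    svs.to_csv(out / "truth_svs.tsv", sep="\t", index=False)
    files["truth_loci"] = out / "truth_loci.tsv"
    files["truth_svs"] = out / "truth_svs.tsv"

    write_manifest(out / "manifest.json", seed=config.seed,
                   n_pop1=config.n_pop1, n_pop2=config.n_pop2,
                   n_snps=config.n_snps, n_indels=config.n_indels,
                   n_svs=config.n_svs, theta_fst=config.theta_fst,
                   files={k: str(v.name) for k, v in files.items()})
    files["manifest"] = out / "manifest.json"
    return files
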