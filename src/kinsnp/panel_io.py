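"""Panel manifests, genotype matrices, interval masks and genetic maps.

This module holds the I/O layer of the workbench: reading and writing the
SNP-panel manifest (TSV), diploid pair genotypes (VCF, GT field only),
masked-region intervals (BED3) and genetic maps (TSV), plus the locus-level
allele-sharing primitive that both IBD detectors and the kinship-coefficient
estimator are built on.

Conventions
-----------
* Genotypes are alt-allele dosages in ``{0, 1, 2}``; missing calls are coded
  ``MISSING`` (−1).  Phase in VCF GT fields is accepted and ignored: every
  method downstream is genotype-level.
* Manifest/VCF positions are 1-based; intervals are 0-based half-open
  (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from ._autosomes import GRCH38_AUTOSOME_BP

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.  Distinct from all dosages.
MISSING: int = -1

MANIFEST_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "category", "alt_freq"]

_CATEGORIES = ("kiSNP", "aiSNP", "iiSNP", "piSNP")


class PanelValidationError(ValueError):
    """Raised when a manifest or genotype file violates panel invariants."""


@dataclass(frozen=True)
class SnpLocus:
    """A single autosomal biallelic marker of the panel."""

    chrom: int
    pos: int
    id: str
    ref: str
    alt: str
    category: str
    alt_freq: float


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval on one autosome."""

    chrom: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelValidationError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start


class PanelManifest:
    """Ordered autosomal SNP loci with positions, alleles and frequencies.

    Loci are sorted by (chrom, pos) with strictly increasing positions within
    each chromosome and unique marker ids.  Columnar views (``chrom``,
    ``pos``, ``alt_freq`` arrays) are exposed for vectorised consumers.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, MANIFEST_COLUMNS].reset_index(drop=True)
        self._validate(df)
        self.df = df
        self.chrom = df["chrom"].to_numpy(np.int16)
        self.pos = df["pos"].to_numpy(np.int64)
        self.alt_freq = df["alt_freq"].to_numpy(np.float64)
        self.ids = df["id"].to_numpy(object)
        # per-chromosome ordinal ranges [start, stop) into the locus order
        self.chrom_ranges: dict[int, tuple[int, int]] = {}
        for c in np.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            self.chrom_ranges[int(c)] = (int(idx[0]), int(idx[-1]) + 1)

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise PanelValidationError(f"duplicate marker id {dup!r}")
        bad = df.index[(df["alt_freq"] <= 0) | (df["alt_freq"] >= 1)]
        if len(bad):
            raise PanelValidationError(
                f"alt_freq outside (0,1) at row {bad[0]} (id {df.loc[bad[0], 'id']!r})"
            )
        bad = df.index[(df["chrom"] < 1) | (df["chrom"] > 22)]
        if len(bad):
            raise PanelValidationError(f"chrom outside 1..22 at row {bad[0]}")
        bad = df.index[df["ref"] == df["alt"]]
        if len(bad):
            raise PanelValidationError(f"ref == alt at row {bad[0]}")
        for c, sub in df.groupby("chrom", sort=False):
            d = np.diff(sub["pos"].to_numpy())
            if (d <= 0).any():
                row = sub.index[int(np.argmax(d <= 0)) + 1]
                raise PanelValidationError(
                    f"positions not strictly increasing on chromosome {c} at row {row} "
                    f"(id {df.loc[row, 'id']!r})"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_loci(self) -> int:
        return len(self.df)

    @property
    def loci(self) -> list[SnpLocus]:
        return [SnpLocus(*row) for row in self.df.itertuples(index=False)]

    def chrom_span_mbp(self, chrom: int) -> float:
        """Panel-covered span (last − first SNP position) of one chromosome."""
        lo, hi = self.chrom_ranges[chrom]
        return float(self.pos[hi - 1] - self.pos[lo]) / 1e6

    def genome_span_mbp(self) -> float:
        """Total panel-covered span over all chromosomes, in Mbp."""
        return sum(self.chrom_span_mbp(c) for c in self.chrom_ranges)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Samples × loci alt-allele dosage codes, aligned to a manifest."""

    sample_ids: list[str]
    codes: np.ndarray  # int8, shape (n_samples, n_loci); MISSING = -1

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.sample_ids):
            raise PanelValidationError("codes shape does not match sample_ids")
        valid = np.isin(self.codes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise PanelValidationError("genotype codes must be in {0,1,2,MISSING}")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]


class GeneticMap:
    """Piecewise-linear bp↔cM map per chromosome.

    Anchor points must be monotone; every chromosome of the panel in use must
    be covered (queries outside the anchored range are clamped linearly using
    the terminal anchors, which keeps a uniform map exact).
    """

    def __init__(self, anchors: dict[int, tuple[np.ndarray, np.ndarray]]):
        self.anchors = {}
        for c, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            if bp.size < 2:
                raise PanelValidationError(f"chromosome {c}: need >=2 map anchors")
            if (np.diff(bp) <= 0).any() or (np.diff(cm) < 0).any():
                raise PanelValidationError(f"chromosome {c}: map anchors not monotone")
            self.anchors[int(c)] = (bp, cm)

    @classmethod
    def uniform(
        cls,
        chrom_lengths_bp: dict[int, int],
        cm_per_mbp: float = 1.0,
    ) -> "GeneticMap":
        """Uniform recombination map (default 1 cM/Mbp) over whole chromosomes."""
        return cls(
            {
                c: (np.array([0.0, float(L)]), np.array([0.0, L / 1e6 * cm_per_mbp]))
                for c, L in chrom_lengths_bp.items()
            }
        )

    def cm_length(self, chrom: int) -> float:
        bp, cm = self.anchors[chrom]
        return float(cm[-1] - cm[0])

    def bp_to_cm(self, chrom: int, pos_bp: np.ndarray | float) -> np.ndarray:
        bp, cm = self.anchors[chrom]
        return np.interp(pos_bp, bp, cm)

    def cm_to_bp(self, chrom: int, pos_cm: np.ndarray | float) -> np.ndarray:
        bp, cm = self.anchors[chrom]
        # cm may contain flat stretches; interp handles them (left edge taken)
        return np.interp(pos_cm, cm, bp)

    def chrom_length_bp(self, chrom: int) -> int:
        bp, _ = self.anchors[chrom]
        return int(bp[-1])


def load_genetic_map(path: str | Path) -> GeneticMap:
    """Read a genetic map TSV with header columns chrom, pos, cM."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "cM"} - set(df.columns)
    if missing:
        raise PanelValidationError(f"genetic map missing columns {sorted(missing)}")
    anchors = {}
    for c, sub in df.groupby("chrom"):
        sub = sub.sort_values("pos")
        anchors[int(c)] = (sub["pos"].to_numpy(float), sub["cM"].to_numpy(float))
    return GeneticMap(anchors)


def load_panel_manifest(path: str | Path) -> PanelManifest:
    """Read and validate a panel manifest TSV (chrom,pos,id,ref,alt,category,alt_freq)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": int, "pos": int, "alt_freq": float})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise PanelValidationError(f"manifest missing columns {sorted(missing)}")
    return PanelManifest(df)


def generate_panel_fixture(
    n_snps: int,
    n_chrom: int = 22,
    seed: int = 0,
    maf_low: float = 0.30,
    maf_high: float = 0.50,
) -> PanelManifest:
    """Generate a synthetic autosomal SNP panel emulating a forensic kinship kit.

    Loci are spread over ``n_chrom`` autosomes with per-chromosome counts
    proportional to GRCh38 autosome lengths (~2,875 Mbp total).  Alternate
    allele frequencies model a kinship-optimised panel: minor-allele
    frequency drawn uniformly from [maf_low, maf_high] with random ref/alt
    orientation, so markers are highly heterozygous as kinship-informative
    SNPs are selected to be.  Deterministic under ``seed``.
    """
    if not (1 <= n_chrom <= 22) or n_snps < n_chrom:
        raise ValueError("require n_snps >= n_chrom and 1 <= n_chrom <= 22")
    rng = np.random.default_rng(seed)
    lengths = GRCH38_AUTOSOME_BP[:n_chrom]
    per = np.maximum(1, np.floor(n_snps * lengths / lengths.sum()).astype(int))
    # distribute the rounding remainder over the largest chromosomes
    short = n_snps - per.sum()
    order = np.argsort(lengths)[::-1]
    for i in range(short):
        per[order[i % n_chrom]] += 1

    rows = []
    n_categories = np.array([9867, 56, 94, 22], dtype=float)  # kit-like proportions
    cat_p = n_categories / n_categories.sum()
    bases = np.array(list("ACGT"))
    k = 0
    for ci, (n_c, L) in enumerate(zip(per, lengths)):
        chrom = ci + 1
        pos = np.unique(rng.integers(1, L, size=n_c, dtype=np.int64))
        while pos.size < n_c:  # collisions are vanishingly rare at panel density
            extra = rng.integers(1, L, size=n_c - pos.size, dtype=np.int64)
            pos = np.unique(np.concatenate([pos, extra]))
        pos.sort()
        maf = rng.uniform(maf_low, maf_high, n_c)
        alt_freq = np.where(rng.random(n_c) < 0.5, maf, 1.0 - maf)
        cats = rng.choice(len(_CATEGORIES), size=n_c, p=cat_p)
        ref_i = rng.integers(0, 4, n_c)
        alt_i = (ref_i + rng.integers(1, 4, n_c)) % 4
        for j in range(n_c):
            rows.append(
                (
                    chrom,
                    int(pos[j]),
                    f"ks{chrom}_{k + j}",
                    bases[ref_i[j]],
                    bases[alt_i[j]],
                    _CATEGORIES[cats[j]],
                    float(alt_freq[j]),
                )
            )
        k += n_c
    return PanelManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


# ---------------------------------------------------------------------------
# VCF I/O (GT only)
# ---------------------------------------------------------------------------

def _vcf_header(manifest: PanelManifest, sample_ids: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    for c in sorted(manifest.chrom_ranges):
        lo, hi = manifest.chrom_ranges[c]
        header.contigs.add(str(c), length=int(manifest.pos[hi - 1]) + 1)
    for s in sample_ids:
        header.add_sample(s)
    return header


def write_genotypes_vcf(
    matrix: GenotypeMatrix, manifest: PanelManifest, path: str | Path
) -> None:
    """Write an uncompressed VCFv4.2 with GT fields aligned to the manifest."""
    if matrix.n_samples == 0:
        raise PanelValidationError("cannot write a VCF with no samples")
    if matrix.n_loci != manifest.n_loci:
        raise PanelValidationError("matrix not aligned to manifest")
    header = _vcf_header(manifest, matrix.sample_ids)
    _GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i in range(manifest.n_loci):
            rec = vf.new_record(
                contig=str(int(manifest.chrom[i])),
                start=int(manifest.pos[i]) - 1,
                stop=int(manifest.pos[i]),
                alleles=(manifest.df.at[i, "ref"], manifest.df.at[i, "alt"]),
                id=str(manifest.ids[i]),
            )
            for s, sample in enumerate(matrix.sample_ids):
                rec.samples[sample]["GT"] = _GT[int(matrix.codes[s, i])]
            vf.write(rec)


def read_genotypes_vcf(path: str | Path, manifest: PanelManifest) -> GenotypeMatrix:
    """Read GT dosages from a VCF, aligned to manifest order.

    Records are matched by (chrom, pos); phase is ignored.  Manifest loci
    absent from the VCF become MISSING for every sample (a count is logged);
    an allele mismatch against the manifest raises.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        codes = np.full((len(samples), manifest.n_loci), MISSING, dtype=np.int8)
        index = {
            (int(manifest.chrom[i]), int(manifest.pos[i])): i
            for i in range(manifest.n_loci)
        }
        seen = np.zeros(manifest.n_loci, dtype=bool)
        for rec in vf:
            key = (int(rec.contig), rec.pos)
            i = index.get(key)
            if i is None:
                continue
            ref, alt = manifest.df.at[i, "ref"], manifest.df.at[i, "alt"]
            if rec.ref != ref or (rec.alts or (None,))[0] != alt:
                raise PanelValidationError(
                    f"allele mismatch at {key[0]}:{key[1]}: VCF {rec.ref}/{rec.alts} "
                    f"vs manifest {ref}/{alt}"
                )
            seen[i] = True
            for s, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue  # stays MISSING
                codes[s, i] = sum(gt)
    n_absent = int((~seen).sum())
    if n_absent:
        logger.warning("%d manifest loci absent from VCF; set MISSING", n_absent)
    return GenotypeMatrix(samples, codes)


# ---------------------------------------------------------------------------
# Interval masks
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort intervals and merge overlapping/touching ones per chromosome."""
    out: list[GenomicInterval] = []
    by_chrom: dict[int, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c], key=lambda iv: iv.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(c, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(c, cur_s, cur_e))
    return out


def load_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-column BED; returns sorted intervals merged within the file."""
    ivs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PanelValidationError(f"BED line {ln}: need 3 columns")
            chrom = int(parts[0].removeprefix("chr"))
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise PanelValidationError(f"BED line {ln}: start >= end")
            ivs.append(GenomicInterval(chrom, start, end))
    return merge_intervals(ivs)


def derive_gap_mask(manifest: PanelManifest, gap_mbp: float = 5.0) -> list[GenomicInterval]:
    """Mask open gaps between adjacent panel SNPs wider than ``gap_mbp``.

    Medium-density panels have stretches with no marker coverage; IBD
    segments cannot be supported there, so they are treated as masked
    regions.  One interval is emitted per adjacent-SNP pair whose distance
    strictly exceeds the threshold, spanning the open gap between the two
    SNPs (neither SNP position is contained).
    """
    if gap_mbp <= 0:
        raise ValueError("gap_mbp must be positive")
    out = []
    thr = gap_mbp * 1e6
    for c, (lo, hi) in sorted(manifest.chrom_ranges.items()):
        pos = manifest.pos[lo:hi]
        gaps = np.flatnonzero(np.diff(pos) > thr)
        for g in gaps:
            # SNP at pos p occupies 0-based [p-1, p); open gap = [p1, p2-1)
            out.append(GenomicInterval(c, int(pos[g]), int(pos[g + 1]) - 1))
    return out


# ---------------------------------------------------------------------------
# Allele sharing
# ---------------------------------------------------------------------------

def shared_allele_count(code_a: int, code_b: int) -> int:
    """Number of alleles (0, 1 or 2) two dosage codes share at one locus.

    Equal codes share 2, het vs either homozygote shares 1, opposite
    homozygotes share 0.  Any MISSING operand propagates MISSING.
    """
    for c in (code_a, code_b):
        if c not in (0, 1, 2, MISSING):
            raise ValueError(f"invalid genotype code {c!r}")
    if code_a == MISSING or code_b == MISSING:
        return MISSING
    return 2 - abs(code_a - code_b)


def shared_allele_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised ``shared_allele_count``: arrays of codes → array of counts."""
    a = np.asarray(a)
    b = np.asarray(b)
    out = 2 - np.abs(a.astype(np.int16) - b.astype(np.int16))
    out[(a == MISSING) | (b == MISSING)] = MISSING
    return out.astype(np.int8)
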