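"""IBD-segment detection for medium-density SNP pair profiles.

Two detection workflows are provided:

* **A1** — concordance runs: maximal stretches of loci at which the pair is
  not opposite-homozygous (i.e. shares at least one allele, the only state
  impossible inside a true IBD tract absent genotyping error), filtered by
  physical length (> 10 Mbp after the base scan), by segment informativity
  (Is > 50, a calibration against how often each SNP lands in runs across a
  reference cohort), and finally trimmed against masked regions.
* **A2** — windowed kinship scan: overlapping windows of L = 80 SNPs scored
  by the robust kinship-coefficient estimator; windows with φ > 0.23 are
  kept, merged by overlap, and merged segments with allele-sharing purity
  p < 0.95 are discarded.

Neither detector separates IBD1 from IBD2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .panel_io import (
    MISSING,
    GenomicInterval,
    PanelManifest,
    shared_allele_counts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IbdSegment",
    "InformativityMap",
    "DetectorConfig",
    "concordance_runs",
    "snp_informativity",
    "segment_informativity",
    "mask_trim",
    "detect_a1",
    "window_scan",
    "detect_a2",
]


@dataclass(frozen=True)
class IbdSegment:
    """A detected segment: chromosome + SNP-ordinal + bp span.

    Ordinals are inclusive indices into the manifest locus order; bp bounds
    are the positions of the segment's terminal SNPs (1-based).
    """

    chrom: int
    start_ord: int
    end_ord: int
    start_bp: int
    end_bp: int
    n_snps: int
    informativity: float | None = None
    purity: float | None = None
    source: str = "A1"

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("segment start_bp must precede end_bp")
        if self.n_snps < 2:
            raise ValueError("segment must span at least 2 SNPs")

    @property
    def length_mbp(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


@dataclass
class InformativityMap:
    """Per-SNP IBS counts Ic and informativities MI = med(Ic)/Ic.

    ``mi`` is NaN for SNPs never contained in a reference run (Ic = 0);
    those loci contribute nothing to segment informativity sums.
    """

    ic: np.ndarray
    mi: np.ndarray
    med: float


@dataclass
class DetectorConfig:
    """Thresholds of both detectors, defaulting to the published values."""

    min_len_mbp: float = 10.0
    min_informativity: float = 50.0
    window_len: int = 80
    window_phi_threshold: float = 0.23
    min_purity: float = 0.95
    masks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        for v in (self.min_len_mbp, self.min_informativity,
                  self.window_phi_threshold, self.min_purity):
            if v <= 0:
                raise ValueError("thresholds must be positive")


def _pair_codes(pair) -> tuple[np.ndarray, np.ndarray]:
    codes = pair.codes if hasattr(pair, "codes") else np.asarray(pair)
    if codes.ndim != 2 or codes.shape[0] != 2:
        raise ValueError("pair genotypes must be a (2, n_loci) code array")
    return codes[0], codes[1]


# ---------------------------------------------------------------------------
# A1: concordance runs + informativity + mask trimming
# ---------------------------------------------------------------------------

def concordance_runs(pair, manifest: PanelManifest) -> list[IbdSegment]:
    """Maximal runs of consecutive concordant SNPs per chromosome.

    A locus is *concordant* when the pair shares at least one allele there
    (anything but opposite homozygotes); a missing call at either sample
    neither breaks nor extends a run and is not counted in ``n_snps``.
    Runs containing fewer than two genotyped concordant SNPs are dropped.
    """
    a, b = _pair_codes(pair)
    if a.size != manifest.n_loci:
        raise ValueError("pair genotypes not aligned to manifest")
    shared = shared_allele_counts(a, b)
    discordant = shared == 0
    usable = shared != MISSING

    out: list[IbdSegment] = []
    for chrom, (lo, hi) in sorted(manifest.chrom_ranges.items()):
        disc = discordant[lo:hi]
        use = usable[lo:hi]
        breaks = np.flatnonzero(disc)
        bounds = np.concatenate(([-1], breaks, [hi - lo]))
        for s, e in zip(bounds[:-1] + 1, bounds[1:]):
            conc = np.flatnonzero(use[s:e] & ~disc[s:e])
            if conc.size < 2:
                continue
            i0, i1 = s + conc[0], s + conc[-1]
            out.append(
                IbdSegment(
                    chrom=chrom,
                    start_ord=lo + i0,
                    end_ord=lo + i1,
                    start_bp=int(manifest.pos[lo + i0]),
                    end_bp=int(manifest.pos[lo + i1]),
                    n_snps=int(conc.size),
                    source="A1",
                )
            )
    return out


def snp_informativity(
    reference_runs: Iterable[IbdSegment], manifest: PanelManifest
) -> InformativityMap:
    """Calibrate per-SNP informativity from base runs of a reference cohort.

    ``Ic(i)`` counts the reference runs whose ordinal span contains SNP i;
    ``med`` is the median of Ic over SNPs contained in at least one run, and
    ``MI(i) = med / Ic(i)`` for those SNPs.  SNPs that are shared in nearly
    every pair (low-information markers) get MI < 1, rarely shared ones
    MI > 1, so informativity rewards segments built from rarely-shared SNPs.
    """
    delta = np.zeros(manifest.n_loci + 1, dtype=np.int64)
    any_run = False
    for seg in reference_runs:
        any_run = True
        delta[seg.start_ord] += 1
        delta[seg.end_ord + 1] -= 1
    if not any_run:
        raise ValueError("cannot calibrate informativity: no reference runs")
    ic = np.cumsum(delta[:-1]).astype(np.float64)
    covered = ic >= 1
    med = float(np.median(ic[covered]))
    mi = np.full(manifest.n_loci, np.nan)
    mi[covered] = med / ic[covered]
    return InformativityMap(ic=ic, mi=mi, med=med)


def segment_informativity(segment: IbdSegment, info: InformativityMap) -> float:
    """Is(j): sum of MI over all manifest SNPs inside the segment's span."""
    return float(np.nansum(info.mi[segment.start_ord : segment.end_ord + 1]))


def mask_trim(
    segment: IbdSegment,
    masks: Sequence[GenomicInterval],
    info: InformativityMap,
    manifest: PanelManifest,
    cfg: DetectorConfig,
) -> list[IbdSegment]:
    """Trim masked bp-intervals out of a segment and re-filter the remnants.

    Each remnant is re-anchored to its outermost contained SNPs and kept
    only if it remains strictly longer than ``cfg.min_len_mbp`` and its
    informativity strictly exceeds ``cfg.min_informativity``.  A segment
    with no mask overlap is returned unchanged.
    """
    # work 0-based half-open: SNP at pos p occupies [p-1, p)
    seg_lo, seg_hi = segment.start_bp - 1, segment.end_bp
    hits = sorted(
        (max(m.start, seg_lo), min(m.end, seg_hi))
        for m in masks
        if m.chrom == segment.chrom and m.start < seg_hi and m.end > seg_lo
    )
    if not hits:
        return [segment]
    remnants = []
    cursor = seg_lo
    for ms, me in hits:
        if ms > cursor:
            remnants.append((cursor, ms))
        cursor = max(cursor, me)
    if cursor < seg_hi:
        remnants.append((cursor, seg_hi))

    pos = manifest.pos
    out = []
    for r_lo, r_hi in remnants:
        # SNPs of the original span whose [p-1, p) lies inside the remnant
        ords = np.arange(segment.start_ord, segment.end_ord + 1)
        inside = ords[(pos[ords] - 1 >= r_lo) & (pos[ords] <= r_hi)]
        if inside.size < 2:
            continue
        rem = IbdSegment(
            chrom=segment.chrom,
            start_ord=int(inside[0]),
            end_ord=int(inside[-1]),
            start_bp=int(pos[inside[0]]),
            end_bp=int(pos[inside[-1]]),
            n_snps=int(inside.size),
            source=segment.source,
        )
        is_j = segment_informativity(rem, info)
        if rem.length_mbp > cfg.min_len_mbp and is_j > cfg.min_informativity:
            out.append(replace(rem, informativity=is_j))
    return out


def detect_a1(
    pair,
    manifest: PanelManifest,
    info: InformativityMap,
    cfg: DetectorConfig | None = None,
) -> list[IbdSegment]:
    """Full A1 workflow: base runs → length filter → informativity → mask trim."""
    cfg = cfg or DetectorConfig()
    out: list[IbdSegment] = []
    for run in concordance_runs(pair, manifest):
        if run.length_mbp < cfg.min_len_mbp:
            continue
        is_j = segment_informativity(run, info)
        if is_j <= cfg.min_informativity:
            continue
        out.extend(mask_trim(replace(run, informativity=is_j), cfg.masks, info,
                             manifest, cfg))
    out.sort(key=lambda s: (s.chrom, s.start_bp))
    return out


# ---------------------------------------------------------------------------
# A2: windowed kinship-coefficient scan
# ---------------------------------------------------------------------------

def _window_sums(x: np.ndarray, L: int) -> np.ndarray:
    """Sliding sums of length L over x (n-L+1 windows)."""
    c = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    return c[L:] - c[:-L]


def window_scan(
    pair,
    manifest: PanelManifest,
    cfg: DetectorConfig | None = None,
) -> list[tuple[int, int, int, float]]:
    """Score every L-SNP window by the robust kinship coefficient.

    Returns the stored windows with φ strictly above the threshold, as
    (chrom, start_ord, end_ord, phi) tuples.  A chromosome with fewer than
    L SNPs yields a single window spanning all of them.  Missing-at-either
    loci are excluded from all window counts; windows in which the
    higher-heterozygosity sample has no usable heterozygous locus are
    skipped (counted in a log message).

    The window statistic puts the *higher* heterozygosity count in the
    denominator (the convention the 0.23 threshold is calibrated to): its
    small upward bias at window scale keeps windows inside IBD1 tracts,
    whose expected coefficient 0.25 sits just above the threshold, from
    dropping below it and shattering long segments.
    """
    cfg = cfg or DetectorConfig()
    a, b = _pair_codes(pair)
    if a.size != manifest.n_loci:
        raise ValueError("pair genotypes not aligned to manifest")
    valid = (a != MISSING) & (b != MISSING)
    het_a = (valid & (a == 1)).astype(np.int64)
    het_b = (valid & (b == 1)).astype(np.int64)
    both_het = het_a & het_b
    opp = (valid & (np.abs(a.astype(np.int16) - b) == 2)).astype(np.int64)

    stored = []
    n_skipped = 0
    for chrom, (lo, hi) in sorted(manifest.chrom_ranges.items()):
        n = hi - lo
        L = min(cfg.window_len, n)
        nA = _window_sums(het_a[lo:hi], L).astype(np.float64)
        nB = _window_sums(het_b[lo:hi], L).astype(np.float64)
        nBoth = _window_sums(both_het[lo:hi], L)
        nOpp = _window_sums(opp[lo:hi], L)
        nMax = np.maximum(nA, nB)
        ok = nMax > 0
        n_skipped += int((~ok).sum())
        phi = np.full(nMax.shape, -np.inf)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi[ok] = (
                (nBoth[ok] - 2.0 * nOpp[ok]) / (2.0 * nMax[ok])
                + 0.5
                - (nA[ok] + nB[ok]) / (4.0 * nMax[ok])
            )
        for w in np.flatnonzero(phi > cfg.window_phi_threshold):
            stored.append((chrom, lo + int(w), lo + int(w) + L - 1, float(phi[w])))
    if n_skipped:
        logger.debug("window_scan: %d windows without heterozygous loci skipped",
                     n_skipped)
    return stored


def detect_a2(
    pair,
    manifest: PanelManifest,
    cfg: DetectorConfig | None = None,
) -> list[IbdSegment]:
    """Full A2 workflow: stored windows → merge by overlap → purity filter.

    Merged-segment purity p is the fraction of genotyped loci in the segment
    at which the pair shares at least one allele; segments with p below
    ``cfg.min_purity`` are removed.
    """
    cfg = cfg or DetectorConfig()
    a, b = _pair_codes(pair)
    windows = window_scan(pair, manifest, cfg)
    shared = shared_allele_counts(a, b)

    segments: list[IbdSegment] = []
    merged: list[list[int]] = []
    for chrom, s, e, _phi in windows:  # windows are sorted by (chrom, start)
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    for chrom, s, e in merged:
        sh = shared[s : e + 1]
        usable = sh != MISSING
        n_use = int(usable.sum())
        if n_use == 0:
            continue
        p = float((sh[usable] >= 1).sum() / n_use)
        if p < cfg.min_purity:
            continue
        segments.append(
            IbdSegment(
                chrom=chrom,
                start_ord=s,
                end_ord=e,
                start_bp=int(manifest.pos[s]),
                end_bp=int(manifest.pos[e]),
                n_snps=e - s + 1,
                purity=p,
                source="A2",
            )
        )
    return segments
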