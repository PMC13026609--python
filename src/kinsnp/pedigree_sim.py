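"""Gene-dropping pedigree simulator with exact identity-by-descent tracking.

Founders are drawn under Hardy–Weinberg equilibrium (and linkage
equilibrium) from the panel's allele frequencies.  Haplotypes are propagated
through pedigrees by meioses whose crossovers follow a Poisson process of
intensity 1 per 100 cM along a genetic map (no crossover interference).
Because every transmitted chromosome is a mosaic of labelled founder
haplotypes, the true IBD1/IBD2 intervals between the two target individuals
of a pedigree are known exactly and are returned alongside the genotypes.

Genotyping noise (per-SNP missingness and error) is injected independently
per cell after gene dropping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import MISSING, GeneticMap, GenotypeMatrix, PanelManifest

__all__ = [
    "RelationshipSpec",
    "TrueIbdRecord",
    "NoiseConfig",
    "SimulatedPair",
    "relationship_catalogue",
    "simulate_founders",
    "gene_drop_pair",
    "inject_noise",
    "simulate_cohort",
    "UNRELATED_ORDINAL",
]

#: Internal degree ordinal for unrelated pairs (adjacent to degree 9 so that
#: margin arithmetic in the evaluation module stays on one scale).  Reports
#: render it as "unrelated".
UNRELATED_ORDINAL = 10


@dataclass(frozen=True)
class RelationshipSpec:
    """A pedigree with two target individuals and its degree of kinship.

    ``parents[i]`` is ``None`` for founders, else a ``(p, q)`` tuple of
    individual indices appearing earlier in the list.  Expected kinship of
    the targets is ``2**-(degree_ordinal + 1)`` for related specs.
    """

    name: str
    degree_ordinal: int  # 1..9 related, UNRELATED_ORDINAL for unrelated
    parents: tuple  # tuple of None | (int, int)
    targets: tuple[int, int]

    @property
    def n_individuals(self) -> int:
        return len(self.parents)

    @property
    def founder_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.parents) if p is None]

    @property
    def expected_kinship(self) -> float:
        if self.degree_ordinal >= UNRELATED_ORDINAL:
            return 0.0
        return 2.0 ** -(self.degree_ordinal + 1)


@dataclass
class TrueIbdRecord:
    """True IBD1/IBD2 bp intervals (0-based half-open) per chromosome."""

    pair_id: str
    ibd1: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    ibd2: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def has_any_ibd(self) -> bool:
        return any(self.ibd1.values()) or any(self.ibd2.values())

    def ibd_bp(self, state: int) -> float:
        ivs = self.ibd1 if state == 1 else self.ibd2
        return float(sum(e - s for chrom in ivs.values() for s, e in chrom))

    def kinship(self, genome_bp: float) -> float:
        """Realised kinship ¼·IBD1 + ½·IBD2 as genome fractions."""
        return (0.25 * self.ibd_bp(1) + 0.5 * self.ibd_bp(2)) / genome_bp

    def ibd0_fraction(self, genome_bp: float) -> float:
        return 1.0 - (self.ibd_bp(1) + self.ibd_bp(2)) / genome_bp


@dataclass(frozen=True)
class NoiseConfig:
    """Per-SNP missingness and genotype-error rates."""

    missing_rate: float = 1e-3
    error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.missing_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("noise rates must be in [0,1]")


@dataclass
class SimulatedPair:
    """One simulated sample pair with its truth annotation."""

    pair_id: str
    relationship: str
    degree: int
    codes: np.ndarray  # int8 (2, n_loci)
    true_ibd: TrueIbdRecord


# ---------------------------------------------------------------------------
# Relationship catalogue
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self) -> None:
        self.parents: list = []

    def founder(self) -> int:
        self.parents.append(None)
        return len(self.parents) - 1

    def child(self, p: int, q: int) -> int:
        self.parents.append((p, q))
        return len(self.parents) - 1

    def descend(self, person: int, generations: int) -> int:
        """Extend a lineage by ``generations`` children with married-in founders."""
        for _ in range(generations):
            person = self.child(person, self.founder())
        return person


def _spec(name: str, degree: int, build) -> RelationshipSpec:
    b = _Builder()
    targets = build(b)
    return RelationshipSpec(name, degree, tuple(b.parents), targets)


def _lineal(generations: int):
    """Ancestor vs direct descendant ``generations`` below (1 = parent–child)."""

    def build(b: _Builder):
        f = b.founder()
        return (f, b.descend(f, generations))

    return build


def _siblings(b: _Builder):
    f, m = b.founder(), b.founder()
    return (b.child(f, m), b.child(f, m))


def _half_siblings(b: _Builder):
    shared = b.founder()
    return (b.child(shared, b.founder()), b.child(shared, b.founder()))


def _avuncular(removed: int):
    """One target vs descendant of their sibling (0 removed = uncle–nephew)."""

    def build(b: _Builder):
        f, m = b.founder(), b.founder()
        a, sib = b.child(f, m), b.child(f, m)
        return (a, b.descend(sib, 1 + removed))

    return build


def _cousins(k: int, removed: int = 0, half: bool = False):
    """k-th cousins, optionally removed; half = one shared common ancestor."""

    def build(b: _Builder):
        if half:
            s1, s2 = _half_siblings(b)
        else:
            s1, s2 = _siblings(b)
        return (b.descend(s1, k), b.descend(s2, k + removed))

    return build


def relationship_catalogue() -> list[RelationshipSpec]:
    """The 18 related pedigree types (degrees 1–9) plus "unrelated"."""
    specs = [
        _spec("parent-child", 1, _lineal(1)),
        _spec("full-siblings", 1, _siblings),
        _spec("half-siblings", 2, _half_siblings),
        _spec("grandparent-grandchild", 2, _lineal(2)),
        _spec("avuncular", 2, _avuncular(0)),
        _spec("first-cousins", 3, _cousins(1)),
        _spec("great-grandparent", 3, _lineal(3)),
        _spec("grand-avuncular", 3, _avuncular(1)),
        _spec("first-cousins-once-removed", 4, _cousins(1, removed=1)),
        _spec("half-first-cousins", 4, _cousins(1, half=True)),
        _spec("second-cousins", 5, _cousins(2)),
        _spec("first-cousins-twice-removed", 5, _cousins(1, removed=2)),
        _spec("second-cousins-once-removed", 6, _cousins(2, removed=1)),
        _spec("first-cousins-thrice-removed", 6, _cousins(1, removed=3)),
        _spec("third-cousins", 7, _cousins(3)),
        _spec("second-cousins-twice-removed", 7, _cousins(2, removed=2)),
        _spec("third-cousins-once-removed", 8, _cousins(3, removed=1)),
        _spec("fourth-cousins", 9, _cousins(4)),
    ]
    b = _Builder()
    specs.append(
        RelationshipSpec(
            "unrelated",
            UNRELATED_ORDINAL,
            (None, None),
            (0, 1),
        )
    )
    return specs


# ---------------------------------------------------------------------------
# Founder simulation
# ---------------------------------------------------------------------------

def _founder_haplotypes(
    manifest: PanelManifest, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(2n, n_loci) uint8 alleles; rows 2i, 2i+1 are founder i's haplotypes."""
    return (
        rng.random((2 * n, manifest.n_loci)) < manifest.alt_freq
    ).astype(np.uint8)


def simulate_founders(manifest: PanelManifest, n: int, seed: int) -> GenotypeMatrix:
    """Simulate ``n`` unrelated founders under HWE: dosage ~ Binomial(2, alt_freq)."""
    if n < 1:
        raise ValueError("need n >= 1 founders")
    rng = np.random.default_rng(seed)
    hap = _founder_haplotypes(manifest, n, rng)
    codes = (hap[0::2] + hap[1::2]).astype(np.int8)
    return GenotypeMatrix([f"founder{i}" for i in range(n)], codes)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _splice(
    hap_a: tuple[list[int], list[int]],
    hap_b: tuple[list[int], list[int]],
    cuts: list[int],
    start: int,
    chrom_len: int,
) -> tuple[list[int], list[int]]:
    """Recombine two parental mosaics at ``cuts``, starting on ``start`` (0/1).

    A mosaic is (breaks, labels) with breaks[0] == 0, breaks[-1] == chrom_len
    and labels[i] applying to [breaks[i], breaks[i+1]).
    """
    haps = (hap_a, hap_b)
    out_breaks = [0]
    out_labels: list[int] = []
    cur = start
    prev = 0
    for cut in [*cuts, chrom_len]:
        if cut <= prev:
            cur ^= 1
            continue
        breaks, labels = haps[cur]
        # copy pieces of haps[cur] overlapping [prev, cut)
        i = np.searchsorted(breaks, prev, side="right") - 1
        while i < len(labels) and breaks[i] < cut:
            seg_end = min(breaks[i + 1], cut)
            if out_labels and out_labels[-1] == labels[i]:
                out_breaks[-1] = seg_end
            else:
                out_labels.append(labels[i])
                out_breaks.append(seg_end)
            i += 1
        prev = cut
        cur ^= 1
    return (out_breaks, out_labels)


def _meiosis(
    parent_haps,
    chrom: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    """One gamete: Poisson crossovers (1 per 100 cM), no interference."""
    cm_len = gmap.cm_length(chrom)
    n_x = rng.poisson(cm_len / 100.0)
    chrom_len = gmap.chrom_length_bp(chrom)
    if n_x:
        cuts_cm = np.sort(rng.uniform(0.0, cm_len, n_x))
        cuts = sorted({int(round(b)) for b in gmap.cm_to_bp(chrom, cuts_cm)})
        cuts = [c for c in cuts if 0 < c < chrom_len]
    else:
        cuts = []
    start = int(rng.integers(0, 2))
    return _splice(parent_haps[0], parent_haps[1], cuts, start, chrom_len)


def _ibd_states(mosaics_a, mosaics_b, chrom_len: int) -> list[tuple[int, int, int]]:
    """Merge the four target mosaics into (start, end, ibd_state) intervals."""
    all_breaks = sorted(
        {0, chrom_len}
        | {b for m in (*mosaics_a, *mosaics_b) for b in m[0][1:-1]}
    )
    labels_at = []
    ptrs = [0, 0, 0, 0]
    mosaics = (*mosaics_a, *mosaics_b)
    out: list[tuple[int, int, int]] = []
    for s, e in zip(all_breaks[:-1], all_breaks[1:]):
        labs = []
        for k, (breaks, labels) in enumerate(mosaics):
            while breaks[ptrs[k] + 1] <= s:
                ptrs[k] += 1
            labs.append(labels[ptrs[k]])
        a0, a1, b0, b1 = labs
        used = [False, False]
        state = 0
        for x in (a0, a1):
            for kk, y in enumerate((b0, b1)):
                if not used[kk] and x == y:
                    used[kk] = True
                    state += 1
                    break
        if out and out[-1][2] == state and out[-1][1] == s:
            out[-1] = (out[-1][0], e, state)
        else:
            out.append((s, e, state))
    return out


def gene_drop_pair(
    spec: RelationshipSpec,
    founders: GenotypeMatrix | np.ndarray,
    gmap: GeneticMap,
    manifest: PanelManifest,
    seed: int | np.random.Generator,
    pair_id: str = "pair0",
    genotypes: bool = True,
) -> tuple[GenotypeMatrix | None, TrueIbdRecord]:
    """Drop founder haplotypes through ``spec`` and read out the target pair.

    ``founders`` may be a GenotypeMatrix (phase assigned at random, exact
    under HWE/linkage equilibrium) or a pre-phased (2F, n_loci) haplotype
    array.  Returns the pair's genotypes (or None when ``genotypes=False``)
    and the exact true-IBD record of the two targets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    founder_idx = spec.founder_indices
    n_f = len(founder_idx)
    if isinstance(founders, GenotypeMatrix):
        if founders.n_samples < n_f:
            raise ValueError(f"pedigree {spec.name!r} needs {n_f} founders")
        hap = np.empty((2 * n_f, founders.n_loci), dtype=np.uint8)
        for i in range(n_f):
            codes = founders.codes[i]
            a = (codes >= 1).astype(np.uint8)
            b = (codes == 2).astype(np.uint8)
            flip = rng.random(codes.size) < 0.5
            hap[2 * i] = np.where(flip, b, a)
            hap[2 * i + 1] = np.where(flip, a, b)
    else:
        hap = np.asarray(founders, dtype=np.uint8)
        if hap.shape[0] < 2 * n_f:
            raise ValueError(f"pedigree {spec.name!r} needs {n_f} phased founders")

    for c in manifest.chrom_ranges:
        if c not in gmap.anchors:
            raise ValueError(f"genetic map does not cover chromosome {c}")

    founder_slot = {ind: k for k, ind in enumerate(founder_idx)}
    record = TrueIbdRecord(pair_id)
    codes = (
        np.zeros((2, manifest.n_loci), dtype=np.int8) if genotypes else None
    )

    for chrom, (lo, hi) in sorted(manifest.chrom_ranges.items()):
        chrom_len = gmap.chrom_length_bp(chrom)
        mosaics: list = [None] * spec.n_individuals
        for ind, par in enumerate(spec.parents):
            if par is None:
                k = founder_slot[ind]
                mosaics[ind] = (
                    ([0, chrom_len], [2 * k]),
                    ([0, chrom_len], [2 * k + 1]),
                )
            else:
                mosaics[ind] = (
                    _meiosis(mosaics[par[0]], chrom, gmap, rng),
                    _meiosis(mosaics[par[1]], chrom, gmap, rng),
                )
        ta, tb = spec.targets
        states = _ibd_states(mosaics[ta], mosaics[tb], chrom_len)
        for s, e, st in states:
            if st == 1:
                record.ibd1.setdefault(chrom, []).append((s, e))
            elif st == 2:
                record.ibd2.setdefault(chrom, []).append((s, e))
        if genotypes:
            pos = manifest.pos[lo:hi]
            for row, t in enumerate((ta, tb)):
                g = np.zeros(hi - lo, dtype=np.int8)
                for breaks, labels in mosaics[t]:
                    lab = np.asarray(labels)[
                        np.searchsorted(breaks, pos, side="right") - 1
                    ]
                    g += hap[lab, np.arange(lo, hi)]
                codes[row, lo:hi] = g
    matrix = (
        GenotypeMatrix([f"{pair_id}_a", f"{pair_id}_b"], codes) if genotypes else None
    )
    return matrix, record


def inject_noise(matrix: GenotypeMatrix, cfg: NoiseConfig) -> GenotypeMatrix:
    """Apply per-cell missingness then genotype error, deterministically.

    An erroneous call is replaced by one of the two *other* dosage codes,
    uniformly, so an error never reproduces the original genotype.
    """
    rng = np.random.default_rng(cfg.seed)
    codes = matrix.codes.copy()
    u = rng.random(codes.shape)
    miss = u < cfg.missing_rate
    err = (~miss) & (u < cfg.missing_rate + cfg.error_rate) & (codes != MISSING)
    shift = 1 + (rng.random(codes.shape) < 0.5).astype(np.int8)
    codes[err] = (codes[err] + shift[err]) % 3
    codes[miss] = MISSING
    return GenotypeMatrix(list(matrix.sample_ids), codes)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Reference/test split of simulated pairs with their truth table."""

    reference: list[SimulatedPair]
    test: list[SimulatedPair]
    truth: pd.DataFrame  # pair_id, sample_a, sample_b, relationship, degree, role


def simulate_cohort(
    catalogue: list[RelationshipSpec],
    pairs_per_type: int,
    split: float,
    manifest: PanelManifest,
    gmap: GeneticMap,
    cfg: NoiseConfig,
    seed: int,
) -> Cohort:
    """Simulate ``pairs_per_type`` pairs per relationship and split them.

    The first ``round(split * pairs_per_type)`` pairs of each type form the
    reference set (used for model calibration), the rest the test set.
    Unrelated pairs are two independent HWE founders.  Noise is applied to
    every pair per ``cfg``.
    """
    if pairs_per_type < 2:
        raise ValueError("need pairs_per_type >= 2")
    ss = np.random.SeedSequence(seed)
    n_ref = int(round(split * pairs_per_type))
    reference: list[SimulatedPair] = []
    test: list[SimulatedPair] = []
    rows = []
    for spec in catalogue:
        child_seeds = ss.spawn(pairs_per_type)
        for j in range(pairs_per_type):
            rng = np.random.default_rng(child_seeds[j])
            pair_id = f"{spec.name}_{j}"
            if spec.degree_ordinal >= UNRELATED_ORDINAL:
                hap = _founder_haplotypes(manifest, 2, rng)
                codes = (hap[0::2] + hap[1::2]).astype(np.int8)
                matrix = GenotypeMatrix([f"{pair_id}_a", f"{pair_id}_b"], codes)
                record = TrueIbdRecord(pair_id)
            else:
                n_f = len(spec.founder_indices)
                hap = _founder_haplotypes(manifest, n_f, rng)
                matrix, record = gene_drop_pair(
                    spec, hap, gmap, manifest, rng, pair_id=pair_id
                )
            noise = NoiseConfig(
                cfg.missing_rate,
                cfg.error_rate,
                int(rng.integers(0, 2**31 - 1)),
            )
            matrix = inject_noise(matrix, noise)
            pair = SimulatedPair(
                pair_id, spec.name, spec.degree_ordinal, matrix.codes, record
            )
            role = "reference" if j < n_ref else "test"
            (reference if j < n_ref else test).append(pair)
            rows.append(
                (pair_id, f"{pair_id}_a", f"{pair_id}_b", spec.name,
                 spec.degree_ordinal, role)
            )
    truth = pd.DataFrame(
        rows, columns=["pair_id", "sample_a", "sample_b", "relationship", "degree", "role"]
    )
    return Cohort(reference, test, truth)
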