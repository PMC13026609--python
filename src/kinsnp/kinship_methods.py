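"""Reference models and the five kinship-inference methods.

Four IBD-based methods classify a pair from its detected segments:

* mean total segment length — nearest relationship mean MS(r);
* gamma distributions — maximum-likelihood gamma fits to segment-length
  distributions, compared by mean absolute density difference over a
  1–150 Mbp grid;
* conditional probability — P(relationship | total shared length) learned
  on 50 Mbp bins over 0–3000 Mbp;
* IBD0 proportion — (genome − total shared)/genome matched against the
  analytic degree ranges (expected 1 − 2^(1−d) for degree d).

One IBS-based method works directly on genotypes: the robust kinship
coefficient φ estimated from heterozygote/opposite-homozygote counts,
matched against its analytic degree ranges (expected 2^−(d+1)).
PCA/PCoA pair embeddings are provided for exploration only; no classifier
is built on them.

All classifier ties resolve toward the higher degree ordinal (the more
conservative claim of relatedness).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .ibd_detect import DetectorConfig, IbdSegment, InformativityMap
from .panel_io import MISSING, PanelManifest, shared_allele_counts
from .pedigree_sim import UNRELATED_ORDINAL

logger = logging.getLogger(__name__)

__all__ = [
    "GammaParams",
    "ConditionalTable",
    "DegreeRanges",
    "ReferenceModel",
    "InferenceResult",
    "total_shared_length",
    "build_reference_model",
    "classify_mean_length",
    "fit_gamma",
    "gamma_profile",
    "gamma_distance",
    "classify_gamma",
    "classify_conditional",
    "ibd0_classify",
    "king_phi",
    "king_classify",
    "pair_sharing_matrix",
    "embed_pairs",
]


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale of a gamma segment-length model (lengths in Mbp)."""

    k: float
    theta: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.theta <= 0:
            raise ValueError("gamma shape and scale must be positive")


@dataclass(frozen=True)
class InferenceResult:
    """One pair's call by one method.

    ``degree`` is the inferred degree ordinal (1–9, or 10 for unrelated);
    an abstention carries ``degree=None`` and scores as incorrect.
    """

    pair_id: str
    method: str
    relationship: str | None
    degree: int | None
    score: float | None
    abstained: bool = False


def total_shared_length(segments: Iterable[IbdSegment]) -> float:
    """Total detected shared length in Mbp (0 for no segments)."""
    return float(sum(s.length_mbp for s in segments))


# ---------------------------------------------------------------------------
# Analytic degree ranges (IBD0 proportion and kinship coefficient)
# ---------------------------------------------------------------------------

class DegreeRanges:
    """Expected values and (lo, hi] inference intervals per kinship class.

    IBD0 proportion: expected 1 − 2^(1−d) for degree d (0 for parent–child,
    0.25 for siblings), with class boundaries at 1 − 2^−((2d−1)/2); the
    upper bound is inclusive and unrelated takes everything above
    1 − 2^−(17/2).  Kinship coefficient: expected 2^−(d+1) with boundaries
    2^−((2d+1)/2), unrelated at or below 2^−(21/2).  Both tables tile their
    domain without overlap.
    """

    def __init__(self) -> None:
        # (label, degree, expected, lo_exclusive, hi_inclusive)
        self.ibd0: list[tuple[str, int, float, float, float]] = []
        self.ibd0.append(("parent-child", 1, 0.0, -math.inf, 0.1))
        self.ibd0.append(("siblings", 1, 0.25, 0.1, 0.365))
        prev = 0.365
        for d in range(2, 10):
            hi = 1 - 2 ** (-(2 * d - 1) / 2)
            self.ibd0.append((f"degree-{d}", d, 1 - 2 ** (1 - d), prev, hi))
            prev = hi
        self.ibd0.append(("unrelated", UNRELATED_ORDINAL, 1.0, prev, math.inf))

        self.king: list[tuple[str, int, float, float, float]] = []
        for d in range(1, 10):
            lo = 2 ** (-(2 * d + 3) / 2)
            hi = 2 ** (-(2 * d + 1) / 2)
            self.king.append((f"degree-{d}", d, 2 ** -(d + 1), lo, hi))
        self.king.append(
            ("unrelated", UNRELATED_ORDINAL, 0.0, -math.inf, 2 ** (-21 / 2))
        )

    def expected_ibd0(self, degree: int) -> float:
        for _, d, exp, _, _ in self.ibd0:
            if d == degree:
                return exp
        raise KeyError(degree)

    def lookup_ibd0(self, proportion: float) -> tuple[str, int]:
        for label, d, _, lo, hi in self.ibd0:
            if lo < proportion <= hi:
                return label, d
        raise ValueError(f"IBD0 proportion {proportion} outside (0,1] tiling")

    def lookup_king(self, phi: float) -> tuple[str, int]:
        for label, d, _, lo, hi in self.king:
            if lo < phi <= hi:
                return label, d
        raise ValueError(f"kinship coefficient {phi} not covered")


# ---------------------------------------------------------------------------
# Gamma segment-length modelling
# ---------------------------------------------------------------------------

def fit_gamma(lengths: Sequence[float]) -> GammaParams | None:
    """Fit a gamma model to segment lengths by ML; scale = mean/k.

    The shape k comes from the maximum-likelihood gamma fit (location fixed
    at zero); the scale is then re-derived as mean(lengths)/k so that the
    fitted model reproduces the sample mean exactly.  Returns ``None``
    (an abstention) for fewer than two lengths or degenerate identical
    lengths, for which no distribution can be modelled.
    """
    x = np.asarray(list(lengths), dtype=float)
    if x.size < 2 or np.ptp(x) == 0.0:
        return None
    k, _loc, _scale = scipy.stats.gamma.fit(x, floc=0.0)
    return GammaParams(k=float(k), theta=float(x.mean() / k))


def gamma_profile(params: GammaParams, x_max: int = 150) -> np.ndarray:
    """Gamma density over the integer grid 1..x_max Mbp."""
    x = np.arange(1, x_max + 1, dtype=float)
    return scipy.stats.gamma.pdf(x, a=params.k, scale=params.theta)


def gamma_distance(profile_p: np.ndarray, profile_r: np.ndarray) -> float:
    """Mean absolute difference between two equal-length density profiles."""
    p = np.asarray(profile_p, float)
    r = np.asarray(profile_r, float)
    if p.shape != r.shape:
        raise ValueError("gamma profiles must be the same length")
    return float(np.abs(p - r).mean())


# ---------------------------------------------------------------------------
# Conditional probability table
# ---------------------------------------------------------------------------

@dataclass
class ConditionalTable:
    """P(relationship | total-shared-length bin) on 50 Mbp bins over 0–3000.

    ``counts`` holds reference-pair counts per (bin, relationship); totals
    above the last edge are clamped into the final bin.  Probabilities in a
    populated bin sum to one; queries hitting an empty bin fall back to the
    nearest populated bin (ties toward the lower bin).
    """

    edges: np.ndarray  # 61 edges: 0, 50, ..., 3000
    counts: pd.DataFrame  # index = bin ordinal, columns = relationships

    @classmethod
    def from_totals(
        cls,
        totals: Iterable[tuple[str, float]],
        bin_mbp: float = 50.0,
        max_mbp: float = 3000.0,
        relationships: Sequence[str] | None = None,
    ) -> "ConditionalTable":
        edges = np.arange(0.0, max_mbp + bin_mbp, bin_mbp)
        n_bins = len(edges) - 1
        rels = list(relationships) if relationships is not None else sorted(
            {r for r, _ in totals}
        )
        counts = pd.DataFrame(0, index=range(n_bins), columns=rels, dtype=int)
        for rel, total in totals:
            b = min(int(total // bin_mbp), n_bins - 1)
            counts.loc[b, rel] += 1
        return cls(edges=edges, counts=counts)

    def bin_of(self, total_mbp: float) -> int:
        n_bins = len(self.edges) - 1
        return min(int(total_mbp // (self.edges[1] - self.edges[0])), n_bins - 1)

    def probabilities(self, total_mbp: float) -> pd.Series | None:
        """P(R|S) in the bin of ``total_mbp``, via nearest-populated fallback."""
        b = self.bin_of(total_mbp)
        row_sums = self.counts.sum(axis=1)
        if row_sums.iloc[b] == 0:
            populated = np.flatnonzero(row_sums.to_numpy() > 0)
            if populated.size == 0:
                return None
            # nearest populated bin, ties toward the lower bin
            b = int(populated[np.argmin(np.abs(populated - b) + (populated > b) * 0.5)])
        row = self.counts.loc[b]
        return row / row.sum()


# ---------------------------------------------------------------------------
# Reference model
# ---------------------------------------------------------------------------

@dataclass
class ReferenceModel:
    """Everything a detector+classifier stack learns from the reference set."""

    detector: str  # "A1" or "A2"
    degrees: dict[str, int]  # relationship -> degree ordinal
    ms: dict[str, float]  # mean total segment length per relationship
    gammas: dict[str, GammaParams | None]
    conditional: ConditionalTable
    genome_length_mbp: float
    ranges: DegreeRanges = field(default_factory=DegreeRanges)
    info: InformativityMap | None = None
    config: DetectorConfig | None = None
    x_max: int = 150

    def gamma_profiles(self) -> dict[str, np.ndarray]:
        if not hasattr(self, "_profiles"):
            self._profiles = {
                r: gamma_profile(p, self.x_max)
                for r, p in self.gammas.items()
                if p is not None
            }
        return self._profiles

    def to_json(self, path) -> None:
        payload = {
            "detector": self.detector,
            "degrees": self.degrees,
            "ms": self.ms,
            "gammas": {
                r: (None if p is None else {"k": p.k, "theta": p.theta})
                for r, p in self.gammas.items()
            },
            "conditional": {
                "edges": self.conditional.edges.tolist(),
                "counts": self.conditional.counts.to_dict(orient="list"),
            },
            "genome_length_mbp": self.genome_length_mbp,
            "x_max": self.x_max,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            d = json.load(fh)
        n_bins = len(d["conditional"]["edges"]) - 1
        counts = pd.DataFrame(d["conditional"]["counts"], index=range(n_bins))
        return cls(
            detector=d["detector"],
            degrees={r: int(v) for r, v in d["degrees"].items()},
            ms={r: float(v) for r, v in d["ms"].items()},
            gammas={
                r: (None if p is None else GammaParams(p["k"], p["theta"]))
                for r, p in d["gammas"].items()
            },
            conditional=ConditionalTable(
                edges=np.asarray(d["conditional"]["edges"], float), counts=counts
            ),
            genome_length_mbp=float(d["genome_length_mbp"]),
            x_max=int(d["x_max"]),
        )


def build_reference_model(
    reference: Iterable[tuple[str, int, list[IbdSegment]]],
    genome_length_mbp: float,
    detector: str = "A1",
    info: InformativityMap | None = None,
    config: DetectorConfig | None = None,
) -> ReferenceModel:
    """Build per-relationship metrics from detected reference-pair segments.

    ``reference`` yields (relationship, degree, segments) per reference
    pair.  MS is the mean of per-pair totals; the gamma model is fitted to
    all segments of a relationship pooled; the conditional table counts
    per-pair totals in 50 Mbp bins.  A relationship whose pooled segments
    cannot support a gamma fit gets ``None`` there (logged) and MS falls
    back on whatever totals exist.
    """
    totals: dict[str, list[float]] = {}
    pooled: dict[str, list[float]] = {}
    degrees: dict[str, int] = {}
    for rel, degree, segments in reference:
        degrees[rel] = degree
        totals.setdefault(rel, []).append(total_shared_length(segments))
        pooled.setdefault(rel, []).extend(s.length_mbp for s in segments)

    ms = {r: float(np.mean(v)) for r, v in totals.items()}
    gammas: dict[str, GammaParams | None] = {}
    for r, lengths in pooled.items():
        gammas[r] = fit_gamma(lengths)
        if gammas[r] is None:
            logger.info("no gamma model for %r (%d segments)", r, len(lengths))
    conditional = ConditionalTable.from_totals(
        [(r, t) for r, v in totals.items() for t in v],
        relationships=sorted(totals, key=lambda r: (degrees[r], r)),
    )
    return ReferenceModel(
        detector=detector,
        degrees=degrees,
        ms=ms,
        gammas=gammas,
        conditional=conditional,
        genome_length_mbp=genome_length_mbp,
        info=info,
        config=config,
    )


def _argbest(
    scores: dict[str, float], degrees: dict[str, int], minimise: bool
) -> tuple[str, float]:
    """Best-scoring relationship; ties resolve toward the higher degree."""
    sign = 1.0 if minimise else -1.0
    best = min(
        scores.items(),
        key=lambda kv: (sign * kv[1], -degrees[kv[0]]),
    )
    return best


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def classify_mean_length(
    total_mbp: float, model: ReferenceModel, pair_id: str = ""
) -> InferenceResult:
    """Nearest-mean classification on the total shared segment length."""
    diffs = {r: abs(total_mbp - m) for r, m in model.ms.items()}
    rel, score = _argbest(diffs, model.degrees, minimise=True)
    return InferenceResult(pair_id, f"{model.detector}-mean_length", rel,
                          model.degrees[rel], score)


def classify_gamma(
    segments: Sequence[IbdSegment], model: ReferenceModel, pair_id: str = ""
) -> InferenceResult:
    """Gamma-profile distance classification; abstains below two segments."""
    method = f"{model.detector}-gamma"
    params = fit_gamma([s.length_mbp for s in segments])
    if params is None:
        return InferenceResult(pair_id, method, None, None, None, abstained=True)
    profile = gamma_profile(params, model.x_max)
    dists = {
        r: gamma_distance(profile, ref)
        for r, ref in model.gamma_profiles().items()
    }
    if not dists:
        return InferenceResult(pair_id, method, None, None, None, abstained=True)
    rel, score = _argbest(dists, model.degrees, minimise=True)
    return InferenceResult(pair_id, method, rel, model.degrees[rel], score)


def classify_conditional(
    total_mbp: float, model: ReferenceModel, pair_id: str = ""
) -> InferenceResult:
    """Most probable relationship given the pair's total-shared-length bin."""
    method = f"{model.detector}-conditional"
    probs = model.conditional.probabilities(total_mbp)
    if probs is None:
        return InferenceResult(pair_id, method, None, None, None, abstained=True)
    rel, score = _argbest(dict(probs), model.degrees, minimise=False)
    return InferenceResult(pair_id, method, rel, model.degrees[rel], score)


def ibd0_classify(
    total_mbp: float,
    genome_length_mbp: float,
    ranges: DegreeRanges,
    pair_id: str = "",
    detector: str = "",
) -> InferenceResult:
    """Classify by the proportion of the genome with no detected sharing."""
    if total_mbp > genome_length_mbp * (1 + 1e-9):
        raise ValueError("total shared length exceeds genome length")
    proportion = (genome_length_mbp - min(total_mbp, genome_length_mbp)) / genome_length_mbp
    label, degree = ranges.lookup_ibd0(proportion)
    method = f"{detector}-ibd0" if detector else "ibd0"
    return InferenceResult(pair_id, method, label, degree, proportion)


@dataclass(frozen=True)
class KingCounts:
    n_both_het: int
    n_opp_hom: int
    n_het_i: int
    n_het_j: int


def king_phi(pair, convention: str = "lesser") -> tuple[float | None, KingCounts]:
    """Robust kinship-coefficient estimate from IBS state counts.

    φ = (N_Aa,Aa − 2·N_AA,aa)/(2·N_Aa(i)) + 1/2 − (N_Aa(i)+N_Aa(j))/(4·N_Aa(i)).

    ``convention`` picks which sample plays the role of i: ``"lesser"``
    (default) uses the sample with fewer heterozygous loci, the original
    robust-estimator designation, which is conservative — for equal expected
    heterozygosities it biases φ̂ down by roughly E|N_Aa(a) − N_Aa(b)| /
    (4·N_Aa(i)), so unrelated pairs stay below the most distant inference
    bound.  ``"greater"`` applies the opposite designation, whose mirror-image
    upward bias inflates the apparent relatedness of unrelated pairs at
    medium panel density.  Loci missing in either sample are excluded from
    every count.  Returns (None, counts) when sample i has no heterozygous
    locus (abstention).
    """
    if convention not in ("lesser", "greater"):
        raise ValueError("convention must be 'lesser' or 'greater'")
    codes = pair.codes if hasattr(pair, "codes") else np.asarray(pair)
    a, b = codes[0], codes[1]
    valid = (a != MISSING) & (b != MISSING)
    het_a = int((valid & (a == 1)).sum())
    het_b = int((valid & (b == 1)).sum())
    n_both = int((valid & (a == 1) & (b == 1)).sum())
    n_opp = int((valid & (np.abs(a.astype(np.int16) - b) == 2)).sum())
    if convention == "lesser":
        n_i, n_j = min(het_a, het_b), max(het_a, het_b)
    else:
        n_i, n_j = max(het_a, het_b), min(het_a, het_b)
    counts = KingCounts(n_both, n_opp, n_i, n_j)
    if n_i == 0:
        return None, counts
    phi = (n_both - 2.0 * n_opp) / (2.0 * n_i) + 0.5 - (n_i + n_j) / (4.0 * n_i)
    return float(phi), counts


def king_classify(
    phi: float | None, ranges: DegreeRanges, pair_id: str = ""
) -> InferenceResult:
    """Map a kinship coefficient to its degree interval (upper-inclusive).

    φ above the first-degree upper bound (e.g. duplicates/twins) is clamped
    to degree 1 with a log note; the estimator can go slightly negative for
    unrelated pairs, which the unrelated interval absorbs.
    """
    if phi is None:
        return InferenceResult(pair_id, "king", None, None, None, abstained=True)
    top = ranges.king[0][4]  # degree-1 upper bound 2^-3/2
    if phi > top:
        logger.info("phi=%.4f above first-degree bound; clamped", phi)
        return InferenceResult(pair_id, "king", "degree-1", 1, phi)
    label, degree = ranges.lookup_king(phi)
    return InferenceResult(pair_id, "king", label, degree, phi)


# ---------------------------------------------------------------------------
# Exploratory pair embeddings
# ---------------------------------------------------------------------------

def pair_sharing_matrix(
    pairs: Sequence, manifest: PanelManifest, missing_policy: str = "pca"
) -> np.ndarray:
    """One row per pairing, one column per SNP, entries = shared alleles.

    Missing genotypes become −1 under the PCA policy and NaN under the PCoA
    policy (pairwise-complete distance computation).
    """
    if missing_policy not in ("pca", "pcoa"):
        raise ValueError("missing_policy must be 'pca' or 'pcoa'")
    rows = np.empty((len(pairs), manifest.n_loci),
                    dtype=np.float64 if missing_policy == "pcoa" else np.int8)
    for i, pair in enumerate(pairs):
        codes = pair.codes if hasattr(pair, "codes") else np.asarray(pair)
        shared = shared_allele_counts(codes[0], codes[1])
        if missing_policy == "pcoa":
            row = shared.astype(np.float64)
            row[shared == MISSING] = np.nan
            rows[i] = row
        else:
            rows[i] = shared
    return rows


def embed_pairs(
    matrix: np.ndarray, method: str = "pca", n_components: int = 2
) -> np.ndarray:
    """Project pair-sharing rows to exploratory coordinates.

    PCA: column-centred principal components.  PCoA: classical scaling of
    the pairwise count-of-differences distance matrix computed over
    pairwise-complete columns.  ``n_components`` above the achievable rank
    is truncated with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two pairings to embed")
    rank_bound = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank_bound:
        logger.warning("n_components truncated from %d to %d", n_components, rank_bound)
        n_components = rank_bound
    if method.lower() == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=n_components).fit_transform(X)
    if method.lower() == "pcoa":
        from skbio.stats.ordination import pcoa

        valid = ~np.isnan(X)
        n = X.shape[0]
        D = np.zeros((n, n))
        for i in range(n):
            both = valid[i] & valid[i + 1 :]
            diff = (X[i] != X[i + 1 :]) & both
            D[i, i + 1 :] = diff.sum(axis=1)
        D = D + D.T
        res = pcoa(D, number_of_dimensions=n_components)
        return res.samples.to_numpy()[:, :n_components]
    raise ValueError(f"unknown embedding method {method!r}")
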