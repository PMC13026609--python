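"""End-to-end study orchestration: simulate → calibrate → detect → infer.

This is the programmatic counterpart of the CLI: one call simulates a
cohort on a synthetic panel, calibrates reference models for both IBD
detectors from the reference half, and classifies the test half with the
retained method–algorithm combinations (mean length, conditional
probability and IBD0 under each of A1 and A2, plus the kinship
coefficient; the gamma method can be included as an extra).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import ibd_detect, kinship_methods as km
from .ibd_detect import DetectorConfig, InformativityMap
from .panel_io import GeneticMap, PanelManifest, derive_gap_mask, generate_panel_fixture
from .pedigree_sim import (
    Cohort,
    NoiseConfig,
    SimulatedPair,
    relationship_catalogue,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

#: The seven retained algorithm–method combinations.
RETAINED_METHODS = (
    "A1-mean_length",
    "A1-conditional",
    "A1-ibd0",
    "A2-mean_length",
    "A2-conditional",
    "A2-ibd0",
    "king",
)


@dataclass
class StudyResult:
    """Cohort, calibrated models and per-method test inferences."""

    cohort: Cohort
    models: dict[str, km.ReferenceModel]  # keyed "A1"/"A2"
    info: InformativityMap
    results: dict[str, pd.DataFrame]  # method -> results frame
    config: DetectorConfig

    @property
    def truth(self) -> pd.DataFrame:
        return self.cohort.truth


def default_panel(seed: int, n_snps: int = 10_030) -> tuple[PanelManifest, GeneticMap]:
    """Synthetic 22-autosome panel with a uniform map of ~3,500 cM total.

    The map is flat in cM/Mbp but scaled to the sex-averaged autosomal
    genetic length of human pedigree maps, so crossover counts per meiosis
    (and hence segment-number statistics) are realistic.
    """
    manifest = generate_panel_fixture(n_snps, 22, seed=seed)
    from ._autosomes import AVG_CM_PER_MBP, GRCH38_AUTOSOME_BP

    gmap = GeneticMap.uniform(
        {c + 1: int(GRCH38_AUTOSOME_BP[c]) for c in range(22)},
        cm_per_mbp=AVG_CM_PER_MBP,
    )
    return manifest, gmap


def _detect_all(
    pairs: list[SimulatedPair],
    manifest: PanelManifest,
    info: InformativityMap,
    cfg: DetectorConfig,
) -> dict[str, dict[str, list]]:
    out = {"A1": {}, "A2": {}}
    for pair in pairs:
        out["A1"][pair.pair_id] = ibd_detect.detect_a1(pair.codes, manifest, info, cfg)
        out["A2"][pair.pair_id] = ibd_detect.detect_a2(pair.codes, manifest, cfg)
    return out


def run_study(
    manifest: PanelManifest,
    gmap: GeneticMap,
    pairs_per_type: int = 50,
    split: float = 0.5,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    config: DetectorConfig | None = None,
    include_gamma: bool = False,
    catalogue=None,
) -> StudyResult:
    """Run the full simulation study on one panel.

    Masks default to the panel's derived coverage-gap mask (5 Mbp).  The
    informativity map is calibrated on the unfiltered base runs of every
    reference pair; reference models for A1 and A2 are then built from the
    detected segments of the reference pairs, and every test pair is
    classified by the retained methods.
    """
    catalogue = catalogue or relationship_catalogue()
    noise = noise or NoiseConfig(seed=seed)
    if config is None:
        config = DetectorConfig(masks=derive_gap_mask(manifest, 5.0))

    logger.info("simulating cohort: %d types x %d pairs", len(catalogue), pairs_per_type)
    cohort = simulate_cohort(catalogue, pairs_per_type, split, manifest, gmap, noise, seed)

    logger.info("calibrating informativity on %d reference pairs", len(cohort.reference))
    base_runs = []
    for pair in cohort.reference:
        base_runs.extend(ibd_detect.concordance_runs(pair.codes, manifest))
    info = ibd_detect.snp_informativity(base_runs, manifest)

    genome_mbp = manifest.genome_span_mbp()
    ref_segments = _detect_all(cohort.reference, manifest, info, config)
    by_pair = {p.pair_id: p for p in cohort.reference}
    models = {}
    for det in ("A1", "A2"):
        models[det] = km.build_reference_model(
            (
                (by_pair[pid].relationship, by_pair[pid].degree, segs)
                for pid, segs in ref_segments[det].items()
            ),
            genome_length_mbp=genome_mbp,
            detector=det,
            info=info,
            config=config,
        )

    logger.info("classifying %d test pairs", len(cohort.test))
    test_segments = _detect_all(cohort.test, manifest, info, config)
    results: dict[str, list] = {m: [] for m in RETAINED_METHODS}
    if include_gamma:
        results.update({"A1-gamma": [], "A2-gamma": []})
    ranges = km.DegreeRanges()
    for pair in cohort.test:
        for det in ("A1", "A2"):
            segs = test_segments[det][pair.pair_id]
            total = km.total_shared_length(segs)
            model = models[det]
            results[f"{det}-mean_length"].append(
                km.classify_mean_length(total, model, pair.pair_id)
            )
            results[f"{det}-conditional"].append(
                km.classify_conditional(total, model, pair.pair_id)
            )
            results[f"{det}-ibd0"].append(
                km.ibd0_classify(total, genome_mbp, ranges, pair.pair_id, det)
            )
            if include_gamma:
                results[f"{det}-gamma"].append(
                    km.classify_gamma(segs, model, pair.pair_id)
                )
        phi, _counts = km.king_phi(pair.codes)
        results["king"].append(km.king_classify(phi, ranges, pair.pair_id))

    frames = {m: _frame(v) for m, v in results.items()}
    return StudyResult(cohort=cohort, models=models, info=info, results=frames,
                       config=config)


def _frame(results):
    from .evaluation import results_frame

    return results_frame(results)
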