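import numpy as np
import pandas as pd
import pytest

from kinsnp import GeneticMap, PanelManifest, generate_panel_fixture
from kinsnp.panel_io import MANIFEST_COLUMNS


def manifest_from_rows(rows) -> PanelManifest:
    """Build a manifest from (chrom, pos, id, ref, alt, category, alt_freq) rows."""
    return PanelManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


def uniform_manifest(n: int, spacing_bp: int = 1_000_000, chrom: int = 1,
                     alt_freq: float = 0.5) -> PanelManifest:
    """n equally spaced SNPs on one chromosome, all at the same frequency."""
    rows = [
        (chrom, (i + 1) * spacing_bp, f"m{chrom}_{i}", "A", "G", "kiSNP", alt_freq)
        for i in range(n)
    ]
    return manifest_from_rows(rows)


@pytest.fixture(scope="session")
def small_panel():
    """A compact multi-chromosome fixture panel (fast for detection tests)."""
    return generate_panel_fixture(1200, 6, seed=7)


@pytest.fixture(scope="session")
def small_map(small_panel):
    from kinsnp._autosomes import AVG_CM_PER_MBP, GRCH38_AUTOSOME_BP

    return GeneticMap.uniform(
        {c + 1: int(GRCH38_AUTOSOME_BP[c]) for c in range(6)},
        cm_per_mbp=AVG_CM_PER_MBP,
    )


@pytest.fixture(scope="session")
def full_panel():
    """Panel at the density of the emulated kit (10,030 SNPs, 22 autosomes)."""
    from kinsnp.pipeline import default_panel

    manifest, gmap = default_panel(seed=1)
    return manifest, gmap
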