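import numpy as np
import pandas as pd
import pytest

from cliptome.annotation_io import TranscriptModel
from cliptome.coverage import BED6_COLS
from cliptome.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture
def single_exon_plus():
    """Plus-strand single-exon gene: exon [100,400), CDS [150,350)."""
    return TranscriptModel("txp", "gp", "chr1", "+", ((100, 400),), (150, 350))


@pytest.fixture
def single_exon_minus():
    """Same intervals on the minus strand (5'UTR at the high genomic end)."""
    return TranscriptModel("txm", "gm", "chr1", "-", ((100, 400),), (150, 350))


@pytest.fixture
def two_exon_plus():
    """Two exons [0,100)+[200,300), CDS [50,250): intron excluded from CDS."""
    return TranscriptModel("tx2", "g2", "chr1", "+", ((0, 100), (200, 300)), (50, 250))


def make_reads(rows):
    """rows: iterable of (chrom, start, end, strand) -> BED6 frame."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df["name"] = "r"
    df["score"] = 0
    return df[BED6_COLS]


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact synthetic dataset shared across tests (deterministic)."""
    out = tmp_path_factory.mktemp("smalldata")
    cfg = SyntheticConfig(
        n_genes=120,
        n_true_targets=25,
        rnaseq_library_size=200_000,
        clip_library_size=80_000,
        rip_library_size=80_000,
        seed=7,
    )
    return generate_dataset(cfg, out)


def random_models(rng: np.random.Generator, n: int) -> list[TranscriptModel]:
    """Random multi-exon transcript models for property tests."""
    models = []
    for i in range(n):
        n_exons = int(rng.integers(1, 5))
        pos = int(rng.integers(0, 1000))
        exons = []
        for _ in range(n_exons):
            a = pos + int(rng.integers(1, 50))
            b = a + int(rng.integers(20, 200))
            exons.append((a, b))
            pos = b
        strand = "+" if rng.random() < 0.5 else "-"
        # CDS inside the exon span, snapped to exonic bases
        gpos = np.concatenate([np.arange(a, b) for a, b in exons])
        if len(gpos) > 10:
            lo, hi = sorted(rng.choice(len(gpos), 2, replace=False))
            cds = (int(gpos[lo]), int(gpos[hi]) + 1)
        else:
            cds = None
        models.append(
            TranscriptModel(f"t{i}", f"g{i}", "chrT", strand, tuple(exons), cds)
        )
    return models
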