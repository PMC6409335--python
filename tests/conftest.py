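import numpy as np
import pytest

from adipolinc.io_formats import GenomicInterval, TranscriptModel
from adipolinc.synthetic_data import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The default synthetic study (seed 1), generated once per session."""
    outdir = tmp_path_factory.mktemp("study")
    truth, paths = generate_study(SimulationConfig(seed=1), outdir)
    return truth, paths


def make_transcript(
    tid: str,
    chrom: str = "chr1",
    exon_coords: list[tuple[int, int]] | None = None,
    strand: str = "+",
    gene_id: str | None = None,
    biotype: str = "unassigned",
) -> TranscriptModel:
    exon_coords = exon_coords or [(0, 100), (200, 300)]
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    return TranscriptModel(tid, gene_id or f"{tid}_gene", exons, biotype=biotype)


def random_transcripts(rng: np.random.Generator, n: int, chroms=("chr1", "chr2")):
    """Random multi-exon transcripts for oracle comparisons."""
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, 900_000))
        n_ex = int(rng.integers(1, 4))
        coords = []
        pos = start
        for _ in range(n_ex):
            length = int(rng.integers(50, 500))
            coords.append((pos, pos + length))
            pos += length + int(rng.integers(50, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(make_transcript(f"t{i}", chrom, coords, strand))
    return out
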