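"""Shared fixtures: toy gene models and SAM fixture builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from titinpsi import ExonRecord, GeneModel

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{chrom}\tLN:{length}\n"


@pytest.fixture
def toy_model() -> GeneModel:
    """Three 100-nt exons on the plus strand at 100-200, 300-400, 500-600."""
    return GeneModel(
        "toy_tx", "chr1", "+",
        [ExonRecord(1, 100, 200), ExonRecord(2, 300, 400),
         ExonRecord(3, 500, 600)],
    )


def sam_line(name: str, pos0: int, cigar: str, mapq: int = 60,
             flag: int = 0, chrom: str = "chr1") -> str:
    """One SAM record; ``pos0`` is 0-based (converted to 1-based POS)."""
    import re

    seqlen = sum(int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)
                 if op in "MIS=X")
    return (f"{name}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t"
            f"{'A' * seqlen}\t*")


def write_sam(path, lines: list[str], chrom: str = "chr1",
              length: int = 10000) -> str:
    content = SAM_HEADER.format(chrom=chrom, length=length) + "\n".join(lines)
    path.write_text(content + "\n")
    return str(path)


def random_toy_fixture(rng: np.random.Generator, max_exons: int = 5,
                       max_reads: int = 200):
    """Random small gene model plus random (possibly spliced) SAM records.

    Reads land anywhere near the gene with arbitrary block/intron structure,
    random MAPQ, and occasional secondary flags, to stress the classifier.
    """
    n_exons = int(rng.integers(2, max_exons + 1))
    pos, exons = 100, []
    for i in range(1, n_exons + 1):
        elen = int(rng.integers(30, 150))
        exons.append(ExonRecord(i, pos, pos + elen))
        pos += elen + int(rng.integers(50, 200))
    model = GeneModel(f"rand{rng.integers(1e6)}", "chr1", "+", exons)
    span = model.span
    lines = []
    n_reads = int(rng.integers(10, max_reads + 1))
    for r in range(n_reads):
        start = int(rng.integers(max(0, span[0] - 60), span[1] + 20))
        mapq = int(rng.choice([0, 5, 10, 30, 60]))
        flag = int(rng.choice([0, 0, 0, 16, 256]))
        if rng.random() < 0.5:
            cigar = f"{int(rng.integers(20, 60))}M"
        else:
            b1, gap, b2 = (int(rng.integers(10, 40)),
                           int(rng.integers(40, 400)),
                           int(rng.integers(10, 40)))
            cigar = f"{b1}M{gap}N{b2}M"
        lines.append(sam_line(f"r{r}", start, cigar, mapq=mapq, flag=flag))
    return model, lines


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


def metadata_frame(samples: list[str]) -> pd.DataFrame:
    """Metadata derived from '{genotype}_{muscle}_{k}' sample ids."""
    rows = []
    for s in samples:
        genotype, muscle, _ = s.split("_")
        rows.append({"sample_id": s, "genotype": genotype, "muscle": muscle})
    return pd.DataFrame(rows).set_index("sample_id")
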