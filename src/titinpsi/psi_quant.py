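"""Percent-spliced-in quantification from spliced alignments.

For every counting bin of the gene model, junction-informative evidence is
tallied per sample: *inclusion* reads overlap the bin body (or splice to one
of its boundaries), *exclusion* reads carry an intron that spans the whole
bin. PSI is the position-normalised inclusion fraction

    psi = (I / pI) / (I / pI + E / pE)

where pI and pE are the numbers of distinct read placements that could have
produced each read class (bin_length + L - 1 and L - 1 for read length L);
``normalize="raw"`` sets both denominators to 1. A bin with fewer than
``min_support`` informative reads in a sample yields a missing PSI.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd

from .gene_model import CountingBin, GeneModel

logger = logging.getLogger("titinpsi")

DEFAULT_MIN_SUPPORT = 10
DEFAULT_MAPQ_MIN = 10


@dataclass
class BinCounts:
    """Inclusion/exclusion evidence for one bin in one sample."""

    sample_id: str
    bin_id: str
    inclusion_reads: int
    exclusion_reads: int
    inclusion_positions: int = 1
    exclusion_positions: int = 1

    def __post_init__(self) -> None:
        if self.inclusion_reads < 0 or self.exclusion_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.inclusion_positions < 1 or self.exclusion_positions < 1:
            raise ValueError("position denominators must be >= 1")

    @property
    def total_support(self) -> int:
        return self.inclusion_reads + self.exclusion_reads


@dataclass(frozen=True)
class PsiValue:
    sample_id: str
    bin_id: str
    psi: float | None
    total_support: int


@dataclass
class PsiTable:
    """Samples x bins PSI matrix with read-support provenance and metadata.

    ``psi`` and ``support`` are DataFrames indexed by sample_id with bin_id
    columns in transcript order; ``meta`` is indexed by sample_id with
    ``genotype`` and ``muscle`` columns. Missing PSI is NaN.
    """

    psi: pd.DataFrame
    support: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.psi.index.equals(self.support.index):
            raise ValueError("psi and support must share the sample index")
        missing = set(self.psi.index) - set(self.meta.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.psi.index)

    @property
    def bin_ids(self) -> list[str]:
        return list(self.psi.columns)

    def to_tsv(self, path: str | os.PathLike) -> None:
        long = (
            self.psi.stack(future_stack=True)
            .rename("psi")
            .reset_index()
            .set_axis(["sample_id", "bin_id", "psi"], axis=1)
        )
        long["support"] = self.support.stack(future_stack=True).to_numpy()
        long.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, psi_path, meta_path_or_df) -> "PsiTable":
        long = pd.read_csv(psi_path, sep="\t", na_values=["NA"],
                           dtype={"sample_id": str, "bin_id": str})
        psi = long.pivot(index="sample_id", columns="bin_id", values="psi")
        support = long.pivot(index="sample_id", columns="bin_id", values="support")
        # preserve file order of bins
        order = list(dict.fromkeys(long["bin_id"]))
        psi, support = psi[order], support[order]
        if isinstance(meta_path_or_df, pd.DataFrame):
            meta = meta_path_or_df
        else:
            meta = pd.read_csv(meta_path_or_df, sep="\t").set_index("sample_id")
        return cls(psi.sort_index(), support.sort_index(), meta)


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

def _read_blocks_introns(read) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Aligned blocks and intron (N) intervals of one alignment, half-open."""
    blocks: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    pos = read.reference_start
    cur = pos
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            pos += length
        elif op == 2:  # D
            pos += length
        elif op == 3:  # N
            if pos > cur:
                blocks.append((cur, pos))
            introns.append((pos, pos + length))
            pos += length
            cur = pos
        # I, S, H, P consume no reference
    if pos > cur:
        blocks.append((cur, pos))
    return blocks, introns


def classify_read(
    blocks: list[tuple[int, int]],
    introns: list[tuple[int, int]],
    bin_: CountingBin,
) -> str | None:
    """Classify one alignment against one bin: 'inclusion', 'exclusion', None.

    Inclusion: an aligned block overlaps the bin body, or a splice junction
    has one end exactly at a bin boundary (consistent with the bin being
    retained in the transcript). Exclusion: an intron fully contains the bin.
    A read never counts both ways for one bin; inclusion evidence wins.
    """
    s, t = bin_.genomic_start, bin_.genomic_end
    for bs, bt in blocks:
        if bs < t and bt > s:
            return "inclusion"
    for js, jt in introns:
        if js <= s and jt >= t:
            return "exclusion"
    for js, jt in introns:
        if jt == s or js == t:
            return "inclusion"
    return None


def count_bin_evidence(
    alignments: "str | os.PathLike",
    model: GeneModel,
    sample_id: str,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    normalize: str = "positions",
    read_length: int | None = None,
) -> list[BinCounts]:
    """Tally inclusion/exclusion evidence per counting bin from SAM/BAM.

    Only primary, mapped alignments on the model's chromosome with
    MAPQ >= ``mapq_min`` are used; each read contributes at most once per
    bin. ``normalize="positions"`` fills the placement-count denominators
    from ``read_length`` (median observed length if not given);
    ``normalize="raw"`` leaves both denominators at 1.
    """
    import pysam

    if normalize not in ("positions", "raw"):
        raise ValueError("normalize must be 'positions' or 'raw'")
    inc = {b.bin_id: 0 for b in model.bins}
    exc = {b.bin_id: 0 for b in model.bins}
    lengths: list[int] = []
    with pysam.AlignmentFile(os.fspath(alignments), require_index=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != model.chrom:
                continue
            if read.mapping_quality < mapq_min:
                continue
            blocks, introns = _read_blocks_introns(read)
            if not blocks:
                continue
            lengths.append(sum(t - s for s, t in blocks))
            for b in model.bins:
                cls = classify_read(blocks, introns, b)
                if cls == "inclusion":
                    inc[b.bin_id] += 1
                elif cls == "exclusion":
                    exc[b.bin_id] += 1
    if normalize == "raw":
        rl = None
    else:
        rl = read_length if read_length is not None else (
            int(median(lengths)) if lengths else 1
        )
    out = []
    for b in model.bins:
        if rl is None:
            p_inc = p_exc = 1
        else:
            p_inc = max(b.bin_length + rl - 1, 1)
            p_exc = max(rl - 1, 1)
        out.append(BinCounts(sample_id, b.bin_id, inc[b.bin_id], exc[b.bin_id],
                             p_inc, p_exc))
    return out


def counts_from_tsv(path: str | os.PathLike) -> list[BinCounts]:
    """Read pre-tabulated bin counts (one row per sample x bin)."""
    df = pd.read_csv(path, sep="\t")
    return [
        BinCounts(str(r.sample_id), str(r.bin_id), int(r.inclusion_reads),
                  int(r.exclusion_reads), int(r.inclusion_positions),
                  int(r.exclusion_positions))
        for r in df.itertuples()
    ]


def counts_to_tsv(counts: list[BinCounts], path: str | os.PathLike) -> None:
    pd.DataFrame([vars(c) for c in counts]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def compute_psi(counts: BinCounts, min_support: int = DEFAULT_MIN_SUPPORT) -> PsiValue:
    """Position-normalised PSI for one bin/sample; missing below min_support."""
    total = counts.total_support
    if total < min_support:
        return PsiValue(counts.sample_id, counts.bin_id, None, total)
    i_rate = counts.inclusion_reads / counts.inclusion_positions
    e_rate = counts.exclusion_reads / counts.exclusion_positions
    psi = i_rate / (i_rate + e_rate)
    return PsiValue(counts.sample_id, counts.bin_id, psi, total)


def build_psi_table(
    counts: list[BinCounts],
    model: GeneModel,
    metadata: pd.DataFrame,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> PsiTable:
    """Assemble the samples x bins PSI matrix.

    ``metadata`` must be indexed by (or contain a) ``sample_id`` column and
    cover every sample appearing in ``counts``. Samples are ordered by id,
    bins by transcript position; missing PSI cells are NaN.
    """
    if "sample_id" in metadata.columns:
        metadata = metadata.set_index("sample_id")
    bin_order = [b.bin_id for b in model.bins]
    samples = sorted({c.sample_id for c in counts})
    missing_meta = set(samples) - set(metadata.index)
    if missing_meta:
        raise ValueError(f"metadata missing for samples: {sorted(missing_meta)}")
    psi = pd.DataFrame(np.nan, index=samples, columns=bin_order)
    support = pd.DataFrame(0, index=samples, columns=bin_order)
    for c in counts:
        if c.bin_id not in psi.columns:
            logger.warning("bin %r not in model; skipped", c.bin_id)
            continue
        v = compute_psi(c, min_support)
        psi.loc[c.sample_id, c.bin_id] = np.nan if v.psi is None else v.psi
        support.loc[c.sample_id, c.bin_id] = v.total_support
    psi.index.name = support.index.name = "sample_id"
    psi.columns.name = support.columns.name = "bin_id"
    return PsiTable(psi, support, metadata.loc[samples])
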