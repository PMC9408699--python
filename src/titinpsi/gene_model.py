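"""Transcript model for exon-level splicing analysis.

Builds an ordered exon model of a single transcript (the mouse titin
transcript ENSMUST00000099981.9 in the motivating application), flattens it
into junction-defined counting bins, names domain regions (Z-repeats, the
three PEVK segments, the M-band exons), and enumerates the amplicon ladder a
primer pair flanking a block of optional exons can produce.

Coordinates are 0-based half-open internally; GTF/GFF3 and the tabular exon
format use 1-based inclusive coordinates, converted only at the I/O boundary.
Exon indices follow transcript (5'->3') order, so on a minus-strand gene such
as mouse *Ttn* exon 1 is the genomically last exon.
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger("titinpsi")

#: Minimum junction-read support for a boundary to split a bin.
DEFAULT_MIN_JUNCTION_READS = 3

#: Default non-overlapping domain-region bounds (exon indices, inclusive).
DEFAULT_REGIONS = {
    "ZR": (10, 14),
    "PEVKI": (112, 135),
    "PEVKII": (136, 155),
    "PEVKIII": (156, 209),
    "MEx": (342, 347),
}

#: Alternative preset preserving the overlapping PEVK bounds (PEVK1 starting
#: at 113 and shared boundary exons 135/155) used in some published analyses.
PAPER_41_REGIONS = {
    "ZR": (10, 14),
    "PEVKI": (113, 135),
    "PEVKII": (135, 155),
    "PEVKIII": (156, 209),
    "MEx": (342, 347),
}


@dataclass(frozen=True)
class ExonRecord:
    """One exon in transcript order.

    ``genomic_start``/``genomic_end`` are 0-based half-open. ``coding_length``
    is the number of coding nucleotides the exon contributes;
    ``frame_offset`` is the phase (0-2) of its first coding base.
    """

    exon_index: int
    genomic_start: int
    genomic_end: int
    coding_length: int = -1
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.genomic_start >= self.genomic_end:
            raise ValueError(
                f"exon {self.exon_index}: start {self.genomic_start} >= end "
                f"{self.genomic_end} (zero-length exons are not allowed)"
            )
        if self.coding_length < 0:
            object.__setattr__(self, "coding_length", self.length)
        if self.coding_length > self.length:
            raise ValueError(
                f"exon {self.exon_index}: coding_length {self.coding_length} "
                f"exceeds exon length {self.length}"
            )
        if not 0 <= self.frame_offset <= 2:
            raise ValueError(f"exon {self.exon_index}: frame_offset must be 0-2")

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start


@dataclass(frozen=True)
class CountingBin:
    """A sub-exonic interval used as the PSI quantification unit.

    ``bin_id`` is the exon label, suffixed ``.k`` when an exon is split at
    observed junction boundaries and ``_hang`` for read-supported segments
    flanking annotated exon boundaries. ``parent_exon`` is None for hang bins.
    """

    bin_id: str
    parent_exon: int | None
    genomic_start: int
    genomic_end: int

    def __post_init__(self) -> None:
        if self.genomic_start >= self.genomic_end:
            raise ValueError(f"bin {self.bin_id}: empty interval")

    @property
    def bin_length(self) -> int:
        return self.genomic_end - self.genomic_start

    @property
    def is_hang(self) -> bool:
        return "_hang" in self.bin_id


@dataclass(frozen=True)
class DomainRegion:
    """A named contiguous exon range (e.g. PEVKII)."""

    name: str
    first_exon: int
    last_exon: int

    def __post_init__(self) -> None:
        if self.first_exon > self.last_exon:
            raise ValueError(f"region {self.name}: first_exon > last_exon")


@dataclass(frozen=True)
class AmpliconDesign:
    """A primer pair spanning a block of optional (cassette) exons.

    ``flank_length`` is the primer-to-primer product size with every optional
    exon spliced out; ``optional_exon_lengths`` are the cassette exon sizes.
    """

    flank_length: int
    optional_exon_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.flank_length <= 0:
            raise ValueError("flank_length must be positive")
        object.__setattr__(
            self, "optional_exon_lengths", tuple(self.optional_exon_lengths)
        )
        if any(x <= 0 for x in self.optional_exon_lengths):
            raise ValueError("optional exon lengths must be positive")


@dataclass
class GeneModel:
    """Ordered exons, counting bins and named regions of one transcript."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[ExonRecord]
    bins: list[CountingBin] = field(default_factory=list)
    regions: dict[str, DomainRegion] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        idx = [e.exon_index for e in self.exons]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("exon_index must be strictly increasing")
        if not self.regions:
            self.regions = {
                name: DomainRegion(name, lo, hi)
                for name, (lo, hi) in DEFAULT_REGIONS.items()
            }
        if not self.bins:
            self.bins = [
                CountingBin(str(e.exon_index), e.exon_index, e.genomic_start,
                            e.genomic_end)
                for e in self.exons
            ]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covered by the transcript, half-open."""
        return (
            min(e.genomic_start for e in self.exons),
            max(e.genomic_end for e in self.exons),
        )

    def exon(self, exon_index: int) -> ExonRecord:
        for e in self.exons:
            if e.exon_index == exon_index:
                return e
        raise KeyError(f"no exon {exon_index} in {self.transcript_id}")

    def bin(self, bin_id: str) -> CountingBin:
        for b in self.bins:
            if b.bin_id == bin_id:
                return b
        raise KeyError(f"no bin {bin_id!r} in {self.transcript_id}")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_gene_model(
    annotation_path: str | os.PathLike,
    transcript_id: str,
    regions: dict[str, tuple[int, int]] | None = None,
) -> GeneModel:
    """Load one transcript's exon model from GTF/GFF3 or a TSV exon table.

    Exons are ordered 5'->3' in transcript orientation (descending genomic
    coordinate on the minus strand) and indexed 1..n unless the annotation
    carries explicit exon numbers.
    """
    path = os.fspath(annotation_path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tsv", ".txt", ".tab"):
        model = _model_from_tsv(path, transcript_id)
    elif ext in (".gtf", ".gff", ".gff3"):
        model = _model_from_gff(path, transcript_id)
    else:
        raise ValueError(f"unrecognised annotation format: {path!r}")
    if regions:
        model.regions = {
            name: DomainRegion(name, lo, hi) for name, (lo, hi) in regions.items()
        }
    return model


def _model_from_gff(path: str, transcript_id: str) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    feats = []
    for f in db.features_of_type("exon"):
        attrs = f.attributes
        tids = attrs.get("transcript_id", []) + attrs.get("Parent", [])
        tids = [t.removeprefix("transcript:") for t in tids]
        if transcript_id in tids:
            feats.append(f)
    if not feats:
        raise ValueError(f"transcript {transcript_id!r} not found in {path}")
    strand = feats[0].strand if feats[0].strand in "+-" else "+"
    feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
    exons = [
        ExonRecord(exon_index=i, genomic_start=f.start - 1, genomic_end=f.end)
        for i, f in enumerate(feats, start=1)
    ]
    return GeneModel(transcript_id, feats[0].seqid, strand, exons)


_TSV_COLUMNS = [
    "exon_index", "chrom", "start_1based", "end_1based", "strand",
    "coding_length", "frame",
]


def _model_from_tsv(path: str, transcript_id: str) -> GeneModel:
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" in df.columns:
        df = df[df["transcript_id"] == transcript_id]
    if df.empty:
        raise ValueError(f"transcript {transcript_id!r} not found in {path}")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"exon TSV missing columns: {sorted(missing)}")
    df = df.sort_values("exon_index")
    exons = [
        ExonRecord(
            exon_index=int(r.exon_index),
            genomic_start=int(r.start_1based) - 1,
            genomic_end=int(r.end_1based),
            coding_length=int(r.coding_length),
            frame_offset=int(r.frame),
        )
        for r in df.itertuples()
    ]
    return GeneModel(transcript_id, str(df["chrom"].iloc[0]),
                     str(df["strand"].iloc[0]), exons)


def model_to_tsv(model: GeneModel, path: str | os.PathLike) -> None:
    """Write the exon table (1-based inclusive coordinates)."""
    rows = [
        {
            "transcript_id": model.transcript_id,
            "exon_index": e.exon_index,
            "chrom": model.chrom,
            "start_1based": e.genomic_start + 1,
            "end_1based": e.genomic_end,
            "strand": model.strand,
            "coding_length": e.coding_length,
            "frame": e.frame_offset,
        }
        for e in model.exons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bins_to_bed(model: GeneModel, path: str | os.PathLike) -> None:
    """Write counting bins as BED (0-based half-open)."""
    rows = [
        {"chrom": model.chrom, "start": b.genomic_start, "end": b.genomic_end,
         "name": b.bin_id, "score": 0, "strand": model.strand}
        for b in model.bins
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# counting-bin flattening
# ---------------------------------------------------------------------------

def flatten_to_bins(
    model: GeneModel,
    observed_junctions: list[tuple[int, int] | tuple[int, int, int]],
    min_junction_reads: int = DEFAULT_MIN_JUNCTION_READS,
) -> GeneModel:
    """Split exons into counting bins at observed splice-junction boundaries.

    ``observed_junctions`` are genomic intron intervals (donor, acceptor)
    half-open, optionally with a read-support count as third element
    (junctions below ``min_junction_reads`` do not induce splits). An exon cut
    internally by a junction end is split into ``.1``, ``.2``, ... sub-bins in
    transcript order; junction ends falling between annotated exons create
    ``_hang`` bins attached to the nearest exon boundary they extend.

    Returns a new GeneModel with ``bins`` populated; ``model`` is unchanged.
    """
    span = model.span
    boundaries: set[int] = set()
    for jct in observed_junctions:
        if len(jct) == 3:
            donor, acceptor, support = jct  # type: ignore[misc]
            if support < min_junction_reads:
                continue
        else:
            donor, acceptor = jct  # type: ignore[misc]
        if donor >= acceptor:
            raise ValueError(f"junction donor {donor} >= acceptor {acceptor}")
        if acceptor <= span[0] or donor >= span[1]:
            logger.warning("junction (%d, %d) outside transcript span %s; ignored",
                           donor, acceptor, span)
            continue
        boundaries.update((donor, acceptor))

    exons_sorted = sorted(model.exons, key=lambda e: e.genomic_start)
    bins: list[CountingBin] = []
    for e in model.exons:
        cuts = sorted(p for p in boundaries if e.genomic_start < p < e.genomic_end)
        edges = [e.genomic_start, *cuts, e.genomic_end]
        parts = list(zip(edges, edges[1:]))
        if model.strand == "-":
            parts = parts[::-1]  # transcript order on minus strand
        if len(parts) == 1:
            bins.append(CountingBin(str(e.exon_index), e.exon_index, *parts[0]))
        else:
            for k, (s, t) in enumerate(parts, start=1):
                bins.append(
                    CountingBin(f"{e.exon_index}.{k}", e.exon_index, s, t)
                )

    bins.extend(_hang_bins(model, exons_sorted, boundaries))
    order = {e.exon_index: i for i, e in enumerate(model.exons)}
    bins.sort(key=lambda b: (
        order.get(b.parent_exon, len(order)) if b.parent_exon is not None else len(order),
        -b.genomic_start if model.strand == "-" else b.genomic_start,
    ))
    return replace(model, bins=bins, exons=list(model.exons),
                   regions=dict(model.regions))


def _hang_bins(
    model: GeneModel,
    exons_sorted: list[ExonRecord],
    boundaries: set[int],
) -> list[CountingBin]:
    """Build _hang bins for junction ends landing in intronic space."""
    out: list[CountingBin] = []
    seen: dict[int, int] = {}
    exonic = [(e.genomic_start, e.genomic_end) for e in exons_sorted]
    for p in sorted(boundaries):
        if any(s <= p <= t for s, t in exonic):
            continue
        # attach to the nearer flanking exon boundary
        right = next((e for e in exons_sorted if e.genomic_start > p), None)
        left = next((e for e in reversed(exons_sorted) if e.genomic_end < p), None)
        cand: list[tuple[int, ExonRecord, tuple[int, int]]] = []
        if right is not None:
            cand.append((right.genomic_start - p, right, (p, right.genomic_start)))
        if left is not None:
            cand.append((p - left.genomic_end, left, (left.genomic_end, p)))
        if not cand:
            continue
        _, exon, (s, t) = min(cand, key=lambda c: c[0])
        n = seen.get(exon.exon_index, 0) + 1
        seen[exon.exon_index] = n
        suffix = "_hang" if n == 1 else f"_hang.{n}"
        out.append(CountingBin(f"{exon.exon_index}{suffix}", None, s, t))
    return out


# ---------------------------------------------------------------------------
# regions and amplicons
# ---------------------------------------------------------------------------

def exons_in_region(model: GeneModel, region_name: str) -> list[int]:
    """Exon indices (inclusive range) of a named domain region."""
    try:
        region = model.regions[region_name]
    except KeyError:
        raise KeyError(
            f"unknown region {region_name!r}; defined: {sorted(model.regions)}"
        ) from None
    have = {e.exon_index for e in model.exons}
    wanted = list(range(region.first_exon, region.last_exon + 1))
    missing = [i for i in wanted if i not in have]
    if missing:
        raise ValueError(
            f"region {region_name} spans exons absent from the model: {missing}"
        )
    return wanted


def predict_amplicons(design: AmpliconDesign) -> list[tuple[int, int]]:
    """Enumerate PCR product sizes over all cassette-exon inclusion subsets.

    Returns ``(included_exon_count, amplicon_length_bp)`` pairs, one per
    distinct product length, sorted by descending length. With K equal-length
    optional exons this is the K+1-rung ladder seen on a gel.
    """
    lengths = design.optional_exon_lengths
    products: dict[int, int] = {}
    for k in range(len(lengths) + 1):
        for subset in itertools.combinations(lengths, k):
            size = design.flank_length + sum(subset)
            products.setdefault(size, k)
    return sorted(((k, size) for size, k in products.items()),
                  key=lambda t: -t[1])
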