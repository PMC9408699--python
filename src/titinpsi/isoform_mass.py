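"""PSI-weighted mass estimation for an exon range (the PEVK segment).

Given a per-exon mass table (supplied directly or derived from the coding
sequence) and group-level PSI values, the expressed mass of a region is
estimated three ways: *min* sums only constitutively included exons
(PSI = 1), *max* sums every expressed exon (PSI > 0), and *weighted* scales
each exon's mass by its PSI — the expected mass of a transcript drawn from
the pool under independent inclusion, and the most realistic of the three.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_weights

WATER_DA = 18.0153

#: Average residue masses (Da): free amino-acid weight minus one water.
RESIDUE_MASSES = {aa: w - WATER_DA for aa, w in protein_weights.items()}

DEFAULT_PSI_TOLERANCE = 0.005

_CODON_TABLE = 1  # standard code


@dataclass(frozen=True)
class ExonMass:
    """Coding mass contributed by one exon.

    ``aa_length`` is in codon-equivalents (fractional when a codon spans an
    exon boundary and is apportioned pro rata by nucleotide count).
    """

    exon_index: int
    aa_length: float
    mass_kda: float

    def __post_init__(self) -> None:
        if self.mass_kda < 0:
            raise ValueError("mass must be non-negative")


@dataclass(frozen=True)
class SegmentMassEstimate:
    """Min / max / PSI-weighted mass of a named exon range for one group."""

    region: str
    group: str
    mass_min: float
    mass_max: float
    mass_weighted: float

    def mass(self, mode: str) -> float:
        try:
            return {"min": self.mass_min, "max": self.mass_max,
                    "weighted": self.mass_weighted}[mode]
        except KeyError:
            raise ValueError(f"mode must be min/max/weighted, got {mode!r}") from None


# ---------------------------------------------------------------------------
# per-exon masses
# ---------------------------------------------------------------------------

def exon_masses_from_sequence(model, cds_fasta: str | os.PathLike) -> list[ExonMass]:
    """Derive per-exon residue masses from the spliced coding sequence.

    The FASTA record is the in-frame CDS (concatenation of the exons' coding
    nucleotides in transcript order). Each codon's average residue mass is
    apportioned to exons pro rata by how many of its three nucleotides fall
    in each exon, so boundary codons are split fractionally. An internal stop
    codon raises an error naming the exon containing its first base.
    """
    from Bio.Seq import Seq

    record = next(SeqIO.parse(os.fspath(cds_fasta), "fasta"))
    seq = str(record.seq).upper()
    coding = [(e.exon_index, e.coding_length) for e in model.exons
              if e.coding_length > 0]
    total_nt = sum(n for _, n in coding)
    if total_nt != len(seq):
        raise ValueError(
            f"CDS length {len(seq)} does not match summed exon coding "
            f"lengths {total_nt}"
        )
    # exon index for every CDS position
    owner: list[int] = []
    for idx, n in coding:
        owner.extend([idx] * n)
    mass = {idx: 0.0 for idx, _ in coding}
    aa = {idx: 0.0 for idx, _ in coding}
    n_codons = len(seq) // 3
    for c in range(n_codons):
        codon = seq[3 * c:3 * c + 3]
        residue = str(Seq(codon).translate(table=_CODON_TABLE))
        if residue == "*":
            if c < n_codons - 1 or len(seq) % 3 != 0:
                raise ValueError(
                    f"internal stop codon at codon {c + 1} "
                    f"(exon {owner[3 * c]})"
                )
            continue  # trailing stop carries no mass
        try:
            m = RESIDUE_MASSES[residue]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r} at codon {c + 1}") from None
        for p in range(3 * c, 3 * c + 3):
            mass[owner[p]] += m / 3
            aa[owner[p]] += 1 / 3
    # a trailing partial codon still counts toward codon-equivalents
    for p in range(3 * n_codons, len(seq)):
        aa[owner[p]] += 1 / 3
    return [ExonMass(idx, aa[idx], mass[idx] / 1000.0) for idx, _ in coding]


def exon_masses_from_tsv(path: str | os.PathLike) -> list[ExonMass]:
    """Read a user-supplied mass table (exon_index, aa_length, mass_kda)."""
    df = pd.read_csv(path, sep="\t")
    return [ExonMass(int(r.exon_index), float(r.aa_length), float(r.mass_kda))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# segment estimates
# ---------------------------------------------------------------------------

def estimate_segment_mass(
    masses: list[ExonMass],
    psi_by_exon: dict[int, float],
    region: str = "",
    group: str = "",
    psi_tolerance: float = DEFAULT_PSI_TOLERANCE,
    missing: str = "error",
) -> SegmentMassEstimate:
    """Min / max / PSI-weighted mass over a set of massed exons.

    Estimated PSI values within ``psi_tolerance`` of 0 or 1 are snapped to
    the exact bound before use (applied to all three estimators, which keeps
    min <= weighted <= max at the boundaries). min sums exons with snapped
    psi = 1, max sums exons with snapped psi > 0, weighted sums mass x
    snapped psi. ``missing`` controls exons without a PSI value:
    "error" (default) raises; "impute" uses the mean PSI of the exons that do
    have one (for the weighted estimate; such exons are excluded from min and
    included in max, i.e. treated as possibly expressed).
    """
    if not masses:
        raise ValueError("no massed exons in region")
    if missing not in ("error", "impute"):
        raise ValueError("missing must be 'error' or 'impute'")
    known = [psi_by_exon[m.exon_index] for m in masses
             if m.exon_index in psi_by_exon]
    if len(known) < len(masses):
        absent = [m.exon_index for m in masses if m.exon_index not in psi_by_exon]
        if missing == "error":
            raise ValueError(f"missing PSI for exons {absent}")
        if not known:
            raise ValueError("cannot impute: no exon in the region has a PSI")
    impute_value = sum(known) / len(known) if known else 0.0

    m_min = m_max = m_wtd = 0.0
    for m in masses:
        if m.exon_index in psi_by_exon:
            psi = psi_by_exon[m.exon_index]
            if not 0.0 <= psi <= 1.0:
                raise ValueError(f"psi for exon {m.exon_index} outside [0, 1]")
            if psi >= 1.0 - psi_tolerance:
                psi = 1.0
            elif psi <= psi_tolerance:
                psi = 0.0
            if psi == 1.0:
                m_min += m.mass_kda
            if psi > 0.0:
                m_max += m.mass_kda
            m_wtd += m.mass_kda * psi
        else:  # imputed
            m_max += m.mass_kda
            m_wtd += m.mass_kda * impute_value
    return SegmentMassEstimate(region, group, m_min, m_max, m_wtd)


def mass_difference(
    wt: SegmentMassEstimate, mut: SegmentMassEstimate, mode: str = "weighted"
) -> float:
    """WT minus mutant mass (kDa) for one estimation mode.

    Rounding to the reporting precision is the caller's concern; the raw
    difference is returned.
    """
    if wt.region != mut.region:
        raise ValueError(
            f"region mismatch: {wt.region!r} vs {mut.region!r}"
        )
    return wt.mass(mode) - mut.mass(mode)
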