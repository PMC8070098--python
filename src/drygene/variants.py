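"""SNP calling and allele-frequency summaries from amplicon alignments.

Tepary bean is an annual autogamous species and every accession
contributes a single Sanger haplotype per gene, so genotypes are coded
haploid (0 = major allele, 1 = minor allele) and expected heterozygosity
H_e = 1 - sum(p_i^2) is the Hardy-Weinberg expectation implied by the
allele frequencies, following the DnaSP convention.

Common-bean sequencing controls (taxon label ``control``) are excluded
from frequency computations by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: Taxon labels excluded from frequency computations by default.
DEFAULT_EXCLUDE_TAXA = ("control",)

VARIANT_COLUMNS = [
    "position",
    "major_allele",
    "major_freq",
    "minor_allele",
    "minor_freq",
    "he",
    "n_called",
]


@dataclass
class Alignment:
    """A multi-sequence nucleotide alignment for one candidate gene.

    ``sequences`` are equal-length upper-case strings over the IUPAC
    alphabet; anything other than A/C/G/T (gaps, N, ambiguity codes) is
    treated as missing data downstream.  ``taxa`` carries one taxon label
    per sequence from the sample sheet.
    """

    gene: str
    ids: list[str]
    sequences: list[str]
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"{self.gene}: empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene}: sequences of unequal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"{self.gene}: duplicate sequence IDs")
        if not self.taxa:
            self.taxa = [""] * len(self.ids)
        if len(self.taxa) != len(self.ids):
            raise ValueError(f"{self.gene}: taxa/ids length mismatch")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def char_matrix(self) -> np.ndarray:
        """(n, L) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def subset(self, mask) -> "Alignment":
        """New alignment restricted to the sequences where ``mask`` is true."""
        mask = np.asarray(mask, dtype=bool)
        return Alignment(
            gene=self.gene,
            ids=[i for i, m in zip(self.ids, mask) if m],
            sequences=[s for s, m in zip(self.sequences, mask) if m],
            taxa=[t for t, m in zip(self.taxa, mask) if m],
        )

    def by_taxon(self, taxon: str) -> "Alignment":
        return self.subset([t == taxon for t in self.taxa])

    def exclude_taxa(self, taxa=DEFAULT_EXCLUDE_TAXA) -> "Alignment":
        return self.subset([t not in taxa for t in self.taxa])


@dataclass
class GenotypeMatrix:
    """Haploid 0/1 genotype matrix (individuals x SNPs; NaN = missing)."""

    gene: str
    ids: list[str]
    taxa: list[str]
    positions: list[int]
    data: np.ndarray  # float array, entries in {0.0, 1.0, nan}

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def n_snps(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.positions)


def expected_heterozygosity(freqs) -> float:
    """H_e = 1 - sum(p_i^2); equals 2pq for a biallelic site."""
    p = np.asarray(freqs, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 - np.sum(p**2))


def call_variants(
    aln: Alignment,
    max_missing: float = 0.5,
    exclude_taxa=DEFAULT_EXCLUDE_TAXA,
) -> pd.DataFrame:
    """Call biallelic SNPs from an alignment.

    Returns one row per polymorphic column with exactly two A/C/G/T
    states among the non-missing calls.  Gaps, Ns and ambiguity codes are
    missing data.  Columns with more than two states, or with a missing
    fraction above ``max_missing``, are excluded and logged.  Frequencies
    are computed over non-missing calls only; ties between the two allele
    counts are broken alphabetically (first base is "major").
    """
    work = aln.exclude_taxa(exclude_taxa) if exclude_taxa else aln
    if work.n == 0:
        raise ValueError(f"{aln.gene}: no sequences left after excluding {exclude_taxa}")
    chars = work.char_matrix()
    rows = []
    for col in range(work.length):
        column = chars[:, col]
        called = np.isin(column, BASES)
        n_called = int(called.sum())
        if n_called == 0 or 1.0 - n_called / work.n > max_missing:
            if n_called and len(set(column[called])) > 1:
                logger.info(
                    "%s: column %d dropped (missing fraction %.2f > %.2f)",
                    aln.gene,
                    col + 1,
                    1.0 - n_called / work.n,
                    max_missing,
                )
            continue
        states, counts = np.unique(column[called], return_counts=True)
        if len(states) < 2:
            continue
        if len(states) > 2:
            logger.info("%s: column %d dropped (%d allele states)", aln.gene, col + 1, len(states))
            continue
        # Sort by count descending, then alphabetically for ties.
        order = sorted(range(2), key=lambda k: (-counts[k], states[k]))
        major, minor = states[order[0]], states[order[1]]
        p_major = counts[order[0]] / n_called
        p_minor = counts[order[1]] / n_called
        rows.append(
            {
                "position": col + 1,
                "major_allele": major,
                "major_freq": p_major,
                "minor_allele": minor,
                "minor_freq": p_minor,
                "he": expected_heterozygosity([p_major, p_minor]),
                "n_called": n_called,
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def maf_filter(table: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Retain rows whose minor-allele frequency is >= ``threshold``.

    The boundary is inclusive so that sites printed at exactly the
    threshold frequency survive the filter.
    """
    if table.empty:
        return table
    return table[table["minor_freq"] >= threshold].reset_index(drop=True)


def genotype_matrix(
    aln: Alignment,
    table: pd.DataFrame,
    exclude_taxa=DEFAULT_EXCLUDE_TAXA,
) -> GenotypeMatrix:
    """Haploid 0/1 coding of each individual at each called SNP."""
    work = aln.exclude_taxa(exclude_taxa) if exclude_taxa else aln
    chars = work.char_matrix()
    positions = [int(p) for p in table["position"]]
    for pos in positions:
        if not 1 <= pos <= work.length:
            raise ValueError(f"{aln.gene}: position {pos} out of range 1..{work.length}")
    data = np.full((work.n, len(positions)), np.nan)
    for j, (_, row) in enumerate(table.iterrows()):
        column = chars[:, int(row["position"]) - 1]
        data[column == row["major_allele"], j] = 0.0
        data[column == row["minor_allele"], j] = 1.0
    return GenotypeMatrix(
        gene=aln.gene, ids=list(work.ids), taxa=list(work.taxa), positions=positions, data=data
    )


def gene_summary(table: pd.DataFrame) -> dict:
    """Per-gene summary: segregating sites, mean maf, mean H_e."""
    if table.empty:
        return {"S": 0, "mean_maf": float("nan"), "mean_he": float("nan")}
    return {
        "S": int(len(table)),
        "mean_maf": float(table["minor_freq"].mean()),
        "mean_he": float(table["he"].mean()),
    }
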