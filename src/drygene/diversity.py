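"""Site-frequency-spectrum summary statistics per gene and per taxon.

Implements the classic per-site estimators used for candidate-gene
resequencing panels: nucleotide diversity pi (mean pairwise difference),
Watterson's theta from the number of segregating sites, and Tajima's D,
the normalized difference between the two, whose sign diagnoses an
excess of rare variants (negative: directional/purifying selection or
expansion) or intermediate-frequency variants (positive: balancing
selection or structure).

Missing data are handled by pairwise deletion: each sequence pair is
compared only at positions called in both, and each pair's difference
count is scaled by its own effective length.  A complete-deletion mode
(drop every column with any missing call first) is available via flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import (
    BASES,
    DEFAULT_EXCLUDE_TAXA,
    Alignment,
    call_variants,
    gene_summary,
    maf_filter,
)

logger = logging.getLogger(__name__)


@dataclass
class SfsSummary:
    """Summary statistics of the site frequency spectrum for one group."""

    gene: str
    taxon: str
    n: int
    length: int
    s: int
    mean_maf: float
    mean_he: float
    pi: float
    theta_w: float
    tajima_d: float


def _valid_mask(chars: np.ndarray) -> np.ndarray:
    return np.isin(chars, BASES)


def _complete_columns(chars: np.ndarray) -> np.ndarray:
    return chars[:, _valid_mask(chars).all(axis=0)]


def _pairwise_diffs(chars: np.ndarray):
    """Per-pair difference counts and effective lengths (pairwise deletion)."""
    valid = _valid_mask(chars)
    n = chars.shape[0]
    diffs, lengths = [], []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            diffs.append(int(np.sum(chars[i][both] != chars[j][both])))
            lengths.append(int(both.sum()))
    return np.array(diffs), np.array(lengths)


def segregating_sites(aln: Alignment) -> int:
    """Columns with >= 2 distinct A/C/G/T states among non-missing calls."""
    chars = aln.char_matrix()
    valid = _valid_mask(chars)
    s = 0
    for col in range(chars.shape[1]):
        states = set(chars[valid[:, col], col])
        if len(states) >= 2:
            s += 1
    return s


def nucleotide_diversity(aln: Alignment, complete_deletion: bool = False) -> float:
    """Per-site nucleotide diversity pi (Nei-Li mean pairwise difference).

    With pairwise deletion (the default) each pair is scored over its own
    effective length; with ``complete_deletion`` all columns carrying any
    missing call are dropped first and a single length is used.
    """
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    chars = aln.char_matrix()
    if complete_deletion:
        chars = _complete_columns(chars)
        if chars.shape[1] == 0:
            raise ValueError("no complete columns left after deletion")
    diffs, lengths = _pairwise_diffs(chars)
    if np.any(lengths == 0):
        raise ValueError("a sequence pair shares no called positions")
    return float(np.mean(diffs / lengths))


def harmonic_number(n: int, power: int = 1) -> float:
    """a1 = sum 1/i (power=1) or a2 = sum 1/i^2 (power=2), i = 1..n-1."""
    return float(np.sum(1.0 / np.arange(1, n) ** power))


def watterson_theta(s: int, n: int, length: int) -> float:
    """Watterson's theta per site: S / (a1 * L)."""
    if n < 2:
        raise ValueError("Watterson's theta needs n >= 2")
    if length <= 0:
        raise ValueError("length must be positive")
    return s / (harmonic_number(n) * length)


def tajimas_d(aln: Alignment) -> float:
    """Tajima's D for one alignment; NaN when undefined (S = 0 or n < 4).

    Uses the 1989 constants computed from the sample size and the
    unnormalized mean pairwise difference count.
    """
    n = aln.n
    if n < 4:
        return float("nan")
    s = segregating_sites(aln)
    if s == 0:
        return float("nan")
    diffs, _ = _pairwise_diffs(aln.char_matrix())
    pi_total = float(np.mean(diffs))

    a1 = harmonic_number(n, 1)
    a2 = harmonic_number(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return float((pi_total - s / a1) / np.sqrt(var))


def _summary_for(
    aln: Alignment,
    gene: str,
    taxon: str,
    length: int,
    table: pd.DataFrame,
    restrict_positions=None,
) -> SfsSummary:
    """Build one summary row; optionally restrict to a set of positions."""
    if restrict_positions is not None:
        chars = aln.char_matrix()
        cols = [p - 1 for p in restrict_positions]
        sub_chars = chars[:, cols] if cols else chars[:, :0]
        sub = Alignment(
            gene=aln.gene,
            ids=aln.ids,
            sequences=["".join(r) for r in sub_chars] if cols else [""] * aln.n,
            taxa=aln.taxa,
        ) if cols else None
        diffs = _pairwise_diffs(sub_chars)[0] if cols else np.zeros(1)
        pi_total = float(np.mean(diffs))
        s = len(cols)
        d = tajimas_d(sub) if sub is not None else float("nan")
    else:
        s = segregating_sites(aln)
        pi_total = float(np.mean(_pairwise_diffs(aln.char_matrix())[0]))
        d = tajimas_d(aln)
    summ = gene_summary(table)
    return SfsSummary(
        gene=gene,
        taxon=taxon,
        n=aln.n,
        length=length,
        s=s,
        mean_maf=summ["mean_maf"],
        mean_he=summ["mean_he"],
        pi=pi_total / length,
        theta_w=watterson_theta(s, aln.n, length),
        tajima_d=d,
    )


def summarize_by_taxon(
    aln: Alignment,
    min_n: int = 4,
    maf_threshold: float = 0.05,
    exclude_taxa=DEFAULT_EXCLUDE_TAXA,
) -> pd.DataFrame:
    """Per-taxon and pooled ("All") site-frequency-spectrum summaries.

    The pooled row applies the minor-allele-frequency filter
    (``maf_threshold``) so its S matches the reported SNP panel; the
    per-taxon rows count every site segregating within that taxon, with
    no frequency filter.  Taxa with fewer than ``min_n`` sequences are
    skipped (logged) because their estimators are unreliable.
    """
    work = aln.exclude_taxa(exclude_taxa) if exclude_taxa else aln
    length = work.length
    rows = []

    all_table = maf_filter(call_variants(work, exclude_taxa=()), maf_threshold)
    rows.append(
        _summary_for(
            work,
            aln.gene,
            "All",
            length,
            all_table,
            restrict_positions=list(all_table["position"]) if not all_table.empty else [],
        )
    )
    for taxon in sorted(set(work.taxa)):
        sub = work.by_taxon(taxon)
        if sub.n < min_n:
            logger.info("%s: taxon %r skipped (n = %d < %d)", aln.gene, taxon, sub.n, min_n)
            continue
        table = call_variants(sub, exclude_taxa=())
        rows.append(_summary_for(sub, aln.gene, taxon, length, table))
    return pd.DataFrame([vars(r) for r in rows])
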