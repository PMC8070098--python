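"""Synthetic alignments, climate series and coupled datasets with known truth.

The generators emulate the structure of a candidate-gene resequencing
panel of tepary bean and its wild relatives: a few dozen Sanger
haplotypes per gene, taxon-differentiated allele frequencies, monthly
climate normals from arid-to-semiarid collection sites, and optionally
an environmentally associated causal SNP.  They exist so that every
analysis stage can be exercised and calibrated without external data.

The neutral alignment simulator is a standard n-coalescent with
infinite-sites mutation: exponential waiting times between pairwise
coalescences, Poisson mutation placement proportional to branch length,
each mutation at a previously unused alignment column.  Under this model
the expected number of segregating sites is theta * sum_{i<n} 1/i,
which serves as an analytic check.

``reference_fixture`` rebuilds, at n = 100, alignments whose variant
columns carry the published SNP positions and allele frequencies of the
three tepary drought candidate genes (Asr2, Dreb2B, ERECTA); with 100
sequences the two-decimal published frequencies are exact counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .climate import MonthlyClimate
from .variants import Alignment

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: Panel composition of the study germplasm: 23 wild P. acutifolius,
#: 6 cultivated P. acutifolius, 4 var. tenuifolius, 19 P. parvifolius.
DEFAULT_TAXA = (
    ("acutifolius_wild", 23),
    ("acutifolius_cult", 6),
    ("tenuifolius", 4),
    ("parvifolius", 19),
)

#: Published SNP panel of the three candidate genes: amplicon length and
#: (position, major allele, major frequency, minor allele, minor frequency)
#: per variant site, as reported for the tepary bean study panel.
REFERENCE_PANEL = {
    "Asr2": {
        "length": 547,
        "snps": [
            (1, "C", 0.5, "T", 0.5),
            (101, "A", 0.67, "G", 0.33),
            (185, "T", 0.73, "A", 0.27),
            (188, "T", 0.55, "A", 0.45),
            (189, "A", 0.67, "T", 0.33),
            (190, "A", 0.74, "T", 0.26),
            (191, "T", 0.69, "A", 0.31),
            (192, "T", 0.69, "A", 0.31),
            (200, "A", 0.88, "T", 0.12),
            (246, "T", 0.88, "A", 0.12),
            (407, "G", 0.67, "A", 0.33),
            (455, "C", 0.74, "A", 0.26),
            (486, "C", 0.9, "T", 0.1),
        ],
    },
    "Dreb2B": {
        "length": 373,
        "snps": [
            (24, "C", 0.89, "G", 0.11),
            (33, "C", 0.64, "G", 0.36),
            (81, "A", 0.93, "T", 0.07),
            (134, "A", 0.68, "G", 0.32),
            (135, "C", 0.68, "T", 0.32),
            (136, "A", 0.68, "G", 0.32),
            (342, "C", 0.8, "T", 0.2),
            (357, "G", 0.82, "C", 0.18),
        ],
    },
    "ERECTA": {
        "length": 750,
        "snps": [
            (32, "C", 0.85, "T", 0.15),
            (33, "T", 0.53, "A", 0.48),
            (46, "C", 0.8, "T", 0.2),
            (47, "A", 0.8, "G", 0.2),
            (55, "T", 0.93, "A", 0.08),
            (137, "G", 0.93, "A", 0.08),
            (172, "G", 0.93, "A", 0.08),
            (187, "G", 0.95, "A", 0.05),
            (189, "C", 0.93, "T", 0.08),
            (223, "T", 0.95, "C", 0.05),
            (228, "C", 0.93, "T", 0.08),
            (285, "T", 0.93, "C", 0.08),
            (286, "G", 0.93, "A", 0.08),
            (311, "C", 0.63, "A", 0.38),
            (449, "C", 0.93, "G", 0.08),
            (476, "T", 0.65, "A", 0.35),
            (480, "A", 0.93, "G", 0.08),
            (615, "T", 0.93, "C", 0.08),
            (637, "G", 0.9, "A", 0.1),
            (683, "T", 0.93, "A", 0.08),
            (725, "C", 0.63, "A", 0.38),
            (734, "T", 0.95, "G", 0.05),
        ],
    },
}


@dataclass
class ClimateConfig:
    """Seasonal climate generator settings (arid northwest-Mexico defaults).

    Mean annual temperature ~24 degC with a ~8 degC seasonal amplitude
    peaking in July, gamma-distributed monthly precipitation with an
    arid annual scale (~20 mm/month mean, drier winters), and collection
    latitudes in the Sonoran range 22-32 degrees N.
    """

    mean_temperature: float = 24.0
    amplitude: float = 8.0
    peak_month: int = 7
    temperature_noise_sd: float = 0.5
    precip_scale: float = 20.0
    precip_shape: float = 1.5
    latitude_range: tuple = (22.0, 32.0)


@dataclass
class CausalConfig:
    """An environmentally associated SNP with effect beta on the index."""

    beta: float = 1.0
    noise_sd: float = 1.0
    position: int | None = None  # None: most informative variant site
    taxon_effect_sd: float = 0.5


@dataclass
class SimConfig:
    """All knobs of the synthetic study; every draw flows from ``seed``."""

    seed: int = 0
    taxa: tuple = DEFAULT_TAXA
    length: int = 500
    theta: float = 5.0
    divergence: float = 0.0
    gene: str = "simgene"
    causal: CausalConfig | None = None
    climate: ClimateConfig = field(default_factory=ClimateConfig)

    @property
    def n(self) -> int:
        return sum(n for _, n in self.taxa)


def _coalescent_branches(n: int, rng: np.random.Generator):
    """Simulate an n-coalescent genealogy.

    Returns a list of (leaf_set, branch_length) pairs in coalescent time
    units, one entry per lineage interval in the genealogy.
    """
    lineages = [frozenset([i]) for i in range(n)]
    birth = {lin: 0.0 for lin in lineages}
    t = 0.0
    branches = []
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        for lin in (a, b):
            branches.append((lin, t - birth[lin]))
        merged = a | b
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        birth[merged] = t
    return branches


def simulate_alignment(cfg: SimConfig) -> Alignment:
    """Neutral coalescent alignment, optionally with taxon divergence.

    Mutations arrive at rate theta/2 per lineage per unit coalescent
    time and each hits a fresh column (infinite sites); a mutation count
    exceeding the alignment length is an error.  With ``divergence`` > 0
    each variant site is, with that probability, converted into a fixed
    difference between one randomly chosen taxon and the rest.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    ancestral = rng.choice(BASES, size=cfg.length)
    seqs = np.tile(ancestral, (n, 1))

    branches = _coalescent_branches(n, rng)
    total_len = sum(b for _, b in branches)
    n_mut = rng.poisson(cfg.theta / 2.0 * total_len)
    if n_mut > cfg.length:
        raise ValueError(
            f"{n_mut} mutations exceed alignment length {cfg.length}; lower theta or raise length"
        )
    columns = rng.choice(cfg.length, size=n_mut, replace=False)
    weights = np.array([b for _, b in branches]) / total_len
    variant_cols = []
    for col in columns:
        leaf_set = branches[rng.choice(len(branches), p=weights)][0]
        derived = rng.choice([b for b in BASES if b != ancestral[col]])
        seqs[list(leaf_set), col] = derived
        variant_cols.append(int(col))

    taxa = [label for label, count in cfg.taxa for _ in range(count)]
    if cfg.divergence > 0:
        labels = [label for label, _ in cfg.taxa]
        taxa_arr = np.array(taxa)
        for col in variant_cols:
            if rng.random() < cfg.divergence:
                chosen = labels[rng.integers(len(labels))]
                derived = rng.choice([b for b in BASES if b != ancestral[col]])
                seqs[:, col] = ancestral[col]
                seqs[taxa_arr == chosen, col] = derived

    ids = [f"acc{i:03d}" for i in range(n)]
    return Alignment(
        gene=cfg.gene,
        ids=ids,
        sequences=["".join(row) for row in seqs],
        taxa=taxa,
    )


def simulate_climate(cfg: SimConfig, accession_ids: list[str]) -> list[MonthlyClimate]:
    """Seasonal monthly climate normals for a list of accessions.

    T_j = mean + amplitude * cos(2 pi (j - peak) / 12) + noise;
    P_j ~ Gamma(shape, seasonal scale) with wetter summers.
    """
    c = cfg.climate
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31) + 1)
    months = np.arange(1, 13)
    out = []
    for acc in accession_ids:
        lat = rng.uniform(*c.latitude_range)
        temp = (
            c.mean_temperature
            + c.amplitude * np.cos(2.0 * np.pi * (months - c.peak_month) / 12.0)
            + rng.normal(0.0, c.temperature_noise_sd, size=12)
        )
        seasonal_scale = c.precip_scale * (
            1.0 + 0.5 * np.cos(2.0 * np.pi * (months - c.peak_month) / 12.0)
        )
        if c.precip_scale == 0:
            precip = np.zeros(12)
        else:
            precip = rng.gamma(c.precip_shape, seasonal_scale / c.precip_shape, size=12)
        out.append(
            MonthlyClimate(
                accession_id=acc, latitude=float(lat), temperature=temp, precipitation=precip
            )
        )
    return out


@dataclass
class TruthRecord:
    """Ground truth of a coupled genotype-environment simulation."""

    beta: float
    causal_position: int
    noise_sd: float
    taxon_effects: dict
    retries: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def simulate_coupled(cfg: SimConfig, max_retries: int = 20):
    """Alignment + climate + environmental index with a known causal SNP.

    The index of each accession is beta * (causal genotype) + a taxon
    mean effect + Gaussian noise.  If the requested causal position is
    monomorphic the alignment is resampled with a shifted seed and the
    retry count recorded in the truth record.
    """
    if cfg.causal is None:
        raise ValueError("simulate_coupled requires cfg.causal")
    from . import variants as _variants

    retries = 0
    work = cfg
    while True:
        aln = simulate_alignment(work)
        table = _variants.call_variants(aln, exclude_taxa=())
        if not table.empty and (
            cfg.causal.position is None or cfg.causal.position in set(table["position"])
        ):
            break
        retries += 1
        if retries > max_retries:
            raise RuntimeError("could not obtain a polymorphic causal site")
        logger.info("causal site monomorphic; resampling (retry %d)", retries)
        work = replace(cfg, seed=cfg.seed + 100_000 * retries)

    if cfg.causal.position is None:
        # most informative site: minor-allele frequency closest to 0.5
        idx = (table["minor_freq"] - 0.5).abs().idxmin()
        causal_pos = int(table.loc[idx, "position"])
    else:
        causal_pos = cfg.causal.position
    gm = _variants.genotype_matrix(aln, table[table["position"] == causal_pos], exclude_taxa=())
    g = np.nan_to_num(gm.data[:, 0], nan=0.0)

    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31) + 2)
    labels = [label for label, _ in cfg.taxa]
    effects = {label: float(rng.normal(0.0, cfg.causal.taxon_effect_sd)) for label in labels}
    taxon_term = np.array([effects[t] for t in aln.taxa])
    env = cfg.causal.beta * g + taxon_term + rng.normal(0.0, cfg.causal.noise_sd, size=aln.n)

    climates = simulate_climate(cfg, aln.ids)
    truth = TruthRecord(
        beta=cfg.causal.beta,
        causal_position=causal_pos,
        noise_sd=cfg.causal.noise_sd,
        taxon_effects=effects,
        retries=retries,
    )
    return aln, climates, env, truth


def reference_fixture(gene: str, n: int = 100, seed: int = 0) -> Alignment:
    """Alignment reproducing the published SNP panel of one gene.

    The alignment is monomorphic except at the published variant
    positions, where the minor allele is assigned to ceil(freq * n)
    randomly chosen sequences (independently per site, since haplotype
    phase is not recoverable from a frequency table).  At the default
    n = 100 the recomputed frequencies equal the published two-decimal
    values exactly.
    """
    if gene not in REFERENCE_PANEL:
        raise ValueError(f"unknown gene {gene!r}; expected one of {sorted(REFERENCE_PANEL)}")
    panel = REFERENCE_PANEL[gene]
    rng = np.random.default_rng(seed)
    seqs = np.full((n, panel["length"]), "A", dtype="U1")
    for pos, major, _pmaj, minor, pmin in panel["snps"]:
        col = pos - 1
        seqs[:, col] = major
        n_minor = int(np.ceil(round(pmin * n, 6)))
        carriers = rng.choice(n, size=n_minor, replace=False)
        seqs[carriers, col] = minor
    # taxon labels in the study panel's proportions, deterministic
    labels = [label for label, _ in DEFAULT_TAXA]
    weights = np.array([c for _, c in DEFAULT_TAXA], dtype=float)
    cum = np.cumsum(weights / weights.sum())
    taxa = [labels[int(np.searchsorted(cum, (i + 0.5) / n))] for i in range(n)]
    ids = [f"{gene}_{i:03d}" for i in range(n)]
    return Alignment(gene=gene, ids=ids, sequences=["".join(r) for r in seqs], taxa=taxa)
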