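"""File formats, configuration and the end-to-end pipeline driver.

The sample sheet (``accession,taxon,latitude,longitude``) is the single
source of taxon labels and coordinates; FASTA headers carry only
sequence IDs.  All tabular outputs are UTF-8 CSV, trees are Newick, and
every pipeline run writes a JSON manifest with versions, seed and
parameters sufficient to reproduce it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .climate import TIMEFRAMES, MonthlyClimate, build_index_table, scale_indices
from .variants import Alignment

logger = logging.getLogger(__name__)

IUPAC_CHARS = set("ACGTURYSWKMBDHVN-.")

CLIMATE_COLUMNS = (
    ["accession", "taxon", "latitude", "longitude"]
    + [f"t{m:02d}" for m in range(1, 13)]
    + [f"p{m:02d}" for m in range(1, 13)]
)


def read_fasta(path, gene: str | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are upper-cased and IDs taken up to the first whitespace.
    Unequal lengths (these are alignments), duplicate IDs and non-IUPAC
    characters are rejected with the offending record named.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    ids, seqs = [], []
    length = len(records[0].seq)
    for rec in records:
        seq = str(rec.seq).upper()
        if len(seq) != length:
            raise ValueError(f"{path}: sequence {rec.id!r} has length {len(seq)}, expected {length}")
        bad = set(seq) - IUPAC_CHARS
        if bad:
            raise ValueError(f"{path}: sequence {rec.id!r} contains non-IUPAC characters {sorted(bad)}")
        ids.append(rec.id)
        seqs.append(seq)
    return Alignment(gene=gene or path.stem, ids=ids, sequences=seqs)


def write_fasta(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV: accession, taxon, latitude, longitude."""
    sheet = pd.read_csv(path)
    required = {"accession", "taxon"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return sheet


def attach_taxa(aln: Alignment, sheet: pd.DataFrame) -> Alignment:
    """Fill the alignment's taxon labels from the sample sheet."""
    mapping = dict(zip(sheet["accession"].astype(str), sheet["taxon"].astype(str)))
    unknown = [i for i in aln.ids if i not in mapping]
    if unknown:
        raise ValueError(f"{aln.gene}: sequence IDs not in sample sheet: {unknown[:5]}")
    return Alignment(
        gene=aln.gene,
        ids=aln.ids,
        sequences=aln.sequences,
        taxa=[mapping[i] for i in aln.ids],
    )


def read_climate_table(path):
    """Climate CSV -> (list of MonthlyClimate, accession -> taxon map)."""
    frame = pd.read_csv(path)
    missing = set(CLIMATE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: climate table missing columns {sorted(missing)}")
    climates = [
        MonthlyClimate(
            accession_id=str(row["accession"]),
            latitude=float(row["latitude"]),
            temperature=np.array([row[f"t{m:02d}"] for m in range(1, 13)], dtype=float),
            precipitation=np.array([row[f"p{m:02d}"] for m in range(1, 13)], dtype=float),
        )
        for _, row in frame.iterrows()
    ]
    taxa = dict(zip(frame["accession"].astype(str), frame["taxon"].astype(str)))
    return climates, taxa


def write_climate_table(climates, taxa, sheet_extra, path) -> None:
    rows = []
    for clim in climates:
        row = {
            "accession": clim.accession_id,
            "taxon": taxa.get(clim.accession_id, ""),
            "latitude": clim.latitude,
            "longitude": sheet_extra.get(clim.accession_id, 0.0),
        }
        row.update({f"t{m:02d}": clim.temperature[m - 1] for m in range(1, 13)})
        row.update({f"p{m:02d}": clim.precipitation[m - 1] for m in range(1, 13)})
        rows.append(row)
    pd.DataFrame(rows, columns=CLIMATE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline driver

def run_pipeline(config: dict, outdir) -> dict:
    """Chain climate -> variants -> diversity -> structure -> gea.

    ``config`` keys: ``genes`` (list of {name, fasta}), ``samples``
    (sample sheet CSV), ``climate`` (climate CSV), ``seed``, and optional
    parameter overrides ``maf``, ``anchor_month``, ``n_pcs``, ``boot``,
    ``models``.  Each stage writes its CSV outputs under ``outdir`` and a
    manifest records everything needed to reproduce the run.  A stage
    failure aborts with the stage name in the error message.
    """
    from . import diversity as _diversity
    from . import gea as _gea
    from . import structure as _structure
    from . import variants as _variants

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    maf = float(config.get("maf", 0.05))
    anchor = int(config.get("anchor_month", 1))
    n_pcs = int(config.get("n_pcs", 2))
    boot = int(config.get("boot", 1000))
    models = config.get("models", ["glm", "mlm", "cmlm", "hap"])
    outputs: dict = {}

    climate_path = Path(config["climate"])
    if not climate_path.exists():
        raise FileNotFoundError(f"stage climate: missing climate table {climate_path}")

    def stage(name):
        logger.info("pipeline stage: %s", name)

    stage("climate")
    climates, clim_taxa = read_climate_table(climate_path)
    indices = scale_indices(build_index_table(climates, clim_taxa, anchor_month=anchor))
    indices_path = outdir / "indices.csv"
    indices.to_csv(indices_path, index=False)
    outputs["indices"] = str(indices_path)

    sheet = read_sample_sheet(config["samples"])
    assoc_frames = []
    n_sites = {}
    for entry in config["genes"]:
        gene = entry["name"]
        try:
            stage(f"variants:{gene}")
            aln = attach_taxa(read_fasta(entry["fasta"], gene=gene), sheet)
            table = _variants.maf_filter(_variants.call_variants(aln), maf)
            table.to_csv(outdir / f"{gene}_snps.csv", index=False)
            gm = _variants.genotype_matrix(aln, table)
            gm.to_frame().to_csv(outdir / f"{gene}_genotypes.csv")
            n_sites[gene] = len(table)

            stage(f"diversity:{gene}")
            _diversity.summarize_by_taxon(aln).to_csv(outdir / f"{gene}_diversity.csv", index=False)

            stage(f"structure:{gene}")
            if len(table):
                _structure.fst_report(gm).to_csv(outdir / f"{gene}_fst.csv", index=False)
                scores, explained = _structure.pca_genotypes(gm, n_components=n_pcs)
                scores.to_csv(outdir / f"{gene}_pca.csv")
                kin = _structure.ibs_kinship(gm)
                kin.to_csv(outdir / f"{gene}_kinship.csv")
                tree, _ = _structure.bootstrap_nj(aln.exclude_taxa(), replicates=boot, seed=seed)
                tree.write(str(outdir / f"{gene}_nj.nwk"))
                hs = _structure.collapse_haplotypes(aln.exclude_taxa())
                net = _structure.mj_network(hs)
                edges, nodes = _structure.network_tables(net)
                edges.to_csv(outdir / f"{gene}_network_edges.csv", index=False)
                nodes.to_csv(outdir / f"{gene}_network_nodes.csv", index=False)

            stage(f"gea:{gene}")
            if len(table):
                order = [i for i in gm.ids]
                idx = indices.set_index("accession")
                spec = _gea.ModelSpec(n_pcs=n_pcs, kinship=kin.to_numpy())
                for tf in TIMEFRAMES:
                    env = idx.loc[order, tf].to_numpy(dtype=float)
                    if "glm" in models:
                        assoc_frames.append(_gea.glm_scan(gm, env, spec, index_name=tf))
                    if "mlm" in models:
                        assoc_frames.append(_gea.mlm_scan(gm, env, spec, index_name=tf))
                    if "cmlm" in models:
                        assoc_frames.append(_gea.cmlm_scan(gm, env, spec, index_name=tf))
                    if "hap" in models:
                        assoc_frames.append(
                            _gea.haplotype_mlm(hs, gm.ids, env, spec, index_name=tf)
                        )
        except Exception as exc:
            raise RuntimeError(f"stage failed for gene {gene}: {exc}") from exc

    if assoc_frames:
        assoc = pd.concat(assoc_frames, ignore_index=True)
        assoc_path = outdir / "assoc.csv"
        assoc.to_csv(assoc_path, index=False)
        outputs["assoc"] = str(assoc_path)
        summary = _gea.significance_report(assoc, n_sites)
        summary.to_csv(outdir / "assoc_summary.csv", index=False)

    manifest = {
        "drygene_version": __version__,
        "seed": seed,
        "parameters": {
            "maf": maf,
            "anchor_month": anchor,
            "n_pcs": n_pcs,
            "boot": boot,
            "models": list(models),
        },
        "inputs": {
            "climate": str(climate_path),
            "samples": str(config["samples"]),
            "genes": [dict(e) for e in config["genes"]],
        },
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
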