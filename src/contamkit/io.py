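"""File formats: quartet tables, reference panels, reads, metadata, reports.

Dialects (fixed column orders, versioned here):

* quartet table TSV — ``species individual contig position nA nC nG nT``,
  header required, positions 1-based;
* reference panel FASTA — headers ``>id|species|component`` (a plain
  header is accepted and doubles as the species label, component
  ``target``), aligned equal-length sequences;
* reads — FASTQ or plain text, one read per line;
* metadata TSV — the columns of
  :data:`contamkit.labmeta.METADATA_COLUMNS`, ISO dates;
* genotype calls — VCF-like TSV with per-individual ``genotype:posterior``
  entries;
* contamination matrix TSV — species x species with ``NA`` for missing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .barcode import ContaminationMatrix, ReferencePanel
from .genotyping import GenotypeCallSet
from .labmeta import METADATA_COLUMNS, validate_metadata
from .quartets import BASES, SiteColumn

logger = logging.getLogger(__name__)

QUARTET_COLUMNS = ["species", "individual", "contig", "position", "nA", "nC", "nG", "nT"]


# ---------------------------------------------------------------------------
# reference panel FASTA


def read_reference_alignment(path: str | Path) -> ReferencePanel:
    """Load an aligned barcode panel from FASTA.

    Headers follow ``id|species|component``; a header without pipes is used
    as both id and species with component ``target``.  Unequal sequence
    lengths or an empty file are hard errors naming the offender.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or unreadable FASTA: {path}")
    ids, species, components, seqs = [], [], [], []
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise ValueError(
                f"unequal sequence length in {path}: record {rec.id!r} has "
                f"{len(rec.seq)} != {length}"
            )
        parts = rec.description.split("|")
        if len(parts) >= 3:
            ids.append(parts[0].strip())
            species.append(parts[1].strip())
            components.append(parts[2].strip())
        elif len(parts) == 2:
            ids.append(parts[0].strip())
            species.append(parts[1].strip())
            components.append("target")
        else:
            ids.append(rec.id)
            species.append(rec.description.strip() or rec.id)
            components.append("target")
        seqs.append(str(rec.seq).upper())
    return ReferencePanel(ids=ids, species=species, components=components, sequences=seqs)


def write_reference_alignment(panel: ReferencePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(panel.n):
            fh.write(f">{panel.ids[i]}|{panel.species[i]}|{panel.components[i]}\n")
            fh.write(panel.sequences[i] + "\n")


# ---------------------------------------------------------------------------
# reads


def read_reads(path: str | Path) -> list[str]:
    """Reads from FASTQ (by extension or leading '@') or plain one-per-line."""
    path = Path(path)
    if path.suffix.lower() in {".fastq", ".fq"}:
        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# quartet tables


def write_quartet_table(
    columns_by_species: Mapping[str, Sequence[SiteColumn]], path: str | Path
) -> None:
    """Write site columns as the canonical TSV (1-based positions)."""
    rows = []
    for species, cols in columns_by_species.items():
        for col in cols:
            for i, ind in enumerate(col.individuals):
                rows.append(
                    (species, ind, col.contig, col.position + 1, *col.counts[i].tolist())
                )
    pd.DataFrame(rows, columns=QUARTET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_quartet_table(path: str | Path) -> dict[str, list[SiteColumn]]:
    """Parse a quartet TSV into per-species SiteColumns.

    Validates the header, non-negative counts and uniqueness of
    (species, individual, contig, position); errors cite the offending
    1-based file line.  An empty table is allowed (warned).
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "individual": str, "contig": str})
    missing = [c for c in QUARTET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("%s: empty quartet table", path)
        return {}
    count_cols = ["nA", "nC", "nG", "nT"]
    bad = df.index[df[count_cols].lt(0).any(axis=1) | df[count_cols].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: negative or missing count at line {bad[0] + 2}")
    dup = df.duplicated(subset=["species", "individual", "contig", "position"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (individual, position) row at line {df.index[dup][0] + 2}"
        )
    out: dict[str, list[SiteColumn]] = {}
    for species, sp_df in df.groupby("species", sort=True):
        individuals = sorted(sp_df["individual"].unique())
        ind_idx = {ind: i for i, ind in enumerate(individuals)}
        cols: list[SiteColumn] = []
        for (contig, pos), grp in sp_df.groupby(["contig", "position"], sort=True):
            counts = np.zeros((len(individuals), 4), dtype=np.int64)
            for _, row in grp.iterrows():
                counts[ind_idx[row["individual"]]] = [
                    row["nA"], row["nC"], row["nG"], row["nT"]
                ]
            cols.append(
                SiteColumn(
                    contig=str(contig),
                    position=int(pos) - 1,
                    individuals=individuals,
                    counts=counts,
                )
            )
        out[str(species)] = cols
    return out


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    for col in ("entry_date", "shipment_date"):
        out[col] = pd.to_datetime(out[col]).dt.date
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype calls


def write_genotype_calls(
    calls: GenotypeCallSet,
    path: str | Path,
    contig: str = "contig1",
    positions: Sequence[int] | None = None,
) -> None:
    """VCF-like TSV: contig, 1-based pos, major allele, alts, per-individual calls."""
    P, N, _ = calls.calls.shape
    if positions is None:
        positions = range(P)
    with open(path, "w") as fh:
        header = ["contig", "pos", "ref", "alt"] + list(calls.individuals)
        fh.write("\t".join(header) + "\n")
        snp_set = set(calls.snp_positions.tolist())
        for p in positions:
            row_calls = calls.calls[p]
            called = row_calls[row_calls[:, 0] >= 0]
            if called.size == 0:
                continue
            alleles, counts = np.unique(called.ravel(), return_counts=True)
            ref = BASES[int(alleles[np.argmax(counts)])]
            alts = ",".join(BASES[int(a)] for a in alleles if BASES[int(a)] != ref) or "."
            fields = [contig, str(p + 1), ref, alts]
            for i in range(N):
                a, b = row_calls[i]
                if a < 0:
                    fields.append("./.")
                else:
                    post = calls.posterior[p, i]
                    fields.append(f"{BASES[int(a)]}/{BASES[int(b)]}:{post:.4f}")
            fh.write("\t".join(fields) + "\n")
    logger.info("wrote %d SNP positions among calls", len(snp_set))


# ---------------------------------------------------------------------------
# contamination matrix and JSON reports


def write_contamination_matrix(M: ContaminationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(M.m, index=M.species, columns=M.species)
    df.to_csv(path, sep="\t", na_rep="NA")


def read_contamination_matrix(path: str | Path, min_reads: int = 1) -> ContaminationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ContaminationMatrix(
        species=list(df.index), m=df.to_numpy(dtype=float), min_reads=min_reads
    )


def write_json_report(report: Mapping, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
        fh.write("\n")
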