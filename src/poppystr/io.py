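"""Readers and writers for the plain-text interchange formats.

FASTA via Biopython; peak tables, genotype matrices, call tables and locus
tables as TSV; ladders, panels and marker references as JSON. A small import
shim maps GeneMapper genotypes-table column names onto the native peak-table
dialect.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mining import SSRLocus
from .nomenclature import MarkerReference, RepeatStructure
from .synthetic import PEAK_COLUMNS

__all__ = [
    "read_fasta", "write_fasta", "read_peak_table", "write_peak_table",
    "read_genotype_matrix", "write_genotype_matrix", "write_loci",
    "read_marker_references", "write_marker_references",
    "read_chrom_lengths",
]

GENEMAPPER_COLUMN_MAP = {
    "Sample Name": "sample_id",
    "Sample File": "sample_id",
    "Marker": "marker",
    "Dye": "dye",
    "Size": "size_bp",
    "Height": "height_rfu",
}


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_peak_table(path) -> pd.DataFrame:
    """Read a peak table TSV; GeneMapper-style column names are remapped."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=GENEMAPPER_COLUMN_MAP)
    missing = {"sample_id", "size_bp", "height_rfu"} - set(df.columns)
    if missing:
        raise ValueError(f"peak table lacks columns: {sorted(missing)}")
    return df


def write_peak_table(peaks: pd.DataFrame, path) -> None:
    cols = [c for c in PEAK_COLUMNS if c in peaks.columns] + \
        [c for c in peaks.columns if c not in PEAK_COLUMNS]
    peaks[cols].to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_genotype_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=False)


def write_loci(loci: Sequence[SSRLocus], path) -> None:
    """Write mined loci as TSV (1-based inclusive forward-strand coords)."""
    rows = [{"chrom": l.chrom, "start": l.start, "end": l.end,
             "motif": l.motif, "canonical_motif": l.canonical_motif,
             "n_repeats": l.n_repeats, "on_chromosome": l.on_chromosome}
            for l in loci]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "motif",
                                "canonical_motif", "n_repeats",
                                "on_chromosome"]).to_csv(
        path, sep="\t", index=False)


def read_chrom_lengths(path) -> dict[str, int]:
    """Chromosome list file: name <tab> length."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_marker_references(refs: Mapping[str, MarkerReference],
                            path) -> None:
    data = {name: {"upstream": r.upstream,
                   "structure": r.structure.serialize(),
                   "downstream": r.downstream,
                   "pigtail": r.pigtail}
            for name, r in refs.items()}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_marker_references(path) -> dict[str, MarkerReference]:
    with open(path) as fh:
        data = json.load(fh)
    return {name: MarkerReference(
        marker=name, upstream=d["upstream"],
        structure=RepeatStructure.parse(d["structure"]),
        downstream=d["downstream"], pigtail=d.get("pigtail", 0))
        for name, d in data.items()}
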