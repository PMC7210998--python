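"""Readers and writers for the external formats the pipeline touches.

All coordinates are converted to the package's internal 0-based half-open
convention on the way in and back to each format's native convention on the
way out.  Writers emit deterministic, sorted output.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import Contig, FormatError, GeneModel, KmerHistogram, SimilarityEdge, assign_ranks

_NUCLEOTIDE_ALPHABET = set("ACGTN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

BLAST_TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_sequences_fasta(path, alphabet: str = "nucleotide") -> Dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping.

    Ids are the first whitespace-delimited token of the header; sequences
    are upper-cased and validated against *alphabet* (``nucleotide`` allows
    A/C/G/T/N, ``protein`` the 20 amino acids plus X).  Record order is
    preserved; duplicate ids are a format error.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError("alphabet must be 'nucleotide' or 'protein'")
    allowed = _NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else _PROTEIN_ALPHABET
    out: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if record.id in out:
            raise FormatError(f"duplicate FASTA id: {record.id}")
        bad = set(seq) - allowed
        if bad:
            raise FormatError(
                f"record {record.id}: characters {sorted(bad)} outside {alphabet} alphabet"
            )
        out[record.id] = seq
    return out


def write_sequences_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    """Write sequences as FASTA, sorted by id for determinism."""
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_contigs_fasta(path) -> List[Contig]:
    seqs = read_sequences_fasta(path, alphabet="nucleotide")
    return [Contig(cid, seq) for cid, seq in seqs.items()]


def write_contigs_fasta(path, contigs: Sequence[Contig]) -> None:
    write_sequences_fasta(path, {c.contig_id: c.sequence for c in contigs})


_NAME_ATTRIBUTE_PRIORITY = ("Name", "description", "product")


def read_gene_models_gff3(
    path,
    fasta: Optional[Mapping[str, str]] = None,
    cds_fasta: Optional[Mapping[str, str]] = None,
) -> List[GeneModel]:
    """Read gene features from a GFF3 file into :class:`GeneModel` objects.

    GFF3 is 1-based inclusive; internal coordinates are 0-based half-open.
    The gene name is taken from the first attribute present among
    ``Name`` > ``description`` > ``product`` and falls back to the gene id.
    Protein/CDS sequences are attached from the optional mappings; a gene id
    absent from both mappings (when given) produces a warning and empty
    sequences.  Ranks are assigned per chromosome by sorted start.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    for feat in db.features_of_type("gene"):
        if feat.end < feat.start:
            raise FormatError(
                f"gene {feat.id}: end {feat.end} < start {feat.start} in GFF3"
            )
        name = feat.id
        for key in _NAME_ATTRIBUTE_PRIORITY:
            if key in feat.attributes and feat.attributes[key]:
                name = feat.attributes[key][0]
                break
        protein = (fasta or {}).get(feat.id, "")
        cds = (cds_fasta or {}).get(feat.id, "")
        if (fasta is not None or cds_fasta is not None) and not protein and not cds:
            warnings.warn(f"gene {feat.id}: no protein or CDS sequence found")
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chromosome=feat.seqid,
                start=feat.start - 1,  # to 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                name=name,
                protein=protein,
                cds=cds,
            )
        )
    assign_ranks(genes)
    return genes


def write_gene_models_gff3(path, genes: Sequence[GeneModel]) -> None:
    """Write gene features as GFF3 (1-based inclusive), sorted by position."""
    ordered = sorted(genes, key=lambda g: (g.chromosome, g.start, g.end, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ordered:
            attrs = f"ID={g.gene_id};Name={g.name}"
            fh.write(
                "\t".join(
                    [
                        g.chromosome, "wgdkit", "gene",
                        str(g.start + 1), str(g.end), ".", g.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


def read_similarity_tabular(
    path,
    query_lengths: Optional[Mapping[str, int]] = None,
    subject_lengths: Optional[Mapping[str, int]] = None,
) -> List[SimilarityEdge]:
    """Read 12-column BLAST tabular (outfmt 6) hits into similarity edges.

    Self-hits are dropped; multiple HSPs of one (query, subject) pair are
    collapsed to the best-bitscore HSP.  When sequence lengths are provided,
    per-side coverages are computed as (end - start + 1) / length and unknown
    ids are an error.
    """
    try:
        df = pd.read_csv(
            str(path), sep="\t", header=None, names=BLAST_TABULAR_COLUMNS,
            comment="#", dtype={"qseqid": str, "sseqid": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"malformed tabular file: {exc}") from exc
    numeric = df.columns[2:]
    converted = df[numeric].apply(pd.to_numeric, errors="coerce")
    if converted.isna().any().any():
        raise FormatError("non-numeric field in BLAST tabular input")
    df[numeric] = converted

    df = df[df.qseqid != df.sseqid]
    # best-bitscore HSP per ordered pair
    df = df.sort_values("bitscore", ascending=False).drop_duplicates(
        ["qseqid", "sseqid"], keep="first"
    )
    df = df.sort_index()

    edges = []
    for row in df.itertuples(index=False):
        qcov = scov = float("nan")
        if query_lengths is not None:
            if row.qseqid not in query_lengths:
                raise FormatError(f"unknown query id {row.qseqid}")
            qcov = (abs(row.qend - row.qstart) + 1) / query_lengths[row.qseqid]
        if subject_lengths is not None:
            if row.sseqid not in subject_lengths:
                raise FormatError(f"unknown subject id {row.sseqid}")
            scov = (abs(row.send - row.sstart) + 1) / subject_lengths[row.sseqid]
        edges.append(
            SimilarityEdge(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                percent_identity=float(row.pident),
                alignment_length=int(row.length),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                query_cov=qcov,
                subject_cov=scov,
            )
        )
    return edges


def read_kmer_histogram(path, k: int) -> KmerHistogram:
    """Read a two-column (KCN, count) histogram, jellyfish-histo dialect."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"line {lineno}: expected two columns")
            try:
                kcn, count = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer field") from exc
            if kcn <= 0 or count < 0:
                raise FormatError(f"line {lineno}: negative or zero KCN / negative count")
            entries.append((kcn, count))
    entries.sort()
    return KmerHistogram(k=k, entries=tuple(entries))


def write_kmer_histogram(path, hist: KmerHistogram) -> None:
    with open(path, "w") as fh:
        for kcn, count in hist.entries:
            fh.write(f"{kcn} {count}\n")
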