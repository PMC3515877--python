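"""Readers and writers for the external formats the pipeline touches.

FASTA (sequences and alignments), GFF3 gene models (via gffutils), TSV
variant tables, TSV expression matrices, Newick trees (via dendropy), YAML
run configuration, and a stderr logger with per-stage timings.

Coordinates are GFF3-native 1-based inclusive in every public type;
conversion to Python slices happens only inside sequence-slicing code.
"""

from __future__ import annotations

import gzip
import io
import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field

import dendropy
import gffutils
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "VariantRecord",
    "ExpressionMatrix",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3_protein_coding",
    "read_variant_table",
    "write_variant_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_newick",
    "write_newick",
    "load_config",
    "save_config",
    "get_logger",
    "stage_timer",
]

DNA_ALPHABET = frozenset("ACGTN-")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")

logger = logging.getLogger("mapkevo")


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class SequenceRecord:
    """One sequence with its declared molecule type.

    ``seq`` is upper-case and restricted to the nucleotide alphabet
    (``ACGTN-``) or the amino-acid alphabet plus gap, per ``moltype``.
    """

    id: str
    seq: str
    moltype: str = "dna"  # {"dna", "protein"}

    def __post_init__(self):
        if self.moltype not in ("dna", "protein"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        alphabet = DNA_ALPHABET if self.moltype == "dna" else PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.moltype} characters {sorted(bad)}"
            )


@dataclass
class GeneModel:
    """Representative protein-coding gene model.

    ``cds_segments`` are (start, end), 1-based inclusive, sorted,
    non-overlapping; the spliced CDS length is divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list
    is_representative: bool = True
    mrna_id: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        segs = list(self.cds_segments)
        if not segs:
            raise ValueError(f"{self.gene_id}: no CDS segments")
        if any(s > e for s, e in segs):
            raise ValueError(f"{self.gene_id}: segment start > end")
        if segs != sorted(segs):
            raise ValueError(f"{self.gene_id}: segments not sorted by start")
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
        if self.spliced_length % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass
class VariantRecord:
    """A SNP or short (1-3 bp) deletion called in one accession.

    ``alt`` is empty for deletions (written as "-" on disk), a single base
    for SNPs.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    accession_id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not 1 <= len(self.ref) <= 3:
            raise ValueError(f"{self.chrom}:{self.pos}: ref length must be 1-3")
        if self.is_deletion:
            pass
        elif len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"{self.chrom}:{self.pos}: unsupported variant (multi-base ref with"
                " non-empty alt)"
            )

    @property
    def is_deletion(self) -> bool:
        return self.alt == ""

    @property
    def end(self) -> int:
        """Last reference position covered, 1-based inclusive."""
        return self.pos + len(self.ref) - 1


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with no missing entries."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(self.sample_ids) < 2:
            raise ValueError("at least 2 samples required for correlation")
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def read_fasta(path, moltype: str = "dna") -> list:
    """Parse a FASTA file into SequenceRecords, in file order.

    Sequences are case-folded to upper.  Malformed headers, characters
    outside the declared alphabet, and duplicate ids raise FormatError
    naming the line number.
    """
    alphabet = DNA_ALPHABET if moltype == "dna" else PROTEIN_ALPHABET
    records: list = []
    seen: dict = {}
    cur_id = None
    cur_chunks: list = []
    cur_line = 0

    def flush():
        if cur_id is None:
            return
        seq = "".join(cur_chunks)
        if not seq:
            raise FormatError(f"line {cur_line}: record {cur_id!r} has no sequence")
        records.append(SequenceRecord(cur_id, seq, moltype))

    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                rec_id = header.split()[0]
                if rec_id in seen:
                    raise FormatError(
                        f"line {lineno}: duplicate id {rec_id!r}"
                        f" (first seen at line {seen[rec_id]})"
                    )
                seen[rec_id] = lineno
                cur_id, cur_chunks, cur_line = rec_id, [], lineno
            else:
                if cur_id is None:
                    raise FormatError(f"line {lineno}: sequence before first header")
                chunk = line.strip().upper()
                bad = set(chunk) - alphabet
                if bad:
                    raise FormatError(
                        f"line {lineno}: illegal {moltype} character(s) {sorted(bad)}"
                    )
                cur_chunks.append(chunk)
        flush()
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


DEFAULT_EXCLUDED_CHROMS = frozenset({"ChrC", "ChrM", "chloroplast", "mitochondria"})


def read_gff3_protein_coding(path, excluded_chroms=DEFAULT_EXCLUDED_CHROMS) -> list:
    """Parse protein-coding gene models from GFF3, one per representative mRNA.

    The representative mRNA is the one flagged ``representative=1`` (or
    ``canonical=1``) in its attribute column; absent any flag, the mRNA with
    the longest spliced CDS wins, ties broken by lexicographically smallest
    mRNA id.  Genes on chromosomes in ``excluded_chroms`` (organelles by
    default) are skipped.  Genes whose CDS length is not divisible by 3, or
    with no CDS at all, are excluded with a logged warning rather than
    aborting the parse.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list = []
    for gene in db.features_of_type("gene"):
        if gene.seqid in excluded_chroms:
            continue
        biotype = gene.attributes.get("biotype") or gene.attributes.get(
            "gene_biotype"
        )
        if biotype and "protein_coding" not in biotype:
            continue
        candidates = []
        for mrna in db.children(gene, featuretype="mRNA"):
            segs = sorted(
                (c.start, c.end) for c in db.children(mrna, featuretype="CDS")
            )
            if not segs:
                logger.warning("gene %s: mRNA %s has no CDS; skipped", gene.id, mrna.id)
                continue
            length = sum(e - s + 1 for s, e in segs)
            flagged = any(
                mrna.attributes.get(key, ["0"])[0] in ("1", "true", "True")
                for key in ("representative", "canonical")
            )
            candidates.append((flagged, length, mrna.id, segs, mrna.strand))
        if not candidates:
            continue
        flagged_set = [c for c in candidates if c[0]]
        pool = flagged_set if flagged_set else candidates
        # longest spliced CDS, tie -> smallest mRNA id
        pool.sort(key=lambda c: (-c[1], c[2]))
        _, length, mrna_id, segs, strand = pool[0]
        if length % 3:
            logger.warning(
                "gene %s: representative CDS length %d not divisible by 3; excluded",
                gene.id,
                length,
            )
            continue
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=strand,
                cds_segments=segs,
                is_representative=True,
                mrna_id=mrna_id,
            )
        )
    return models


VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


def read_variant_table(path, accession_id: str) -> list:
    """Read one accession's variant TSV (chrom, pos, ref, alt; "-" = deletion).

    A header line is optional and detected by a non-numeric second column.
    Records are returned sorted by (chrom, pos); overlapping records and
    multi-base substitutions are rejected.  Gzip input is transparent.
    """
    df = pd.read_csv(
        str(path),
        sep="\t",
        header=None,
        names=VARIANT_COLUMNS,
        dtype=str,
        comment="#",
    )
    if len(df) and not df.iloc[0]["pos"].isdigit():
        df = df.iloc[1:].reset_index(drop=True)  # header line present
    records = []
    for row in df.itertuples(index=False):
        ref = row.ref.upper()
        alt = "" if row.alt in ("-", "", ".") else row.alt.upper()
        if len(ref) > 1 and alt:
            raise FormatError(
                f"{row.chrom}:{row.pos}: unsupported variant {ref}->{alt or '-'}"
            )
        records.append(
            VariantRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=ref,
                alt=alt,
                accession_id=accession_id,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    for a, b in zip(records, records[1:]):
        if a.chrom == b.chrom and b.pos <= a.end:
            raise FormatError(
                f"overlapping variants at {a.chrom}:{a.pos} and {b.chrom}:{b.pos}"
                f" for accession {accession_id}"
            )
    return records


def write_variant_table(records, path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("chrom\tpos\tref\talt\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            out.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt or '-'}\n")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header = sample ids).

    Rows with any missing entry are rejected.
    """
    df = pd.read_csv(str(path), sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise FormatError(f"missing expression values for genes {bad}")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(str(path), sep="\t", index_label="gene_id")


def _format_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = round(float(edge.length), 6)


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick with supports as internal node labels and
    branch lengths rounded to 6 decimals."""
    _format_branch_lengths(tree)
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=False,
    ).strip()


def read_newick(text: str) -> dendropy.Tree:
    """Parse Newick text; internal node labels are kept (support convention)."""
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"newick parse error: {exc}") from exc


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    return data or {}


def save_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        yaml.safe_dump(config, out, sort_keys=True)


def get_logger(level: int = logging.INFO) -> logging.Logger:
    """Package logger writing to stderr."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


@contextmanager
def stage_timer(stage: str):
    """Log elapsed wall time for a pipeline stage."""
    log = get_logger()
    start = time.perf_counter()
    try:
        yield
    finally:
        log.info("stage %s finished in %.2fs", stage, time.perf_counter() - start)
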