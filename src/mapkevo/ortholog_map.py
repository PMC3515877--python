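"""Closest-counterpart search between two proteomes and codon alignments.

``best_hit`` ranks targets by exact Smith-Waterman local alignment score
(BLOSUM62, gap open 11 / extend 1 — the classic protein-search defaults);
the retained alignment for the winning pair is a global alignment with the
same scoring so that each row, ungapped, is the full source sequence and
can be expanded codon-by-codon into a codon alignment (``back_translate``).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from ._codons import GENETIC_CODE, STOP_CODONS

__all__ = ["OrthologPair", "CodonAlignment", "best_hit", "back_translate", "translate_cds"]


@dataclass
class OrthologPair:
    query_id: str
    target_id: str
    alignment_score: float  # local SW score used for ranking
    protein_alignment: tuple  # two equal-length gapped rows (global)
    reciprocal_best: bool | None = None


@dataclass
class CodonAlignment:
    """Gapped nucleotide rows with gaps only in whole-codon units."""

    ids: list
    rows: list

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("codon alignment needs >= 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows differ in length")
        if lengths.pop() % 3:
            raise ValueError("column count not divisible by 3")


def _make_aligner(mode: str, matrix_name: str = "BLOSUM62",
                  gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # affine cost open + k*extend for a gap of length k
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def translate_cds(cds: str, strip_terminal_stop: bool = True) -> str:
    """Translate an in-frame CDS; internal stops raise, terminal stop optional."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    codons = [cds[i : i + 3].upper() for i in range(0, len(cds), 3)]
    if strip_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aas = []
    for i, codon in enumerate(codons):
        aa = GENETIC_CODE.get(codon)
        if aa is None:
            raise ValueError(f"untranslatable codon {codon!r} at codon index {i + 1}")
        if aa == "*":
            raise ValueError(f"internal stop codon at codon index {i + 1}")
        aas.append(aa)
    return "".join(aas)


def best_hit(query, target_proteome, matrix_name: str = "BLOSUM62",
             gap_open: int = 11, gap_extend: int = 1,
             query_proteome=None) -> OrthologPair:
    """Best-scoring target for ``query`` under local alignment.

    Ties are broken by lexicographically smallest target id.  The stored
    protein alignment is global (see module docstring).  When
    ``query_proteome`` is given, the reciprocal-best-hit status is computed
    and reported (never enforced).
    """
    if not target_proteome:
        raise ValueError("empty target proteome")
    local = _make_aligner("local", matrix_name, gap_open, gap_extend)
    best_id, best_score = None, None
    for rec in sorted(target_proteome, key=lambda r: r.id):
        score = local.score(query.seq, rec.seq)
        if best_score is None or score > best_score:
            best_id, best_score = rec.id, score
    target = next(r for r in target_proteome if r.id == best_id)
    global_aln = _make_aligner("global", matrix_name, gap_open, gap_extend)
    aln = global_aln.align(query.seq, target.seq)[0]
    reciprocal = None
    if query_proteome is not None:
        back_id, back_score = None, None
        for rec in sorted(query_proteome, key=lambda r: r.id):
            score = local.score(target.seq, rec.seq)
            if back_score is None or score > back_score:
                back_id, back_score = rec.id, score
        reciprocal = back_id == query.id
    return OrthologPair(
        query_id=query.id,
        target_id=target.id,
        alignment_score=float(best_score),
        protein_alignment=(str(aln[0]), str(aln[1])),
        reciprocal_best=reciprocal,
    )


def back_translate(protein_alignment, cds_query: str, cds_target: str) -> CodonAlignment:
    """Expand a pairwise protein alignment to a codon alignment.

    Each CDS must translate exactly to its ungapped protein row (a terminal
    stop codon is stripped); every amino-acid column becomes its source
    codon, protein gaps become ``---``.
    """
    row_q, row_t = protein_alignment
    if len(row_q) != len(row_t):
        raise ValueError("protein alignment rows differ in length")
    out_rows = []
    for row, cds in ((row_q, cds_query), (row_t, cds_target)):
        cds = cds.upper()
        protein = translate_cds(cds)
        ungapped = row.replace("-", "").upper()
        if protein != ungapped:
            # name the first mismatching codon index
            idx = next(
                (i for i, (a, b) in enumerate(zip(protein, ungapped)) if a != b),
                min(len(protein), len(ungapped)),
            )
            raise ValueError(
                f"CDS translation does not match protein row at codon index {idx + 1}"
            )
        codons = [cds[i : i + 3] for i in range(0, 3 * len(protein), 3)]
        chunks = []
        k = 0
        for aa in row:
            if aa == "-":
                chunks.append("---")
            else:
                chunks.append(codons[k])
                k += 1
        out_rows.append("".join(chunks))
    return CodonAlignment(ids=["query", "target"], rows=out_rows)
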