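"""Within-population polymorphism from accession variant data.

Per-accession pseudochromosomes are built by substituting called SNPs into
the reference and writing "-" at deleted positions, so every accession
keeps the reference coordinate system and the reference gene models apply
unchanged.  CDS alignments extracted from the pseudochromosomes are
screened for large-effect variants (premature stops, lost start/stop,
frameshift deletions) and summarized as nucleotide diversity pi
partitioned into synonymous (pi_s) and nonsynonymous (pi_a) sites.

pi is the mean over all sequence pairs of the per-site difference
proportion (Tajima's pairwise estimator in its plain pairwise-average
form, no n/(n-1) correction); pi_a and pi_s divide pathway-averaged
difference counts by Nei-Gojobori site counts.  Within-species proportions
are left uncorrected for multiple hits, as is standard for polymorphism
data (the between-species module applies the correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from . import divergence
from ._codons import is_stop, is_valid_codon
from .io_formats import get_logger

__all__ = [
    "PseudoChromosome",
    "DiversityEstimate",
    "LargeEffectReport",
    "apply_variants",
    "extract_cds_alignment",
    "detect_large_effect",
    "exclusion_policy",
    "nucleotide_diversity",
]

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving gap ("-") and N characters."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PseudoChromosome:
    """Accession chromosome in reference coordinates ("-" marks deletions)."""

    accession_id: str
    chrom: str
    seq: str


@dataclass
class DiversityEstimate:
    n: int  # sequences used
    L: float  # mean compared sites per pair
    pi: float
    pi_a: float
    pi_s: float
    ratio: float  # pi_a / pi_s, nan when undefined
    flags: set = field(default_factory=set)


@dataclass
class LargeEffectReport:
    gene_id: str
    effects: dict  # accession_id -> set of effect names

    @property
    def affected_accessions(self) -> list:
        return sorted(self.effects)


def apply_variants(reference_chrom: str, variants, accession_id: str = "",
                   chrom: str = "") -> PseudoChromosome:
    """Substitute an accession's variants into the reference chromosome.

    SNP positions get the alternate base; deleted positions become "-" so
    the sequence keeps the reference length.  Variants must be sorted and
    non-overlapping; a reference-allele mismatch raises, naming chrom:pos.
    """
    seq = list(reference_chrom.upper())
    last_end = 0
    for v in variants:
        if v.pos <= last_end:
            raise ValueError(f"overlapping variants at {v.chrom}:{v.pos}")
        last_end = v.end
        if v.end > len(seq):
            raise ValueError(f"{v.chrom}:{v.pos}: variant beyond chromosome end")
        ref_here = "".join(seq[v.pos - 1 : v.end])
        if ref_here != v.ref.upper():
            raise ValueError(
                f"{v.chrom}:{v.pos}: reference allele mismatch"
                f" (table says {v.ref!r}, reference has {ref_here!r})"
            )
        if v.is_deletion:
            for i in range(v.pos - 1, v.end):
                seq[i] = "-"
        else:
            seq[v.pos - 1] = v.alt.upper()
    return PseudoChromosome(
        accession_id=accession_id or (variants[0].accession_id if variants else ""),
        chrom=chrom,
        seq="".join(seq),
    )


def extract_cds(chrom_seq: str, gene_model) -> str:
    """Spliced CDS of a gene model from one chromosome sequence (1-based
    inclusive segments; minus-strand genes reverse-complemented, "-" kept)."""
    parts = [chrom_seq[s - 1 : e] for s, e in gene_model.cds_segments]
    cds = "".join(parts)
    if gene_model.strand == "-":
        cds = reverse_complement(cds)
    return cds


def extract_cds_alignment(pseudochromosomes, gene_model) -> tuple:
    """One CDS row per accession, all in reference-CDS coordinates.

    ``pseudochromosomes`` maps accession_id -> {chrom -> sequence-like};
    values may be PseudoChromosome objects or plain strings.  Rows are a
    multiple alignment by construction (equal reference length).  Returns
    (accession_ids, rows).
    """
    ids, rows = [], []
    for acc in sorted(pseudochromosomes):
        chroms = pseudochromosomes[acc]
        if gene_model.chrom not in chroms:
            raise ValueError(
                f"accession {acc!r} lacks chromosome {gene_model.chrom!r}"
            )
        entry = chroms[gene_model.chrom]
        seq = entry.seq if isinstance(entry, PseudoChromosome) else entry
        ids.append(acc)
        rows.append(extract_cds(seq, gene_model))
    return ids, rows


def detect_large_effect(cds_rows, gene_id: str, accession_ids=None) -> LargeEffectReport:
    """Flag accessions whose CDS row carries a presumably disabling variant.

    Checked per row: premature stop (in-frame stop before the final codon,
    on gap-free codons), lost start ATG, lost terminal stop, and any "-"
    run whose length is not divisible by 3 (frameshift deletion).
    """
    if accession_ids is None:
        accession_ids = [f"row{i}" for i in range(len(cds_rows))]
    effects: dict = {}

    def add(acc, effect):
        effects.setdefault(acc, set()).add(effect)

    for acc, row in zip(accession_ids, cds_rows):
        row = row.upper()
        # frameshift: any maximal gap run of length not divisible by 3
        run = 0
        for ch in row + "X":
            if ch == "-":
                run += 1
            else:
                if run and run % 3:
                    add(acc, "frameshift_deletion")
                run = 0
        codons = [row[i : i + 3] for i in range(0, len(row), 3)]
        if codons and is_valid_codon(codons[0]) and codons[0] != "ATG":
            add(acc, "lost_start")
        if codons and is_valid_codon(codons[-1]) and not is_stop(codons[-1]):
            add(acc, "lost_stop")
        for codon in codons[:-1]:
            if is_valid_codon(codon) and is_stop(codon):
                add(acc, "premature_stop")
                break
    return LargeEffectReport(gene_id=gene_id, effects=effects)


def exclusion_policy(accession_ids, cds_rows, report: LargeEffectReport,
                     mode: str = "drop_accessions"):
    """Apply a large-effect exclusion rule to a CDS alignment.

    ``drop_gene`` removes the whole gene from the analysis set (returns
    None) as soon as any accession is affected; ``drop_accessions`` removes
    only the affected rows.  If fewer than 2 rows remain, the gene is
    excluded with a warning.  Returns (accession_ids, rows) or None.
    """
    if mode not in ("drop_gene", "drop_accessions"):
        raise ValueError(f"unknown exclusion mode {mode!r}")
    if not report.effects:
        return list(accession_ids), list(cds_rows)
    log = get_logger()
    if mode == "drop_gene":
        log.info(
            "gene %s excluded (large-effect variants in %s)",
            report.gene_id,
            ",".join(report.affected_accessions),
        )
        return None
    kept = [
        (acc, row)
        for acc, row in zip(accession_ids, cds_rows)
        if acc not in report.effects
    ]
    log.info(
        "gene %s: dropped accessions %s",
        report.gene_id,
        ",".join(report.affected_accessions),
    )
    if len(kept) < 2:
        log.warning("gene %s excluded: fewer than 2 clean rows", report.gene_id)
        return None
    ids, rows = zip(*kept)
    return list(ids), list(rows)


def _pair_counts(row_a: str, row_b: str):
    """Per-pair (sites, mismatches, S, N, Sd, Nd) over codon-clean columns."""
    sites = mismatches = 0
    s_sites = n_sites = sd = nd = 0.0
    for ca, cb in divergence._comparable_codons(row_a, row_b):
        sites += 3
        mismatches += sum(a != b for a, b in zip(ca, cb))
        s1, n1 = divergence.count_sites(ca)
        s2, n2 = divergence.count_sites(cb)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        d_s, d_n = divergence.count_differences(ca, cb)
        sd += d_s
        nd += d_n
    return sites, mismatches, s_sites, n_sites, sd, nd


def nucleotide_diversity(cds_rows) -> DiversityEstimate:
    """pi, pi_a, pi_s over an accession CDS alignment.

    For every pair of rows, codon columns containing gaps, ambiguity, or
    stops in either row are dropped; pi averages total mismatch proportions
    over the n(n-1)/2 pairs, pi_s averages Sd/S, pi_a averages Nd/N.  Pairs
    with no comparable sites are skipped with a flag.
    """
    rows = [r.upper() for r in cds_rows]
    if len(rows) < 2:
        raise ValueError("need >= 2 rows for diversity")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows differ in length")
    flags: set = set()
    pis, pas, pss, Ls = [], [], [], []
    for a, b in combinations(rows, 2):
        sites, mm, s_sites, n_sites, sd, nd = _pair_counts(a, b)
        if sites == 0:
            flags.add("pair_without_comparable_sites")
            continue
        Ls.append(sites)
        pis.append(mm / sites)
        pss.append(sd / s_sites if s_sites > 0 else 0.0)
        pas.append(nd / n_sites if n_sites > 0 else 0.0)
    if not pis:
        raise ValueError("no pair has comparable sites")
    pi = sum(pis) / len(pis)
    pi_a = sum(pas) / len(pas)
    pi_s = sum(pss) / len(pss)
    if pi_s == 0.0:
        ratio = float("nan")
        flags.add("ratio_undefined")
    else:
        ratio = pi_a / pi_s
    return DiversityEstimate(
        n=len(rows),
        L=sum(Ls) / len(Ls),
        pi=pi,
        pi_a=pi_a,
        pi_s=pi_s,
        ratio=ratio,
        flags=flags,
    )
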