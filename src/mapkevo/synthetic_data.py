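"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generators emulate the structure of the real study inputs — a reference
genome with multi-exon protein-coding genes on both strands, per-accession
variant tables (SNPs and 1-3 bp deletions) for a resequenced population,
ortholog pairs diverged under a codon model with a tunable
nonsynonymous/synonymous rate ratio, decoy-contaminated proteomes with
planted activation-loop motifs, and clustered expression profiles.

Population variation uses an infinite-sites scheme: the number of
segregating mutations has expectation theta_site * L * a_n (a_n the
harmonic number sum 1/i), derived-allele counts follow the neutral
frequency spectrum (probability proportional to 1/i), and nonsynonymous
mutations are thinned by the factor omega.  This is a site-independent
heuristic, not a coalescent with genealogical correlation or
recombination; it is chosen because the expectations it targets (E[pi] =
theta, pi_a/pi_s -> omega) are analytically checkable.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._codons import (
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    codon_neighbors,
    is_stop,
    is_transition,
    translate_codon,
)
from .io_formats import ExpressionMatrix, SequenceRecord, VariantRecord

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "simulate_coding_gene",
    "evolve_ortholog_pair",
    "simulate_population_sample",
    "simulate_genome_bundle",
    "write_bundle",
    "simulate_proteome",
    "simulate_expression",
    "GenomeBundle",
]


@dataclass
class SimulationConfig:
    """Study conditions for a full synthetic bundle.

    Defaults mirror the real study's scale where it states one (80
    accessions) and otherwise use values typical of an *A. thaliana*-like
    system: theta_site 0.005 per site, omega 0.3 (purifying selection),
    kappa 1.0, and an ortholog branch length of 0.4 neutral substitutions
    per codon (a Ks around 0.13, the *A. thaliana* / *A. lyrata* scale).
    """

    seed: int = 0
    n_accessions: int = 80
    theta_site: float = 0.005
    omega: float = 0.3
    kappa: float = 1.0
    branch_length_t: float = 0.4
    n_genes: int = 6
    codons_per_gene: int = 300

    def __post_init__(self):
        if self.theta_site < 0:
            raise ValueError("theta_site must be >= 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.n_accessions < 2:
            raise ValueError("n_accessions must be >= 2")


@dataclass
class TruthLedger:
    """Ground truth behind one simulated bundle."""

    genes: dict = field(default_factory=dict)  # gene_id -> structure + cds + omega
    mutations: dict = field(default_factory=dict)  # gene_id -> list of mutation dicts
    injected_effects: dict = field(default_factory=dict)  # gene_id -> list
    family_members: dict = field(default_factory=dict)  # protein_id -> loop class
    expression_clusters: dict = field(default_factory=dict)  # gene_id -> cluster

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        return cls(**json.loads(text))


def simulate_coding_gene(codons_per_gene: int, seed: int) -> SequenceRecord:
    """Random coding sequence: ATG, random sense codons, one terminal stop."""
    if codons_per_gene < 2:
        raise ValueError("codons_per_gene must be >= 2")
    rng = np.random.default_rng(seed)
    middle = rng.choice(len(SENSE_CODONS), size=codons_per_gene - 2)
    stop = sorted(STOP_CODONS)[rng.integers(0, len(STOP_CODONS))]
    seq = "ATG" + "".join(SENSE_CODONS[i] for i in middle) + stop
    return SequenceRecord(id=f"gene_seed{seed}", seq=seq, moltype="dna")


def _weighted_neighbor(codon: str, pos: int, kappa: float, rng) -> str | None:
    """Propose a non-stop single-base change at ``pos``; transitions weighted
    ``kappa`` over transversions.  None when every change creates a stop."""
    options = [nb for nb in codon_neighbors(codon, pos) if not is_stop(nb)]
    if not options:
        return None
    weights = np.array(
        [kappa if is_transition(codon[pos], nb[pos]) else 1.0 for nb in options]
    )
    return options[rng.choice(len(options), p=weights / weights.sum())]


def _evolve_lineage(codons: list, t: float, omega: float, kappa: float, rng) -> list:
    """Evolve for t expected neutral substitutions per codon.

    Proposal events arrive at the neutral rate; each picks a uniform
    position and a non-stop change (kappa-weighted), accepted with relative
    probability 1 if synonymous and omega if nonsynonymous (scaled so the
    larger class accepts with probability 1).
    """
    codons = list(codons)
    n_events = rng.poisson(t * len(codons))
    scale = max(1.0, omega)
    for _ in range(n_events):
        site = rng.integers(0, 3 * len(codons))
        ci, pos = divmod(int(site), 3)
        proposal = _weighted_neighbor(codons[ci], pos, kappa, rng)
        if proposal is None:
            continue
        syn = translate_codon(proposal) == translate_codon(codons[ci])
        accept_p = (1.0 if syn else omega) / scale
        if rng.random() < accept_p:
            codons[ci] = proposal
    return codons


def evolve_ortholog_pair(cds: str, branch_length_t: float, omega: float,
                         kappa: float, seed: int) -> tuple:
    """Two descendants of ``cds`` evolved independently for t/2 each.

    No indels; both outputs stay stop-free in frame and keep the input
    length.  ``branch_length_t`` is in expected neutral substitutions per
    codon along the whole path between the descendants.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(is_stop(c) for c in codons[:-1]):
        raise ValueError("internal stop codon in input CDS")
    body = codons[:-1] if is_stop(codons[-1]) else codons
    tail = codons[len(body):]
    rng = np.random.default_rng(seed)
    a = _evolve_lineage(body, branch_length_t / 2.0, omega, kappa, rng)
    b = _evolve_lineage(body, branch_length_t / 2.0, omega, kappa, rng)
    return "".join(a + tail), "".join(b + tail)


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def simulate_population_sample(cds: str, n_accessions: int, theta_site: float,
                               seed: int, omega: float = 1.0,
                               chrom: str = "gene",
                               accession_ids=None,
                               stop_injections=None,
                               cds_deletions=None) -> tuple:
    """Segregating variants for a sample of accessions over one CDS.

    Infinite-sites: distinct sites, mutation count with expectation
    theta_site * L * a_n, derived-allele counts from the neutral frequency
    spectrum, nonsynonymous mutations thinned by ``omega``.  The terminal
    stop codon is left untouched.  ``stop_injections`` plants premature
    stops as [(accession_id, codon_index_1based)]; ``cds_deletions`` plants
    deletions as [(accession_id, pos_1based, length)] (for gap-handling
    tests; the genome bundle keeps its own deletions outside CDS).

    Returns (variants_by_accession, truth_list); positions are 1-based CDS
    coordinates on ``chrom``.
    """
    cds = cds.upper()
    if n_accessions < 2:
        raise ValueError("n_accessions must be >= 2")
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    rng = np.random.default_rng(seed)
    if accession_ids is None:
        accession_ids = [f"acc{i:03d}" for i in range(n_accessions)]
    variants = {acc: [] for acc in accession_ids}
    truth = []
    L = len(cds)
    codons = [cds[i : i + 3] for i in range(0, L, 3)]
    mutable_sites = np.arange(L - 3 if is_stop(codons[-1]) else L)
    a_n = _harmonic(n_accessions)
    n_mut = rng.poisson(theta_site * len(mutable_sites) * a_n)
    n_mut = min(n_mut, len(mutable_sites))
    sites = rng.choice(mutable_sites, size=n_mut, replace=False)
    spectrum = 1.0 / np.arange(1, n_accessions)
    spectrum /= spectrum.sum()
    for site in sorted(int(s) for s in sites):
        ci, pos = divmod(site, 3)
        proposal = _weighted_neighbor(codons[ci], pos, 1.0, rng)
        if proposal is None:
            continue
        syn = translate_codon(proposal) == translate_codon(codons[ci])
        if not syn and rng.random() >= omega:
            continue
        count = 1 + rng.choice(n_accessions - 1, p=spectrum)
        carriers = rng.choice(n_accessions, size=count, replace=False)
        for k in carriers:
            variants[accession_ids[k]].append(
                VariantRecord(
                    chrom=chrom,
                    pos=site + 1,
                    ref=cds[site],
                    alt=proposal[pos],
                    accession_id=accession_ids[k],
                )
            )
        truth.append(
            {
                "pos": site + 1,
                "ref": cds[site],
                "alt": proposal[pos],
                "synonymous": bool(syn),
                "carriers": sorted(accession_ids[int(k)] for k in carriers),
            }
        )
    taken = {t["pos"] for t in truth}
    for acc, codon_index in stop_injections or []:
        planted = _plant_stop(codons, codon_index, taken)
        if planted is None:
            raise ValueError(f"cannot plant a stop in codon {codon_index}")
        pos, alt = planted
        taken.add(pos)
        variants[acc].append(
            VariantRecord(chrom=chrom, pos=pos, ref=cds[pos - 1], alt=alt,
                          accession_id=acc)
        )
        truth.append(
            {"pos": pos, "ref": cds[pos - 1], "alt": alt, "synonymous": False,
             "carriers": [acc], "injected": "premature_stop"}
        )
    for acc, pos, length in cds_deletions or []:
        if not 1 <= length <= 3:
            raise ValueError("deletion length must be 1-3")
        if any(p in taken for p in range(pos, pos + length)):
            raise ValueError(f"deletion at {pos} overlaps an existing variant")
        taken.update(range(pos, pos + length))
        variants[acc].append(
            VariantRecord(chrom=chrom, pos=pos, ref=cds[pos - 1 : pos - 1 + length],
                          alt="", accession_id=acc)
        )
        truth.append(
            {"pos": pos, "ref": cds[pos - 1 : pos - 1 + length], "alt": "",
             "carriers": [acc], "injected": "deletion"}
        )
    for acc in variants:
        variants[acc].sort(key=lambda v: v.pos)
    return variants, truth


def _plant_stop(codons, codon_index: int, taken: set):
    """A single-base change turning codon ``codon_index`` (1-based) into a
    stop, avoiding positions already used; returns (cds_pos_1based, alt)."""
    codon = codons[codon_index - 1]
    for pos in range(3):
        cds_pos = 3 * (codon_index - 1) + pos + 1
        if cds_pos in taken:
            continue
        for nb in codon_neighbors(codon, pos):
            if is_stop(nb):
                return cds_pos, nb[pos]
    return None


# ---------------------------------------------------------------------------
# genome bundle


@dataclass
class GenomeBundle:
    chromosomes: dict  # chrom -> reference sequence
    gff3: str
    variant_tables: dict  # accession_id -> list[VariantRecord] (genomic coords)
    ref_cds: list  # SequenceRecord per gene
    ref_proteins: list
    ortholog_cds: list
    ortholog_proteins: list
    ledger: TruthLedger


def _random_dna(rng, length: int) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length))


def _cds_to_genomic(offset0: int, segments, strand: str, length: int = 1):
    """Map a 0-based CDS offset to a genomic position (1-based).

    For minus-strand genes the CDS reads along the reverse complement, so
    offset 0 is the rightmost base of the last segment.  Returns the
    genomic position of the run's leftmost base when mapping ``length``
    consecutive CDS bases (the run must stay within one segment).
    """
    total = sum(e - s + 1 for s, e in segments)
    if strand == "-":
        # leftmost genomic base of the run corresponds to the CDS run's end
        offset0 = total - offset0 - length
    walked = 0
    for s, e in segments:
        seg_len = e - s + 1
        if offset0 < walked + seg_len:
            within = offset0 - walked
            if within + length > seg_len:
                raise ValueError("run crosses an exon boundary")
            return s + within
        walked += seg_len
    raise ValueError("offset beyond CDS")


_COMP = str.maketrans("ACGT", "TGCA")


def simulate_genome_bundle(config: SimulationConfig,
                           stop_injections=None) -> GenomeBundle:
    """A complete synthetic input set: reference genome on two chromosomes
    with multi-exon genes on both strands, per-accession variant tables in
    genomic coordinates (CDS SNPs from the population model, intergenic
    SNPs and 1-3 bp deletions), diverged ortholog sequences, and the truth
    ledger.

    ``stop_injections`` maps gene index (0-based) to [(accession_id,
    codon_index)] premature-stop plants.
    """
    from .ortholog_map import translate_cds

    rng = np.random.default_rng(config.seed)
    accession_ids = [f"acc{i:03d}" for i in range(config.n_accessions)]
    ledger = TruthLedger()
    chrom_parts = {"Chr1": [], "Chr2": []}
    chrom_pos = {"Chr1": 0, "Chr2": 0}
    variant_tables = {acc: [] for acc in accession_ids}
    ref_cds, ref_prot, ort_cds, ort_prot = [], [], [], []

    for g in range(config.n_genes):
        gene_id = f"g{g + 1:03d}"
        chrom = "Chr1" if g % 2 == 0 else "Chr2"
        strand = "+" if (g // 2) % 2 == 0 else "-"
        cds = simulate_coding_gene(
            config.codons_per_gene, int(rng.integers(0, 2**31 - 1))
        ).seq
        # exon layout: split the (strand-oriented) genomic CDS into 2-3 exons
        genomic_cds = cds if strand == "+" else cds.translate(_COMP)[::-1]
        n_exons = int(rng.integers(2, 4))
        cuts = sorted(
            rng.choice(np.arange(10, len(cds) - 10), size=n_exons - 1, replace=False)
        )
        bounds = [0] + [int(c) for c in cuts] + [len(cds)]
        spacer = _random_dna(rng, int(rng.integers(100, 300)))
        chrom_parts[chrom].append(spacer)
        chrom_pos[chrom] += len(spacer)
        segments = []
        for k in range(n_exons):
            exon = genomic_cds[bounds[k] : bounds[k + 1]]
            start = chrom_pos[chrom] + 1
            chrom_parts[chrom].append(exon)
            chrom_pos[chrom] += len(exon)
            segments.append((start, start + len(exon) - 1))
            if k < n_exons - 1:
                intron = _random_dna(rng, int(rng.integers(50, 150)))
                chrom_parts[chrom].append(intron)
                chrom_pos[chrom] += len(intron)
        # population variants on the CDS
        injections = (stop_injections or {}).get(g)
        var_by_acc, truth = simulate_population_sample(
            cds,
            config.n_accessions,
            config.theta_site,
            seed=int(rng.integers(0, 2**31 - 1)),
            omega=config.omega,
            chrom=gene_id,
            accession_ids=accession_ids,
            stop_injections=injections,
        )
        genomic_truth = []
        for mut in truth:
            length = max(1, len(mut["ref"]))
            gpos = _cds_to_genomic(mut["pos"] - 1, segments, strand, length)
            if strand == "+":
                gref, galt = mut["ref"], mut["alt"]
            else:
                gref = mut["ref"].translate(_COMP)[::-1]
                galt = mut["alt"].translate(_COMP)[::-1]
            genomic_truth.append({**mut, "chrom": chrom, "genomic_pos": gpos,
                                  "genomic_ref": gref, "genomic_alt": galt})
        for acc, records in var_by_acc.items():
            for v in records:
                length = len(v.ref)
                gpos = _cds_to_genomic(v.pos - 1, segments, strand, length)
                if strand == "+":
                    gref, galt = v.ref, v.alt
                else:
                    gref = v.ref.translate(_COMP)[::-1]
                    galt = v.alt.translate(_COMP)[::-1]
                variant_tables[acc].append(
                    VariantRecord(chrom=chrom, pos=gpos, ref=gref, alt=galt,
                                  accession_id=acc)
                )
        # diverged ortholog
        cds_a, cds_b = evolve_ortholog_pair(
            cds,
            config.branch_length_t,
            config.omega,
            config.kappa,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ref_cds.append(SequenceRecord(gene_id, cds, "dna"))
        ref_prot.append(SequenceRecord(gene_id, translate_cds(cds), "protein"))
        ort_id = f"{gene_id}_ort"
        ort_cds.append(SequenceRecord(ort_id, cds_b, "dna"))
        ort_prot.append(SequenceRecord(ort_id, translate_cds(cds_b), "protein"))
        ledger.genes[gene_id] = {
            "chrom": chrom,
            "strand": strand,
            "cds_segments": segments,
            "cds": cds,
            "omega": config.omega,
            "ortholog_id": ort_id,
            "ortholog_cds": cds_b,
        }
        ledger.mutations[gene_id] = genomic_truth
        if injections:
            ledger.injected_effects[gene_id] = [
                {"accession": acc, "codon_index": ci, "effect": "premature_stop"}
                for acc, ci in injections
            ]

    # intergenic polymorphism and deletions (outside CDS by design)
    chromosomes = {}
    for chrom, parts in chrom_parts.items():
        tail = _random_dna(rng, int(rng.integers(100, 300)))
        chromosomes[chrom] = "".join(parts) + tail
    cds_positions = {chrom: set() for chrom in chromosomes}
    for gene in ledger.genes.values():
        for s, e in gene["cds_segments"]:
            cds_positions[gene["chrom"]].update(range(s, e + 1))
    a_n = _harmonic(config.n_accessions)
    spectrum = 1.0 / np.arange(1, config.n_accessions)
    spectrum /= spectrum.sum()
    for chrom, seq in chromosomes.items():
        noncds = sorted(set(range(1, len(seq) + 1)) - cds_positions[chrom])
        # SNPs at the same theta; deletions at a tenth of it
        for kind, rate in (("snp", config.theta_site), ("del", config.theta_site / 10)):
            n_mut = rng.poisson(rate * len(noncds) * a_n)
            n_mut = min(n_mut, max(0, len(noncds) // 4))
            if n_mut == 0:
                continue
            sites = rng.choice(len(noncds), size=n_mut, replace=False)
            for si in sorted(int(s) for s in sites):
                pos = noncds[si]
                if kind == "snp":
                    ref = seq[pos - 1]
                    alt = NUCLEOTIDES[
                        (NUCLEOTIDES.index(ref) + 1 + rng.integers(0, 3)) % 4
                    ]
                else:
                    length = int(rng.integers(1, 4))
                    if pos + length - 1 > len(seq):
                        continue
                    run = set(range(pos, pos + length))
                    if run & cds_positions[chrom]:
                        continue
                    ref, alt = seq[pos - 1 : pos - 1 + length], ""
                count = 1 + rng.choice(config.n_accessions - 1, p=spectrum)
                carriers = rng.choice(config.n_accessions, size=count, replace=False)
                for k in carriers:
                    variant_tables[accession_ids[int(k)]].append(
                        VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                      accession_id=accession_ids[int(k)])
                    )

    # drop per-accession overlaps introduced by independent intergenic draws
    for acc in accession_ids:
        records = sorted(variant_tables[acc], key=lambda v: (v.chrom, v.pos))
        cleaned = []
        for v in records:
            if cleaned and cleaned[-1].chrom == v.chrom and v.pos <= cleaned[-1].end:
                continue
            cleaned.append(v)
        variant_tables[acc] = cleaned

    gff_lines = ["##gff-version 3"]
    for gene_id, info in ledger.genes.items():
        segs = info["cds_segments"]
        start, end = segs[0][0], segs[-1][1]
        chrom, strand = info["chrom"], info["strand"]
        gff_lines.append(
            f"{chrom}\tmapkevo\tgene\t{start}\t{end}\t.\t{strand}\t."
            f"\tID={gene_id};biotype=protein_coding"
        )
        mrna_id = f"{gene_id}.1"
        gff_lines.append(
            f"{chrom}\tmapkevo\tmRNA\t{start}\t{end}\t.\t{strand}\t."
            f"\tID={mrna_id};Parent={gene_id};representative=1"
        )
        for k, (s, e) in enumerate(segs):
            phase = 0  # phases are informational here; extraction uses segments
            gff_lines.append(
                f"{chrom}\tmapkevo\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}"
                f"\tID={mrna_id}.cds{k};Parent={mrna_id}"
            )
    return GenomeBundle(
        chromosomes=chromosomes,
        gff3="\n".join(gff_lines) + "\n",
        variant_tables=variant_tables,
        ref_cds=ref_cds,
        ref_proteins=ref_prot,
        ortholog_cds=ort_cds,
        ortholog_proteins=ort_prot,
        ledger=ledger,
    )


def write_bundle(bundle: GenomeBundle, out_dir, config: SimulationConfig | None = None,
                 proteome=None, seed_alignment=None, expression=None) -> None:
    """Write a bundle directory (FASTA/GFF3/TSV/JSON, all plain text)."""
    import os

    from . import io_formats

    os.makedirs(out_dir, exist_ok=True)
    os.makedirs(os.path.join(out_dir, "variants"), exist_ok=True)
    io_formats.write_fasta(
        [SequenceRecord(c, s, "dna") for c, s in sorted(bundle.chromosomes.items())],
        os.path.join(out_dir, "genome.fasta"),
    )
    with open(os.path.join(out_dir, "annotation.gff3"), "w", encoding="utf-8") as out:
        out.write(bundle.gff3)
    for acc, records in bundle.variant_tables.items():
        io_formats.write_variant_table(
            records, os.path.join(out_dir, "variants", f"{acc}.tsv")
        )
    io_formats.write_fasta(bundle.ref_cds, os.path.join(out_dir, "ref_cds.fasta"))
    io_formats.write_fasta(
        bundle.ref_proteins, os.path.join(out_dir, "ref_proteins.fasta")
    )
    io_formats.write_fasta(
        bundle.ortholog_cds, os.path.join(out_dir, "ortholog_cds.fasta")
    )
    io_formats.write_fasta(
        bundle.ortholog_proteins, os.path.join(out_dir, "ortholog_proteins.fasta")
    )
    with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as out:
        out.write(bundle.ledger.to_json())
    if config is not None:
        io_formats.save_config(asdict(config), os.path.join(out_dir, "config.yaml"))
    if proteome is not None:
        io_formats.write_fasta(proteome, os.path.join(out_dir, "proteome.fasta"))
    if seed_alignment is not None:
        io_formats.write_fasta(
            seed_alignment, os.path.join(out_dir, "seed_alignment.fasta")
        )
    if expression is not None:
        io_formats.write_expression_matrix(
            expression, os.path.join(out_dir, "expression.tsv")
        )


# ---------------------------------------------------------------------------
# proteome with planted family


TXY_TEMPLATE = "T{x}YV{a}{b}RWYRAPE"
MEY_TEMPLATE = "MEY{a}{b}RWYRAPE"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _family_consensus(rng, length: int = 180, motif_at: int = 90) -> tuple:
    """Random family consensus with a canonical TEY loop planted at
    ``motif_at`` (0-based).  Returns (consensus, motif_start, motif_len)."""
    residues = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]
    motif = TXY_TEMPLATE.format(x="E", a="A", b="T")
    residues[motif_at : motif_at + len(motif)] = motif
    return "".join(residues), motif_at, len(motif)


def _member_from_consensus(consensus: str, motif_at: int, motif_len: int,
                           loop_type: str, rng, mutation_rate: float) -> str:
    seq = list(consensus)
    for i in range(len(seq)):
        if motif_at <= i < motif_at + motif_len:
            continue
        if rng.random() < mutation_rate:
            seq[i] = AMINO_ACIDS[rng.integers(0, 20)]
    a, b = (AMINO_ACIDS[rng.integers(0, 20)] for _ in range(2))
    if loop_type in ("TDY", "TEY"):
        motif = TXY_TEMPLATE.format(x=loop_type[1], a=a, b=b)
    elif loop_type == "MEY":
        # one residue shorter than the canonical loop; pad to keep the
        # downstream kinase core in register
        motif = MEY_TEMPLATE.format(a=a, b=b) + AMINO_ACIDS[rng.integers(0, 20)]
    else:
        raise ValueError(f"unknown loop type {loop_type!r}")
    seq[motif_at : motif_at + motif_len] = motif
    return "".join(seq)


def simulate_proteome(n_family: int, n_decoys: int, loop_types=("TEY",),
                      seed: int = 0, mutation_rate: float = 0.08,
                      n_seed: int = 8) -> tuple:
    """Decoy-contaminated proteome with a planted kinase-like family.

    Family members are mutated copies of a shared consensus carrying the
    requested activation-loop motif (cycled over ``loop_types``); decoys
    are composition-matched random proteins, redrawn if they accidentally
    contain a loop motif.  A separate ``n_seed``-member ungapped seed
    alignment from the same family model is returned for profile building.

    Returns (proteome_records, ledger, seed_alignment_records).
    """
    from .family_scan import classify_activation_loop

    if not set(loop_types) <= {"TDY", "TEY", "MEY"}:
        raise ValueError("loop_types must be a subset of {TDY, TEY, MEY}")
    rng = np.random.default_rng(seed)
    consensus, motif_at, motif_len = _family_consensus(rng)
    ledger = TruthLedger()
    records = []
    for i in range(n_family):
        loop = loop_types[i % len(loop_types)]
        seq = _member_from_consensus(
            consensus, motif_at, motif_len, loop, rng, mutation_rate
        )
        pid = f"fam{i:03d}"
        records.append(SequenceRecord(pid, seq, "protein"))
        ledger.family_members[pid] = loop
    comp = np.array([consensus.count(aa) for aa in AMINO_ACIDS], dtype=float)
    comp /= comp.sum()
    for i in range(n_decoys):
        while True:
            seq = "".join(
                AMINO_ACIDS[k]
                for k in rng.choice(20, size=len(consensus), p=comp)
            )
            if classify_activation_loop(seq)[0] == "none":
                break
        records.append(SequenceRecord(f"decoy{i:03d}", seq, "protein"))
    seed_alignment = [
        SequenceRecord(
            f"seed{i:03d}",
            _member_from_consensus(
                consensus, motif_at, motif_len, "TEY", rng, mutation_rate
            ),
            "protein",
        )
        for i in range(n_seed)
    ]
    return records, ledger, seed_alignment


def simulate_expression(n_genes: int, n_samples: int, cluster_map: dict,
                        within_cluster_rho: float = 0.9, noise_sd: float = 1.0,
                        seed: int = 0) -> ExpressionMatrix:
    """Clustered expression profiles: genes in one cluster share a latent
    sample profile plus independent noise.

    With ``within_cluster_rho`` = r and ``noise_sd`` = s the noise amplitude
    is s * sqrt((1 - r) / r), so realized within-cluster correlation
    increases with r and equals 1 when s = 0.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2 (correlation undefined)")
    if not 0 <= within_cluster_rho <= 1:
        raise ValueError("within_cluster_rho must be in [0, 1]")
    genes = sorted(cluster_map)
    if len(genes) != n_genes:
        raise ValueError("cluster_map must cover every gene exactly once")
    rng = np.random.default_rng(seed)
    clusters = sorted(set(cluster_map.values()))
    latent = {c: rng.normal(size=n_samples) for c in clusters}
    if within_cluster_rho > 0:
        amp = noise_sd * np.sqrt((1 - within_cluster_rho) / within_cluster_rho)
    else:
        amp = None  # pure noise, no shared signal
    values = np.empty((n_genes, n_samples))
    for i, gene in enumerate(genes):
        noise = rng.normal(size=n_samples)
        if amp is None:
            values[i] = noise_sd * noise if noise_sd > 0 else noise
        else:
            values[i] = latent[cluster_map[gene]] + amp * noise
    return ExpressionMatrix(gene_ids=genes, sample_ids=[
        f"sample{j:02d}" for j in range(n_samples)
    ], values=values)
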