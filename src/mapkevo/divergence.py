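"""Between-species Ka, Ks and Ka/Ks on pairwise codon alignments.

Sites and differences are counted with the Nei-Gojobori (1986) scheme:
synonymous site fractions per codon position (stop-codon changes excluded
from the mutational opportunity), mutation-pathway averaging for codons
differing at more than one position, and a Jukes-Cantor multiple-hit
correction d = -(3/4) ln(1 - (4/3) p) applied to the difference
proportions.  A kappa-weighted site-counting variant (transition/
transversion-aware mutational opportunity, kappa estimated from fourfold
degenerate sites) is available as an approximation to rate-weighted
estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

from ._codons import (
    GENETIC_CODE,
    NUCLEOTIDES,
    codon_neighbors,
    is_stop,
    is_transition,
    is_valid_codon,
    translate_codon,
)

__all__ = [
    "DivergenceEstimate",
    "count_sites",
    "count_differences",
    "jukes_cantor",
    "ka_ks",
    "estimate_kappa_fourfold",
]


@dataclass
class DivergenceEstimate:
    """Site and difference counts plus corrected rates for one codon alignment.

    ``ratio`` is ``nan`` when Ks is zero or either rate is saturated; the
    condition is recorded in ``flags``.
    """

    n_codons: int
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    ka: float
    ks: float
    ratio: float
    flags: set = field(default_factory=set)


@lru_cache(maxsize=8192)
def count_sites(codon: str, kappa: float | None = None) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (S, N) for one codon.

    For each of the three positions the synonymous fraction is the number of
    single-base changes that preserve the amino acid divided by the number of
    changes that do not create a stop codon.  With ``kappa`` set, changes are
    weighted kappa (transitions) vs 1 (transversions) in both numerator and
    denominator.  S + N = 3 always.
    """
    if not is_valid_codon(codon):
        raise ValueError(f"invalid codon {codon!r}")
    if is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = translate_codon(codon)
    # Each position contributes exactly one site, split into syn/nonsyn.
    s = 0.0
    for pos in range(3):
        syn_w = 0.0
        valid_w = 0.0
        for nb in codon_neighbors(codon, pos):
            if is_stop(nb):
                continue
            w = 1.0
            if kappa is not None and is_transition(codon[pos], nb[pos]):
                w = kappa
            valid_w += w
            if translate_codon(nb) == aa:
                syn_w += w
        if valid_w > 0:
            s += syn_w / valid_w
    return s, 3.0 - s


@lru_cache(maxsize=4096)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """(Sd, Nd, stop_crossing_only) by averaging over mutational pathways."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0, False
    surviving: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn = 0
        nonsyn = 0
        crosses_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                crosses_stop = True
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not crosses_stop:
            surviving.append((syn, nonsyn))
    pool = surviving if surviving else all_paths
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd, not surviving


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts (Sd, Nd).

    All orderings of the single-base steps between the two codons are
    enumerated; pathways passing through stop codons are discarded (if every
    pathway does, the average is taken over all of them).  Sd + Nd equals the
    number of differing positions.
    """
    for c in (codon_a, codon_b):
        if not is_valid_codon(c):
            raise ValueError(f"invalid codon {c!r}")
        if is_stop(c):
            raise ValueError(f"stop codon {c!r} not comparable")
    sd, nd, _ = _pathway_counts(codon_a, codon_b)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p); nan when p >= 3/4."""
    if p < 0:
        raise ValueError("difference proportion must be >= 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _comparable_codons(row_a: str, row_b: str):
    """Yield (codon_a, codon_b) for codon columns free of gaps/ambiguity/stops
    in both rows; used by ka_ks and reusable for site filtering."""
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    if len(row_a) % 3:
        raise ValueError("alignment length not divisible by 3")
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        if not (is_valid_codon(ca) and is_valid_codon(cb)):
            continue
        if is_stop(ca) or is_stop(cb):
            continue
        yield ca, cb


def ka_ks(row_a: str, row_b: str, kappa: float | None = None) -> DivergenceEstimate:
    """NG86 Ka, Ks and Ka/Ks for a pairwise codon alignment.

    Codon columns containing gaps, ambiguous bases, or stop codons in either
    row are dropped.  Site counts are averaged over the two sequences; the
    Jukes-Cantor correction is applied to pN and pS.  ``kappa`` switches to
    transition/transversion-weighted site counting.
    """
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    n_codons = 0
    flags: set = set()
    for ca, cb in _comparable_codons(row_a.upper(), row_b.upper()):
        n_codons += 1
        s1, nn1 = count_sites(ca, kappa)
        s2, nn2 = count_sites(cb, kappa)
        s_a += s1
        n_a += nn1
        s_b += s2
        n_b += nn2
        d_s, d_n = count_differences(ca, cb)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise ValueError("no comparable codons in alignment")
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    p_s = sd / s_sites if s_sites > 0 else 0.0
    ka = jukes_cantor(p_n)
    ks = jukes_cantor(p_s)
    if math.isnan(ka):
        flags.add("ka_saturated")
    if math.isnan(ks):
        flags.add("ks_saturated")
    if ks == 0.0 or math.isnan(ks) or math.isnan(ka):
        ratio = math.nan
        flags.add("ratio_undefined")
    else:
        ratio = ka / ks
    return DivergenceEstimate(
        n_codons=n_codons,
        N=n_sites,
        S=s_sites,
        Nd=nd,
        Sd=sd,
        pN=p_n,
        pS=p_s,
        ka=ka,
        ks=ks,
        ratio=ratio,
        flags=flags,
    )


def estimate_kappa_fourfold(row_a: str, row_b: str) -> float:
    """Crude transition/transversion rate ratio from fourfold degenerate sites.

    kappa = 2 * (transitions / transversions) at third positions of fourfold
    codons, reflecting the 1:2 transition:transversion opportunity.  Returns
    1.0 when there are no transversions (or no differences) to calibrate on.
    """
    ts = tv = 0
    for ca, cb in _comparable_codons(row_a.upper(), row_b.upper()):
        aa = translate_codon(ca)
        fourfold = all(
            translate_codon(ca[:2] + b) == aa for b in NUCLEOTIDES
        ) and ca[:2] == cb[:2]
        if not fourfold or ca[2] == cb[2]:
            continue
        if is_transition(ca[2], cb[2]):
            ts += 1
        else:
            tv += 1
    if tv == 0 or ts == 0:
        return 1.0
    return 2.0 * ts / tv
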