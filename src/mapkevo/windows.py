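"""Sliding-window polymorphism and divergence tracks along a CDS.

Windows follow the nucleotide grid (default width 51, step 9) on the
reference CDS.  Because 51 is not divisible by 3, each window is trimmed
inward to complete codons before site-class statistics are computed, which
keeps the synonymous/nonsynonymous arithmetic codon-coherent while
preserving the window grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

from . import divergence, diversity

__all__ = ["WindowTrack", "make_windows", "window_stats"]

DEFAULT_WIDTH = 51
DEFAULT_STEP = 9


@dataclass
class WindowTrack:
    gene_id: str
    width: int
    step: int
    windows: list = field(default_factory=list)  # dicts with start/end + stats


def make_windows(L: int, width: int = DEFAULT_WIDTH, step: int = DEFAULT_STEP) -> list:
    """Window coordinates (start, end), 1-based inclusive, on a length-L CDS.

    Starts run 1, 1+step, ... while start <= L; the final windows are
    truncated at L; windows shorter than one codon are dropped.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if width < 3:
        raise ValueError("width must be >= 3")
    if step < 1:
        raise ValueError("step must be >= 1")
    out = []
    start = 1
    while start <= L:
        end = min(start + width - 1, L)
        if end - start + 1 >= 3:
            out.append((start, end))
        start += step
    return out


def _codon_trim(start: int, end: int) -> tuple | None:
    """Trim a 1-based nt window inward to whole reference codons.

    Returns (codon_start_nt, codon_end_nt) 1-based, or None if no complete
    codon fits.
    """
    c0 = math.ceil((start - 1) / 3)  # first codon fully inside, 0-based
    c1 = end // 3 - 1  # last codon fully inside, 0-based
    if c1 < c0:
        return None
    return 3 * c0 + 1, 3 * (c1 + 1)


def window_stats(ingroup_rows, outgroup_row=None, width: int = DEFAULT_WIDTH,
                 step: int = DEFAULT_STEP, gene_id: str = "") -> WindowTrack:
    """Per-window pi_a/pi_s (ingroup) and Ka/Ks (ingroup vs outgroup).

    All rows must be equal length (reference CDS coordinates).  Divergence
    per window is the mean over (ingroup row, outgroup) pairs; window
    entries carry NaN where a statistic's denominator class has no sites or
    the window holds no complete codon.  ``outgroup_row=None`` gives a
    polymorphism-only track.  Raw ingroup pairwise mismatch counts and
    compared sites are included so tracks can be aggregated exactly.
    """
    rows = [r.upper() for r in ingroup_rows]
    if len(rows) < 2:
        raise ValueError("need >= 2 ingroup rows")
    L = len(rows[0])
    if outgroup_row is not None and len(outgroup_row) != L:
        raise ValueError("outgroup row length differs from ingroup")
    track = WindowTrack(gene_id=gene_id, width=width, step=step)
    nan = float("nan")
    for start, end in make_windows(L, width, step):
        entry = {
            "start": start,
            "end": end,
            "pi": nan,
            "pi_a": nan,
            "pi_s": nan,
            "ka": nan,
            "ks": nan,
            "ka_ks": nan,
            "ingroup_mismatches": nan,
            "ingroup_sites": nan,
        }
        trimmed = _codon_trim(start, end)
        if trimmed is not None:
            lo, hi = trimmed
            sub = [r[lo - 1 : hi] for r in rows]
            try:
                est = diversity.nucleotide_diversity(sub)
            except ValueError:
                est = None
            if est is not None:
                entry["pi"] = est.pi
                entry["pi_a"] = est.pi_a
                entry["pi_s"] = est.pi_s
                # raw counts for exact aggregation across windows
                total_mm = total_sites = 0
                for a, b in combinations(sub, 2):
                    sites, mm, *_ = diversity._pair_counts(a, b)
                    total_mm += mm
                    total_sites += sites
                entry["ingroup_mismatches"] = total_mm
                entry["ingroup_sites"] = total_sites
            if outgroup_row is not None:
                out_sub = outgroup_row.upper()[lo - 1 : hi]
                kas, kss = [], []
                for r in sub:
                    try:
                        div = divergence.ka_ks(r, out_sub)
                    except ValueError:
                        continue
                    kas.append(div.ka)
                    kss.append(div.ks)
                kas = [k for k in kas if not math.isnan(k)]
                kss = [k for k in kss if not math.isnan(k)]
                if kas:
                    entry["ka"] = sum(kas) / len(kas)
                if kss:
                    entry["ks"] = sum(kss) / len(kss)
                if kas and kss and entry["ks"] > 0:
                    entry["ka_ks"] = entry["ka"] / entry["ks"]
        track.windows.append(entry)
    return track
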