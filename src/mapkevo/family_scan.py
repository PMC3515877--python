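"""Gene-family identification by position-specific profile scoring.

A log-odds scoring profile (PSSM) is built from a seed alignment of known
family members and slid along every protein in a proteome; candidates above
a data-derived threshold are classified by their kinase activation loop:
the canonical T-x-Y motif embedded in ``TxYVxxRWYRAPE`` (TDY when x = D,
TEY when x = E) or the atypical ``MEYxxRWYRAPE``.  A species-specific
refinement loop rebuilds the profile from the current candidates and
rescans until the candidate set is stable.

The profile is an ungapped position-specific scoring matrix rather than a
full profile HMM: the family's discriminative signal is a highly conserved
kinase core, and the activation-loop motif is the decisive criterion, so
insert/delete states add nothing at this scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import get_logger

__all__ = [
    "AMINO_ACIDS",
    "ScoringProfile",
    "FamilyAssignment",
    "build_profile",
    "score_protein",
    "scan_proteome",
    "classify_activation_loop",
    "refine_species_profile",
    "tabulate_family",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

TXY_PATTERN = re.compile(r"T[A-Z]YV[A-Z][A-Z]RWYRAPE")
MEY_PATTERN = re.compile(r"MEY[A-Z][A-Z]RWYRAPE")


@dataclass
class ScoringProfile:
    """Position-specific log-odds profile.

    ``scores[p, a]`` is ln(freq[p, a] / background[a]) with pseudocount-
    smoothed position frequencies; ``threshold`` is the minimum best-window
    score reported by a scan.
    """

    scores: np.ndarray  # (length, 20)
    background: np.ndarray  # (20,)
    threshold: float

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class FamilyAssignment:
    protein_id: str
    loop_class: str  # "TDY", "TEY", "MEY", "TxY" (other x), or "none"
    loop_position: int  # 1-based index of the motif's first residue; 0 if none
    profile_score: float
    species: str = ""


def _column_frequencies(column_residues: list, pseudocount: float) -> np.ndarray:
    counts = np.zeros(20)
    for aa in column_residues:
        if aa in _AA_INDEX:
            counts[_AA_INDEX[aa]] += 1
    return (counts + pseudocount) / (counts.sum() + 20 * pseudocount)


def build_profile(
    seed_alignment,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    threshold_fraction: float = 0.5,
) -> ScoringProfile:
    """Build a log-odds profile from an aligned set of family proteins.

    Columns with more than 50% gaps are dropped.  Position frequencies are
    observed residue counts plus ``pseudocount``; the background is the
    overall residue frequency of the seed set (pseudocount-smoothed) unless
    given explicitly.

    The reporting threshold defaults to ``threshold_fraction`` times the
    mean leave-one-out self-score of the seeds (each seed scored against a
    profile built from the others, the unbiased preview of a fresh family
    member's score).  A fraction of the self-score is used rather than a
    self-score-minus-k-SD rule because with small seed sets the SD estimate
    is noisy while true members and composition-matched background
    sequences are separated by hundreds of log-odds units; should the mean
    self-score be non-positive (no conservation signal), the threshold
    falls back to mean minus 3 SD.
    """
    rows = [rec.seq.upper() for rec in seed_alignment]
    if len(rows) < 2:
        raise ValueError("seed alignment needs >= 2 sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged seed alignment")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 (zero gives -inf scores)")
    if background is None:
        counts = np.zeros(20)
        for r in rows:
            for aa in r:
                if aa in _AA_INDEX:
                    counts[_AA_INDEX[aa]] += 1
        background = (counts + pseudocount) / (counts.sum() + 20 * pseudocount)
    background = np.asarray(background, dtype=float)
    profile = _matrix_profile(rows, pseudocount, background)
    if len(rows) >= 3:
        self_scores = [
            score_protein(
                rows[i].replace("-", ""),
                _matrix_profile(rows[:i] + rows[i + 1 :], pseudocount, background),
            )
            for i in range(len(rows))
        ]
    else:
        self_scores = [score_protein(r.replace("-", ""), profile) for r in rows]
    mean, sd = float(np.mean(self_scores)), float(np.std(self_scores))
    if mean > 0:
        profile.threshold = threshold_fraction * mean
    else:
        profile.threshold = mean - 3.0 * sd
    return profile


def _matrix_profile(rows, pseudocount: float, background: np.ndarray) -> ScoringProfile:
    """Log-odds matrix for aligned rows; threshold left at -inf."""
    n_rows = len(rows)
    kept_cols = [
        c
        for c in range(len(rows[0]))
        if sum(r[c] == "-" for r in rows) <= 0.5 * n_rows
    ]
    if not kept_cols:
        raise ValueError("all columns are majority-gap")
    freqs = np.vstack(
        [
            _column_frequencies([r[c] for r in rows], pseudocount)
            for c in kept_cols
        ]
    )
    return ScoringProfile(
        scores=np.log(freqs / background), background=background, threshold=-np.inf
    )


def _encode(seq: str) -> np.ndarray:
    """Map a protein string to AA indices; -1 for non-standard residues."""
    return np.array([_AA_INDEX.get(aa, -1) for aa in seq], dtype=int)


def score_protein(seq: str, profile: ScoringProfile) -> float:
    """Best ungapped-window log-odds sum of ``seq`` against ``profile``.

    Proteins shorter than the profile are scored over all placements of the
    protein within the profile.  Non-standard residues contribute 0.
    """
    idx = _encode(seq.upper())
    w = profile.length
    n = len(idx)
    padded = np.zeros((profile.length, 21))
    padded[:, :20] = profile.scores  # column 20 (index -1) scores 0
    if n >= w:
        best = -np.inf
        for off in range(n - w + 1):
            s = padded[np.arange(w), idx[off : off + w]].sum()
            best = max(best, s)
        return float(best)
    best = -np.inf
    for off in range(w - n + 1):
        s = padded[off + np.arange(n), idx].sum()
        best = max(best, s)
    return float(best)


def _best_window_segment(seq: str, profile: ScoringProfile) -> str:
    """The profile-length window of ``seq`` achieving the best score (the
    full protein if shorter than the profile)."""
    idx = _encode(seq.upper())
    w = profile.length
    if len(idx) < w:
        return seq.upper()
    padded = np.zeros((profile.length, 21))
    padded[:, :20] = profile.scores
    scores = [
        padded[np.arange(w), idx[off : off + w]].sum()
        for off in range(len(idx) - w + 1)
    ]
    off = int(np.argmax(scores))
    return seq.upper()[off : off + w]


def classify_activation_loop(seq: str) -> tuple[str, int]:
    """Locate the activation-loop motif and classify it.

    Scans for ``T?YV??RWYRAPE`` (class = TDY / TEY / literal TxY for other
    x); the atypical ``MEY??RWYRAPE`` is checked only when the canonical
    pattern is absent.  The leftmost match wins.  Returns (class, 1-based
    position of the motif's first residue), or ("none", 0).
    """
    s = seq.upper()
    m = TXY_PATTERN.search(s)
    if m:
        x = m.group(0)[1]
        cls = {"D": "TDY", "E": "TEY"}.get(x, f"T{x}Y")
        return cls, m.start() + 1
    m = MEY_PATTERN.search(s)
    if m:
        return "MEY", m.start() + 1
    return "none", 0


def scan_proteome(proteins, profile: ScoringProfile, species: str = "") -> list:
    """Score every protein against the profile; keep those at or above the
    profile threshold, sorted by score descending (ties by id)."""
    hits = []
    for rec in proteins:
        score = score_protein(rec.seq, profile)
        if score >= profile.threshold:
            loop_class, loop_pos = classify_activation_loop(rec.seq)
            hits.append(
                FamilyAssignment(
                    protein_id=rec.id,
                    loop_class=loop_class,
                    loop_position=loop_pos,
                    profile_score=score,
                    species=species,
                )
            )
    hits.sort(key=lambda h: (-h.profile_score, h.protein_id))
    return hits


def refine_species_profile(
    profile: ScoringProfile,
    candidates,
    proteome,
    max_iter: int = 5,
    pseudocount: float = 0.5,
    threshold_fraction: float = 0.5,
):
    """Iteratively rebuild a species-specific profile from the candidates.

    Each round rebuilds the profile from the current candidates' best-window
    segments (an ungapped alignment by construction), rescans the proteome,
    and adds motif-positive new hits; iteration stops at a fixed point or
    after ``max_iter`` rounds (the latter sets ``converged=False``).

    Returns (profile, assignments, n_iterations, converged).
    """
    if not candidates:
        raise ValueError("refinement needs a non-empty initial candidate set")
    if max_iter == 0:
        return profile, list(candidates), 0, True
    from .io_formats import SequenceRecord

    by_id = {rec.id: rec for rec in proteome}
    species = candidates[0].species
    current_ids = {c.protein_id for c in candidates}
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        segments = [
            SequenceRecord(pid, _best_window_segment(by_id[pid].seq, profile), "protein")
            for pid in sorted(current_ids)
            if pid in by_id
        ]
        if len(segments) >= 2:
            min_len = min(len(s.seq) for s in segments)
            segments = [
                SequenceRecord(s.id, s.seq[:min_len], "protein") for s in segments
            ]
            profile = build_profile(
                segments, pseudocount, threshold_fraction=threshold_fraction
            )
        rescan = scan_proteome(proteome, profile, species=species)
        new_ids = current_ids | {
            h.protein_id for h in rescan if h.loop_class != "none"
        }
        if new_ids == current_ids:
            converged = True
            break
        current_ids = new_ids
    if not converged:
        get_logger().warning(
            "profile refinement did not converge within %d iterations", max_iter
        )
    assignments = []
    for pid in sorted(current_ids):
        rec = by_id.get(pid)
        if rec is None:
            continue
        loop_class, loop_pos = classify_activation_loop(rec.seq)
        assignments.append(
            FamilyAssignment(
                protein_id=pid,
                loop_class=loop_class,
                loop_position=loop_pos,
                profile_score=score_protein(rec.seq, profile),
                species=species,
            )
        )
    assignments.sort(key=lambda h: (-h.profile_score, h.protein_id))
    return profile, assignments, n_iter, converged


def tabulate_family(assignments, by_species: bool = True) -> pd.DataFrame:
    """Per-species counts of TEY, TDY, MEY and total family members.

    Motif-negative assignments (loop_class "none") are not counted; loop
    classes other than the three canonical ones are pooled under "other".
    """
    columns = ["TEY", "TDY", "MEY", "other", "total"]
    if not assignments:
        return pd.DataFrame(columns=columns)
    rows: dict = {}
    for a in assignments:
        if a.loop_class == "none":
            continue
        key = a.species if by_species else "all"
        row = rows.setdefault(key, dict.fromkeys(columns, 0))
        cls = a.loop_class if a.loop_class in ("TEY", "TDY", "MEY") else "other"
        row[cls] += 1
        row["total"] += 1
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns).sort_index()
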