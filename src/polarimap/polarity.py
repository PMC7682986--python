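"""Per-filament polarity from per-segment direction labels.

A filament can only have one polarity, so the per-segment direction labels
(A/B, from the psi-mode classification) are aggregated by majority vote.
The 'majority confidence score' — the fraction of segments agreeing with
the majority — gates which filaments enter the neighborhood analysis:
filaments scoring below 2/3 are excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from polarimap.errors import EmptyFilamentError

__all__ = [
    "FilamentTrace",
    "majority_vote",
    "vote_filaments",
    "filter_by_confidence",
    "link_segments_to_filaments",
    "CONFIDENCE_THRESHOLD",
]

#: default exclusion cutoff on the majority confidence score (inclusive: >= kept)
CONFIDENCE_THRESHOLD = 2.0 / 3.0


@dataclass
class FilamentTrace:
    """Ordered segments of one filament with its voted polarity.

    ``confidence`` = max(n_A, n_B) / (n_A + n_B), in [0.5, 1]; a tie gives
    0.5 and polarity 'undetermined'.
    """

    filament_id: int
    segment_ids: list
    labels: list
    voted_polarity: str
    confidence: float


def majority_vote(labels) -> tuple[str, float]:
    """Voted polarity and majority confidence score of one filament.

    Returns ``(polarity, confidence)`` with polarity in {'A', 'B',
    'undetermined'}; a tie is undetermined with confidence 0.5.
    """
    labels = list(labels)
    if not labels:
        raise EmptyFilamentError("cannot vote on a filament with no segments")
    counts = Counter(labels)
    n_a, n_b = counts.get("A", 0), counts.get("B", 0)
    if n_a + n_b != len(labels):
        bad = set(labels) - {"A", "B"}
        raise ValueError(f"unknown direction labels: {sorted(bad)}")
    confidence = max(n_a, n_b) / (n_a + n_b)
    if n_a > n_b:
        polarity = "A"
    elif n_b > n_a:
        polarity = "B"
    else:
        polarity = "undetermined"
    return polarity, confidence


def vote_filaments(segments: pd.DataFrame, label_column: str = "direction") -> pd.DataFrame:
    """Per-filament vote over a segment table.

    ``segments`` needs columns ``filament_id`` and ``label_column``.
    Returns a report with columns ``filament_id, n_segments, polarity,
    confidence`` (one row per filament, sorted by id).
    """
    rows = []
    for fid, grp in segments.groupby("filament_id", sort=True):
        polarity, confidence = majority_vote(grp[label_column].tolist())
        rows.append((fid, len(grp), polarity, confidence))
    return pd.DataFrame(rows, columns=["filament_id", "n_segments", "polarity", "confidence"])


def filter_by_confidence(report: pd.DataFrame,
                         threshold: float = CONFIDENCE_THRESHOLD
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a filament report into (kept, excluded) by confidence.

    The comparison is inclusive: confidence exactly at the threshold is
    kept (the exclusion rule is '< threshold'). Ties (confidence 0.5) are
    always below the default 2/3 cutoff and drop out automatically.
    """
    keep = report["confidence"] >= threshold
    return report[keep].copy(), report[~keep].copy()


def link_segments_to_filaments(segments: pd.DataFrame,
                               max_gap_nm: float = 33.0,
                               max_angle_deg: float = 20.0) -> pd.DataFrame:
    """Greedy chaining of unassigned segments into filaments (optional helper).

    Segments within ``max_gap_nm`` of a chain end are appended when the
    step direction deviates less than ``max_angle_deg`` from the chain's
    current direction. When two candidate continuations disagree by more
    than ``max_angle_deg`` (an ambiguous junction) the chain is terminated
    there, so ambiguous regions yield shorter unambiguous pieces. Isolated
    segments become single-segment filaments.

    Returns a copy of ``segments`` with a ``filament_id`` column assigned.
    Ground-truth filament ids, when available, are the preferred pathway;
    this automates what was done by hand in the original analysis.
    """
    df = segments.reset_index(drop=True)
    pos = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    n = len(df)
    assigned = np.full(n, -1, dtype=int)
    if n == 0:
        out = df.copy()
        out["filament_id"] = pd.Series(dtype=int)
        return out

    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    cos_tol = np.cos(np.radians(max_angle_deg))

    def candidates(end_idx, direction):
        """Unassigned neighbors of a chain end compatible with its direction."""
        found = []
        for j in tree.query_ball_point(pos[end_idx], max_gap_nm):
            if j == end_idx or assigned[j] >= 0:
                continue
            step = pos[j] - pos[end_idx]
            norm = np.linalg.norm(step)
            if norm == 0:
                continue
            if direction is None or np.dot(step, direction) / norm >= cos_tol:
                found.append((norm, j, step / norm))
        found.sort(key=lambda t: t[0])
        return found

    def extend(chain, forward):
        """Grow one end of the chain until no unambiguous continuation exists."""
        while True:
            end = chain[-1] if forward else chain[0]
            if len(chain) >= 2:
                prev = chain[-2] if forward else chain[1]
                direction = pos[end] - pos[prev]
                direction = direction / np.linalg.norm(direction)
            else:
                direction = None
            cand = candidates(end, direction)
            if not cand:
                return
            if len(cand) >= 2:
                # ambiguous junction: two continuations that disagree -> stop
                _, _, u0 = cand[0]
                _, _, u1 = cand[1]
                if np.dot(u0, u1) < cos_tol:
                    return
            _, j, _ = cand[0]
            assigned[j] = assigned[end]
            chain.append(j) if forward else chain.insert(0, j)

    next_fid = 0
    for i in np.argsort(pos[:, 0], kind="stable"):
        if assigned[i] >= 0:
            continue
        assigned[i] = next_fid
        chain = [i]
        extend(chain, forward=True)
        extend(chain, forward=False)
        next_fid += 1

    out = df.copy()
    out["filament_id"] = assigned
    return out
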