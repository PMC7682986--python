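"""3D neighborhood analysis of filament polarity and inter-filament spacing.

For every segment of a kept filament the (up to) three nearest segments of
*neighboring* filaments within a 40 nm radius define its neighborhood.
Each such relation is uniform-polarity (UP) when the two filaments' voted
polarities match and mixed-polarity (MP) otherwise. The bundle score

    S = (MPs - UPs) / (MPs + UPs)

summarizes a bundle: -1 when all filaments point the same way, +1 when
every counted relation joins filaments of opposite polarity.

Two neighbor semantics are provided:

* ``per-filament`` (default): one relation to the nearest segment of each
  of the up-to-k nearest *distinct* neighboring filaments — filament-level
  neighborhoods, so a single adjacent filament cannot fill all k slots;
* ``per-segment``: the k nearest foreign segments regardless of filament.

Relations are directed (counted from each source segment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from polarimap.errors import UndefinedScoreError

__all__ = [
    "find_neighbors",
    "polarity_degrees",
    "bundle_score",
    "interfilament_spacing",
    "DEFAULT_RADIUS_NM",
    "DEFAULT_K",
]

DEFAULT_RADIUS_NM = 40.0
DEFAULT_K = 3

_RELATION_COLUMNS = ["source_index", "neighbor_index", "source_filament",
                     "neighbor_filament", "distance_nm", "relation"]


def find_neighbors(segments: pd.DataFrame, radius_nm: float = DEFAULT_RADIUS_NM,
                   k: int = DEFAULT_K, mode: str = "per-filament") -> pd.DataFrame:
    """Neighbor relations of every segment within a 3D radius.

    ``segments`` needs columns ``filament_id, x_nm, y_nm, z_nm, polarity``
    (polarity of the segment's *filament*; restrict to kept filaments
    before calling). Returns one row per directed relation with columns
    ``source_index, neighbor_index, source_filament, neighbor_filament,
    distance_nm, relation`` where relation is 'UP' or 'MP'. A segment with
    no foreign segment in range simply contributes no rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("per-filament", "per-segment"):
        raise ValueError(f"unknown neighbor mode {mode!r}")

    df = segments.reset_index(drop=True)
    pos = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    fil = df["filament_id"].to_numpy()
    pol = df["polarity"].to_numpy()
    idx = df.index.to_numpy()

    rows = []
    if len(df) == 0:
        return pd.DataFrame(columns=_RELATION_COLUMNS)
    tree = cKDTree(pos)
    in_range = tree.query_ball_point(pos, radius_nm)
    for i in range(len(df)):
        foreign = [(float(np.linalg.norm(pos[j] - pos[i])), j)
                   for j in in_range[i] if fil[j] != fil[i]]
        if not foreign:
            continue
        foreign.sort()
        if mode == "per-filament":
            # nearest segment of each distinct neighboring filament,
            # filaments ranked by that nearest distance, capped at k
            seen: dict = {}
            for d, j in foreign:
                if fil[j] not in seen:
                    seen[fil[j]] = (d, j)
            chosen = sorted(seen.values())[:k]
        else:
            chosen = foreign[:k]
        for d, j in chosen:
            rel = "UP" if pol[i] == pol[j] else "MP"
            rows.append((idx[i], idx[j], fil[i], fil[j], d, rel))
    return pd.DataFrame(rows, columns=_RELATION_COLUMNS)


def polarity_degrees(relations: pd.DataFrame) -> pd.DataFrame:
    """Per-source-segment UP and MP degrees (relation counts).

    Returns columns ``source_index, up_degree, mp_degree``; segments with
    no relations are absent (degree (0, 0)).
    """
    if len(relations) == 0:
        return pd.DataFrame(columns=["source_index", "up_degree", "mp_degree"])
    counts = (relations.groupby(["source_index", "relation"]).size()
              .unstack(fill_value=0).reindex(columns=["UP", "MP"], fill_value=0))
    out = counts.reset_index()
    out.columns = ["source_index", "up_degree", "mp_degree"]
    return out


def bundle_score(relations: pd.DataFrame) -> float:
    """Bundle polarity score S = (MPs - UPs) / (MPs + UPs), in [-1, 1]."""
    ups = int((relations["relation"] == "UP").sum())
    mps = int((relations["relation"] == "MP").sum())
    if ups + mps == 0:
        raise UndefinedScoreError("no neighbor relations; score undefined "
                                  "(single-filament bundle or radius too small)")
    return (mps - ups) / (mps + ups)


def interfilament_spacing(segments: pd.DataFrame,
                          radius_nm: float = np.inf) -> dict:
    """Inter-filament spacing distribution of a bundle.

    For each segment: the distance to the nearest segment belonging to a
    different filament (optionally capped at ``radius_nm``). Returns a
    summary dict with the per-segment distances and their median, mean and
    standard deviation; all-nan summary if no filament has a neighbor.
    """
    df = segments.reset_index(drop=True)
    pos = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    fil = df["filament_id"].to_numpy()
    dists = np.full(len(df), np.nan)
    if len(df) > 1 and len(np.unique(fil)) > 1:
        tree = cKDTree(pos)
        kq = min(len(df), 64)
        for i in range(len(df)):
            # expand k until a foreign segment is found (bundles are dense,
            # so the first few neighbors almost always suffice)
            k = kq
            while True:
                dd, jj = tree.query(pos[i], k=k)
                dd, jj = np.atleast_1d(dd), np.atleast_1d(jj)
                foreign = dd[(fil[jj] != fil[i]) & np.isfinite(dd)]
                if foreign.size or k >= len(df):
                    break
                k = min(2 * k, len(df))
            if foreign.size and foreign[0] <= radius_nm:
                dists[i] = foreign[0]
    valid = dists[np.isfinite(dists)]
    return {
        "distances_nm": dists,
        "median_nm": float(np.median(valid)) if valid.size else float("nan"),
        "mean_nm": float(np.mean(valid)) if valid.size else float("nan"),
        "sd_nm": float(np.std(valid, ddof=1)) if valid.size > 1 else float("nan"),
        "n": int(valid.size),
    }
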