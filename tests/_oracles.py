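"""Shared independent reference implementations used by multiple test modules."""

import numpy as np
import pandas as pd


def make_segments(positions, filament_ids, polarities):
    pts = np.asarray(positions, dtype=float)
    return pd.DataFrame({
        "filament_id": filament_ids,
        "x_nm": pts[:, 0], "y_nm": pts[:, 1], "z_nm": pts[:, 2],
        "polarity": polarities,
    })


def brute_force_neighbors(df, radius, k, mode):
    """O(n^2) all-pairs neighbor search, the oracle for the KD-tree path."""
    pos = df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
    fil = df["filament_id"].to_numpy()
    pol = df["polarity"].to_numpy()
    rows = []
    for i in range(len(df)):
        cands = []
        for j in range(len(df)):
            if fil[j] == fil[i]:
                continue
            d = float(np.linalg.norm(pos[j] - pos[i]))
            if d <= radius:
                cands.append((d, j))
        cands.sort()
        if mode == "per-filament":
            best = {}
            for d, j in cands:
                best.setdefault(fil[j], (d, j))
            chosen = sorted(best.values())[:k]
        else:
            chosen = cands[:k]
        for d, j in chosen:
            rows.append((i, j, fil[i], fil[j], d,
                         "UP" if pol[i] == pol[j] else "MP"))
    return rows
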