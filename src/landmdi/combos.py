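"""Co-occurring process combinations within each LMI class.

A combination is the exact set of critical processes at a pixel, encoded
as a bitset over the canonical process order (bit 0 = WaE .. bit 11 = A)
and labelled "WaE + SPP + ..." in that order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .criticality import PROCESS_ORDER
from .grid import MASK_NODATA, Grid

__all__ = [
    "combo_label",
    "combo_key_from_processes",
    "enumerate_combos",
    "top_combinations",
    "coarsen_display",
    "COMBO_NODATA",
]

COMBO_NODATA = -1


def combo_label(key: int) -> str:
    """Human-readable label of a bitset key, canonical process order."""
    parts = [pid for i, pid in enumerate(PROCESS_ORDER) if key >> i & 1]
    return " + ".join(parts) if parts else "(none)"


def combo_key_from_processes(processes) -> int:
    key = 0
    for pid in processes:
        key |= 1 << PROCESS_ORDER.index(pid)
    return key


def combo_grid(masks, classes: Grid) -> Grid:
    """Per-pixel bitset of critical processes; COMBO_NODATA outside the domain."""
    template = classes
    key = np.zeros(template.shape, dtype=np.int32)
    for m in masks:
        bit = PROCESS_ORDER.index(m.process_id)
        key |= (np.where(m.mask.valid(), m.mask.values, 0) == 1).astype(np.int32) << bit
    out = np.where(classes.valid(), key, COMBO_NODATA).astype(np.int32)
    return Grid(out, template.transform, template.crs_id, nodata=COMBO_NODATA)


def enumerate_combos(
    masks, classes: Grid, lmi_counts: Grid | None = None,
    stratum_area_km2: float | None = None,
) -> pd.DataFrame:
    """Tally every (LMI class, combination) pair over valid pixels.

    Each valid pixel contributes exactly one combination; within a class
    combo areas therefore partition the class area.  Popcount of a key
    must equal the pixel's process count (class 5 pools counts >= 5);
    a mismatch is an internal consistency error.
    """
    for m in masks:
        if not m.mask.same_geometry(classes):
            raise ValueError("masks and class grid must share geometry")
    keys = combo_grid(masks, classes)
    valid = classes.valid()
    k = keys.values[valid].astype(np.int64)
    c = classes.values[valid].astype(np.int64)

    pop = np.array([bin(int(v)).count("1") for v in k], dtype=np.int64)
    bad = np.where(c < 5, pop != c, pop < 5)
    if bad.any():
        raise RuntimeError("combo popcount disagrees with LMI class (internal error)")

    cell_area = (classes.cell_size / 1000.0) ** 2
    df = (
        pd.DataFrame({"lmi_class": c, "combo_key": k})
        .groupby(["lmi_class", "combo_key"])
        .size()
        .rename("pixels")
        .reset_index()
    )
    df["combo"] = df["combo_key"].map(combo_label)
    df["area_km2"] = df["pixels"] * cell_area
    denom = stratum_area_km2 if stratum_area_km2 else valid.sum() * cell_area
    df["pct_stratum"] = 100.0 * df["area_km2"] / denom
    class_area = df.groupby("lmi_class")["area_km2"].transform("sum")
    df["pct_class"] = 100.0 * df["area_km2"] / class_area
    df = df.sort_values(
        ["lmi_class", "area_km2", "combo_key"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["cum_pct_class"] = df.groupby("lmi_class")["pct_class"].cumsum()
    return df


def top_combinations(table: pd.DataFrame, lmi_class: int, k: int = 12):
    """The k largest combinations of one class, by area (ties: lowest key).

    Returns ``(sub_table, meets_half_coverage)`` where the flag records
    whether the selection cumulatively covers at least 50 % of the class
    area.  An absent class yields an empty table and False.
    """
    sub = table[table["lmi_class"] == lmi_class]
    if sub.empty:
        return sub.copy(), False
    sub = sub.sort_values(
        ["area_km2", "combo_key"], ascending=[False, True]
    ).head(k).copy()
    class_area = table.loc[table["lmi_class"] == lmi_class, "area_km2"].sum()
    sub["cum_coverage_pct"] = 100.0 * sub["area_km2"].cumsum() / class_area
    coverage = float(sub["cum_coverage_pct"].iloc[-1])
    return sub.reset_index(drop=True), coverage >= 50.0


def coarsen_display(keys: Grid, factor: int = 10) -> Grid:
    """Modal combination label per factor x factor block — display only.

    Area statistics must always come from the fine grid.  Modal ties and
    the nodata-vs-label contest resolve to the lowest key (nodata is -1,
    so blocks that are mostly nodata stay nodata only when nodata wins
    the count outright; ties prefer nodata by the same lowest-key rule).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return keys.with_values(keys.values.copy())
    rows, cols = keys.shape
    out_rows = -(-rows // factor)
    out_cols = -(-cols // factor)
    padded = np.full((out_rows * factor, out_cols * factor), COMBO_NODATA, dtype=keys.values.dtype)
    padded[:rows, :cols] = keys.values
    blocks = padded.reshape(out_rows, factor, out_cols, factor).transpose(0, 2, 1, 3)
    out = np.empty((out_rows, out_cols), dtype=keys.values.dtype)
    for i in range(out_rows):
        for j in range(out_cols):
            vals, counts = np.unique(blocks[i, j], return_counts=True)
            out[i, j] = vals[np.argmax(counts)]  # ties: first (lowest) value
    from .grid import GridTransform

    tr = keys.transform
    new_tr = GridTransform(tr.x0, tr.y0, tr.cell_size * factor)
    return Grid(out, new_tr, keys.crs_id, nodata=COMBO_NODATA)
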