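"""Land multi-degradation index: co-occurrence counts, class binning,
zonal area accounting, histograms, and the natural-breaks cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import MASK_NODATA, Grid, LandMask, ZonePartition

__all__ = [
    "LMIGrid",
    "compute_lmi",
    "classify_lmi",
    "zonal_stats",
    "lmi_histogram",
    "natural_breaks",
    "CLASS_LABELS",
]

CLASS_LABELS = {
    0: "No degradation (0)",
    1: "Very low degradation (1)",
    2: "Low degradation (2)",
    3: "Medium degradation (3)",
    4: "High degradation (4)",
    5: "Very high degradation (>=5)",
}


@dataclass
class LMIGrid:
    """Per-pixel count of co-occurring critical processes.

    ``n_available`` records how many layers were valid at each pixel, so
    zones with incomplete data (9-11 layers) stay distinguishable from
    complete ones.
    """

    counts: Grid
    n_available: Grid

    @property
    def values(self) -> np.ndarray:
        return self.counts.values


def compute_lmi(masks, land: LandMask, stratum: str = "agricultural") -> LMIGrid:
    """Sum the binary criticality masks per pixel, inside one land stratum.

    Pixels outside the stratum are nodata.  Where individual layers are
    nodata (e.g. zones lacking a process), the sum runs over the valid
    layers and ``n_available`` is reduced accordingly.
    """
    if not masks:
        raise ValueError("at least one criticality mask required")
    template = masks[0].mask
    for m in masks[1:]:
        if not m.mask.same_geometry(template):
            raise ValueError("criticality masks must share geometry")
    in_stratum = land.stratum_mask(stratum)

    total = np.zeros(template.shape, dtype=np.int32)
    n_avail = np.zeros(template.shape, dtype=np.int32)
    for m in masks:
        valid = m.mask.valid()
        total += np.where(valid, m.mask.values, 0).astype(np.int32)
        n_avail += valid
    # a pixel with no valid layer at all cannot carry a count
    usable = in_stratum & (n_avail > 0)

    counts = np.full(template.shape, MASK_NODATA, dtype=np.uint8)
    counts[usable] = total[usable]
    avail = np.full(template.shape, MASK_NODATA, dtype=np.uint8)
    avail[usable] = n_avail[usable]
    tr, crs = template.transform, template.crs_id
    return LMIGrid(
        counts=Grid(counts, tr, crs, nodata=MASK_NODATA),
        n_available=Grid(avail, tr, crs, nodata=MASK_NODATA),
    )


def classify_lmi(lmi: LMIGrid) -> Grid:
    """Bin counts into degradation classes {0,1,2,3,4} with 5 meaning >=5."""
    counts = lmi.counts.values
    valid = lmi.counts.valid()
    if counts[valid].size and (counts[valid].astype(np.int64) < 0).any():
        raise ValueError("negative co-occurrence counts")
    classes = np.full(counts.shape, MASK_NODATA, dtype=np.uint8)
    classes[valid] = np.minimum(counts[valid], 5)
    return Grid(classes, lmi.counts.transform, lmi.counts.crs_id, nodata=MASK_NODATA)


def _stratum_rows(classes, counts, sel, cell_area, zone_label, stratum, complete):
    rows = []
    npix = int(sel.sum())
    stratum_area = npix * cell_area
    mean_count = float(counts[sel].mean()) if npix else 0.0
    for k in range(6):
        nk = int(np.count_nonzero(classes[sel] == k))
        rows.append(
            {
                "zone": zone_label,
                "stratum": stratum,
                "lmi_class": k,
                "class_label": CLASS_LABELS[k],
                "area_km2": nk * cell_area,
                "percent": (100.0 * nk / npix) if npix else 0.0,
                "mean_processes": mean_count,
                "stratum_area_km2": stratum_area,
                "complete_data": complete,
            }
        )
    return rows


def zonal_stats(
    class_grid: Grid,
    lmi: LMIGrid,
    zones: ZonePartition,
    land: LandMask,
    stratum: str = "agricultural",
    n_layers: int = 12,
) -> pd.DataFrame:
    """Per-zone class areas, percentages and mean co-occurrence.

    Aggregate rows: ``ALL`` over every zone and ``COMPLETE`` over zones
    with all ``n_layers`` input layers (headline statistics exclude
    incomplete-data zones).  Percentages are
    relative to the zone's stratum area; the mean includes class-0
    pixels.
    """
    for g in (lmi.counts, zones.zones, land.codes):
        if not g.same_geometry(class_grid):
            raise ValueError("zonal inputs must share geometry")
    cell_area = (class_grid.cell_size / 1000.0) ** 2
    classes = class_grid.values
    counts = lmi.counts.values.astype(np.int64)
    in_stratum = land.stratum_mask(stratum) & class_grid.valid()
    zvals = zones.zones.values
    zvalid = zones.zones.valid()

    rows = []
    complete_ids = set(zones.complete_zone_ids(n_layers))
    for zid in zones.zone_ids():
        sel = in_stratum & zvalid & (zvals == zid)
        rows += _stratum_rows(
            classes, counts, sel, cell_area, zid, stratum, zid in complete_ids
        )
    sel_all = in_stratum & zvalid
    rows += _stratum_rows(classes, counts, sel_all, cell_area, "ALL", stratum, False)
    sel_complete = sel_all & np.isin(zvals, sorted(complete_ids))
    rows += _stratum_rows(
        classes, counts, sel_complete, cell_area, "COMPLETE", stratum, True
    )
    return pd.DataFrame(rows)


def lmi_histogram(lmi: LMIGrid) -> pd.DataFrame:
    """Exact count per LMI value, with the share of nonzero pixels in [1, 5]."""
    valid = lmi.counts.valid()
    vals = lmi.counts.values[valid].astype(np.int64)
    top = int(vals.max()) if vals.size else 0
    counts = np.bincount(vals, minlength=top + 1)
    nonzero = int((vals > 0).sum())
    in_1_5 = int(((vals >= 1) & (vals <= 5)).sum())
    share = (in_1_5 / nonzero) if nonzero else 0.0
    return pd.DataFrame(
        {
            "lmi_value": np.arange(top + 1),
            "pixels": counts,
            "share_nonzero_in_1_5": share,
        }
    )


def natural_breaks(values, k: int) -> list[float]:
    """Jenks natural breaks: k-1 interior break points minimizing the
    within-class sum of squared deviations.

    Returned breaks are the maxima of the first k-1 classes (a value v
    belongs to the first class whose break is >= v).  Dynamic program
    over the sorted sample, O(k n^2).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = np.unique(x).size
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct values")

    # prefix sums for O(1) within-class SSE
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:
        # SSE of x[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csum2[j] - csum2[i]) - s * s / m

    best = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=np.int64)
    best[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            for i in range(c - 1, j):
                cand = best[c - 1, i] + sse(i, j)
                if cand < best[c, j]:
                    best[c, j] = cand
                    split[c, j] = i
    # walk back class boundaries
    bounds = []
    j = n
    for c in range(k, 1, -1):
        i = split[c, j]
        bounds.append(float(x[i - 1]))  # max of the preceding class
        j = i
    return bounds[::-1]
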