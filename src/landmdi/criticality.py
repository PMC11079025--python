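"""Critical / Non-critical binarization of the twelve degradation processes.

Each process carries one registered rule that maps raw input values to a
binary criticality mask.  Scalar comparisons are strict (a value exactly
at a cut-off is Non-critical); the trend-significance cut-off p <= 0.1
is non-strict.  Rules are data, not code: the registry serializes to a
plain dict so the uncertainty stage can perturb every scalar cut-off.

Canonical process order and abbreviations::

    WaE   water erosion            (rate > 2 t/ha/yr)
    WiE   wind erosion             (rate > 2 t/ha/yr)
    SOCL  soil organic carbon loss (trend < -0.1 t C/km2/yr, p <= 0.1)
    SS    soil salinization        (saline/sodic share > 50 %)
    SA    soil acidification       (pH < 5.5)
    SC    soil compaction          (susceptibility class High/Very high)
    SNI   soil nutrient imbalances (N/P composite, four cut-offs)
    SPP   soil pollution, pesticides (risk-score class High/Very high, RS > 3)
    SPHM  soil pollution, heavy metals (union of nine concentration cut-offs)
    VD    vegetation degradation   (NDVI trend < -0.001 /yr, p <= 0.1)
    GD    groundwater decline      (water-table trend < -0.001 m/yr, p <= 0.1)
    A     aridity                  (P/PET < 0.65, dry sub-humid .. arid only)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import MASK_NODATA, Grid

__all__ = [
    "PROCESS_ORDER",
    "METAL_THRESHOLDS",
    "CriticalityRule",
    "CriticalMask",
    "default_registry",
    "registry_thresholds",
    "classify_simple_threshold",
    "classify_class_membership",
    "classify_nutrient_imbalance",
    "classify_heavy_metals",
    "compute_aridity",
    "classify_trend_process",
    "risk_score_to_class",
    "build_critical_stack",
]

PROCESS_ORDER = (
    "WaE", "WiE", "SOCL", "SS", "SA", "SC",
    "SNI", "SPP", "SPHM", "VD", "GD", "A",
)

#: safe-limit concentration cut-offs, mg/kg topsoil
METAL_THRESHOLDS = {
    "As": 5.0, "Cd": 1.0, "Cr": 100.0, "Co": 20.0, "Pb": 60.0,
    "Sb": 2.0, "Ni": 50.0, "Cu": 100.0, "Hg": 0.5,
}

#: compaction susceptibility codes: 1 low, 2 moderate, 3 high, 4 very high
COMPACTION_CODES = {1: "L", 2: "M", 3: "H", 4: "VH"}
COMPACTION_CRITICAL_CODES = frozenset({3, 4})

#: dryland class codes for the aridity layer
ARIDITY_CLASSES = {0: "humid", 1: "dry_subhumid", 2: "semi_arid", 3: "arid", 4: "hyper_arid"}
#: only these dryland classes count as critical (hyper-arid land is excluded)
ARIDITY_CRITICAL_CLASSES = frozenset({1, 2, 3})
HYPER_ARID_BOUND = 0.03


@dataclass(frozen=True)
class CriticalityRule:
    """One process's binarization rule.

    ``thresholds`` maps scalar cut-off names to baseline values; the
    names double as the perturbation handles of the uncertainty stage.
    """

    process_id: str
    kind: str  # simple_threshold | class_membership | nutrient_composite | metal_union | aridity | trend
    thresholds: dict[str, float] = field(default_factory=dict)
    direction: str | None = None  # greater | less, for simple_threshold
    units: str = ""
    critical_codes: frozenset[int] | None = None


@dataclass
class CriticalMask:
    """Binary criticality layer for one process (1 critical, 0 not, 255 nodata)."""

    mask: Grid
    process_id: str
    provenance: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.mask.values


def default_registry() -> dict[str, CriticalityRule]:
    """The documented rule registry, keyed by process id, canonical order."""
    r = {}
    r["WaE"] = CriticalityRule("WaE", "simple_threshold", {"WaE": 2.0}, "greater", "t/ha/yr")
    r["WiE"] = CriticalityRule("WiE", "simple_threshold", {"WiE": 2.0}, "greater", "t/ha/yr")
    r["SOCL"] = CriticalityRule(
        "SOCL", "trend", {"SOCL_slope": -0.1, "SOCL_p": 0.1}, units="t C/km2/yr"
    )
    r["SS"] = CriticalityRule("SS", "simple_threshold", {"SS": 50.0}, "greater", "%")
    r["SA"] = CriticalityRule("SA", "simple_threshold", {"SA": 5.5}, "less", "pH")
    r["SC"] = CriticalityRule(
        "SC", "class_membership", {"SC_code": 2.5}, units="class",
        critical_codes=COMPACTION_CRITICAL_CODES,
    )
    r["SNI"] = CriticalityRule(
        "SNI", "nutrient_composite",
        {"SNI_n_surplus": 50.0, "SNI_nue": 0.9, "SNI_p_hi": 50.0, "SNI_p_lo": 25.0},
        units="kg/ha (N), mg/kg (P)",
    )
    r["SPP"] = CriticalityRule(
        "SPP", "class_membership", {"SPP_rs": 3.0}, units="risk score",
        critical_codes=frozenset({3, 4}),
    )
    r["SPHM"] = CriticalityRule(
        "SPHM", "metal_union",
        {f"SPHM_{m}": t for m, t in METAL_THRESHOLDS.items()}, units="mg/kg",
    )
    r["VD"] = CriticalityRule("VD", "trend", {"VD_slope": -0.001, "VD_p": 0.1}, units="NDVI/yr")
    r["GD"] = CriticalityRule("GD", "trend", {"GD_slope": -0.001, "GD_p": 0.1}, units="m/yr")
    r["A"] = CriticalityRule("A", "aridity", {"AI": 0.65}, units="mm/mm")
    return r


def registry_thresholds(registry=None) -> dict[str, float]:
    """Flat name -> baseline value map of every scalar cut-off."""
    registry = registry or default_registry()
    out: dict[str, float] = {}
    for pid in PROCESS_ORDER:
        if pid in registry:
            out.update(registry[pid].thresholds)
    return out


def _mask_grid(template: Grid, critical: np.ndarray, valid: np.ndarray) -> Grid:
    out = np.full(template.shape, MASK_NODATA, dtype=np.uint8)
    out[valid] = critical[valid].astype(np.uint8)
    return Grid(out, template.transform, template.crs_id, nodata=MASK_NODATA)


def classify_simple_threshold(values: Grid, rule: CriticalityRule) -> CriticalMask:
    """Binary mask from a single strict scalar comparison."""
    if rule.kind != "simple_threshold":
        raise ValueError(f"rule for {rule.process_id} is not a simple threshold")
    (t,) = rule.thresholds.values()
    if rule.direction == "greater":
        crit = values.values > t
    elif rule.direction == "less":
        crit = values.values < t
    else:
        raise ValueError(f"invalid direction {rule.direction!r}")
    return CriticalMask(_mask_grid(values, crit, values.valid()), rule.process_id)


def classify_class_membership(codes: Grid, critical_codes) -> Grid:
    """Binary mask where the categorical code belongs to the critical set."""
    critical_codes = frozenset(int(c) for c in critical_codes)
    valid = codes.valid()
    vals = codes.values[valid]
    known = set(np.unique(vals).astype(int).tolist())
    # codes 1..4 for compaction / pesticide risk classes
    if not known <= {1, 2, 3, 4}:
        raise ValueError(f"unknown class codes: {sorted(known - {1, 2, 3, 4})}")
    crit = np.isin(codes.values, sorted(critical_codes))
    return _mask_grid(codes, crit, valid)


def risk_score_to_class(rs: Grid) -> Grid:
    """Continuous pesticide risk score -> class codes 1..4.

    Low (RS <= 2), moderate (2 < RS <= 3), high (3 < RS <= 4),
    very high (RS > 4).
    """
    v = rs.values
    codes = np.full(rs.shape, MASK_NODATA, dtype=np.uint8)
    valid = rs.valid()
    c = np.where(v <= 2, 1, np.where(v <= 3, 2, np.where(v <= 4, 3, 4)))
    codes[valid] = c[valid]
    return Grid(codes, rs.transform, rs.crs_id, nodata=MASK_NODATA)


def compaction_score_to_class(score: Grid) -> Grid:
    """Continuous susceptibility score -> codes 1..4 at unit-step cut points."""
    v = score.values
    codes = np.full(score.shape, MASK_NODATA, dtype=np.uint8)
    valid = score.valid()
    c = np.where(v <= 1.5, 1, np.where(v <= 2.5, 2, np.where(v <= 3.5, 3, 4)))
    codes[valid] = c[valid]
    return Grid(codes, score.transform, score.crs_id, nodata=MASK_NODATA)


def classify_nutrient_imbalance(
    n_surplus: Grid, nue: Grid, p_avail: Grid, p_budget: Grid,
    thresholds: dict[str, float] | None = None,
):
    """Nutrient-imbalance composite.

    Critical where any of the four conditions holds:

    * N surplus  > 50 kg/ha
    * NUE        > 0.9 (soil-fertility mining)
    * P surplus: available P > 50 mg/kg with positive budget
    * P deficit: available P < 25 mg/kg with negative budget

    Returns ``(CriticalMask, dict of the four sub-condition masks)``.
    """
    t = dict(default_registry()["SNI"].thresholds)
    if thresholds:
        t.update(thresholds)
    for g in (nue, p_avail, p_budget):
        if not g.same_geometry(n_surplus):
            raise ValueError("nutrient inputs must share geometry")
    nue_vals = nue.values[nue.valid()]
    if nue_vals.size and (nue_vals < 0).any():
        raise ValueError("NUE must be non-negative")

    c_nsur = n_surplus.values > t["SNI_n_surplus"]
    c_nue = nue.values > t["SNI_nue"]
    c_psur = (p_avail.values > t["SNI_p_hi"]) & (p_budget.values > 0)
    c_pdef = (p_avail.values < t["SNI_p_lo"]) & (p_budget.values < 0)
    valid = n_surplus.valid() & nue.valid() & p_avail.valid() & p_budget.valid()
    crit = c_nsur | c_nue | c_psur | c_pdef
    subclasses = {
        "n_surplus": _mask_grid(n_surplus, c_nsur, valid),
        "n_deficit": _mask_grid(n_surplus, c_nue, valid),
        "p_surplus": _mask_grid(n_surplus, c_psur, valid),
        "p_deficit": _mask_grid(n_surplus, c_pdef, valid),
    }
    return CriticalMask(_mask_grid(n_surplus, crit, valid), "SNI"), subclasses


def classify_heavy_metals(
    metals: dict[str, Grid], thresholds: dict[str, float] | None = None,
    allow_subset: bool = False,
) -> CriticalMask:
    """Union rule over the nine metal concentration grids.

    A pixel is critical when ANY valid metal exceeds its cut-off.  If no
    valid metal exceeds but some metals are nodata, the pixel is nodata
    (Non-critical cannot be certified from partial evidence).
    """
    t = {m: METAL_THRESHOLDS[m] for m in METAL_THRESHOLDS}
    if thresholds:
        for name, value in thresholds.items():
            t[name.removeprefix("SPHM_")] = value
    missing = set(METAL_THRESHOLDS) - set(metals)
    if missing and not allow_subset:
        raise ValueError(f"missing metal grids: {sorted(missing)}")
    if not metals:
        raise ValueError("no metal grids supplied")
    grids = list(metals.values())
    first = grids[0]
    for g in grids[1:]:
        if not g.same_geometry(first):
            raise ValueError("metal grids must share geometry")

    any_exceed = np.zeros(first.shape, dtype=bool)
    all_valid = np.ones(first.shape, dtype=bool)
    for name, g in metals.items():
        valid = g.valid()
        any_exceed |= valid & (g.values > t[name])
        all_valid &= valid
    out = np.full(first.shape, MASK_NODATA, dtype=np.uint8)
    out[all_valid] = 0
    out[any_exceed] = 1
    grid = Grid(out, first.transform, first.crs_id, nodata=MASK_NODATA)
    return CriticalMask(grid, "SPHM")


def compute_aridity(p: Grid, pet: Grid, ai_threshold: float = 0.65):
    """Aridity index AI = P/PET, dryland classes, and the criticality mask.

    Classes: humid (AI >= 0.65), dry sub-humid [0.5, 0.65), semi-arid
    [0.2, 0.5), arid [0.03, 0.2), hyper-arid (< 0.03).  Critical pixels
    are those with AI < 0.65 in the dry sub-humid, semi-arid or arid
    class; hyper-arid land is excluded.
    """
    if not pet.same_geometry(p):
        raise ValueError("P and PET must share geometry")
    valid = p.valid() & pet.valid() & (pet.values > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(valid, p.values / np.where(valid, pet.values, 1.0), np.nan)
    ai_grid = Grid(ai, p.transform, p.crs_id, nodata=float(np.nan))

    classes = np.full(p.shape, MASK_NODATA, dtype=np.uint8)
    cls = np.where(
        ai >= 0.65, 0,
        np.where(ai >= 0.5, 1, np.where(ai >= 0.2, 2, np.where(ai >= HYPER_ARID_BOUND, 3, 4))),
    )
    classes[valid] = cls[valid]
    class_grid = Grid(classes, p.transform, p.crs_id, nodata=MASK_NODATA)

    crit = (ai < ai_threshold) & (ai >= HYPER_ARID_BOUND)
    mask = CriticalMask(_mask_grid(p, np.nan_to_num(crit), valid), "A")
    return ai_grid, class_grid, mask


def classify_trend_process(
    slope: Grid, p: Grid, slope_threshold: float, p_threshold: float = 0.1,
    process_id: str = "trend",
) -> CriticalMask:
    """Critical where slope < slope_threshold (strict) and p <= p_threshold."""
    if slope_threshold >= 0:
        raise ValueError("trend criticality expects a negative slope threshold")
    if not p.same_geometry(slope):
        raise ValueError("slope and p grids must share geometry")
    valid = slope.valid() & p.valid()
    crit = (slope.values < slope_threshold) & (p.values <= p_threshold)
    return CriticalMask(_mask_grid(slope, np.nan_to_num(crit), valid), process_id)


def classify_process(process_id: str, inputs: dict, registry=None) -> CriticalMask:
    """Dispatch one process's rule onto its raw input grid(s)."""
    registry = registry or default_registry()
    rule = registry[process_id]
    if rule.kind == "simple_threshold":
        return classify_simple_threshold(inputs["value"], rule)
    if rule.kind == "class_membership":
        codes = inputs.get("codes")
        if codes is None:
            score = inputs["score"]
            codes = (
                risk_score_to_class(score) if process_id == "SPP"
                else compaction_score_to_class(score)
            )
        grid = classify_class_membership(codes, rule.critical_codes)
        return CriticalMask(grid, process_id)
    if rule.kind == "nutrient_composite":
        mask, _ = classify_nutrient_imbalance(
            inputs["n_surplus"], inputs["nue"], inputs["p_avail"], inputs["p_budget"],
            rule.thresholds,
        )
        return mask
    if rule.kind == "metal_union":
        return classify_heavy_metals(inputs["metals"], rule.thresholds)
    if rule.kind == "aridity":
        _, _, mask = compute_aridity(inputs["p"], inputs["pet"], rule.thresholds["AI"])
        return mask
    if rule.kind == "trend":
        slope_name = f"{process_id}_slope"
        p_name = f"{process_id}_p"
        return classify_trend_process(
            inputs["slope"], inputs["p"],
            rule.thresholds[slope_name], rule.thresholds[p_name], process_id,
        )
    raise ValueError(f"unknown rule kind {rule.kind!r}")


def build_critical_stack(inputs: dict[str, dict], registry=None):
    """Classify every available process, in canonical order.

    ``inputs`` maps process id -> the raw-input dict that
    :func:`classify_process` expects.  Returns ``(masks, missing)``
    where ``missing`` lists the process ids with no inputs.
    """
    if not inputs:
        raise ValueError("empty input manifest")
    unknown = set(inputs) - set(PROCESS_ORDER)
    if unknown:
        raise ValueError(f"unknown process ids: {sorted(unknown)}")
    registry = registry or default_registry()
    masks, missing = [], []
    for pid in PROCESS_ORDER:
        if pid in inputs:
            masks.append(classify_process(pid, inputs[pid], registry))
        else:
            missing.append(pid)
    return masks, missing
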