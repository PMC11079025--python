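"""Synthetic scenario generation with known per-pixel ground truth.

Every raw input the classification stage consumes is generated here:
process value grids (constructed so the registered rule reproduces a
planted criticality mask exactly, with a configurable safety margin
around each cut-off), annual stacks with planted negative trends, P/PET
climatologies spanning the dryland classes, a CLC-like land-use mask and
a Voronoi zone partition with optional incomplete-data zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .criticality import METAL_THRESHOLDS, PROCESS_ORDER
from .grid import MASK_NODATA, Grid, GridTransform, LandMask, ZonePartition

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "gen_gaussian_field",
    "gen_trend_stack",
    "gen_landuse_and_zones",
    "gen_process_inputs",
    "gen_boundary_inputs",
]

#: CLC-like land-use codes
ARABLE_CODES = frozenset({211, 212, 213})
AGRICULTURAL_CODES = frozenset({211, 212, 213, 221, 222, 223, 231, 241, 242, 243, 244})
NONAGRI_CODE = 312

#: processes withheld in incomplete-data zones (9 layers available)
MISSING_3 = ("SA", "SC", "SPHM")
#: processes withheld in partially incomplete zones (10 layers available)
MISSING_2 = ("SA", "SPHM")

_TREND_DEFAULTS = {
    # n_years, critical slope (2x the cut-off), typical intercept level
    "SOCL": (15, -0.2, 5000.0),
    "VD": (16, -0.002, 0.6),
    "GD": (10, -0.002, 5.0),
}

FLOAT_NODATA = -9999.0


@dataclass
class ScenarioConfig:
    """Everything that determines a synthetic scenario (seed included)."""

    shape: tuple[int, int] = (96, 96)
    cell_size_m: float = 500.0
    seed: int = 0
    n_zones: int = 4
    frac_agricultural: float = 0.7
    frac_arable: float = 0.4
    #: per-process planted critical fraction (of the full domain)
    process_fractions: dict = dc_field(default_factory=dict)
    #: margin around each cut-off, as a fraction of its magnitude
    margin_fraction: float | dict = 0.05
    correlation_length: float = 4.0
    #: trend stack parameters; noise defaults to 0 so recovery is exact
    n_years: dict = dc_field(default_factory=dict)
    trend_noise_sd: float = 0.0
    #: optional exact LMI class shares {0..5 -> fraction} over agricultural land
    planted_class_proportions: dict | None = None
    #: draw all process masks as superlevel sets of ONE shared field, so
    #: masks nest and the pixel patterns collapse to count levels — the
    #: easy-to-learn separability limit used by uncertainty checks
    nested_masks: bool = False
    crs_id: int = 3035

    def __post_init__(self) -> None:
        for name in ("frac_agricultural", "frac_arable"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.frac_arable > self.frac_agricultural:
            raise ValueError("arable fraction cannot exceed agricultural fraction")
        fracs = {pid: 0.25 for pid in PROCESS_ORDER}
        fracs.update(self.process_fractions)
        bad = [p for p, f in fracs.items() if not 0.0 <= f <= 1.0]
        if bad:
            raise ValueError(f"process fractions outside [0,1]: {bad}")
        self.process_fractions = fracs
        margins = (
            list(self.margin_fraction.values())
            if isinstance(self.margin_fraction, dict)
            else [self.margin_fraction]
        )
        # > 1/3 would invert the available-P window between its two cut-offs
        if any(not 0.0 <= m < 1 / 3 for m in margins):
            raise ValueError("margin fractions must lie in [0, 1/3)")
        years = {pid: _TREND_DEFAULTS[pid][0] for pid in _TREND_DEFAULTS}
        years.update(self.n_years)
        if any(n < 10 for n in years.values()):
            raise ValueError("trend windows must span at least 10 years")
        self.n_years = years
        if self.planted_class_proportions is not None:
            p = {int(k): float(v) for k, v in self.planted_class_proportions.items()}
            if abs(sum(p.values()) - 1.0) > 1e-9:
                raise ValueError("planted class proportions must sum to 1")
            if not set(p) <= set(range(6)):
                raise ValueError("planted classes must be 0..5")
            self.planted_class_proportions = p

    def margin(self, threshold_name: str) -> float:
        if isinstance(self.margin_fraction, dict):
            return float(self.margin_fraction.get(threshold_name, 0.05))
        return float(self.margin_fraction)

    @property
    def transform(self) -> GridTransform:
        return GridTransform(0.0, self.shape[0] * self.cell_size_m, self.cell_size_m)

    def grid(self, values, nodata=None) -> Grid:
        return Grid(values, self.transform, self.crs_id, nodata=nodata)


@dataclass
class GroundTruth:
    """Planted criticality per process plus the implied LMI over farmland."""

    masks: dict[str, Grid]
    lmi: Grid
    class_proportions: dict[int, float]


def gen_gaussian_field(
    shape,
    correlation_length: float,
    mean: float = 0.0,
    sd: float = 1.0,
    seed: int | None = None,
    cell_size_m: float = 500.0,
    crs_id: int = 3035,
) -> Grid:
    """Seeded spatially autocorrelated Gaussian field.

    ``correlation_length`` is in pixels; 0 gives i.i.d. noise.  The
    smoothed field is re-standardized before scaling, so the marginal
    spread stays ``sd`` regardless of smoothing.  ``sd=0`` degenerates
    to a constant field; negative sd is an error.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if correlation_length < 0:
        raise ValueError("correlation length must be non-negative")
    rng = np.random.default_rng(seed)
    transform = GridTransform(0.0, shape[0] * cell_size_m, cell_size_m)
    if sd == 0:
        return Grid(np.full(shape, float(mean)), transform, crs_id)
    z = rng.standard_normal(shape)
    if correlation_length > 0:
        z = ndimage.gaussian_filter(z, sigma=correlation_length, mode="wrap")
        z = (z - z.mean()) / z.std()
        values = mean + sd * z
    else:
        values = mean + sd * z
    return Grid(values, transform, crs_id)


def _fraction_mask(shape, fraction, correlation_length, rng) -> np.ndarray:
    """Spatially coherent boolean mask covering exactly round(frac*N) pixels."""
    n = shape[0] * shape[1]
    k = int(round(fraction * n))
    if k == 0:
        return np.zeros(shape, dtype=bool)
    if k == n:
        return np.ones(shape, dtype=bool)
    z = rng.standard_normal(shape)
    if correlation_length > 0:
        z = ndimage.gaussian_filter(z, sigma=correlation_length, mode="wrap")
    z = z + rng.uniform(0, 1e-9, size=shape)  # break ties deterministically
    flat = z.ravel()
    order = np.argsort(flat)[::-1]
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(shape)


def gen_trend_stack(
    n_years: int,
    degraded_fraction: float,
    slope: float,
    noise_sd: float,
    seed: int | None = None,
    shape=(64, 64),
    cell_size_m: float = 500.0,
    intercept: float = 1.0,
    correlation_length: float = 0.0,
    crs_id: int = 3035,
):
    """Annual stack with a planted fraction of trending pixels.

    Degraded pixels follow ``intercept + slope * t + eps`` with
    ``eps ~ Normal(0, noise_sd)``; all other pixels have zero slope.
    Returns ``(stack: list of Grid, degraded mask: Grid)``.
    """
    if n_years < 3:
        raise ValueError("need at least 3 years")
    if not 0.0 <= degraded_fraction <= 1.0:
        raise ValueError("degraded_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    transform = GridTransform(0.0, shape[0] * cell_size_m, cell_size_m)
    degraded = _fraction_mask(shape, degraded_fraction, correlation_length, rng)
    base = np.full(shape, float(intercept))
    stack = []
    slopes = np.where(degraded, slope, 0.0)
    for t in range(n_years):
        eps = rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else 0.0
        stack.append(Grid(base + slopes * t + eps, transform, crs_id))
    mask = Grid(degraded.astype(np.uint8), transform, crs_id, nodata=MASK_NODATA)
    return stack, mask


def gen_landuse_and_zones(config: ScenarioConfig):
    """CLC-like land-use mask and a seeded Voronoi zone partition.

    Agricultural and arable fractions are hit exactly (rank-based
    selection).  With three or more zones the last zone is flagged
    incomplete (9 of 12 layers); with four or more, the second-to-last
    holds 10 layers.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    shape = config.shape
    rows, cols = shape

    ag = _fraction_mask(shape, config.frac_agricultural, config.correlation_length, rng)
    n_arable = int(round(config.frac_arable * rows * cols))
    score = rng.standard_normal(shape)
    if config.correlation_length > 0:
        score = ndimage.gaussian_filter(score, sigma=config.correlation_length, mode="wrap")
    score = np.where(ag, score + rng.uniform(0, 1e-9, size=shape), -np.inf)
    order = np.argsort(score.ravel())[::-1]
    arable = np.zeros(rows * cols, dtype=bool)
    arable[order[: min(n_arable, int(ag.sum()))]] = True
    arable = arable.reshape(shape)

    codes = np.full(shape, NONAGRI_CODE, dtype=np.int32)
    ag_only = ag & ~arable
    arable_choices = rng.choice(sorted(ARABLE_CODES), size=int(arable.sum()))
    other_choices = rng.choice(
        sorted(AGRICULTURAL_CODES - ARABLE_CODES), size=int(ag_only.sum())
    )
    codes[arable] = arable_choices
    codes[ag_only] = other_choices
    land = LandMask(
        codes=config.grid(codes),
        agricultural_codes=AGRICULTURAL_CODES,
        arable_codes=ARABLE_CODES,
    )

    pts = rng.uniform(0, 1, size=(config.n_zones, 2)) * [rows, cols]
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr[..., None] - pts[:, 0]) ** 2 + (cc[..., None] - pts[:, 1]) ** 2
    zones = d2.argmin(axis=2).astype(np.int32) + 1

    completeness = {z: 12 for z in range(1, config.n_zones + 1)}
    missing: dict[int, list[str]] = {}
    if config.n_zones >= 3:
        completeness[config.n_zones] = 9
        missing[config.n_zones] = list(MISSING_3)
    if config.n_zones >= 4:
        completeness[config.n_zones - 1] = 10
        missing[config.n_zones - 1] = list(MISSING_2)
    partition = ZonePartition(
        zones=config.grid(zones), completeness=completeness, missing=missing
    )
    return land, partition


def _planted_masks(config: ScenarioConfig, land, zones, rng):
    """Per-process {0,1} planted masks honouring zone-level data gaps."""
    shape = config.shape
    unavailable = {pid: np.zeros(shape, dtype=bool) for pid in PROCESS_ORDER}
    for zid, miss in zones.missing.items():
        zsel = zones.zones.values == zid
        for pid in miss:
            unavailable[pid] |= zsel

    masks = {}
    if config.planted_class_proportions is None:
        if config.nested_masks:
            z = rng.standard_normal(shape)
            if config.correlation_length > 0:
                z = ndimage.gaussian_filter(z, sigma=config.correlation_length, mode="wrap")
            z = z + rng.uniform(0, 1e-9, size=shape)
            order = np.argsort(z.ravel())[::-1]
            n = shape[0] * shape[1]
            for pid in PROCESS_ORDER:
                k = int(round(config.process_fractions[pid] * n))
                m = np.zeros(n, dtype=bool)
                m[order[:k]] = True
                masks[pid] = m.reshape(shape) & ~unavailable[pid]
        else:
            for pid in PROCESS_ORDER:
                m = _fraction_mask(
                    shape, config.process_fractions[pid], config.correlation_length, rng
                )
                m &= ~unavailable[pid]
                masks[pid] = m
        return masks, unavailable

    # exact class shares over agricultural pixels (largest-remainder counts)
    ag = land.stratum_mask("agricultural")
    ag_idx = np.flatnonzero(ag.ravel())
    n_ag = ag_idx.size
    props = config.planted_class_proportions
    targets = {k: props.get(k, 0.0) * n_ag for k in range(6)}
    counts = {k: int(np.floor(v)) for k, v in targets.items()}
    short = n_ag - sum(counts.values())
    for k in sorted(range(6), key=lambda k: targets[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    per_pixel_class = np.concatenate(
        [np.full(counts[k], k, dtype=np.int8) for k in range(6)]
    )
    rng.shuffle(per_pixel_class)

    flat_masks = {pid: np.zeros(shape[0] * shape[1], dtype=bool) for pid in PROCESS_ORDER}
    unavail_flat = {pid: unavailable[pid].ravel() for pid in PROCESS_ORDER}
    order = np.arange(len(PROCESS_ORDER))
    for pix, cls in zip(ag_idx, per_pixel_class):
        k = int(cls)
        if k == 0:
            continue
        avail = [i for i in order if not unavail_flat[PROCESS_ORDER[i]][pix]]
        if k > len(avail):
            raise ValueError(
                "planted class proportions infeasible: a pixel needs more "
                "critical processes than it has available layers"
            )
        chosen = rng.permutation(avail)[:k]
        for i in chosen:
            flat_masks[PROCESS_ORDER[i]][pix] = True
    masks = {pid: flat_masks[pid].reshape(shape) for pid in PROCESS_ORDER}
    return masks, unavailable


def _split(rng, mask, low_range, high_range):
    """Values from high_range where mask, from low_range elsewhere."""
    lo = rng.uniform(*low_range, size=mask.shape)
    hi = rng.uniform(*high_range, size=mask.shape)
    return np.where(mask, hi, lo)


def _apply_nodata(values, unavailable, config, nodata=FLOAT_NODATA):
    out = np.where(unavailable, nodata, values)
    return config.grid(out, nodata=nodata)


def gen_process_inputs(config: ScenarioConfig):
    """Raw inputs for all twelve processes plus the ground truth.

    Values are drawn from the critical side of each cut-off for planted
    pixels and the non-critical side otherwise, with a margin of at
    least ``margin_fraction`` of the cut-off magnitude, so that applying
    the rule registry recovers the planted masks exactly.

    Returns ``(land, zones, inputs, truth)`` where ``inputs`` maps
    process id to the raw-input dict the classification stage expects
    (trend processes carry their annual stacks under ``"stack"``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    land, zones = gen_landuse_and_zones(config)
    masks, unavailable = _planted_masks(config, land, zones, rng)
    m = config.margin

    inputs: dict[str, dict] = {}
    # --- simple thresholds ---------------------------------------------------
    for pid, t in (("WaE", 2.0), ("WiE", 2.0), ("SS", 50.0)):
        vals = _split(
            rng, masks[pid],
            (0.0, t * (1 - m(pid))),
            (t * (1 + m(pid)), t * (1 + m(pid)) * 3),
        )
        inputs[pid] = {"value": _apply_nodata(vals, unavailable[pid], config)}
    # acidification: critical is LOW pH
    t = 5.5
    vals = _split(
        rng, masks["SA"], (t * (1 + m("SA")), 8.5), (3.5, t * (1 - m("SA")))
    )
    inputs["SA"] = {"value": _apply_nodata(vals, unavailable["SA"], config)}

    # --- class memberships ---------------------------------------------------
    sc = _split(rng, masks["SC"], (0.6, 2.5 * (1 - m("SC_code"))),
                (2.5 * (1 + m("SC_code")), 4.4))
    inputs["SC"] = {"score": _apply_nodata(sc, unavailable["SC"], config)}
    rs = _split(rng, masks["SPP"], (0.2, 3.0 * (1 - m("SPP_rs"))),
                (3.0 * (1 + m("SPP_rs")), 5.0))
    inputs["SPP"] = {"score": _apply_nodata(rs, unavailable["SPP"], config)}

    # --- nutrient composite --------------------------------------------------
    shape = config.shape
    mn = m("SNI_n_surplus")
    n_surplus = rng.uniform(0.0, 50 * (1 - mn), size=shape)
    nue = rng.uniform(0.1, 0.9 * (1 - m("SNI_nue")), size=shape)
    p_avail = rng.uniform(25 * (1 + m("SNI_p_lo")), 50 * (1 - m("SNI_p_hi")), size=shape)
    p_budget = rng.choice([-1.0, 1.0], size=shape) * rng.uniform(0.5, 10.0, size=shape)
    variant = rng.integers(0, 4, size=shape)
    sel = masks["SNI"]
    n_surplus = np.where(sel & (variant == 0),
                         rng.uniform(50 * (1 + mn), 150, size=shape), n_surplus)
    nue = np.where(sel & (variant == 1),
                   rng.uniform(0.9 * (1 + m("SNI_nue")), 1.3, size=shape), nue)
    p_hi = sel & (variant == 2)
    p_avail = np.where(p_hi, rng.uniform(50 * (1 + m("SNI_p_hi")), 120, size=shape), p_avail)
    p_budget = np.where(p_hi, rng.uniform(0.5, 10.0, size=shape), p_budget)
    p_lo = sel & (variant == 3)
    p_avail = np.where(p_lo, rng.uniform(1.0, 25 * (1 - m("SNI_p_lo")), size=shape), p_avail)
    p_budget = np.where(p_lo, -rng.uniform(0.5, 10.0, size=shape), p_budget)
    ua = unavailable["SNI"]
    inputs["SNI"] = {
        "n_surplus": _apply_nodata(n_surplus, ua, config),
        "nue": _apply_nodata(nue, ua, config),
        "p_avail": _apply_nodata(p_avail, ua, config),
        "p_budget": _apply_nodata(p_budget, ua, config),
    }

    # --- heavy-metal union ---------------------------------------------------
    metal_names = list(METAL_THRESHOLDS)
    exceed_pick = rng.integers(0, len(metal_names), size=shape)
    metals = {}
    for i, name in enumerate(metal_names):
        t = METAL_THRESHOLDS[name]
        mm = m(f"SPHM_{name}")
        vals = rng.uniform(t * 0.05, t * (1 - mm), size=shape)
        hot = masks["SPHM"] & (exceed_pick == i)
        vals = np.where(hot, rng.uniform(t * (1 + mm), t * 3, size=shape), vals)
        metals[name] = _apply_nodata(vals, unavailable["SPHM"], config)
    inputs["SPHM"] = {"metals": metals}

    # --- aridity -------------------------------------------------------------
    ma = m("AI")
    ai = rng.uniform(0.65 * (1 + ma), 1.4, size=shape)
    hyper = (~masks["A"]) & (rng.uniform(size=shape) < 0.05)
    ai = np.where(hyper, rng.uniform(0.005, 0.03 * (1 - ma), size=shape), ai)
    ai = np.where(
        masks["A"],
        rng.uniform(max(0.03 * (1 + ma), 0.035), 0.65 * (1 - ma), size=shape),
        ai,
    )
    pet = rng.uniform(800.0, 1200.0, size=shape)
    inputs["A"] = {
        "p": _apply_nodata(ai * pet, unavailable["A"], config),
        "pet": _apply_nodata(pet, unavailable["A"], config),
    }

    # --- trend processes -----------------------------------------------------
    for pid in ("SOCL", "VD", "GD"):
        _, slope_c, level = _TREND_DEFAULTS[pid]
        n_years = config.n_years[pid]
        slopes = np.where(masks[pid], slope_c, 0.0)
        base = np.full(shape, level)
        stack = []
        for ti in range(n_years):
            eps = (
                rng.normal(0.0, config.trend_noise_sd, size=shape)
                if config.trend_noise_sd > 0
                else 0.0
            )
            stack.append(
                _apply_nodata(base + slopes * ti + eps, unavailable[pid], config)
            )
        inputs[pid] = {"stack": stack, "planted_slope": slope_c}

    # --- ground truth --------------------------------------------------------
    truth_masks = {}
    for pid in PROCESS_ORDER:
        arr = np.where(
            unavailable[pid], MASK_NODATA, masks[pid].astype(np.uint8)
        ).astype(np.uint8)
        truth_masks[pid] = config.grid(arr, nodata=MASK_NODATA)
    ag = land.stratum_mask("agricultural")
    counts = np.zeros(shape, dtype=np.int32)
    for pid in PROCESS_ORDER:
        counts += np.where(unavailable[pid], 0, masks[pid])
    lmi_vals = np.where(ag, counts, MASK_NODATA).astype(np.uint8)
    lmi = config.grid(lmi_vals, nodata=MASK_NODATA)
    classes = np.minimum(counts[ag], 5)
    hist = np.bincount(classes, minlength=6)
    proportions = {k: float(hist[k] / ag.sum()) for k in range(6)}
    truth = GroundTruth(masks=truth_masks, lmi=lmi, class_proportions=proportions)
    return land, zones, inputs, truth


def gen_boundary_inputs(config: ScenarioConfig):
    """Inputs with every scalar quantity exactly at its cut-off.

    Under the strict-inequality convention all twelve masks must come
    out Non-critical everywhere.  Trend processes supply slope/p grids
    directly (slope bit-for-bit at the cut-off, p significant), since a
    synthetic line at the cut-off would re-introduce floating-point
    noise through the pairwise-slope estimator.
    """
    shape = config.shape

    def const(v):
        return config.grid(np.full(shape, float(v)))

    inputs: dict[str, dict] = {
        "WaE": {"value": const(2.0)},
        "WiE": {"value": const(2.0)},
        "SS": {"value": const(50.0)},
        "SA": {"value": const(5.5)},
        "SC": {"score": const(2.5)},
        "SPP": {"score": const(3.0)},
        "SNI": {
            "n_surplus": const(50.0),
            "nue": const(0.9),
            "p_avail": const(50.0),
            "p_budget": const(1.0),
        },
        "SPHM": {"metals": {n: const(t) for n, t in METAL_THRESHOLDS.items()}},
        "A": {"p": const(650.0), "pet": const(1000.0)},
    }
    for pid, slope_t in (("SOCL", -0.1), ("VD", -0.001), ("GD", -0.001)):
        inputs[pid] = {"slope": const(slope_t), "p": const(0.05)}
    return inputs
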