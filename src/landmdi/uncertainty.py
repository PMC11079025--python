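"""Threshold-driven uncertainty of the multi-degradation index.

The raw inputs feeding every criticality rule are stacked into one
matrix (rows = pixels, one column per thresholded quantity).  Each of
n Monte-Carlo draws perturbs every scalar cut-off independently with
Normal(t0, |t0|/10), re-binarizes the matrix, and re-sums rows into LMI
classes.  A Random-Forest classifier trained on the perturbed labels
(original raw values as covariates) yields per-pixel class
probabilities, an out-of-bag error, and per-column sensitivities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .criticality import (
    HYPER_ARID_BOUND,
    METAL_THRESHOLDS,
    PROCESS_ORDER,
    registry_thresholds,
)
from .grid import MASK_NODATA, Grid

__all__ = [
    "MATRIX_COLUMNS",
    "THRESHOLD_NAMES",
    "InputMatrix",
    "UncertaintyMaps",
    "build_input_matrix",
    "sample_thresholds",
    "evaluate_matrix",
    "simulate_lmi_labels",
    "fit_rf_uncertainty",
    "class_area_error_ranges",
]

_METALS = list(METAL_THRESHOLDS)

#: matrix columns: every raw quantity feeding a rule (26 columns; the
#: available-P column serves both P cut-offs, the P budget has no
#: perturbable cut-off of its own)
MATRIX_COLUMNS = (
    ["WaE", "WiE", "SOCL_slope", "SOCL_p", "SS", "SA", "SC_score"]
    + ["SNI_n_surplus", "SNI_nue", "SNI_p_avail", "SNI_p_budget", "SPP_rs"]
    + [f"SPHM_{m}" for m in _METALS]
    + ["VD_slope", "VD_p", "GD_slope", "GD_p", "AI"]
)

THRESHOLD_NAMES = tuple(registry_thresholds())

#: which way each cut-off points: 'greater' flags high values, 'less' low
#: values, 'p' is the non-strict significance bound.  Moving a 'greater'
#: cut-off down (or a 'less'/'p' cut-off up) relaxes it toward criticality.
THRESHOLD_DIRECTIONS = {
    "WaE": "greater", "WiE": "greater", "SS": "greater", "SC_code": "greater",
    "SNI_n_surplus": "greater", "SNI_nue": "greater", "SNI_p_hi": "greater",
    "SPP_rs": "greater",
    **{f"SPHM_{m}": "greater" for m in _METALS},
    "SA": "less", "SNI_p_lo": "less", "AI": "less",
    "SOCL_slope": "less", "VD_slope": "less", "GD_slope": "less",
    "SOCL_p": "p", "VD_p": "p", "GD_p": "p",
}


@dataclass
class InputMatrix:
    """Stacked raw inputs at sampled pixels plus their baseline labels."""

    data: pd.DataFrame  # columns = MATRIX_COLUMNS
    baseline_class: np.ndarray  # int, 0..5
    rows: np.ndarray  # pixel row index into the template grid
    cols: np.ndarray
    template: Grid
    scale: float = 1.0  # stratum pixels per matrix row (subsampling factor)

    def __post_init__(self) -> None:
        missing = set(MATRIX_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"matrix missing columns: {sorted(missing)}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("matrix contains non-finite entries")


@dataclass
class UncertaintyMaps:
    probabilities: dict[int, Grid]  # class -> probability grid
    predicted: Grid
    oob_error: float
    importances: pd.Series
    oob_per_rep: list[float] = field(default_factory=list)


def build_input_matrix(
    raw: dict[str, Grid],
    stratum_mask: np.ndarray,
    max_rows: int | None = 100_000,
    seed: int | None = None,
) -> InputMatrix:
    """Assemble the per-pixel input matrix over one land stratum.

    ``raw`` maps every MATRIX_COLUMNS name to its grid (trend processes
    contribute their slope and p grids).  Rows with any nodata are
    dropped; if more rows remain than ``max_rows`` a seeded uniform
    subsample is taken and the area scale factor recorded.
    """
    template = raw[MATRIX_COLUMNS[0]]
    valid = np.asarray(stratum_mask, dtype=bool).copy()
    for name in MATRIX_COLUMNS:
        g = raw[name]
        if not g.same_geometry(template):
            raise ValueError(f"grid {name} does not share the template geometry")
        valid &= g.valid()
    r, c = np.nonzero(valid)
    n_total = r.size
    if n_total == 0:
        raise ValueError("no valid pixels in the stratum")
    if max_rows is not None and n_total > max_rows:
        rng = np.random.default_rng(seed)
        pick = rng.choice(n_total, size=max_rows, replace=False)
        pick.sort()
        r, c = r[pick], c[pick]
    data = pd.DataFrame(
        {name: raw[name].values[r, c].astype(float) for name in MATRIX_COLUMNS}
    )
    baseline = classify_rows(evaluate_matrix(data))
    return InputMatrix(
        data=data, baseline_class=baseline, rows=r, cols=c, template=template,
        scale=n_total / r.size,
    )


def sample_thresholds(
    baseline: dict[str, float] | None = None,
    n_sims: int = 20_000,
    sd_fraction: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw perturbed cut-offs: t' ~ Normal(t0, |t0| * sd_fraction).

    Independent across cut-offs and draws; columns ordered as
    THRESHOLD_NAMES.  ``sd_fraction=0`` reproduces the baseline exactly.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if sd_fraction < 0:
        raise ValueError("sd_fraction must be non-negative")
    baseline = dict(baseline or registry_thresholds())
    rng = np.random.default_rng(seed)
    t0 = np.array([baseline[name] for name in THRESHOLD_NAMES])
    draws = rng.normal(
        loc=t0, scale=np.abs(t0) * sd_fraction, size=(n_sims, t0.size)
    )
    return pd.DataFrame(draws, columns=list(THRESHOLD_NAMES))


def evaluate_matrix(data: pd.DataFrame, thresholds: dict[str, float] | None = None) -> np.ndarray:
    """Re-binarize every rule column-set under one threshold vector.

    Returns an (n_rows, 12) uint8 array in canonical process order.
    Scalar comparisons strict; p cut-offs non-strict; the P-budget sign
    conditions and the hyper-arid exclusion are structural, not
    perturbed.
    """
    t = registry_thresholds()
    if thresholds:
        t.update(thresholds)
    d = data
    crit = {
        "WaE": d["WaE"].to_numpy() > t["WaE"],
        "WiE": d["WiE"].to_numpy() > t["WiE"],
        "SOCL": (d["SOCL_slope"].to_numpy() < t["SOCL_slope"])
        & (d["SOCL_p"].to_numpy() <= t["SOCL_p"]),
        "SS": d["SS"].to_numpy() > t["SS"],
        "SA": d["SA"].to_numpy() < t["SA"],
        "SC": d["SC_score"].to_numpy() > t["SC_code"],
        "SNI": (d["SNI_n_surplus"].to_numpy() > t["SNI_n_surplus"])
        | (d["SNI_nue"].to_numpy() > t["SNI_nue"])
        | ((d["SNI_p_avail"].to_numpy() > t["SNI_p_hi"]) & (d["SNI_p_budget"].to_numpy() > 0))
        | ((d["SNI_p_avail"].to_numpy() < t["SNI_p_lo"]) & (d["SNI_p_budget"].to_numpy() < 0)),
        "SPP": d["SPP_rs"].to_numpy() > t["SPP_rs"],
        "SPHM": np.logical_or.reduce(
            [d[f"SPHM_{m}"].to_numpy() > t[f"SPHM_{m}"] for m in _METALS]
        ),
        "VD": (d["VD_slope"].to_numpy() < t["VD_slope"])
        & (d["VD_p"].to_numpy() <= t["VD_p"]),
        "GD": (d["GD_slope"].to_numpy() < t["GD_slope"])
        & (d["GD_p"].to_numpy() <= t["GD_p"]),
        "A": (d["AI"].to_numpy() < t["AI"]) & (d["AI"].to_numpy() >= HYPER_ARID_BOUND),
    }
    return np.stack([crit[pid] for pid in PROCESS_ORDER], axis=1).astype(np.uint8)


def classify_rows(binary: np.ndarray) -> np.ndarray:
    """Row sums binned into LMI classes (>=5 pooled)."""
    return np.minimum(binary.sum(axis=1), 5).astype(np.int8)


def simulate_lmi_labels(matrix: InputMatrix, samples: pd.DataFrame):
    """Recompute LMI class labels for every threshold draw.

    Returns ``(labels, freq)``: labels is (n_sims, n_rows) int8, freq is
    the (n_rows, 6) empirical class distribution over draws.
    """
    if list(samples.columns) != list(THRESHOLD_NAMES):
        raise ValueError("threshold sample columns do not match the registry")
    n_sims = len(samples)
    n_rows = len(matrix.data)
    labels = np.empty((n_sims, n_rows), dtype=np.int8)
    draws = samples.to_numpy()
    for s in range(n_sims):
        thr = dict(zip(THRESHOLD_NAMES, draws[s]))
        labels[s] = classify_rows(evaluate_matrix(matrix.data, thr))
    freq = np.stack([(labels == k).mean(axis=0) for k in range(6)], axis=1)
    return labels, freq


def _sample_labels_per_row(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One label per row, drawn independently from its simulated draws."""
    n_sims, n_rows = labels.shape
    pick = rng.integers(0, n_sims, size=n_rows)
    return labels[pick, np.arange(n_rows)]


def fit_rf_uncertainty(
    matrix: InputMatrix,
    labels: np.ndarray | None = None,
    n_trees: int = 1000,
    reps: int = 20,
    seed: int | None = None,
    target: str = "perturbed",
    n_jobs: int = 1,
) -> UncertaintyMaps:
    """Random-Forest class-probability model of threshold uncertainty.

    Covariates are the original raw input values; the target is, per
    repetition, a fresh draw of the perturbed labels (``target=
    'perturbed'``) or the fixed baseline classes (``target='baseline'``).
    Probabilities, impurity importances and the out-of-bag error are
    averaged over repetitions.
    """
    if target not in ("perturbed", "baseline"):
        raise ValueError("target must be 'perturbed' or 'baseline'")
    if target == "perturbed" and labels is None:
        raise ValueError("perturbed target requires simulated labels")
    rng = np.random.default_rng(seed)
    x = matrix.data.to_numpy()
    n_rows = x.shape[0]
    proba = np.zeros((n_rows, 6))
    importances = np.zeros(len(MATRIX_COLUMNS))
    oob_per_rep = []
    for rep in range(reps):
        if target == "perturbed":
            y = _sample_labels_per_row(labels, rng)
        else:
            y = matrix.baseline_class
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            oob_score=True,
            n_jobs=n_jobs,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        if np.unique(y).size < 2:
            warnings.warn("single-class labels: probabilities are trivially 1, OOB 0")
            proba[:, int(y[0])] += 1.0
            oob_per_rep.append(0.0)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse classes may miss some OOB rows
            rf.fit(x, y)
        p = rf.predict_proba(x)
        for i, cls in enumerate(rf.classes_):
            proba[:, int(cls)] += p[:, i]
        oob_per_rep.append(1.0 - float(rf.oob_score_))
        importances += rf.feature_importances_
    proba /= reps
    importances /= reps
    predicted = proba.argmax(axis=1).astype(np.uint8)

    template = matrix.template
    tr, crs = template.transform, template.crs_id
    prob_grids = {}
    for k in range(6):
        arr = np.full(template.shape, np.nan)
        arr[matrix.rows, matrix.cols] = proba[:, k]
        prob_grids[k] = Grid(arr, tr, crs, nodata=float(np.nan))
    pred = np.full(template.shape, MASK_NODATA, dtype=np.uint8)
    pred[matrix.rows, matrix.cols] = predicted
    return UncertaintyMaps(
        probabilities=prob_grids,
        predicted=Grid(pred, tr, crs, nodata=MASK_NODATA),
        oob_error=float(np.mean(oob_per_rep)),
        importances=pd.Series(importances, index=list(MATRIX_COLUMNS)),
        oob_per_rep=oob_per_rep,
    )


def class_area_error_ranges(
    matrix: InputMatrix,
    labels: np.ndarray,
    maps: UncertaintyMaps | None = None,
    cell_area_km2: float = 0.25,
) -> pd.DataFrame:
    """Per-class area intervals under threshold perturbation.

    ``area_min``/``area_max`` span the per-draw class areas across all
    Monte-Carlo draws; ``area_expected`` sums the RF class probabilities
    when maps are supplied (else the empirical label frequencies).
    Areas are scaled by the matrix subsampling factor.
    """
    scale = matrix.scale * cell_area_km2
    n_sims = labels.shape[0]
    per_draw = np.stack(
        [(labels == k).sum(axis=1) * scale for k in range(6)], axis=1
    )  # (n_sims, 6)
    baseline = np.array(
        [(matrix.baseline_class == k).sum() * scale for k in range(6)]
    )
    if maps is not None:
        expected = np.array(
            [
                maps.probabilities[k].values[matrix.rows, matrix.cols].sum() * scale
                for k in range(6)
            ]
        )
    else:
        expected = per_draw.mean(axis=0)
    return pd.DataFrame(
        {
            "lmi_class": np.arange(6),
            "area_baseline_km2": baseline,
            "area_expected_km2": expected,
            "area_min_km2": per_draw.min(axis=0),
            "area_max_km2": per_draw.max(axis=0),
            "n_sims": n_sims,
            "range_method": "min-max across threshold draws",
        }
    )
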