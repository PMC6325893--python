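"""Synthetic Coulter-style cell-size cohorts with known ground truth.

The generator emulates the data a channelyzer screen produces: per-strain
histograms of cell volumes (fL) on a linear channel grid, built by binning
simulated single-cell values.  Four mutant classes reproduce the departure
patterns seen in deletion-collection screens:

* ``wildtype_gamma`` — gamma(shape, rate) sizes, the wild-type pattern;
* ``shifted_gamma``  — same shape, rate divided by a shift factor (larger
  mean, unchanged distributional form);
* ``left_skew``      — negatively skewed sizes with a large mode and a
  heavy left shoulder, built by reflecting a gamma about a large anchor
  (``size = anchor - gamma``; truncated at the grid minimum so support
  stays positive);
* ``multimodal``     — a well-separated gamma mixture;
* ``debris``         — a wild-type histogram plus a small-particle spike
  (default 3% of mass) in the smallest bins, mimicking culture debris.

Defaults: wild-type shape 3.8277 and rate 0.078949 /fL (the averaged
haploid reference), 20,000 cells per histogram, 256 linear channels over
5-250 fL.  Per-strain seeds derive from the master seed and the strain id,
so a cohort is reproducible strain-by-strain regardless of order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .histogram_io import SizeHistogram, ValidationError, derive_strain_seed

DEFAULT_SHAPE = 3.8277
DEFAULT_RATE = 0.078949
DEFAULT_CELLS = 20_000

MUTANT_CLASSES = ("wildtype_gamma", "shifted_gamma", "left_skew", "multimodal", "debris")

DEFAULT_PARAMS: dict[str, dict] = {
    "wildtype_gamma": {"shape": DEFAULT_SHAPE, "rate": DEFAULT_RATE},
    "shifted_gamma": {"shape": DEFAULT_SHAPE, "rate": DEFAULT_RATE, "shift": 1.6},
    "left_skew": {"anchor": 200.0, "shape": 4.0, "rate": 0.05},
    "multimodal": {
        "weights": (0.5, 0.5),
        # means ~60 and ~138 fL; both components fit inside the default grid
        "components": ((6.6, 0.11), (20.0, 0.145)),
    },
    "debris": {"shape": DEFAULT_SHAPE, "rate": DEFAULT_RATE, "debris_mass": 0.03, "debris_bins": 3},
}


def default_bin_grid(min_fl: float = 5.0, max_fl: float = 250.0, n_bins: int = 256) -> np.ndarray:
    """Linear channel centers approximating a channelyzer window for yeast."""
    if not (0 < min_fl < max_fl) or n_bins < 2:
        raise ValidationError("bin grid must be increasing with at least two bins")
    return np.linspace(min_fl, max_fl, n_bins)


def _edges_from_centers(centers: np.ndarray) -> np.ndarray:
    mids = (centers[:-1] + centers[1:]) / 2.0
    return np.concatenate([[centers[0] - (mids[0] - centers[0])], mids,
                           [centers[-1] + (centers[-1] - mids[-1])]])


def _bin_values(values: np.ndarray, bins: np.ndarray, strain_id: str) -> SizeHistogram:
    """Bin simulated sizes onto the grid; out-of-grid draws accumulate in the
    edge bins (count surfaced as a warning when substantial)."""
    edges = _edges_from_centers(bins)
    n_out = int(np.sum(values < edges[0]) + np.sum(values > edges[-1]))
    if n_out > 0.01 * values.size:
        warnings.warn(
            f"{strain_id}: {n_out} of {values.size} simulated cells fell outside "
            f"the bin grid and were accumulated in the edge bins",
            stacklevel=3,
        )
    clipped = np.clip(values, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, edges)
    return SizeHistogram(strain_id=strain_id, bin_values=bins, frequencies=counts / counts.sum())


def simulate_wildtype(
    shape: float = DEFAULT_SHAPE,
    rate: float = DEFAULT_RATE,
    cells: int = DEFAULT_CELLS,
    bins: np.ndarray | None = None,
    seed: int = 0,
    strain_id: str = "WT",
) -> SizeHistogram:
    """Gamma-distributed wild-type sizes binned onto the channel grid."""
    if shape <= 0 or rate <= 0:
        raise ValidationError("shape and rate must be > 0")
    bins = default_bin_grid() if bins is None else np.asarray(bins, float)
    lo, hi = stats.gamma.ppf([0.005, 0.995], shape, scale=1.0 / rate)
    edges = _edges_from_centers(bins)
    if lo < edges[0] or hi > edges[-1]:
        warnings.warn(
            f"{strain_id}: bin grid [{edges[0]:.1f}, {edges[-1]:.1f}] fL does not cover "
            f"the central 99% of gamma({shape:g}, {rate:g}) = [{lo:.1f}, {hi:.1f}] fL",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    values = rng.gamma(shape, 1.0 / rate, cells)
    return _bin_values(values, bins, strain_id)


def _draw_mutant(class_name: str, params: dict, cells: int, rng: np.random.Generator) -> np.ndarray:
    if class_name in ("wildtype_gamma", "debris"):
        return rng.gamma(params["shape"], 1.0 / params["rate"], cells)
    if class_name == "shifted_gamma":
        shift = params.get("shift", 1.0)
        if shift <= 0:
            raise ValidationError("shift factor must be > 0")
        # scale multiplied by shift: identical draws to wildtype at shift=1
        return rng.gamma(params["shape"], shift / params["rate"], cells)
    if class_name == "left_skew":
        anchor = params["anchor"]
        values = anchor - rng.gamma(params["shape"], 1.0 / params["rate"], cells)
        return np.maximum(values, params.get("floor", 5.0))
    if class_name == "multimodal":
        weights = np.asarray(params["weights"], float)
        comps = params["components"]
        if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
            raise ValidationError("mixture weights must be nonnegative and sum to 1")
        if len(comps) != weights.size:
            raise ValidationError("one (shape, rate) pair needed per mixture weight")
        which = rng.choice(weights.size, size=cells, p=weights)
        values = np.empty(cells)
        for ci, (a, r) in enumerate(comps):
            mask = which == ci
            values[mask] = rng.gamma(a, 1.0 / r, int(mask.sum()))
        return values
    raise ValidationError(f"unknown mutant class {class_name!r}")


def simulate_mutant(
    class_name: str,
    params: dict | None = None,
    cells: int = DEFAULT_CELLS,
    bins: np.ndarray | None = None,
    seed: int = 0,
    strain_id: str | None = None,
) -> SizeHistogram:
    """One histogram of the requested mutant class (defaults per class)."""
    if class_name not in MUTANT_CLASSES:
        raise ValidationError(f"unknown mutant class {class_name!r}; choose from {MUTANT_CLASSES}")
    merged = dict(DEFAULT_PARAMS[class_name])
    merged.update(params or {})
    bins = default_bin_grid() if bins is None else np.asarray(bins, float)
    rng = np.random.default_rng(seed)
    values = _draw_mutant(class_name, merged, cells, rng)
    hist = _bin_values(values, bins, strain_id or class_name)
    if class_name == "debris":
        mass = merged["debris_mass"]
        k = int(merged["debris_bins"])
        freq = hist.frequencies * (1.0 - mass)
        freq[:k] += mass / k
        hist = SizeHistogram(hist.strain_id, hist.bin_values, freq,
                             replicate=hist.replicate, condition=hist.condition)
    return hist


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort recipe: how many strains of each class, with which parameters.

    ``classes`` maps class name -> (n_strains, params overrides).
    """

    classes: dict[str, tuple[int, dict]] = field(
        default_factory=lambda: {"wildtype_gamma": (90, {}), "multimodal": (10, {})}
    )
    cells_per_strain: int = DEFAULT_CELLS
    bin_min_fl: float = 5.0
    bin_max_fl: float = 250.0
    n_bins: int = 256
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes or sum(n for n, _ in self.classes.values()) < 1:
            raise ValidationError("spec must request at least one strain")
        for name in self.classes:
            if name not in MUTANT_CLASSES:
                raise ValidationError(f"unknown mutant class {name!r}")

    def bin_grid(self) -> np.ndarray:
        return default_bin_grid(self.bin_min_fl, self.bin_max_fl, self.n_bins)


def simulate_cohort(spec: SyntheticSpec) -> tuple[list[SizeHistogram], pd.DataFrame]:
    """Generate a cohort plus its ground-truth label table.

    Strain ids are ``<CLASS>_<index>``; each strain's seed derives from the
    spec's master seed and the strain id.  The label table records class and
    parameters per strain, sufficient to score spike-in recovery.
    """
    bins = spec.bin_grid()
    hists: list[SizeHistogram] = []
    labels: list[dict] = []
    for class_name, (n_strains, overrides) in spec.classes.items():
        params = dict(DEFAULT_PARAMS[class_name])
        params.update(overrides)
        for i in range(n_strains):
            # no separator before the index: a trailing "_<digits>" would look
            # like a replicate suffix to the screen's collapsing rule
            sid = f"{class_name.upper()}{i:03d}"
            seed = derive_strain_seed(spec.master_seed, sid)
            hists.append(
                simulate_mutant(class_name, params, spec.cells_per_strain, bins, seed, strain_id=sid)
            )
            labels.append(
                {
                    "strain": sid,
                    "class": class_name,
                    "is_mutant": class_name != "wildtype_gamma",
                    "seed": seed,
                    "params": json.dumps(params, sort_keys=True, default=list),
                }
            )
    return hists, pd.DataFrame(labels)
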