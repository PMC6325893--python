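"""Cohort screening: per-strain resampling, fitting, testing and ranking.

For every strain histogram in a cohort the pipeline resamples n cells
(default 1000), screens normality (Shapiro-Wilk, raw and log scale), fits
the candidate right-skewed families, computes EDF goodness-of-fit
statistics per family, calibrates a composite-gamma p-value by parametric
bootstrap, evaluates the Anderson-Darling statistic against the fixed
wild-type reference gamma null, and records the weighted median size.

Strains are then ranked by descending fixed-null A² (rank 1 = worst fit to
the wild-type gamma pattern), replicate measurements of the same strain
collapse to unique strain ids after selection, and strains are annotated
as ``lge``/``whi`` when their median size falls in the top/bottom tail
(default 5%) of the cohort.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import distfit, gof
from .histogram_io import (
    SCREEN_COLUMNS,
    CellSample,
    SizeHistogram,
    ValidationError,
    derive_strain_seed,
    resample_cells,
    weighted_median,
)

DEFAULT_REPLICATE_PATTERN = r"[._-]\d+$"


@dataclass(frozen=True)
class ReferenceNull:
    """Fixed gamma null: arithmetic mean of wild-type fitted parameters."""

    shape: float
    rate: float
    source_strain_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValidationError("reference null shape and rate must be > 0")


@dataclass
class ScreenRow:
    """Per-strain screening record (one row of the output table)."""

    strain_id: str
    condition: str | None = None
    n: int | None = None
    seed: int | None = None
    sw_p: float = math.nan
    sw_log_p: float = math.nan
    gamma_shape: float = math.nan
    gamma_rate: float = math.nan
    lognormal_ad: float = math.nan
    weibull_ad: float = math.nan
    gamma_ad: float = math.nan
    gamma_ks: float = math.nan
    gamma_cvm: float = math.nan
    gamma_ad_p: float = math.nan
    fixed_null_ad: float = math.nan
    fixed_null_p: float = math.nan
    bic_gamma: float = math.nan
    bic_gengamma: float = math.nan
    median_fl: float = math.nan
    size_class: str = "normal"
    deviant_rank: int | None = None
    status: str = "ok"


@dataclass(frozen=True)
class ScreenConfig:
    """Screening configuration; the defaults are the standard settings of
    the screen (n=1000 resampled cells, B=999 bootstrap replicates,
    alpha=0.01, 5% size tails, top 50 deviants)."""

    n: int = 1000
    master_seed: int = 42
    bootstrap_B: int | None = 999
    jitter: bool = False
    resample_mode: str = "multinomial"
    min_size: float | None = None
    fit_gengamma: bool = True
    families: tuple[str, ...] = ("gamma", "lognormal", "weibull")
    reference: ReferenceNull | None = None
    wild_type_ids: tuple[str, ...] = ()
    alpha: float = 0.01
    top_k: int = 50
    tail_q: float = 0.05
    replicate_pattern: str = DEFAULT_REPLICATE_PATTERN


def reference_null(wt_fits: Sequence[distfit.FitResult]) -> ReferenceNull:
    """Average wild-type gamma fits into a fixed reference null."""
    if not wt_fits:
        raise ValidationError("need at least one wild-type fit")
    families = {f.family for f in wt_fits}
    if families != {"gamma"}:
        raise ValidationError(f"reference null requires gamma fits only, got {sorted(families)}")
    if not all(f.converged for f in wt_fits):
        raise ValidationError("all wild-type fits must have converged")
    return ReferenceNull(
        shape=float(np.mean([f.params["shape"] for f in wt_fits])),
        rate=float(np.mean([f.params["rate"] for f in wt_fits])),
        source_strain_ids=tuple(str(f.params.get("strain_id", "")) for f in wt_fits),
    )


def _build_reference(cohort: Sequence[SizeHistogram], config: ScreenConfig) -> ReferenceNull:
    if config.reference is not None:
        return config.reference
    if not config.wild_type_ids:
        raise ValidationError(
            "a fixed-null screen needs either an explicit reference (shape, rate) "
            "or wild_type_ids naming the cohort's wild-type strains"
        )
    by_id = {h.strain_id: h for h in cohort}
    missing = [s for s in config.wild_type_ids if s not in by_id]
    if missing:
        raise ValidationError(f"wild-type ids not present in cohort: {missing}")
    fits = []
    for sid in config.wild_type_ids:
        seed = derive_strain_seed(config.master_seed, sid)
        sample = resample_cells(by_id[sid], config.n, seed, jitter=config.jitter,
                                mode=config.resample_mode, min_size=config.min_size)
        fits.append(distfit.fit_gamma(sample))
    ref = reference_null(fits)
    return ReferenceNull(ref.shape, ref.rate, tuple(config.wild_type_ids))


def _screen_one(hist: SizeHistogram, config: ScreenConfig, ref: ReferenceNull) -> ScreenRow:
    seed = derive_strain_seed(config.master_seed, hist.strain_id)
    row = ScreenRow(strain_id=hist.strain_id, condition=hist.condition, n=config.n, seed=seed)
    try:
        sample = resample_cells(hist, config.n, seed, jitter=config.jitter,
                                mode=config.resample_mode, min_size=config.min_size)
        row.median_fl = weighted_median(hist)
        row.sw_p = gof.shapiro_wilk(sample).p_value
        row.sw_log_p = gof.lognormality_check(sample).p_value

        sel = distfit.model_select(sample, families=config.families)
        if "gamma" in sel.fits:
            gfit = sel.fits["gamma"]
            row.gamma_shape = gfit.params["shape"]
            row.gamma_rate = gfit.params["rate"]
            row.bic_gamma = gfit.bic
            row.gamma_ad, row.gamma_ks, row.gamma_cvm = sel.edf["gamma"]
        if "lognormal" in sel.edf:
            row.lognormal_ad = sel.edf["lognormal"][0]
        if "weibull" in sel.edf:
            row.weibull_ad = sel.edf["weibull"][0]

        if config.bootstrap_B is not None:
            comp = gof.ad_test_fitted_gamma(sample, B=config.bootstrap_B, seed=seed)
            row.gamma_ad_p = comp.p_value
        fixed = gof.ad_test_fixed(sample, ref.shape, ref.rate)
        row.fixed_null_ad = fixed.statistic
        row.fixed_null_p = fixed.p_value
        if config.fit_gengamma:
            row.bic_gengamma = distfit.fit_gengamma(sample).bic
    except (distfit.FitError, ValidationError) as exc:
        row.status = f"failed: {exc}"
    return row


def screen_cohort(cohort: Sequence[SizeHistogram], config: ScreenConfig) -> list[ScreenRow]:
    """Run the full per-strain pipeline over a cohort.

    Rows come back in input order with deviant ranks and size classes
    attached; per-strain failures are recorded in the row's ``status`` and
    never abort the cohort.  Results are fully reproducible for a fixed
    master seed: each strain's seed derives from (master seed, strain id),
    so cohort order does not matter.
    """
    if not cohort:
        raise ValidationError("cohort must be nonempty")
    ref = _build_reference(cohort, config)
    rows = [_screen_one(h, config, ref) for h in cohort]
    _attach_ranks(rows)
    classify_size(rows, config.tail_q, allow_missing=True)
    return rows


def _rank_key(row: ScreenRow):
    stat = row.fixed_null_ad
    failed = row.status != "ok" or not np.isfinite(stat)
    # worst fit first; failed strains rank last
    return (failed, -(stat if np.isfinite(stat) else -math.inf), row.strain_id)


def _attach_ranks(rows: list[ScreenRow]) -> None:
    for rank, row in enumerate(sorted(rows, key=_rank_key), start=1):
        row.deviant_rank = rank


def base_strain_id(strain_id: str, replicate_pattern: str = DEFAULT_REPLICATE_PATTERN) -> str:
    """Strip a replicate suffix appended to a systematic name."""
    return re.sub(replicate_pattern, "", strain_id)


@dataclass(frozen=True)
class DeviantSet:
    """Top-k worst-fitting samples and the unique strains behind them."""

    rows: tuple[ScreenRow, ...]
    strain_ids: tuple[str, ...]


def rank_deviants(
    rows: Sequence[ScreenRow],
    k: int,
    replicate_pattern: str = DEFAULT_REPLICATE_PATTERN,
) -> DeviantSet:
    """Top-k samples by descending fixed-null A² (worst fit first).

    Replicate samples of the same strain collapse to unique base strain ids
    after selection, so k samples may map to fewer strains.
    """
    if k > len(rows):
        raise ValidationError(f"k={k} exceeds the {len(rows)} available rows")
    ordered = sorted(rows, key=_rank_key)[:k]
    seen: dict[str, None] = {}
    for row in ordered:
        seen.setdefault(base_strain_id(row.strain_id, replicate_pattern), None)
    return DeviantSet(rows=tuple(ordered), strain_ids=tuple(seen))


def classify_size(rows: Sequence[ScreenRow], q: float, allow_missing: bool = False) -> None:
    """Annotate size classes in place: top-q medians -> ``lge``, bottom-q ->
    ``whi``, remainder ``normal``.

    Exactly ``ceil(q*N)`` strains land in each tail (ordinal rank, ties
    broken by strain id).
    """
    if not 0 < q < 0.5:
        raise ValidationError("tail fraction q must be in (0, 0.5)")
    usable = [r for r in rows if np.isfinite(r.median_fl)]
    if len(usable) < len(rows) and not allow_missing:
        raise ValidationError("median sizes missing for some strains")
    if not usable:
        return
    m = math.ceil(q * len(usable))
    by_large = sorted(usable, key=lambda r: (-r.median_fl, r.strain_id))
    by_small = sorted(usable, key=lambda r: (r.median_fl, r.strain_id))
    lge = {id(r) for r in by_large[:m]}
    whi = set()
    for r in by_small:  # first m strains not already claimed by the large tail
        if id(r) not in lge:
            whi.add(id(r))
            if len(whi) == m:
                break
    for r in usable:
        r.size_class = "lge" if id(r) in lge else ("whi" if id(r) in whi else "normal")


def rows_to_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Screening rows as a DataFrame in the documented column order."""
    records = []
    for r in rows:
        records.append(
            {
                "strain": r.strain_id,
                "condition": r.condition,
                "n": r.n,
                "seed": r.seed,
                "sw_p": r.sw_p,
                "sw_log_p": r.sw_log_p,
                "gamma_shape": r.gamma_shape,
                "gamma_rate": r.gamma_rate,
                "lognormal_ad": r.lognormal_ad,
                "weibull_ad": r.weibull_ad,
                "gamma_ad": r.gamma_ad,
                "gamma_ks": r.gamma_ks,
                "gamma_cvm": r.gamma_cvm,
                "gamma_ad_p": r.gamma_ad_p,
                "fixed_null_ad": r.fixed_null_ad,
                "fixed_null_p": r.fixed_null_p,
                "bic_gamma": r.bic_gamma,
                "bic_gengamma": r.bic_gengamma,
                "median_fl": r.median_fl,
                "size_class": r.size_class,
                "deviant_rank": r.deviant_rank,
                "status": r.status,
            }
        )
    return pd.DataFrame.from_records(records, columns=list(SCREEN_COLUMNS))
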