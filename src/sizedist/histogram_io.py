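"""Read, validate, normalize and resample binned cell-size frequency data.

Coulter-type channelyzers report single-cell volumes (femtoliters, fL) as
counts per discrete size channel.  Genome-wide size screens distribute these
measurements as binned frequency tables: one column of channel centers plus
one relative-frequency column per strain.  This module holds the two
containers the rest of the pipeline operates on (:class:`SizeHistogram`,
:class:`CellSample`), readers/writers for the wide and long table layouts,
and the frequency-to-cells resampling step that turns a histogram back into
per-cell size values suitable for likelihood fitting.

Bin semantics: tables list a single size value per channel; these are
treated as bin *centers*, with bin edges inferred from consecutive
midpoints (edge bins reuse the width of their nearest neighbour), matching
how channelyzers export channel centers.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A table cell could not be interpreted as a number."""


class ValidationError(ValueError):
    """Input data violate a container invariant."""


#: Fixed column order of the screening output table.
SCREEN_COLUMNS = (
    "strain",
    "condition",
    "n",
    "seed",
    "sw_p",
    "sw_log_p",
    "gamma_shape",
    "gamma_rate",
    "lognormal_ad",
    "weibull_ad",
    "gamma_ad",
    "gamma_ks",
    "gamma_cvm",
    "gamma_ad_p",
    "fixed_null_ad",
    "fixed_null_p",
    "bic_gamma",
    "bic_gengamma",
    "median_fl",
    "size_class",
    "deviant_rank",
    "status",
)


@dataclass(frozen=True)
class SizeHistogram:
    """A binned size-frequency distribution for one strain/replicate.

    Parameters
    ----------
    strain_id
        Strain label.  Replicate suffixes appended to systematic ORF names
        (e.g. ``YPR119W-2``) are preserved verbatim.
    bin_values
        Strictly increasing channel centers in fL, all positive.
    frequencies
        Nonnegative relative frequencies (or raw counts), one per bin, with
        at least two strictly positive entries.
    """

    strain_id: str
    bin_values: np.ndarray
    frequencies: np.ndarray
    replicate: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        bins = np.asarray(self.bin_values, dtype=float)
        freq = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "bin_values", bins)
        object.__setattr__(self, "frequencies", freq)
        if bins.ndim != 1 or freq.ndim != 1 or bins.size != freq.size:
            raise ValidationError(
                f"{self.strain_id}: bin_values and frequencies must be "
                f"1-D arrays of equal length"
            )
        if bins.size and (np.any(bins <= 0) or np.any(np.diff(bins) <= 0)):
            raise ValidationError(
                f"{self.strain_id}: bin values must be strictly increasing and > 0"
            )
        if np.any(freq < 0) or not np.all(np.isfinite(freq)):
            raise ValidationError(
                f"{self.strain_id}: frequencies must be finite and >= 0"
            )
        if np.count_nonzero(freq > 0) < 2:
            raise ValidationError(
                f"{self.strain_id}: need at least two bins with positive frequency"
            )

    @property
    def n_bins(self) -> int:
        return int(self.bin_values.size)

    @property
    def is_normalized(self) -> bool:
        return abs(float(self.frequencies.sum()) - 1.0) <= 1e-12

    def bin_edges(self) -> np.ndarray:
        """Bin edges inferred from consecutive midpoints.

        The first/last edge extends the nearest internal width outward, so
        every center sits strictly inside its bin.
        """
        c = self.bin_values
        if c.size < 2:
            raise ValidationError("bin widths undefined for a single bin")
        mids = (c[:-1] + c[1:]) / 2.0
        first = c[0] - (mids[0] - c[0])
        last = c[-1] + (c[-1] - mids[-1])
        return np.concatenate([[first], mids, [last]])


@dataclass(frozen=True)
class CellSample:
    """An ordered collection of per-cell size values in fL.

    ``seed`` records the RNG seed used for resampling; it is ``None`` for
    directly measured data.
    """

    values: np.ndarray
    seed: int | None = None
    strain_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise ValidationError("sample must be a nonempty 1-D array")
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValidationError("all cell size values must be finite and > 0")

    @property
    def n(self) -> int:
        return int(self.values.size)


def normalize(hist: SizeHistogram) -> SizeHistogram:
    """Rescale frequencies to sum to one; bins unchanged.  Idempotent."""
    total = float(hist.frequencies.sum())
    if total <= 0:
        raise ValidationError(f"{hist.strain_id}: cannot normalize all-zero frequencies")
    if abs(total - 1.0) <= 1e-12:
        return hist
    return replace(hist, frequencies=hist.frequencies / total)


def derive_strain_seed(master_seed: int, strain_id: str) -> int:
    """Deterministic per-strain seed from (master seed, strain id).

    Uses a CRC32 of the strain id mixed into a ``SeedSequence`` so cohort
    order does not affect per-strain results.
    """
    tag = zlib.crc32(strain_id.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0])


def resample_cells(
    hist: SizeHistogram,
    n: int,
    seed: int,
    jitter: bool = False,
    mode: Literal["multinomial", "round"] = "multinomial",
    min_size: float | None = None,
) -> CellSample:
    """Draw ``n`` per-cell size values from a histogram.

    Counts per bin come from a seeded multinomial over the normalized
    frequencies (default), or from deterministic rounding with a
    largest-remainder correction (``mode="round"``).  Each drawn value is
    the bin center; with ``jitter=True`` a uniform offset inside the bin
    replaces the center, removing the massive ties that center resampling
    produces.

    ``min_size`` optionally drops bins below a size cutoff before sampling
    (small-particle debris is *not* trimmed by default).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    hist = normalize(hist)
    bins = hist.bin_values
    probs = hist.frequencies
    if min_size is not None:
        keep = bins >= min_size
        if np.count_nonzero(probs[keep] > 0) < 1:
            raise ValidationError("min_size cutoff removes all frequency mass")
        probs = np.where(keep, probs, 0.0)
        probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    if mode == "multinomial":
        counts = rng.multinomial(n, probs)
    elif mode == "round":
        raw = probs * n
        counts = np.floor(raw).astype(int)
        short = n - counts.sum()
        if short > 0:  # largest-remainder correction
            order = np.argsort(-(raw - counts), kind="stable")
            counts[order[:short]] += 1
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")

    values = np.repeat(bins, counts).astype(float)
    if jitter:
        try:
            edges = hist.bin_edges()
        except ValidationError:
            warnings.warn(
                "bin width undefined; jitter disabled for this histogram",
                stacklevel=2,
            )
        else:
            lo = np.repeat(edges[:-1], counts)
            hi = np.repeat(edges[1:], counts)
            values = lo + rng.uniform(0.0, 1.0, values.size) * (hi - lo)
            values = np.maximum(values, np.finfo(float).tiny)
    rng.shuffle(values)
    return CellSample(values=values, seed=int(seed), strain_id=hist.strain_id)


def weighted_median(hist: SizeHistogram) -> float:
    """Smallest bin value at which the cumulative frequency crosses 0.5.

    A bin whose cumulative frequency equals 0.5 exactly does not yet carry
    the median: half the mass lies strictly below the next bin, so the
    median is the first bin with cumulative frequency above one half.
    """
    hist = normalize(hist)
    cum = np.cumsum(hist.frequencies)
    idx = int(np.searchsorted(cum, 0.5 + 1e-12, side="left"))
    return float(hist.bin_values[min(idx, hist.n_bins - 1)])


# ---------------------------------------------------------------------------
# table I/O


def _infer_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row {r + 2}, "
            f"column {df.columns[c]!r}"
        )
    if coerced.isna().to_numpy().any():
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise ParseError(f"{path}: missing value at row {r + 2}, column {df.columns[c]!r}")
    # numpy's string parser is correctly rounded (to_numeric's fast path is not),
    # which keeps the writer/reader round trip lossless
    return df.astype(float)


def read_frequency_table(
    path: str | Path,
    layout: Literal["wide", "long"] = "wide",
    sep: str | None = None,
) -> list[SizeHistogram]:
    """Read a cell-size frequency table into one histogram per strain.

    Wide layout: first column = size in fL, remaining columns = per-strain
    frequencies, header row = strain ids.  Long layout: three columns
    (strain, size_fl, frequency).
    """
    path = Path(path)
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected at least two columns")

    hists: list[SizeHistogram] = []
    if layout == "wide":
        num = _numeric(df, path)
        bins = num.iloc[:, 0].to_numpy(float)
        if np.unique(bins).size != bins.size:
            raise ValidationError(f"{path}: duplicate bin value in column {df.columns[0]!r}")
        order = np.argsort(bins)
        for col in df.columns[1:]:
            freq = num[col].to_numpy(float)[order]
            if not np.any(freq > 0):
                raise ValidationError(f"{path}: all-zero frequency column {col!r}")
            hists.append(SizeHistogram(strain_id=str(col), bin_values=bins[order], frequencies=freq))
    elif layout == "long":
        if df.shape[1] < 3:
            raise ParseError(f"{path}: long layout needs (strain, size_fl, frequency)")
        strain_col, size_col, freq_col = df.columns[:3]
        num = _numeric(df[[size_col, freq_col]], path)
        for strain, group in df.groupby(strain_col, sort=False):
            b = num.loc[group.index, size_col].to_numpy(float)
            f = num.loc[group.index, freq_col].to_numpy(float)
            if np.unique(b).size != b.size:
                raise ValidationError(f"{path}: duplicate bin value within strain {strain!r}")
            order = np.argsort(b)
            if not np.any(f > 0):
                raise ValidationError(f"{path}: all-zero frequency column {strain!r}")
            hists.append(SizeHistogram(strain_id=str(strain), bin_values=b[order], frequencies=f[order]))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return hists


def write_frequency_table(
    hists: Sequence[SizeHistogram],
    path: str | Path,
    layout: Literal["wide", "long"] = "wide",
    sep: str | None = None,
) -> None:
    """Write histograms in the wide or long input layout (lossless round trip)."""
    if not hists:
        raise ValidationError("no histograms to write")
    path = Path(path)
    sep = sep or _infer_sep(path)
    if layout == "wide":
        bins = hists[0].bin_values
        for h in hists:
            if h.n_bins != bins.size or not np.array_equal(h.bin_values, bins):
                raise ValidationError("wide layout requires a shared bin grid; use layout='long'")
        data = {"size_fl": bins}
        data.update({h.strain_id: h.frequencies for h in hists})
        pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format=lambda v: repr(float(v)))
    elif layout == "long":
        frames = [
            pd.DataFrame(
                {"strain": h.strain_id, "size_fl": h.bin_values, "frequency": h.frequencies}
            )
            for h in hists
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False, float_format=lambda v: repr(float(v)))
    else:
        raise ValueError(f"unknown layout {layout!r}")


def convert_spreadsheet(
    xlsx_path: str | Path,
    sheet: str | int,
    out_path: str | Path,
    sep: str = "\t",
) -> None:
    """Convert a spreadsheet sheet with the wide table shape to delimited text."""
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    df.to_csv(out_path, sep=sep, index=False)


def write_screen_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a screening table as TSV with the fixed ``SCREEN_COLUMNS`` order.

    Floats are written at full (shortest round-tripping) precision.
    """
    if len(rows) == 0:
        raise ValidationError("screen table must be nonempty")
    missing = [c for c in SCREEN_COLUMNS if c not in rows.columns]
    if missing:
        raise ValidationError(f"screen table missing columns: {missing}")
    rows.loc[:, list(SCREEN_COLUMNS)].to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_screen_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: the writer emits shortest round-tripping reprs
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
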