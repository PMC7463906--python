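"""FTIR spectra handling: quality control, rubberband baseline, normalization.

Whole-cell FTIR fingerprints arrive as a wide CSV (wavenumber axis in the
first column, one column per sample). Preprocessing mirrors the standard
transmission-mode workflow: a signal-to-noise quality test on the
2100-1900 cm^-1 window, rubberband (lower convex hull) baseline
correction anchored on 64 support points, and vector normalization of
the whole spectrum. Spectral windows W1-W4 carve the fingerprint into
the conventional macromolecular regions (fatty acids, amides, mixed,
carbohydrates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "SpectrumSet",
    "RegionMap",
    "DEFAULT_REGIONS",
    "read_spectra_csv",
    "write_spectra_csv",
    "quality_snr",
    "rubberband_baseline",
    "vector_normalize",
    "extract_region",
    "average_replicates",
    "mask_intervals",
    "preprocess",
    "SnrResult",
]

META_COLUMNS = ("sample_id", "strain", "condition", "replicate")


@dataclass(frozen=True)
class SpectrumSet:
    """Wavenumber axis + absorbance matrix + per-sample metadata.

    ``axis`` is strictly decreasing with a uniform step (instrument
    convention, e.g. 4000..400 cm^-1 at 4 cm^-1); ``absorbance`` is
    samples x wavelengths; ``meta`` has one row per sample with columns
    ``sample_id, strain, condition, replicate``.
    """

    axis: np.ndarray = field(repr=False)
    absorbance: np.ndarray = field(repr=False)
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "absorbance", ab)
        if axis.ndim != 1 or axis.size < 1:
            raise ValueError("axis must be a non-empty 1-D array")
        if axis.size >= 2:
            steps = np.diff(axis)
            if not np.all(steps < 0):
                raise ValueError("axis must be strictly decreasing")
            if np.ptp(steps) > 1e-9:
                raise ValueError("axis step is not uniform")
        if ab.ndim != 2 or ab.shape[1] != axis.size:
            raise ValueError(
                f"absorbance shape {ab.shape} does not match axis ({axis.size})"
            )
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance contains non-finite values")
        for col in META_COLUMNS[:3]:
            if col not in self.meta.columns:
                raise ValueError(f"metadata missing column {col!r}")
        ids = list(self.meta["sample_id"])
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if len(ids) != ab.shape[0]:
            raise ValueError("metadata rows do not match absorbance rows")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def step(self) -> float:
        if self.axis.size < 2:
            raise ValueError("step undefined for a single-point axis")
        return float(abs(self.axis[1] - self.axis[0]))

    def sample(self, sample_id: str) -> np.ndarray:
        idx = list(self.meta["sample_id"]).index(sample_id)
        return self.absorbance[idx]

    def subset(self, mask) -> "SpectrumSet":
        mask = np.asarray(mask)
        return SpectrumSet(
            self.axis, self.absorbance[mask], self.meta.loc[mask].reset_index(drop=True)
        )


class RegionMap(dict):
    """Named wavenumber windows ``name -> (upper, lower)``, half-open.

    A window ``(upper, lower)`` selects wavenumbers ``lower < w <= upper``
    (the upper bound included, lower excluded), so adjacent windows tile
    an axis without overlap.
    """

    def interval(self, name: str) -> tuple[float, float]:
        try:
            return self[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; known: {sorted(self)}"
            ) from None


#: Conventional fingerprint windows: W1 fatty acids, W2 amides, W3 mixed,
#: W4 carbohydrates; ``quality`` is the SNR test window.
DEFAULT_REGIONS = RegionMap(
    W1=(3200.0, 2800.0),
    W2=(1800.0, 1500.0),
    W3=(1500.0, 1200.0),
    W4=(1200.0, 900.0),
    quality=(2100.0, 1900.0),
)


def _parse_sample_id(sid: str) -> tuple[str, float, int]:
    parts = sid.rsplit("_", 2)
    if len(parts) != 3:
        raise ValueError(
            f"cannot parse metadata from sample id {sid!r} "
            "(expected strain_condition_replicate)"
        )
    strain, cond, rep = parts
    try:
        return strain, float(cond), int(rep)
    except ValueError:
        raise ValueError(f"cannot parse metadata from sample id {sid!r}") from None


def read_spectra_csv(path, meta: pd.DataFrame | None = None, strict: bool = True) -> SpectrumSet:
    """Read a wide spectra CSV (first column ``wavenumber_cm1``).

    Sample metadata is parsed from column names ``strain_condition_rep``
    unless an explicit ``meta`` frame (indexed or keyed by ``sample_id``)
    is given. With ``strict=False`` a shuffled axis is sorted to
    decreasing order instead of raising.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    ids = header[1:]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in spectra CSV")
    df = pd.read_csv(path)
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    ab = df.iloc[:, 1:].to_numpy(dtype=float).T
    if np.any(np.diff(axis) >= 0):
        if strict:
            raise ValueError("wavenumber axis is not strictly decreasing")
        order = np.argsort(axis)[::-1]
        axis = axis[order]
        ab = ab[:, order]
    if meta is None:
        rows = []
        for sid in ids:
            strain, cond, rep = _parse_sample_id(sid)
            rows.append((sid, strain, cond, rep))
        meta = pd.DataFrame(rows, columns=list(META_COLUMNS))
    else:
        meta = meta.copy()
        if "sample_id" not in meta.columns:
            meta = meta.reset_index().rename(columns={"index": "sample_id"})
        missing = [s for s in ids if s not in set(meta["sample_id"])]
        if missing:
            raise ValueError(f"missing metadata for samples: {missing}")
        meta = meta.set_index("sample_id").loc[ids].reset_index()
    return SpectrumSet(axis, ab, meta)


def write_spectra_csv(sset: SpectrumSet, path) -> None:
    df = pd.DataFrame(
        sset.absorbance.T,
        columns=list(sset.meta["sample_id"]),
    )
    df.insert(0, "wavenumber_cm1", sset.axis)
    df.to_csv(path, index=False)


class SnrResult(NamedTuple):
    snr: float
    passed: bool


def quality_snr(
    spectrum: np.ndarray,
    axis: np.ndarray,
    quality_interval: tuple[float, float] = (2100.0, 1900.0),
    threshold: float = 4000.0,
) -> SnrResult:
    """Signal-to-noise quality test.

    Signal is the full-spectrum amplitude (max - min); noise is the RMS
    of residuals after a linear detrend of the quality window. A flat,
    noise-free window gives ``snr = inf`` (pass); a constant spectrum
    gives ``snr = 0`` (fail).
    """
    y = np.asarray(spectrum, dtype=float)
    x = np.asarray(axis, dtype=float)
    hi, lo = max(quality_interval), min(quality_interval)
    sel = (x > lo) & (x <= hi)
    if sel.sum() < 8:
        raise ValueError(
            f"quality interval ({lo}, {hi}] contains {int(sel.sum())} points (< 8)"
        )
    signal = float(np.ptp(y))
    coef = np.polyfit(x[sel], y[sel], 1)
    resid = y[sel] - np.polyval(coef, x[sel])
    noise = float(np.sqrt(np.mean(resid**2)))
    if noise == 0.0:
        snr = 0.0 if signal == 0.0 else float("inf")
    else:
        snr = signal / noise
    return SnrResult(snr, snr > threshold)


def _lower_hull(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Support points of the lower convex hull, x strictly increasing."""
    pts = np.column_stack([x, y])
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # flat (collinear) spectrum: the hull is the segment between ends
        return x[[0, -1]], y[[0, -1]]
    v = hull.vertices  # counter-clockwise
    left = int(np.argmin(pts[v, 0]))
    v = np.roll(v, -left)
    # CCW from the leftmost vertex walks the lower boundary first
    right = int(np.argmax(pts[v, 0]))
    chain = v[: right + 1]
    return x[chain], y[chain]


def rubberband_baseline(
    spectrum: np.ndarray,
    axis: np.ndarray | None = None,
    n_points: int = 64,
    return_baseline: bool = False,
):
    """Rubberband baseline correction of one spectrum.

    The baseline is the lower convex hull of the spectrum, interpolated
    through ``n_points`` equally spaced support abscissae (the hull is
    evaluated on that grid, then linearly interpolated back to the full
    axis). The corrected spectrum is ``spectrum - baseline``; it is zero
    at both ends and non-negative at the support points.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.size < 2:
        raise ValueError("spectrum needs >= 2 points")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x = np.arange(y.size, dtype=float) if axis is None else np.asarray(axis, dtype=float)
    # operate on increasing x
    if x[0] > x[-1]:
        xi, yi = x[::-1], y[::-1]
        flip = True
    else:
        xi, yi = x, y
        flip = False
    hx, hy = _lower_hull(xi, yi)
    envelope = np.interp(xi, hx, hy)
    anchors_x = np.linspace(xi[0], xi[-1], n_points)
    anchors_y = np.interp(anchors_x, xi, envelope)
    baseline = np.interp(xi, anchors_x, anchors_y)
    corrected = yi - baseline
    if flip:
        corrected = corrected[::-1]
        baseline = baseline[::-1]
    if return_baseline:
        return corrected, baseline
    return corrected


def vector_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Center to zero mean, scale to unit sum of squares (OPUS dialect)."""
    y = np.asarray(spectrum, dtype=float)
    centered = y - y.mean()
    norm = float(np.sqrt(np.sum(centered**2)))
    if norm == 0.0:
        raise ValueError("cannot vector-normalize a constant spectrum")
    return centered / norm


def extract_region(
    sset: SpectrumSet, region_map: RegionMap | None = None, name: str = "W1"
) -> SpectrumSet:
    """Restrict to one named window; metadata preserved."""
    region_map = DEFAULT_REGIONS if region_map is None else region_map
    upper, lower = region_map.interval(name)
    sel = (sset.axis > lower) & (sset.axis <= upper)
    if not np.any(sel):
        raise ValueError(
            f"region {name!r} ({lower}, {upper}] does not intersect the axis"
        )
    return SpectrumSet(sset.axis[sel], sset.absorbance[:, sel], sset.meta.copy())


def concat_regions(sset: SpectrumSet, region_map: RegionMap, names) -> np.ndarray:
    """Column-concatenated absorbance over several windows (for profiles)."""
    blocks = [extract_region(sset, region_map, n).absorbance for n in names]
    return np.hstack(blocks)


def average_replicates(sset: SpectrumSet, by=("strain", "condition")) -> SpectrumSet:
    """One mean spectrum per group; metadata records the group size."""
    by = list(by)
    groups = sset.meta.groupby(by, sort=True).indices
    rows, metas = [], []
    for key, idx in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        rows.append(sset.absorbance[np.asarray(idx)].mean(axis=0))
        rec = dict(zip(by, key))
        rec["sample_id"] = "_".join(str(k) for k in key)
        rec["n_averaged"] = len(idx)
        metas.append(rec)
    meta = pd.DataFrame(metas)
    for col in ("strain", "condition", "replicate"):
        if col not in meta.columns:
            meta[col] = np.nan
    cols = ["sample_id"] + by + ["n_averaged"] + [
        c for c in ("strain", "condition", "replicate") if c not in by
    ]
    return SpectrumSet(sset.axis, np.vstack(rows), meta[cols])


def mask_intervals(sset: SpectrumSet, intervals) -> SpectrumSet:
    """Zero out the given ``(upper, lower)`` windows (e.g. CO2 2400-2300)."""
    ab = sset.absorbance.copy()
    for upper, lower in intervals:
        hi, lo = max(upper, lower), min(upper, lower)
        sel = (sset.axis > lo) & (sset.axis <= hi)
        ab[:, sel] = 0.0
    return SpectrumSet(sset.axis, ab, sset.meta.copy())


def preprocess(
    sset: SpectrumSet,
    n_points: int = 64,
    snr_threshold: float | None = None,
) -> SpectrumSet:
    """Quality test (optional), rubberband correction, vector normalization.

    With ``snr_threshold`` set, samples failing the SNR test are dropped
    (mirrors re-acquisition in the wet lab). A spectrum that is exactly
    constant after baseline correction carries no information to
    normalize and is passed through centered (all zero) instead of
    raising. Returns a new SpectrumSet.
    """
    keep = np.ones(sset.n_samples, dtype=bool)
    if snr_threshold is not None:
        for i in range(sset.n_samples):
            keep[i] = quality_snr(
                sset.absorbance[i], sset.axis, threshold=snr_threshold
            ).passed
        sset = sset.subset(keep)
    out = np.empty_like(sset.absorbance)
    for i in range(sset.n_samples):
        corrected = rubberband_baseline(sset.absorbance[i], sset.axis, n_points)
        try:
            out[i] = vector_normalize(corrected)
        except ValueError:
            out[i] = corrected - corrected.mean()
    return SpectrumSet(sset.axis, out, sset.meta.copy())
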