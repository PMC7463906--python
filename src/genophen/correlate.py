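"""Genotype-phenotype distance correlation: whole-profile, per-descriptor, PSW.

This is the statistic at the heart of the pipeline. Two labeled distance
matrices over the same strains (one genetic, one phenotypic) are compared
by the Pearson correlation of their lower triangles, with significance
from Mantel-style row/column permutations (exhaustive when n! fits the
permutation budget; with 4 strains all 24 relabelings are enumerated).

The per-descriptor scan repeats this for every single spectral
wavelength or metabolite: strain distances at one descriptor are the
absolute value differences |x_i - x_j|, and the fraction of descriptors
whose correlation with a marker exceeds 0.75 is the percentage of
significative wavelengths (PSW). PSW trajectories across ethanol doses
are classified as low, high, or non-monotonous response.

Small-n caveat: with 4 strains (6 pairs) a pure-noise descriptor clears
the 0.75 filter about 5-7% of the time, so PSW carries a noise floor of
a few points; the parametric p-value is anti-conservative for distances
and the permutation p is the default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .distmat import DistanceMatrix
from .ftir import RegionMap, SpectrumSet, average_replicates, extract_region

__all__ = [
    "CorrelationResult",
    "DescriptorScan",
    "PSWTrend",
    "profile_distance",
    "matrix_correlation",
    "descriptor_scan",
    "scan_spectra_by_condition",
    "psw",
    "classify_trend",
    "region_max_correlation",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Mantel-style correlation between two distance matrices."""

    r: float
    p_value: float
    n_pairs: int
    method: str  # parametric_t | permutation
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")


@dataclass(frozen=True)
class DescriptorScan:
    """Per-descriptor correlations of one marker at one condition."""

    descriptors: tuple = field(repr=False)
    r: np.ndarray = field(repr=False)
    p: np.ndarray | None = field(repr=False, default=None)
    marker: str = ""
    condition: float | str | None = None

    def __post_init__(self) -> None:
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError("duplicate descriptor ids")
        if len(self.descriptors) != len(self.r):
            raise ValueError("descriptor/r length mismatch")


@dataclass(frozen=True)
class PSWTrend:
    """PSW per condition for one marker, with its trend class."""

    marker: str
    conditions: tuple[float, ...]
    psw_percent: tuple[float, ...]
    trend_class: str

    def __post_init__(self) -> None:
        if not all(0.0 <= v <= 100.0 for v in self.psw_percent):
            raise ValueError("PSW outside [0, 100]")
        if self.trend_class not in ("low", "high", "non_monotonous"):
            raise ValueError(f"unknown trend class {self.trend_class!r}")


def profile_distance(profiles, labels=None) -> DistanceMatrix:
    """Pairwise Euclidean distances between whole profiles (rows)."""
    if isinstance(profiles, pd.DataFrame):
        if labels is None:
            labels = list(profiles.index)
        profiles = profiles.to_numpy(dtype=float)
    X = np.asarray(profiles, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least two profiles")
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    return DistanceMatrix.from_condensed(labels, pdist(X, metric="euclidean"))


def _permuted_r(c1: np.ndarray, values2: np.ndarray, perm) -> float:
    sq = values2[np.ix_(perm, perm)]
    iu = np.triu_indices(sq.shape[0], 1)
    c2 = sq[iu]
    return float(np.corrcoef(c1, c2)[0, 1])


def matrix_correlation(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    method: str = "permutation",
    n_perm: int = 9999,
    seed: int | None = None,
) -> CorrelationResult:
    """Pearson correlation of the lower triangles of two distance matrices.

    Matrices are aligned by label (order-insensitive); a label-set
    mismatch raises with the difference listed. ``method='parametric_t'``
    uses the t approximation on n_pairs - 2 degrees of freedom
    (anti-conservative for distances, reported for parity with cor.test);
    ``method='permutation'`` permutes rows/columns of D2 jointly, running
    all n! relabelings exhaustively whenever n! <= n_perm, otherwise
    sampling n_perm of them. Two-sided in |r| in both cases.
    """
    if D1.n < 3:
        raise ValueError("need at least 3 items")
    D2a = D2.reorder(D1.labels)
    iu = np.triu_indices(D1.n, 1)
    c1 = D1.values[iu]
    c2 = D2a.values[iu]
    if np.std(c1) == 0.0 or np.std(c2) == 0.0:
        raise ValueError("zero-variance distance triangle")
    r = float(np.corrcoef(c1, c2)[0, 1])
    m = len(c1)
    if method == "parametric_t":
        t = r * math.sqrt(m - 2) / math.sqrt(max(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(abs(t), df=m - 2)
        return CorrelationResult(r, min(p, 1.0), m, "parametric_t")
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    n = D1.n
    n_fact = math.factorial(n)
    tol = 1e-12
    if n_fact <= n_perm:
        hits = 0
        for perm in itertools.permutations(range(n)):
            if abs(_permuted_r(c1, D2a.values, perm)) >= abs(r) - tol:
                hits += 1
        p = hits / n_fact
        return CorrelationResult(r, p, m, "permutation", seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(_permuted_r(c1, D2a.values, perm)) >= abs(r) - tol:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return CorrelationResult(r, p, m, "permutation", seed, exhaustive=False)


# ---------------------------------------------------------------------------
# descriptor scan / PSW
# ---------------------------------------------------------------------------


def descriptor_scan(
    genetic_D: DistanceMatrix,
    profiles: pd.DataFrame,
    marker: str = "",
    condition=None,
    p_values: bool = True,
) -> DescriptorScan:
    """Correlate one marker with every single descriptor.

    ``profiles`` holds one replicate-averaged row per strain (index =
    strain labels matching ``genetic_D``) and one column per descriptor
    (wavenumber or metabolite). For each descriptor the strain distance
    matrix is |x_i - x_j| and its lower triangle is correlated with the
    marker's. Constant descriptors are recorded with r = 0 (kept in the
    PSW denominator). p-values come from exhaustive permutations when
    n! <= 5040, otherwise from the t approximation.
    """
    if genetic_D.n < 3:
        raise ValueError("need at least 3 strains")
    X = profiles.loc[list(genetic_D.labels)].to_numpy(dtype=float)
    n, p = X.shape
    iu = np.triu_indices(n, 1)
    Dd = np.abs(X[iu[0], :] - X[iu[1], :])  # pairs x descriptors
    g = genetic_D.values[iu]
    gc = g - g.mean()
    gn = float(np.sqrt((gc**2).sum()))
    if gn == 0.0:
        raise ValueError("zero-variance genetic distance triangle")
    Dc = Dd - Dd.mean(axis=0)
    dn = np.sqrt((Dc**2).sum(axis=0))
    constant = dn == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (gc @ Dc) / (gn * dn)
    r[constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    pv = None
    if p_values:
        m = len(g)
        if math.factorial(n) <= 5040:
            perms = np.array(list(itertools.permutations(range(n))))
            # condensed index map for each permutation of the strain labels
            sq_idx = np.zeros((n, n), dtype=int)
            sq_idx[iu] = np.arange(m)
            sq_idx = sq_idx + sq_idx.T
            gperm = np.empty((len(perms), m))
            for k, perm in enumerate(perms):
                gperm[k] = genetic_D.values[np.ix_(perm, perm)][iu]
            gpc = gperm - gperm.mean(axis=1, keepdims=True)
            gpn = np.sqrt((gpc**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                rperm = (gpc @ Dc) / (gpn[:, None] * dn[None, :])
            rperm[:, constant] = 0.0
            pv = (np.abs(rperm) >= np.abs(r)[None, :] - 1e-12).mean(axis=0)
            pv[constant] = 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                t = r * np.sqrt(m - 2) / np.sqrt(np.maximum(1.0 - r * r, 1e-300))
            pv = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
            pv = np.minimum(pv, 1.0)
            pv[constant] = 1.0
    return DescriptorScan(tuple(profiles.columns), r, pv, marker, condition)


def _strain_profiles(
    sset: SpectrumSet, mask: np.ndarray, strains
) -> pd.DataFrame:
    sub = sset.subset(mask)
    avg = average_replicates(sub, by=["strain"])
    prof = pd.DataFrame(
        avg.absorbance, index=list(avg.meta["strain"]), columns=list(sub.axis)
    )
    return prof.loc[list(strains)]


def scan_spectra_by_condition(
    genetic_D: DistanceMatrix,
    sset: SpectrumSet,
    marker: str = "",
    p_values: bool = False,
) -> dict[float, DescriptorScan]:
    """One descriptor scan per ethanol condition (replicates averaged)."""
    conditions = sorted(set(sset.meta["condition"]))
    out = {}
    for c in conditions:
        mask = (sset.meta["condition"] == c).to_numpy()
        prof = _strain_profiles(sset, mask, genetic_D.labels)
        out[c] = descriptor_scan(genetic_D, prof, marker, c, p_values=p_values)
    return out


def psw(scan, threshold: float = 0.75) -> float:
    """Percentage of descriptors with correlation strictly above threshold."""
    r = scan.r if isinstance(scan, DescriptorScan) else np.asarray(scan, dtype=float)
    if len(r) == 0:
        raise ValueError("empty scan")
    return 100.0 * float(np.sum(r > threshold)) / len(r)


def classify_trend(psw_by_condition, split: float = 5.0) -> str:
    """Classify a PSW trajectory over increasing ethanol conditions.

    ``non_monotonous`` when the maximum PSW sits strictly inside the dose
    range (above both the first and the last condition, so a plateau
    extending to a boundary counts as monotone); otherwise ``high`` when
    the maximum reaches the split (default 5%, midway between the
    observed low-response and high-response ranges) and ``low`` below it.
    """
    vals = np.asarray(list(psw_by_condition), dtype=float)
    if len(vals) < 3:
        raise ValueError("need at least 3 conditions")
    peak = float(np.max(vals))
    if peak > vals[0] and peak > vals[-1]:
        return "non_monotonous"
    return "high" if peak >= split else "low"


def psw_trend(
    marker: str,
    scans_by_condition: dict[float, DescriptorScan],
    threshold: float = 0.75,
    split: float = 5.0,
) -> PSWTrend:
    """Convenience: PSW per condition plus trend class for one marker."""
    conds = tuple(sorted(scans_by_condition))
    values = tuple(psw(scans_by_condition[c], threshold) for c in conds)
    return PSWTrend(marker, conds, values, classify_trend(values, split))


def region_max_correlation(
    genetic_Ds: dict[str, DistanceMatrix],
    sset: SpectrumSet,
    region_map: RegionMap | None = None,
    regions=("W1", "W2", "W3", "W4"),
    control_condition: float = 0.0,
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Maximum per-descriptor correlation per marker x region x group.

    Spectra split into a control group (condition == ``control_condition``)
    and a stressed group pooling every other condition; replicates (and,
    for the stressed group, conditions) are averaged per strain before
    scanning. Returns a tidy frame with columns ``marker, region, group,
    max_r, significant``.
    """
    from .ftir import DEFAULT_REGIONS

    region_map = DEFAULT_REGIONS if region_map is None else region_map
    cond = sset.meta["condition"].to_numpy()
    groups = {
        "control": cond == control_condition,
        "stressed": cond != control_condition,
    }
    rows = []
    for gname, mask in groups.items():
        if not mask.any():
            raise ValueError(f"no samples in group {gname!r}")
        for region in regions:
            rset = extract_region(sset, region_map, region)
            for marker, D in genetic_Ds.items():
                prof = _strain_profiles(rset, mask, D.labels)
                scan = descriptor_scan(D, prof, marker, gname, p_values=False)
                max_r = float(np.max(scan.r))
                rows.append(
                    {
                        "marker": marker,
                        "region": region,
                        "group": gname,
                        "max_r": max_r,
                        "significant": max_r > threshold,
                    }
                )
    return pd.DataFrame(rows)
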