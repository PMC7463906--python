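"""LC-MS feature-table processing, PLS-DA/VIP selection, clustering, mortality.

The module starts from an annotated feature table (samples x metabolites,
non-negative intensities) and applies the standard metabolomics chain:
IQR-based variable filtering, per-sample median normalization and Pareto
scaling. Discriminant metabolites are selected by VIP scores from a
PLS-DA fit (PLS2 via NIPALS on the one-hot class matrix) with the
greater-than-one rule, which works because the mean of squared VIP
scores equals 1 by construction. Hierarchical clustering uses Ward
linkage on Euclidean or Spearman (1 - rho) distances. Viability counts
turn into mortality percentages via M = (1 - Cv/Ct) * 100.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

__all__ = [
    "FeatureTable",
    "VipResult",
    "Dendrogram",
    "iqr_filter",
    "median_normalize",
    "pareto_scale",
    "plsda_vip",
    "select_discriminant",
    "hca",
    "dendrogram_to_newick",
    "mortality",
    "mortality_table",
    "read_feature_csv",
    "write_feature_csv",
]

logger = logging.getLogger(__name__)

_STATES = ("raw", "filtered", "normalized", "scaled")


@dataclass(frozen=True)
class FeatureTable:
    """Samples x metabolites intensity matrix with per-sample metadata.

    ``data`` is indexed by sample id with one column per metabolite;
    ``meta`` carries ``sample_id, strain, condition, replicate``. The
    ``state`` flag tracks the processing chain raw -> filtered ->
    normalized -> scaled; raw intensities must be non-negative.
    """

    data: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame = field(repr=False)
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate metabolite names")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensities contain non-finite values")
        if self.state == "raw" and np.any(vals < 0):
            raise ValueError("raw intensities must be non-negative")
        if list(self.meta["sample_id"]) != list(self.data.index):
            raise ValueError("metadata sample_ids do not match data index")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_feature_csv(path) -> FeatureTable:
    """Read a feature CSV with strain/condition/replicate metadata columns."""
    df = pd.read_csv(path, index_col=0)
    meta_cols = [c for c in ("strain", "condition", "replicate") if c in df.columns]
    meta = df[meta_cols].copy()
    meta.insert(0, "sample_id", df.index.astype(str))
    data = df.drop(columns=meta_cols)
    data.index = df.index.astype(str)
    meta = meta.reset_index(drop=True)
    return FeatureTable(data, meta, state="raw")


def write_feature_csv(table: FeatureTable, path) -> None:
    df = table.data.copy()
    for col in ("strain", "condition", "replicate"):
        if col in table.meta.columns:
            df[col] = table.meta.set_index("sample_id")[col].reindex(df.index).values
    df.to_csv(path, index_label="sample_id")


def _require_state(table: FeatureTable, expected: str, op: str) -> None:
    if table.state != expected:
        raise ValueError(f"{op} expects a {expected!r} table, got {table.state!r}")


def iqr_filter(table: FeatureTable, drop_fraction: float = 0.1) -> FeatureTable:
    """Drop the least variable metabolites by interquartile range.

    Zero-IQR (constant) metabolites are always removed; further columns
    with the lowest IQR are removed until ``floor(p * drop_fraction)``
    are gone (ties break by column order).
    """
    _require_state(table, "raw", "iqr_filter")
    if not (0.0 <= drop_fraction < 1.0):
        raise ValueError("drop_fraction must be in [0, 1)")
    iqr = table.data.quantile(0.75) - table.data.quantile(0.25)
    p = table.data.shape[1]
    n_drop = math.floor(p * drop_fraction)
    drop = set(iqr.index[iqr <= 0.0])
    if len(drop) < n_drop:
        ranked = iqr.sort_values(kind="stable").index
        for name in ranked:
            if len(drop) >= n_drop:
                break
            drop.add(name)
    keep = [m for m in table.data.columns if m not in drop]
    if not keep:
        raise ValueError("IQR filter would remove every metabolite")
    return replace(table, data=table.data[keep], state="filtered")


def median_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each sample by its own median intensity."""
    if table.state not in ("raw", "filtered"):
        raise ValueError(f"median_normalize expects raw/filtered, got {table.state!r}")
    med = table.data.median(axis=1)
    bad = med[med <= 0]
    if len(bad):
        raise ValueError(f"non-positive sample median for: {list(bad.index)}")
    return replace(table, data=table.data.div(med, axis=0), state="normalized")


def pareto_scale(table: FeatureTable) -> FeatureTable:
    """Center each metabolite and divide by the square root of its SD.

    Zero-SD columns become all-zero (with a warning) rather than NaN.
    """
    _require_state(table, "normalized", "pareto_scale")
    centered = table.data - table.data.mean(axis=0)
    sd = table.data.std(axis=0, ddof=1)
    zero = sd[sd == 0.0].index
    if len(zero):
        warnings.warn(
            f"pareto_scale: {len(zero)} constant metabolite(s) set to zero",
            stacklevel=2,
        )
    scaled = centered / np.sqrt(sd.replace(0.0, np.nan))
    scaled[zero] = 0.0
    return replace(table, data=scaled, state="scaled")


# ---------------------------------------------------------------------------
# PLS-DA / VIP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VipResult:
    """Per-metabolite VIP scores from a PLS-DA fit.

    Invariant: the mean of squared scores over metabolites is 1, which is
    what justifies the VIP > 1 selection rule.
    """

    scores: pd.Series = field(repr=False)
    n_components: int
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        msq = float(np.mean(self.scores.to_numpy() ** 2))
        if abs(msq - 1.0) > 1e-9:
            raise ValueError(f"VIP invariant violated: mean(VIP^2) = {msq!r}")


def _nipals_pls2(X: np.ndarray, Y: np.ndarray, n_components: int, tol: float = 1e-12,
                 max_iter: int = 1000):
    """NIPALS PLS2. Returns (W weights, SSY per component, achieved)."""
    n, p = X.shape
    Xa = X.copy()
    Ya = Y.copy()
    W = np.zeros((n_components, p))
    ssy = np.zeros(n_components)
    achieved = 0
    for a in range(n_components):
        u = Ya[:, int(np.argmax(Ya.var(axis=0)))].copy()
        if np.allclose(Ya, 0.0) or np.allclose(Xa, 0.0):
            logger.info("NIPALS: deflation exhausted at component %d", a)
            break
        t_old = None
        for _ in range(max_iter):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0.0:
                logger.info("NIPALS: zero-norm weight at component %d", a)
                return W[:achieved], ssy[:achieved], achieved
            w /= nw
            t = Xa @ w
            tt = float(t @ t)
            if tt == 0.0:
                return W[:achieved], ssy[:achieved], achieved
            q = Ya.T @ t / tt
            qq = float(q @ q)
            if qq == 0.0:
                return W[:achieved], ssy[:achieved], achieved
            u = Ya @ q / qq
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        p_load = Xa.T @ t / tt
        Xa = Xa - np.outer(t, p_load)
        Ya = Ya - np.outer(t, q)
        W[a] = w
        ssy[a] = tt * qq  # Y-variance explained by component a
        achieved = a + 1
    return W[:achieved], ssy[:achieved], achieved


def plsda_vip(
    table: FeatureTable,
    class_labels=None,
    n_components: int = 2,
) -> VipResult:
    """PLS-DA via NIPALS on a one-hot class matrix; VIP per metabolite.

    ``VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )``
    with ``p`` the metabolite count and ``SSY_a`` the Y-variance explained
    by component ``a``. Class labels default to the strain column of the
    table metadata. Degenerate deflation stops early with the achieved
    number of components (logged).
    """
    _require_state(table, "scaled", "plsda_vip")
    if class_labels is None:
        class_labels = table.meta["strain"].to_numpy()
    labels = np.asarray([str(c) for c in class_labels])
    if labels.size != table.n_samples:
        raise ValueError("class_labels length does not match samples")
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    n, p = table.data.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components={n_components} out of range for {n} samples x {p} metabolites"
        )
    Y = np.zeros((n, len(classes)))
    for k, c in enumerate(classes):
        Y[labels == c, k] = 1.0
    Y -= Y.mean(axis=0)
    X = table.values()
    W, ssy, achieved = _nipals_pls2(X, Y, n_components)
    if achieved == 0:
        raise ValueError("PLS-DA failed: no component could be extracted")
    if ssy.sum() == 0.0:
        raise ValueError("PLS-DA explained no class variance")
    # W rows are unit-norm already
    vip = np.sqrt(p * (ssy[:, None] * W**2).sum(axis=0) / ssy.sum())
    scores = pd.Series(vip, index=table.data.columns, name="VIP")
    return VipResult(scores, achieved, classes)


def select_discriminant(vip: VipResult, threshold: float = 1.0) -> list[str]:
    """Metabolites with VIP strictly greater than the threshold, in order."""
    return [m for m, v in vip.scores.items() if v > threshold]


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dendrogram:
    """Ward-linkage dendrogram: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    distance: str = "euclidean"

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hca(matrix, labels=None, distance: str = "euclidean") -> Dendrogram:
    """Hierarchical clustering with Ward's algorithm.

    ``distance='euclidean'`` clusters rows of the matrix directly
    (ward.D2-consistent heights); ``distance='spearman'`` uses
    1 - Spearman correlation between rows. Ward formally assumes
    Euclidean geometry, so the Spearman variant is a heuristic in the
    tradition of correlation-distance heatmaps.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = list(matrix.index)
        matrix = matrix.to_numpy(dtype=float)
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains NaN/inf")
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    if distance == "euclidean":
        Z = linkage(X, method="ward")
    elif distance == "spearman":
        with warnings.catch_warnings():
            # constant rows yield NaN rho; we raise a clearer error below
            warnings.simplefilter("ignore")
            rho = spearmanr(X, axis=1).statistic
        rho = np.atleast_2d(rho)
        D = 1.0 - rho
        np.fill_diagonal(D, 0.0)
        if np.any(~np.isfinite(D)):
            raise ValueError("Spearman distance undefined (constant rows?)")
        Z = linkage(squareform(D, checks=False), method="ward")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return Dendrogram(Z, tuple(str(l) for l in labels), distance)


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Serialize a dendrogram as Newick with branch lengths from heights."""
    root = to_tree(dend.linkage)

    def rec(node, parent_height) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{dend.labels[node.id]}:{length:.6g}"
        inner = ",".join(rec(c, node.dist) for c in (node.left, node.right))
        return f"({inner}):{length:.6g}"

    inner = ",".join(rec(c, root.dist) for c in (root.left, root.right))
    return f"({inner});"


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------


def mortality(cv: float, ct: float) -> float:
    """Cell mortality percent, M = (1 - Cv/Ct) * 100.

    Negative values (growth relative to control) are returned as-is,
    not clipped; callers may flag them.
    """
    if ct <= 0:
        raise ValueError("Ct must be > 0")
    if cv < 0:
        raise ValueError("Cv must be >= 0")
    return (1.0 - cv / ct) * 100.0


def mortality_table(viability: pd.DataFrame) -> pd.DataFrame:
    """Per strain x condition mortality from a viability table.

    Expects columns ``strain, condition, Cv, Ct``; returns
    ``strain, condition, M`` with a ``growth_flag`` column marking
    negative mortality.
    """
    required = {"strain", "condition", "Cv", "Ct"}
    missing = required - set(viability.columns)
    if missing:
        raise ValueError(f"viability table missing columns {sorted(missing)}")
    grouped = viability.groupby(["strain", "condition"], sort=True)[["Cv", "Ct"]].mean()
    out = grouped.reset_index()
    out["M"] = [mortality(cv, ct) for cv, ct in zip(out["Cv"], out["Ct"])]
    out["growth_flag"] = out["M"] < 0
    return out[["strain", "condition", "M", "growth_flag"]]
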