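"""Synthetic study-condition generator: marker loci, spectra, features, counts.

Every downstream stage of the pipeline is exercised on data produced
here, with the statistical structure the analysis assumes:

* marker alignments evolve site-independently under JC69 on a known
  4-taxon tree (the *Saccharomyces sensu stricto* panel), with per-locus
  rate multipliers;
* FTIR-like spectra live on the 4000-400 cm^-1 axis at 4 cm^-1 (901
  points) and are a smooth polynomial baseline plus condition-dependent
  planted signals plus i.i.d. Gaussian noise. A planted signal adds, on
  a fixed subset of wavelengths inside one spectral window, a component
  proportional to a per-strain score whose pairwise differences track
  the source locus' genetic distances (classical 1-D embedding);
* LC-MS-like feature tables get log-normal baselines with strain- and
  dose-specific shifts driven by the same locus scores;
* viability counts follow Poisson plate-count noise around
  Ct * (1 - M/100), with the default mortality profile shaped like the
  published strain-specific ethanol responses.

Identical :class:`ScenarioConfig` (including seed) gives byte-identical
outputs; each generator draws from its own seed substream so the pieces
can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .distmat import DistanceMatrix
from .ftir import DEFAULT_REGIONS, RegionMap, SpectrumSet, write_spectra_csv
from .metabolome import FeatureTable, write_feature_csv
from .seqdist import (
    MarkerAlignment,
    evolutionary_distance,
    tree_distance_matrix,
    write_alignment_fasta,
)

__all__ = [
    "PlantedSignal",
    "ScenarioConfig",
    "DEFAULT_TREE",
    "DEFAULT_LOCI",
    "DEFAULT_MORTALITY",
    "simulate_marker_alignment",
    "simulate_alignments",
    "simulate_spectra",
    "simulate_feature_table",
    "simulate_viability",
    "strain_scores",
    "strain_embedding",
    "planted_wavelengths",
    "scenario_from_json",
    "write_scenario_outputs",
    "random_tree_newick",
    "random_additive_matrix",
]

#: Wavenumber axis: 4000..400 cm^-1 at 4 cm^-1 (901 points).
AXIS = 4000.0 - 4.0 * np.arange(901)

#: Rooted 4-taxon tree, branch lengths in substitutions/site, shaped like
#: the sensu stricto panel (cerevisiae/paradoxus sisters, bayanus deep).
DEFAULT_TREE = (
    "((S_cerevisiae:0.010,S_paradoxus:0.014):0.012,"
    "(S_bayanus:0.022,S_pastorianus:0.016):0.008);"
)

#: (locus name, alignment length, rate multiplier). Ribosomal loci slow,
#: mitochondrial fast, single-copy coding genes in between.
DEFAULT_LOCI: tuple[tuple[str, int, float], ...] = (
    ("ITS", 600, 1.0),
    ("LSU", 570, 0.6),
    ("SSU", 1800, 0.3),
    ("mtSSU", 900, 1.5),
    ("mtCOXII", 750, 2.0),
    ("ACT1", 1100, 0.8),
    ("DAL2", 1000, 1.6),
    ("FAS1", 1200, 1.2),
    ("ICL1", 1100, 1.4),
    ("RPB1", 1000, 0.7),
    ("RPB2", 1200, 0.9),
    ("TEF1a", 900, 1.0),
)

#: Strain -> condition -> mortality %, mirroring the strain-specific
#: ethanol tolerance of the panel (sensitive S. bayanus, tolerant rest).
DEFAULT_MORTALITY: dict[str, dict[float, float]] = {
    "S_bayanus": {0.0: 0.0, 8.0: 40.6, 12.0: 97.2, 16.0: 100.0},
    "S_paradoxus": {0.0: 0.0, 8.0: 12.3, 12.0: 12.5, 16.0: 13.3},
    "S_cerevisiae": {0.0: 0.0, 8.0: 0.0, 12.0: 10.8, 16.0: 20.3},
    "S_pastorianus": {0.0: 0.0, 8.0: 0.0, 12.0: 3.7, 16.0: 9.7},
}


@dataclass(frozen=True)
class PlantedSignal:
    """A condition-dependent spectral signal driven by one locus.

    ``region`` is a window name (W1..W4) or an explicit ``(upper, lower)``
    wavenumber interval; ``amplitude_per_condition`` has one absorbance
    amplitude per ethanol condition; the signal occupies ``n_wavelengths``
    fixed wavelengths inside the window.
    """

    region: str | tuple[float, float]
    source_locus: str
    amplitude_per_condition: tuple[float, ...]
    n_wavelengths: int = 50


DEFAULT_PLANTED: tuple[PlantedSignal, ...] = (
    # amide-region response rising with dose, driven by TEF1a
    PlantedSignal("W2", "TEF1a", (0.0, 0.0, 0.004, 0.008), 50),
    # fatty-acid-region response peaking at 8%, driven by RPB2
    PlantedSignal("W1", "RPB2", (0.001, 0.006, 0.003, 0.001), 40),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study.

    Defaults emulate the published design: 4 strains x 4 ethanol doses
    (0/8/12/16 % v/v) x 3 replicates, 13 marker loci (12 simulated plus
    the ITS_LSU concatenation downstream), 89 annotated metabolites.
    ``baseline_per_sample=False`` shares the spectral baseline within a
    condition (useful for exact planted-signal constructions).
    """

    tree_newick: str = DEFAULT_TREE
    locus_specs: tuple[tuple[str, int, float], ...] = DEFAULT_LOCI
    conditions: tuple[float, ...] = (0.0, 8.0, 12.0, 16.0)
    #: sigma of the lognormal per-locus, per-branch rate factors (mean 1);
    #: gives each locus its own realized distance structure, as gene trees do
    branch_rate_sd: float = 0.7
    n_replicates: int = 3
    noise_sd: float = 0.0008
    baseline_sd: float = 0.01
    baseline_per_sample: bool = True
    #: scale of the fixed, strain-shared absorbance band structure
    #: (CH stretch, amide I/II, fingerprint); keeps vector normalization
    #: anchored on shared biomass rather than on the planted signals
    background_amplitude: float = 0.5
    planted_signals: tuple[PlantedSignal, ...] = DEFAULT_PLANTED
    region_map: RegionMap = field(default_factory=lambda: RegionMap(DEFAULT_REGIONS))
    feature_source_locus: str | None = "mtCOXII"
    feature_effect_size: float = 0.5
    feature_affected_fraction: float = 0.5
    feature_noise_sd: float = 0.03
    n_metabolites: int = 89
    seed: int = 0

    def __post_init__(self) -> None:
        taxa = self.taxa  # parses the tree, raises on malformation
        if len(taxa) < 3:
            raise ValueError("tree must have >= 3 leaves")
        if len(set(taxa)) != len(taxa):
            raise ValueError("tree leaf labels are not unique")
        names = [n for n, _, _ in self.locus_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        for name, length, rate in self.locus_specs:
            if length < 1:
                raise ValueError(f"locus {name!r}: length must be >= 1")
            if not rate > 0:
                raise ValueError(f"locus {name!r}: rate multiplier must be > 0")
        if list(self.conditions) != sorted(set(self.conditions)):
            raise ValueError("conditions must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise/baseline SD must be >= 0")
        if self.background_amplitude < 0:
            raise ValueError("background_amplitude must be >= 0")
        if self.branch_rate_sd < 0:
            raise ValueError("branch_rate_sd must be >= 0")
        for sig in self.planted_signals:
            if len(sig.amplitude_per_condition) != len(self.conditions):
                raise ValueError(
                    f"planted signal in {sig.region!r}: needs one amplitude "
                    f"per condition ({len(self.conditions)})"
                )
            if sig.source_locus not in names:
                raise ValueError(
                    f"planted signal references unknown locus {sig.source_locus!r}"
                )
            if sig.n_wavelengths < 1:
                raise ValueError("planted signal needs >= 1 wavelength")
        if self.feature_source_locus is not None and self.feature_source_locus not in names:
            raise ValueError(
                f"feature_source_locus {self.feature_source_locus!r} not in loci"
            )
        if not (0.0 <= self.feature_affected_fraction <= 1.0):
            raise ValueError("feature_affected_fraction must be in [0, 1]")
        if self.n_metabolites < 2:
            raise ValueError("n_metabolites must be >= 2")

    @property
    def taxa(self) -> tuple[str, ...]:
        tree = _parse_tree(self.tree_newick)
        return tuple(l.taxon.label for l in tree.leaf_node_iter())

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one seed substream."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _parse_tree(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick tree: {exc}") from exc
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has unlabeled leaves")
    return tree


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_marker_alignment(
    tree_newick: str,
    length: int,
    rate_multiplier: float,
    seed=None,
    locus_name: str = "locus",
    branch_rate_sd: float = 0.0,
) -> MarkerAlignment:
    """Evolve one locus on a tree under JC69.

    Each branch substitutes a site with probability
    ``3/4 (1 - exp(-4 d r / 3))`` for branch length ``d`` and rate
    multiplier ``r``; substitutions pick a different base uniformly.
    With ``branch_rate_sd > 0`` each branch additionally draws a
    lognormal rate factor (mean 1), emulating gene-specific lineage-rate
    variation. Same seed gives an identical alignment.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if rate_multiplier < 0:
        raise ValueError("rate_multiplier must be >= 0")
    tree = _parse_tree(tree_newick)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=length, dtype=np.int64)
    taxa, out = [], []
    for node in tree.preorder_node_iter():
        if node is root:
            parent_seq = seqs[id(root)]
        else:
            d = node.edge.length or 0.0
            if not np.isfinite(d) or d < 0:
                raise ValueError(f"invalid branch length {d!r}")
            factor = 1.0
            if branch_rate_sd > 0:
                factor = rng.lognormal(-branch_rate_sd**2 / 2.0, branch_rate_sd)
            p_sub = 0.75 * (1.0 - np.exp(-4.0 * d * rate_multiplier * factor / 3.0))
            parent_seq = seqs[id(node.parent_node)].copy()
            hit = np.flatnonzero(rng.random(length) < p_sub)
            if hit.size:
                parent_seq[hit] = (
                    parent_seq[hit] + rng.integers(1, 4, size=hit.size)
                ) % 4
            seqs[id(node)] = parent_seq
        if node.is_leaf():
            taxa.append(node.taxon.label)
            out.append(_BASES[seqs[id(node)]].tobytes().decode())
    return MarkerAlignment(locus_name, tuple(taxa), tuple(out))


def simulate_alignments(scenario: ScenarioConfig) -> dict[str, MarkerAlignment]:
    """All loci of a scenario, one seed substream per locus."""
    out = {}
    for k, (name, length, rate) in enumerate(scenario.locus_specs):
        out[name] = simulate_marker_alignment(
            scenario.tree_newick,
            length,
            rate,
            scenario.rng(100 + k),
            name,
            branch_rate_sd=scenario.branch_rate_sd,
        )
    return out


def strain_scores(D: DistanceMatrix) -> pd.Series:
    """Classical 1-D embedding of a distance matrix, scaled to unit range.

    The leading principal-coordinate axis, so |score_i - score_j|
    correlates with the input distances. Sign is fixed deterministically;
    a degenerate (all-zero) matrix gives all-zero scores.
    """
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.values**2) @ J
    w, v = np.linalg.eigh(B)
    k = int(np.argmax(w))
    score = v[:, k] * np.sqrt(max(w[k], 0.0))
    if score[int(np.argmax(np.abs(score)))] < 0:
        score = -score
    rng_width = float(np.ptp(score))
    if rng_width > 0:
        score = (score - score.mean()) / rng_width
    else:
        score = np.zeros(n)
    return pd.Series(score, index=list(D.labels))


def strain_embedding(D: DistanceMatrix) -> pd.DataFrame:
    """Full classical-MDS embedding of a distance matrix (n x n-1 coords).

    Pairwise Euclidean distances between rows reproduce the input up to
    the non-Euclidean part (negative eigenvalues are dropped). Used to
    drive metabolite shifts so that whole-profile metabolome distances
    approximate the source locus' distance matrix itself, not only its
    leading axis.
    """
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.values**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][: n - 1]
    w = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(w)
    return pd.DataFrame(coords, index=list(D.labels))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


#: (center cm^-1, width, relative height) of the shared absorbance bands:
#: OH/NH stretch envelope, CH2/CH3 stretches, amide I, amide II, mixed
#: region, carbohydrates.
_BACKGROUND_BANDS = (
    (3380.0, 130.0, 2.4),
    (2925.0, 50.0, 0.75),
    (2855.0, 35.0, 0.45),
    (1655.0, 45.0, 1.0),
    (1545.0, 35.0, 0.65),
    (1240.0, 50.0, 0.35),
    (1050.0, 70.0, 0.55),
)


def background_spectrum(amplitude: float, axis: np.ndarray = AXIS) -> np.ndarray:
    """Fixed whole-cell-like band structure shared by every sample."""
    y = np.zeros_like(axis, dtype=float)
    for center, width, height in _BACKGROUND_BANDS:
        y += height * np.exp(-((axis - center) ** 2) / (2.0 * width**2))
    return amplitude * y


def _signal_interval(sig: PlantedSignal, region_map: RegionMap) -> tuple[float, float]:
    if isinstance(sig.region, str):
        return region_map.interval(sig.region)
    upper, lower = sig.region
    return float(max(upper, lower)), float(min(upper, lower))


def planted_wavelengths(scenario: ScenarioConfig) -> list[np.ndarray]:
    """The fixed wavelength indices used by each planted signal (in AXIS)."""
    out = []
    for i, sig in enumerate(scenario.planted_signals):
        upper, lower = _signal_interval(sig, scenario.region_map)
        cand = np.flatnonzero((AXIS > lower) & (AXIS <= upper))
        if cand.size == 0:
            raise ValueError(f"planted region {sig.region!r} is outside the axis")
        if sig.n_wavelengths > cand.size:
            raise ValueError(
                f"planted signal in {sig.region!r} wants {sig.n_wavelengths} "
                f"wavelengths, window has {cand.size}"
            )
        rng = scenario.rng(210 + i)
        out.append(np.sort(rng.choice(cand, size=sig.n_wavelengths, replace=False)))
    return out


def simulate_spectra(
    scenario: ScenarioConfig,
    alignments: dict[str, MarkerAlignment] | None = None,
) -> SpectrumSet:
    """Synthetic FTIR spectra for every strain x condition x replicate.

    Each sample is shared background bands + baseline + planted signals
    + noise. The per-strain
    planted component is ``amplitude[c] * score(strain)`` where the score
    is the 1-D embedding of the source locus' p-distance matrix, so
    strain separation at the planted wavelengths mirrors genetic
    distance. With ``baseline_per_sample=False`` the polynomial baseline
    is shared by all samples of a condition.
    """
    if alignments is None:
        alignments = simulate_alignments(scenario)
    taxa = scenario.taxa
    rng = scenario.rng(200)
    planted_idx = planted_wavelengths(scenario)
    scores = []
    for sig in scenario.planted_signals:
        D = evolutionary_distance(alignments[sig.source_locus], model="p")
        scores.append(strain_scores(D))
    u = np.linspace(-1.0, 1.0, AXIS.size)
    deg_scale = np.array([1.0, 1.0, 0.5, 0.25])
    background = background_spectrum(scenario.background_amplitude)

    def baseline() -> np.ndarray:
        coef = rng.normal(size=4) * scenario.baseline_sd * deg_scale
        return coef[0] + coef[1] * u + coef[2] * u**2 + coef[3] * u**3

    rows, meta = [], []
    for ci, cond in enumerate(scenario.conditions):
        shared = None if scenario.baseline_per_sample else baseline()
        for strain in taxa:
            for rep in range(1, scenario.n_replicates + 1):
                y = background + (baseline() if shared is None else shared)
                for sig, idx, sc in zip(scenario.planted_signals, planted_idx, scores):
                    y[idx] += sig.amplitude_per_condition[ci] * sc[strain]
                if scenario.noise_sd > 0:
                    y += rng.normal(0.0, scenario.noise_sd, size=AXIS.size)
                rows.append(y)
                meta.append(
                    {
                        "sample_id": f"{strain}_{cond:g}_{rep}",
                        "strain": strain,
                        "condition": float(cond),
                        "replicate": rep,
                    }
                )
    return SpectrumSet(AXIS.copy(), np.vstack(rows), pd.DataFrame(meta))


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


def simulate_feature_table(
    scenario: ScenarioConfig,
    n_metabolites: int | None = None,
    alignments: dict[str, MarkerAlignment] | None = None,
) -> FeatureTable:
    """Annotated LC-MS-like feature table (samples x metabolites).

    Log-normal baseline intensities; a fixed random subset of metabolites
    shifts per strain along the axes of the source locus' classical-MDS
    embedding, amplified with dose, with multiplicative log-normal
    replicate noise. The affected metabolites cover the embedding axes
    in a balanced way (equal counts per axis, effect magnitude fixed,
    sign random), so between-strain log-profile distances reproduce the
    locus' genetic distances up to noise — the recoverable plant the
    analysis is meant to find. All intensities are strictly positive.
    ``feature_effect_size=0`` gives a strain-null table.
    """
    n_met = scenario.n_metabolites if n_metabolites is None else int(n_metabolites)
    if n_met < 2:
        raise ValueError("n_metabolites must be >= 2")
    taxa = scenario.taxa
    rng = scenario.rng(300)
    mu = rng.normal(12.0, 0.8, size=n_met)
    k = int(np.floor(scenario.feature_affected_fraction * n_met))
    affected = rng.choice(n_met, size=k, replace=False)
    beta = np.zeros(n_met)
    beta[affected] = scenario.feature_effect_size * rng.choice([-1.0, 1.0], size=k)
    if scenario.feature_source_locus is not None:
        if alignments is None:
            alignments = simulate_alignments(scenario)
        D = evolutionary_distance(
            alignments[scenario.feature_source_locus], model="p"
        )
        emb = strain_embedding(D)
        width = float(np.ptp(emb.to_numpy()))
        coords = emb.to_numpy() / width if width > 0 else emb.to_numpy()
        dims = coords.shape[1]
        # balanced axis assignment: metabolite j responds to one latent
        # axis of metabolic divergence; axes are represented equally
        axis_of = np.zeros(n_met, dtype=int)
        axis_of[affected] = rng.permutation(np.arange(k) % dims)
        shift = pd.DataFrame(
            coords[:, axis_of] * (dims**-0.5), index=list(emb.index)
        )
    else:
        shift = pd.DataFrame(np.zeros((len(taxa), n_met)), index=list(taxa))
    cmax = max(scenario.conditions) if max(scenario.conditions) > 0 else 1.0
    rows, meta = [], []
    for cond in scenario.conditions:
        dose = 1.0 + cond / cmax
        for strain in taxa:
            for rep in range(1, scenario.n_replicates + 1):
                logx = mu + beta * shift.loc[strain].to_numpy() * dose
                logx = logx + rng.normal(0.0, scenario.feature_noise_sd, size=n_met)
                rows.append(np.exp(logx))
                meta.append(
                    {
                        "sample_id": f"{strain}_{cond:g}_{rep}",
                        "strain": strain,
                        "condition": float(cond),
                        "replicate": rep,
                    }
                )
    meta_df = pd.DataFrame(meta)
    data = pd.DataFrame(
        np.vstack(rows),
        index=meta_df["sample_id"],
        columns=[f"met{j + 1:03d}" for j in range(n_met)],
    )
    return FeatureTable(data, meta_df, state="raw")


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------


def simulate_viability(
    scenario: ScenarioConfig,
    mortality_profile: dict[str, dict[float, float]] | None = None,
    ct: int = 1_000_000,
) -> pd.DataFrame:
    """Viable plate counts per strain x condition with Poisson noise.

    ``Cv ~ Poisson(Ct * (1 - M/100))`` with ``Ct`` fixed; the control
    condition (lowest dose) has M = 0 by definition. The default profile
    follows the published strain-specific ethanol mortality pattern;
    strains without a profile entry default to zero mortality.
    """
    profile = DEFAULT_MORTALITY if mortality_profile is None else mortality_profile
    rng = scenario.rng(400)
    control = scenario.conditions[0]
    rows = []
    for strain in scenario.taxa:
        for cond in scenario.conditions:
            m = 0.0 if cond == control else float(
                profile.get(strain, {}).get(cond, 0.0)
            )
            if not 0.0 <= m <= 100.0:
                raise ValueError(
                    f"mortality {m} for {strain} at {cond}% outside [0, 100]"
                )
            cv = int(rng.poisson(ct * (1.0 - m / 100.0)))
            rows.append(
                {"strain": strain, "condition": float(cond), "Cv": cv, "Ct": ct}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario IO and test-support utilities
# ---------------------------------------------------------------------------


def write_scenario_outputs(scenario: ScenarioConfig, outdir) -> dict[str, Path]:
    """Write loci FASTA, spectra/feature/viability CSVs and the scenario echo."""
    outdir = Path(outdir)
    (outdir / "loci").mkdir(parents=True, exist_ok=True)
    alignments = simulate_alignments(scenario)
    paths: dict[str, Path] = {}
    for name, aln in alignments.items():
        p = outdir / "loci" / f"{name}.fasta"
        write_alignment_fasta(aln, p)
        paths[f"locus:{name}"] = p
    sset = simulate_spectra(scenario, alignments)
    paths["spectra"] = outdir / "spectra.csv"
    write_spectra_csv(sset, paths["spectra"])
    table = simulate_feature_table(scenario, alignments=alignments)
    paths["features"] = outdir / "features.csv"
    write_feature_csv(table, paths["features"])
    via = simulate_viability(scenario)
    paths["viability"] = outdir / "viability.csv"
    via.to_csv(paths["viability"], index=False)
    paths["scenario"] = outdir / "scenario.json"
    cfg = dataclasses.asdict(scenario)
    cfg["region_map"] = {k: list(v) for k, v in scenario.region_map.items()}
    cfg["planted_signals"] = [dataclasses.asdict(s) for s in scenario.planted_signals]
    with open(paths["scenario"], "w") as fh:
        json.dump(cfg, fh, indent=2, default=list)
    return paths


def scenario_from_json(source) -> ScenarioConfig:
    """Rebuild a ScenarioConfig from a dict or a JSON file path."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = json.load(fh)
    else:
        cfg = dict(source)
    if "planted_signals" in cfg:
        cfg["planted_signals"] = tuple(
            PlantedSignal(
                region=tuple(s["region"]) if isinstance(s["region"], list) else s["region"],
                source_locus=s["source_locus"],
                amplitude_per_condition=tuple(s["amplitude_per_condition"]),
                n_wavelengths=int(s.get("n_wavelengths", 50)),
            )
            for s in cfg["planted_signals"]
        )
    if "region_map" in cfg:
        cfg["region_map"] = RegionMap(
            {k: tuple(v) for k, v in cfg["region_map"].items()}
        )
    if "locus_specs" in cfg:
        cfg["locus_specs"] = tuple(
            (str(n), int(l), float(r)) for n, l, r in cfg["locus_specs"]
        )
    for key in ("conditions",):
        if key in cfg:
            cfg[key] = tuple(float(x) for x in cfg[key])
    return ScenarioConfig(**cfg)


def random_tree_newick(
    labels, rng: np.random.Generator, branch_scale: float = 1.0
) -> str:
    """Random binary tree over ``labels`` with positive branch lengths."""
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need >= 2 labels")

    def build(group) -> str:
        if len(group) == 1:
            return f"{group[0]}:{rng.uniform(0.1, 1.0) * branch_scale:.6f}"
        cut = int(rng.integers(1, len(group)))
        left, right = group[:cut], group[cut:]
        blen = rng.uniform(0.1, 1.0) * branch_scale
        return f"({build(left)},{build(right)}):{blen:.6f}"

    perm = [labels[i] for i in rng.permutation(len(labels))]
    cut = int(rng.integers(1, len(perm)))
    return f"({build(perm[:cut])},{build(perm[cut:])});"


def random_additive_matrix(
    n_taxa: int, rng: np.random.Generator, branch_scale: float = 1.0
) -> tuple[DistanceMatrix, str]:
    """Additive distance matrix realized by a random tree (plus its newick)."""
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    newick = random_tree_newick(labels, rng, branch_scale)
    tree = _parse_tree(newick)
    return tree_distance_matrix(tree), newick
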