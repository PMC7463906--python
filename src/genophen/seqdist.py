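"""Per-locus evolutionary distances, neighbor-joining and bootstrap.

Implements the genotype side of the pipeline: aligned marker loci are
turned into pairwise distances under closed-form substitution models
(p-distance, JC69, K80, TN93), trees are built with Saitou & Nei's
neighbor-joining, and internal-branch support comes from nonparametric
bootstrap over alignment columns.

Model notes
-----------
* ``JC69``: equal rates; ``d = -(3/4) ln(1 - 4p/3)``.
* ``K80``: transitions vs transversions;
  ``d = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q)``.
* ``TN93``: purine and pyrimidine transitions separated, empirical base
  frequencies; closest closed-form analogue of composite-likelihood
  distances (equal rates among sites, unequal transition rates).

Gap/ambiguity handling defaults to *complete deletion* (drop every column
containing ``-`` or ``N``), matching ape's ``dist.dna`` default; pairwise
deletion is available by flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distmat import DistanceMatrix

__all__ = [
    "MarkerAlignment",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "evolutionary_distance",
    "concatenate",
    "neighbor_joining",
    "bootstrap_support",
    "tree_distance_matrix",
    "tree_bipartitions",
    "write_newick",
    "read_newick",
]

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN-")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
MODELS = ("p", "JC69", "K80", "TN93")


@dataclass(frozen=True)
class MarkerAlignment:
    """One aligned locus: equal-length IUPAC DNA sequences keyed by taxon."""

    locus_name: str
    taxa: tuple[str, ...]
    sequences: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxa)
        seqs = tuple(str(s).upper() for s in self.sequences)
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "sequences", seqs)
        if len(taxa) != len(seqs):
            raise ValueError("taxa and sequences differ in count")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels")
        if not seqs:
            raise ValueError("empty alignment")
        L = len(seqs[0])
        if L < 1:
            raise ValueError("zero-length alignment")
        for t, s in zip(taxa, seqs):
            if len(s) != L:
                raise ValueError(
                    f"ragged alignment: sequence for {t!r} has length "
                    f"{len(s)}, expected {L}"
                )
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in {t!r}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def codes(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_taxa, length)."""
        lut = np.full(128, 255, dtype=np.uint8)
        for ch, v in _CODE.items():
            lut[ord(ch)] = v
        return np.vstack(
            [lut[np.frombuffer(s.encode(), dtype=np.uint8)] for s in self.sequences]
        )


def read_alignment_fasta(path, locus_name: str | None = None) -> MarkerAlignment:
    """Read an aligned multi-FASTA; preserves order, uppercases, validates."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    taxa, seqs = [], []
    for rec in records:
        if rec.id in taxa:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        taxa.append(rec.id)
        seqs.append(str(rec.seq))
    return MarkerAlignment(locus_name or path.stem, tuple(taxa), tuple(seqs))


def write_alignment_fasta(aln: MarkerAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="") for t, s in zip(aln.taxa, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def concatenate(alignments, name: str | None = None) -> MarkerAlignment:
    """Concatenate loci sharing the same taxon set (order of the first)."""
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments to concatenate")
    ref = alignments[0]
    parts = {t: [] for t in ref.taxa}
    for aln in alignments:
        if set(aln.taxa) != set(ref.taxa):
            missing = sorted(set(ref.taxa) - set(aln.taxa))
            extra = sorted(set(aln.taxa) - set(ref.taxa))
            raise ValueError(
                f"taxon-set mismatch in {aln.locus_name!r}: "
                f"missing={missing} extra={extra}"
            )
        lookup = dict(zip(aln.taxa, aln.sequences))
        for t in ref.taxa:
            parts[t].append(lookup[t])
    return MarkerAlignment(
        name or "_".join(a.locus_name for a in alignments),
        ref.taxa,
        tuple("".join(parts[t]) for t in ref.taxa),
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _pair_distance(a: np.ndarray, b: np.ndarray, model: str, pair: tuple[str, str]) -> float:
    """Distance between two encoded sequences over their shared valid sites."""
    valid = (a < 4) & (b < 4)
    m = int(valid.sum())
    if m == 0:
        raise ValueError(f"no comparable sites for pair {pair}")
    aa, bb = a[valid], b[valid]
    diff = aa != bb
    p = float(diff.mean())
    if model == "p":
        return p
    if model == "JC69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise ValueError(f"JC69 saturation (p={p:.4f}) for pair {pair}")
        return -0.75 * math.log(arg)
    purine_a = (aa == 0) | (aa == 2)
    purine_b = (bb == 0) | (bb == 2)
    transition = diff & (purine_a == purine_b)
    P = float(transition.mean())
    Q = p - P
    if model == "K80":
        a1 = 1.0 - 2.0 * P - Q
        a2 = 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            raise ValueError(f"K80 saturation (P={P:.4f}, Q={Q:.4f}) for pair {pair}")
        return -0.5 * math.log(a1) - 0.25 * math.log(a2)
    if model == "TN93":
        counts = np.bincount(np.concatenate([aa, bb]), minlength=4)[:4]
        piA, piC, piG, piT = counts / (2.0 * m)
        piR, piY = piA + piG, piC + piT
        if piA * piG == 0 or piT * piC == 0:
            raise ValueError(
                f"TN93 undefined (missing purine or pyrimidine) for pair {pair}"
            )
        P1 = float((transition & purine_a).mean())  # A<->G
        P2 = P - P1  # C<->T
        k1 = 2.0 * piA * piG / piR
        k2 = 2.0 * piT * piC / piY
        k3 = 2.0 * (piR * piY - piA * piG * piY / piR - piT * piC * piR / piY)
        a1 = 1.0 - P1 / k1 - Q / (2.0 * piR)
        a2 = 1.0 - P2 / k2 - Q / (2.0 * piY)
        a3 = 1.0 - Q / (2.0 * piR * piY)
        if a1 <= 0 or a2 <= 0 or a3 <= 0:
            raise ValueError(f"TN93 saturation for pair {pair}")
        return -k1 * math.log(a1) - k2 * math.log(a2) - k3 * math.log(a3)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def _distances_from_codes(
    codes: np.ndarray, taxa: tuple[str, ...], model: str, deletion: str
) -> DistanceMatrix:
    if deletion == "complete":
        keep = np.all(codes < 4, axis=0)
        codes = codes[:, keep]
        if codes.shape[1] == 0:
            raise ValueError("no comparable sites after complete deletion")
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _pair_distance(codes[i], codes[j], model, (taxa[i], taxa[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa, values)


def evolutionary_distance(
    aln: MarkerAlignment, model: str = "K80", deletion: str = "complete"
) -> DistanceMatrix:
    """Pairwise substitutions-per-site distances for one locus.

    Parameters
    ----------
    model
        One of ``p``, ``JC69``, ``K80``, ``TN93``.
    deletion
        ``complete`` drops every column containing a gap or ``N``;
        ``pairwise`` drops them per sequence pair.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least two taxa")
    return _distances_from_codes(aln.codes(), aln.taxa, model, deletion)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining tree from a distance matrix.

    Exact on additive distances (path-length matrix reproduces the input).
    Negative branch lengths are kept, not clamped. Ties in the Q-matrix
    minimisation break to the lowest (row, column) index pair of the
    current agglomeration step, which makes the result deterministic.
    Returns an unrooted :class:`dendropy.Tree` with a trifurcating seed
    node (for n >= 4).
    """
    n = D.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    ns = dendropy.TaxonNamespace(list(D.labels))
    nodes = [dendropy.Node(taxon=ns.get_taxon(l)) for l in D.labels]
    dist = D.values.copy()

    def join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        return parent

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        Q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major => lowest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = dist[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dist[i, j] - li
        parent = join(i, j, li, lj)
        d_new = (dist[i, :] + dist[j, :] - dist[i, j]) / 2.0
        dist[i, :] = d_new
        dist[:, i] = d_new
        dist[i, i] = 0.0
        nodes[i] = parent
        dist = np.delete(np.delete(dist, j, axis=0), j, axis=1)
        del nodes[j]

    # three-point formulas for the final trifurcation
    d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
    center = dendropy.Node()
    for k, ek in ((0, (d01 + d02 - d12) / 2), (1, (d01 + d12 - d02) / 2), (2, (d02 + d12 - d01) / 2)):
        center.add_child(nodes[k])
        nodes[k].edge.length = ek
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=center)
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix (sums branch lengths, sign kept)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = tuple(sorted(l.taxon.label for l in tree.leaf_node_iter()))
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted splits as frozensets of the two leaf-label sides."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits: set[frozenset] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        other = leaves - below
        if len(below) >= 2 and len(other) >= 2:
            splits.add(frozenset({below, other}))
    return splits


def bootstrap_support(
    aln: MarkerAlignment,
    model: str = "K80",
    deletion: str = "complete",
    n_reps: int = 1000,
    seed: int | None = None,
) -> dendropy.Tree:
    """NJ tree with internal-node bootstrap supports (percent of replicates).

    Columns are resampled with replacement ``n_reps`` times; each replicate
    is rebuilt with the same distance model and NJ; support of an internal
    edge of the full-data tree is the percentage of successful replicates
    whose tree contains the same bipartition. Replicates whose distances
    fail (e.g. saturation) are skipped, counted and logged; supports are
    percentages of the successful replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = neighbor_joining(evolutionary_distance(aln, model, deletion))
    targets = tree_bipartitions(full)
    counts = {s: 0 for s in targets}
    codes = aln.codes()
    L = aln.length
    rng = np.random.default_rng(seed)
    skipped = 0
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        try:
            D = _distances_from_codes(codes[:, idx], aln.taxa, model, deletion)
            rep = neighbor_joining(D)
        except ValueError:
            skipped += 1
            continue
        found = tree_bipartitions(rep)
        for s in targets:
            if s in found:
                counts[s] += 1
    ok = n_reps - skipped
    if skipped:
        logger.warning("bootstrap: %d of %d replicates skipped", skipped, n_reps)
    if ok == 0:
        raise ValueError("all bootstrap replicates failed")
    leaves = frozenset(aln.taxa)
    for nd in full.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        key = frozenset({below, leaves - below})
        if key in counts:
            nd.label = str(int(round(100.0 * counts[key] / ok)))
    return full


def write_newick(tree: dendropy.Tree, path) -> None:
    """Standard Newick with branch lengths; supports as internal labels."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
    )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
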