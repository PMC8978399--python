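"""Pairwise distances, neighbor-joining trees and clade assignment for
transposase (TPase) comparative analysis.

Protein p-distances and Tamura (1992) three-parameter nucleotide distances
(optionally gamma-corrected) are computed on pre-aligned sequences;
neighbor joining (via scikit-bio) turns a distance matrix into an unrooted
Newick tree; queries are assigned to reference clades by the nearest-
reference rule. The published two-clade structure of Chenopodium TPases
(two well-separated lineages coexisting in single genomes) is the use
case: clade separation, not deep-branch resolution, is the claim this
desk-scale stand-in supports.

The Tamura (1992) distance corrects for transition/transversion bias and
GC-content bias: with transition proportion P, transversion proportion Q
and h = 2*theta*(1-theta) for GC fraction theta,

    d = -h * ln(1 - P/h - Q) - (1 - h)/2 * ln(1 - 2Q)

and the continuous-gamma variant with shape a replaces -ln(x) by
a * (x**(-1/a) - 1). Saturated pairs (non-positive log arguments) are
flagged as ``inf`` rather than raising; neighbor joining refuses matrices
still containing them, after excluding flagged taxa with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "CladeAssignment",
    "p_distance_protein",
    "t92_distance",
    "distance_matrix",
    "nj_tree",
    "assign_clade",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_DNA = frozenset("ACGT")
_GAPLIKE = frozenset("-.")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.d)
        if not np.allclose(self.d[finite], self.d.T[finite.T]):
            raise ValueError("matrix must be symmetric")

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        """Label pairs whose distance is flagged as saturated (inf)."""
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.d[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(f"{lab:<10s} " +
                         " ".join(f"{x:.6f}" for x in row) + "\n")


@dataclass(frozen=True)
class CladeAssignment:
    query_label: str
    clade: str  # cladeI | cladeII | ... | unassigned
    nearest_reference: str
    distance: float


def p_distance_protein(a: str, b: str) -> float:
    """Proportion of differing sites between two aligned protein
    sequences; columns with a gap in either sequence are excluded."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    compared = 0
    diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        compared += 1
        diff += x != y
    if compared == 0:
        raise ValueError("zero comparable sites")
    return diff / compared


def t92_distance(a: str, b: str, gamma_shape: Optional[float] = None) -> float:
    """Tamura (1992) three-parameter distance between aligned DNA
    sequences; see the module docstring for the closed form. Sites where
    either sequence is not a plain A/C/G/T are excluded pairwise.
    Saturation returns ``math.inf`` (flagged, not raised)."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = a.upper(), b.upper()
    n = 0
    transitions = 0
    transversions = 0
    gc = 0
    for x, y in zip(a, b):
        if x not in _DNA or y not in _DNA:
            continue
        n += 1
        gc += (x in "GC") + (y in "GC")
        if x != y:
            if (x in _PURINES) == (y in _PURINES):
                transitions += 1
            else:
                transversions += 1
    if n == 0:
        raise ValueError("zero comparable sites")
    P = transitions / n
    Q = transversions / n
    theta = gc / (2 * n)
    h = 2.0 * theta * (1.0 - theta)
    if h == 0.0:
        # no G/C content at all: transitions cannot be corrected for
        if P > 0:
            return math.inf
        arg2 = 1.0 - 2.0 * Q
        if arg2 <= 0:
            return math.inf
        if gamma_shape is not None:
            return 0.5 * gamma_shape * (arg2 ** (-1.0 / gamma_shape) - 1.0)
        return -0.5 * math.log(arg2)
    arg1 = 1.0 - P / h - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return math.inf
    if gamma_shape is not None:
        ginv = 1.0 / gamma_shape
        return (h * gamma_shape * (arg1 ** -ginv - 1.0)
                + 0.5 * (1.0 - h) * gamma_shape * (arg2 ** -ginv - 1.0))
    return -h * math.log(arg1) - 0.5 * (1.0 - h) * math.log(arg2)


_MODELS = {"p_protein", "t92"}


def _pair_distance(a: str, b: str, model: str,
                   gamma_shape: Optional[float] = None) -> float:
    if model == "p_protein":
        return p_distance_protein(a, b)
    if model == "t92":
        return t92_distance(a, b, gamma_shape)
    raise ValueError(f"unknown model {model!r}; expected one of {_MODELS}")


def distance_matrix(seqs: Sequence[tuple[str, str]], model: str,
                    gamma_shape: Optional[float] = None) -> DistanceMatrix:
    """All pairwise distances among labeled pre-aligned sequences."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for _, s in seqs}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    labels = [lab for lab, _ in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(seqs[i][1], seqs[j][1],
                                               model, gamma_shape)
    return DistanceMatrix(labels=labels, d=d)


def nj_tree(m: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, as an unrooted Newick
    string with branch lengths. Taxa carrying saturated (inf) distances
    are excluded with a warning before agglomeration; ties break by the
    label order of the input matrix."""
    labels = list(m.labels)
    d = m.d.copy()
    while True:
        bad = np.count_nonzero(~np.isfinite(d), axis=1)
        if not bad.any():
            break
        drop = int(np.argmax(bad))
        warnings.warn(
            f"excluding {labels[drop]!r} from NJ: saturated distance",
            stacklevel=2)
        keep = [i for i in range(len(labels)) if i != drop]
        labels = [labels[i] for i in keep]
        d = d[np.ix_(keep, keep)]
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    from skbio import DistanceMatrix as _SkbioDM
    from skbio.tree import nj as _sk_nj

    tree = _sk_nj(_SkbioDM(d, ids=labels))
    return str(tree).strip()


def assign_clade(query: tuple[str, str],
                 references: Sequence[tuple[str, str, str]], model: str,
                 cutoff: float,
                 gamma_shape: Optional[float] = None) -> CladeAssignment:
    """Nearest-reference clade assignment.

    ``references`` holds (label, clade, sequence) triples; both clades
    must be represented. The query takes the clade of its nearest
    reference when that distance is <= ``cutoff``, else ``unassigned``
    (equidistance beyond the cutoff is therefore unassigned too). Ties at
    the minimum distance resolve to the first reference in input order.
    """
    if not references:
        raise ValueError("references must be non-empty")
    clades = {c for _, c, _ in references}
    if len(clades) < 2:
        raise ValueError("both clades must be represented in references")
    qlabel, qseq = query
    best_label, best_clade, best_d = None, None, math.inf
    for label, clade, seq in references:
        dist = _pair_distance(qseq, seq, model, gamma_shape)
        if dist < best_d:
            best_label, best_clade, best_d = label, clade, dist
    if best_d <= cutoff:
        return CladeAssignment(qlabel, best_clade, best_label, best_d)
    return CladeAssignment(qlabel, "unassigned", best_label, best_d)
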