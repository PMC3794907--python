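"""Time-calibrated phylogenies and trait covariance matrices.

Under Brownian motion (BM) a continuous trait diffuses along every branch
with increment variance rate x branch length, so the tip values of one
gene are multivariate normal with covariance sigma^2 * V, where V_ij is
the time shared from the root down to the most recent common ancestor of
tips i and j.  A lineage-specific rate shift multiplies the rate on a
designated subtree (its stem branch plus all branches inside it) by a
constant r, which is equivalent to stretching those branch lengths by r.

Under a fixed-root Ornstein-Uhlenbeck (OU) process with constraint
strength theta (units 1/time), the covariance becomes

    V_ij(theta) = exp(-2 theta (T - t_ij)) (1 - exp(-2 theta t_ij)) / (2 theta)

with T the tree height and t_ij the shared time (t_ii = T).  As theta -> 0
this converges elementwise to the BM covariance, so the BM model is nested
within the OU family.

Because the ancestral trait value is unknown, inference operates on
contrasts against a reference tip; the corresponding contrast covariance
is V'_jk = V_jk - V_j,ref - V_k,ref + V_ref,ref over the non-reference
tips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import TreeError

#: relative tolerance on root-to-tip path length spread
ULTRAMETRIC_RTOL = 1e-6

#: pectinate four-taxon tree mirroring the Saccharomyces sensu stricto
#: topology (S. cerevisiae, S. paradoxus, S. mikatae, S. bayanus), height
#: 0.5 in substitution-like time units as for a calibrated yeast genome
#: tree; used as the default simulation fixture.  BM inferences are
#: invariant to the overall time scale (it is absorbed by the rate
#: scale), but the OU constraint has units 1/time, so the height fixes
#: which constraint strengths are identifiable.
YEAST_NEWICK = "(((cer:0.125,par:0.125):0.125,mik:0.25):0.25,bay:0.5);"


class CalibratedTree:
    """Rooted ultrametric phylogeny with branch lengths in time units.

    Nodes are stored in preorder (parents before children); tips keep
    their order of first appearance in the Newick string, which fixes the
    row/column order of every covariance matrix built from the tree.

    Parameters
    ----------
    parents : sequence of int
        Parent node index for each node, ``-1`` for the root.
    lengths : sequence of float
        Branch length above each node (ignored for the root).
    tip_names : sequence of str or None
        Tip label per node, ``None`` for internal nodes.
    """

    def __init__(
        self,
        parents: Sequence[int],
        lengths: Sequence[float],
        tip_names: Sequence[str | None],
    ):
        self._parents = np.asarray(parents, dtype=int)
        self._lengths = np.asarray(lengths, dtype=float)
        n_nodes = len(self._parents)
        if len(lengths) != n_nodes or len(tip_names) != n_nodes:
            raise TreeError("parents, lengths and tip_names must have equal length")

        tip_nodes = [i for i, nm in enumerate(tip_names) if nm is not None]
        self.tip_names: tuple[str, ...] = tuple(tip_names[i] for i in tip_nodes)
        self._tip_nodes = np.asarray(tip_nodes, dtype=int)
        if len(self.tip_names) < 2:
            raise TreeError("a calibrated tree needs at least 2 tips")
        if len(set(self.tip_names)) != len(self.tip_names):
            raise TreeError("tip names must be unique")
        if np.any(self._lengths[self._parents >= 0] < 0):
            raise TreeError("branch lengths must be nonnegative")

        # node depths (time from the root); preorder guarantees parents first
        depths = np.zeros(n_nodes)
        for v in range(n_nodes):
            p = self._parents[v]
            if p >= 0:
                depths[v] = depths[p] + self._lengths[v]
        self._depths = depths

        tip_depths = depths[self._tip_nodes]
        self.height: float = float(tip_depths.max())
        if self.height <= 0:
            raise TreeError("tree height must be positive")
        if np.any(np.abs(tip_depths - self.height) > ULTRAMETRIC_RTOL * self.height):
            raise TreeError(
                "tree is not ultrametric: root-to-tip path lengths "
                f"{tip_depths.tolist()} differ beyond relative tolerance "
                f"{ULTRAMETRIC_RTOL}"
            )

        # tip-index set below each node (postorder accumulation)
        tip_pos = {v: i for i, v in enumerate(tip_nodes)}
        below: list[list[int]] = [[] for _ in range(n_nodes)]
        for v in range(n_nodes - 1, -1, -1):
            if v in tip_pos:
                below[v].append(tip_pos[v])
            p = self._parents[v]
            if p >= 0:
                below[p].extend(below[v])
        self._clade_idx = [np.asarray(sorted(b), dtype=int) for b in below]
        # clade lookup: frozenset of tip names -> node, non-root nodes only
        self._clade_nodes: dict[frozenset[str], int] = {}
        for v in range(n_nodes):
            if self._parents[v] >= 0:
                key = frozenset(self.tip_names[i] for i in self._clade_idx[v])
                self._clade_nodes.setdefault(key, v)

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "CalibratedTree":
        """Parse a Newick string into a validated :class:`CalibratedTree`."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises various error types
            raise TreeError(f"malformed Newick string: {exc}") from exc

        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parents, lengths, names = [], [], []
        for nd in nodes:
            p = index[id(nd.parent_node)] if nd.parent_node is not None else -1
            length = nd.edge.length
            if p == -1:
                length = 0.0  # root edge length is ignored
            elif length is None:
                raise TreeError("missing branch length on a non-root edge")
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError("every tip must be labeled")
                names.append(nd.taxon.label)
            else:
                names.append(None)
            parents.append(p)
            lengths.append(float(length))
        return cls(parents, lengths, names)

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def tip_index(self, name: str) -> int:
        try:
            return self.tip_names.index(name)
        except ValueError:
            raise TreeError(f"{name!r} is not a tip of this tree") from None

    def find_clade(self, tips: Iterable[str]) -> int:
        """Node index whose descendant tip set equals ``tips``.

        Raises :class:`TreeError` if the set is not a proper monophyletic
        clade of this tree.
        """
        key = frozenset(tips)
        unknown = key - set(self.tip_names)
        if unknown:
            raise TreeError(f"unknown tips in clade: {sorted(unknown)}")
        if len(key) == self.n_tips:
            raise TreeError("a rate-shift clade must be a proper subset of the tips")
        node = self._clade_nodes.get(key)
        if node is None:
            raise TreeError(f"tip set {sorted(key)} is not a clade of this tree")
        return node

    def shared_times(self) -> np.ndarray:
        """Matrix t with t_ij = shared time from root to the MRCA of tips
        i and j, and t_ii = the tip's root-to-tip depth (~ tree height)."""
        n = self.n_tips
        t = np.zeros((n, n))
        for v in range(len(self._parents)):
            if self._parents[v] < 0:
                continue
            idx = self._clade_idx[v]
            t[np.ix_(idx, idx)] += self._lengths[v]
        return t

    def patristic_distance(self, a: str, b: str) -> float:
        """Path length between two tips along the tree."""
        t = self.shared_times()
        i, j = self.tip_index(a), self.tip_index(b)
        return float(t[i, i] + t[j, j] - 2.0 * t[i, j])

    def __repr__(self) -> str:  # pragma: no cover
        return f"CalibratedTree(n_tips={self.n_tips}, height={self.height:.6g})"


def parse_newick(text: str) -> CalibratedTree:
    """Parse and validate a Newick string (see :class:`CalibratedTree`)."""
    return CalibratedTree.from_newick(text)


def yeast_fixture_tree() -> CalibratedTree:
    """The packaged unit-height four-taxon Saccharomyces-like tree."""
    return parse_newick(YEAST_NEWICK)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RateShiftSpec:
    """A lineage-specific rate shift: every branch of ``clade`` (its stem
    plus all branches inside) evolves at ``r`` times the background rate."""

    clade: tuple[str, ...]
    r: float

    def __post_init__(self):
        if self.r <= 0:
            raise TreeError("rate-shift multiplier r must be positive")
        object.__setattr__(self, "clade", tuple(self.clade))


@dataclass
class CovarianceMatrix:
    """Symmetric covariance matrix with provenance tags.

    ``kind`` is ``"tip"`` (one row per tip) or ``"contrast"`` (one row per
    non-reference tip); ``model_tag`` is ``"BM"`` or ``"OU"``.
    """

    values: np.ndarray
    kind: str
    model_tag: str
    labels: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise TreeError("covariance matrix must be square")
        if not np.allclose(self.values, self.values.T, rtol=0, atol=1e-12):
            raise TreeError("covariance matrix must be symmetric")


def _affected_mask(tree: CalibratedTree, clade: Iterable[str]) -> np.ndarray:
    """Boolean per node: True when the node's edge lies within the shift
    clade (stem included)."""
    tree.find_clade(clade)  # validates
    key = set(clade)
    n_nodes = len(tree._parents)
    mask = np.zeros(n_nodes, dtype=bool)
    for v in range(n_nodes):
        if tree._parents[v] < 0:
            continue
        names = {tree.tip_names[i] for i in tree._clade_idx[v]}
        mask[v] = names <= key
    return mask


def bm_shift_components(
    tree: CalibratedTree, clade: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose the shifted BM covariance as ``V(r) = base + r * scaled``.

    ``scaled`` collects the contributions of the branches affected by the
    shift; the decomposition is linear in r, which model fitting exploits.
    """
    mask = _affected_mask(tree, clade)
    n = tree.n_tips
    base = np.zeros((n, n))
    scaled = np.zeros((n, n))
    for v in range(len(tree._parents)):
        if tree._parents[v] < 0:
            continue
        idx = tree._clade_idx[v]
        target = scaled if mask[v] else base
        target[np.ix_(idx, idx)] += tree._lengths[v]
    return base, scaled


def bm_covariance(
    tree: CalibratedTree, shift: RateShiftSpec | None = None
) -> CovarianceMatrix:
    """Brownian-motion tip covariance: V_ij = shared root-to-MRCA time,
    with branch lengths inside the shift clade (stem included) multiplied
    by r when a shift is supplied."""
    if shift is None:
        values = tree.shared_times()
    else:
        base, scaled = bm_shift_components(tree, shift.clade)
        values = base + shift.r * scaled
    return CovarianceMatrix(values, kind="tip", model_tag="BM", labels=tree.tip_names)


def _ou_values_and_grad(
    tree: CalibratedTree, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    t = tree.shared_times()
    np.fill_diagonal(t, tree.height)
    big_t = tree.height
    a = big_t - t  # time not shared, 0 on the diagonal
    ea = np.exp(-2.0 * theta * a)
    et = np.exp(-2.0 * theta * big_t)
    # V = (exp(-2 theta a) - exp(-2 theta T)) / (2 theta)
    values = (ea - et) / (2.0 * theta)
    grad = (-2.0 * a * ea + 2.0 * big_t * et) / (2.0 * theta) - (ea - et) / (
        2.0 * theta**2
    )
    return values, grad


def ou_covariance(tree: CalibratedTree, theta: float) -> CovarianceMatrix:
    """Fixed-root Ornstein-Uhlenbeck tip covariance.

    V_ij = exp(-2 theta (T - t_ij)) (1 - exp(-2 theta t_ij)) / (2 theta),
    with t_ii = T.  Converges elementwise to the BM covariance as
    theta -> 0, and to diag(1 / (2 theta)) as theta -> infinity.
    """
    if theta <= 0:
        raise TreeError("OU constraint strength theta must be positive")
    values, _ = _ou_values_and_grad(tree, theta)
    return CovarianceMatrix(values, kind="tip", model_tag="OU", labels=tree.tip_names)


def contrast_values(values: np.ndarray, ref: int) -> np.ndarray:
    """Raw (n-1)x(n-1) covariance of contrasts X_j - X_ref (ndarray in,
    ndarray out); rows keep the original order of the non-reference tips."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if not 0 <= ref < n:
        raise TreeError(f"reference index {ref} out of range for {n} tips")
    keep = [i for i in range(n) if i != ref]
    sub = values[np.ix_(keep, keep)]
    return sub - values[keep, ref][:, None] - values[keep, ref][None, :] + values[ref, ref]


def contrast_covariance(V: CovarianceMatrix, ref: int | str) -> CovarianceMatrix:
    """Covariance of the contrasts Y_j = X_j - X_ref.

    V'_jk = V_jk - V_j,ref - V_k,ref + V_ref,ref for j, k != ref.  The
    transform eliminates the unknown ancestral mean and is positive
    definite whenever all branch lengths are positive.
    """
    if V.kind != "tip":
        raise TreeError("contrast_covariance expects a tip-space covariance")
    if isinstance(ref, str):
        try:
            ref_idx = V.labels.index(ref)
        except ValueError:
            raise TreeError(f"{ref!r} is not a label of this matrix") from None
    else:
        ref_idx = ref
    out = contrast_values(V.values, ref_idx)
    labels = tuple(lab for i, lab in enumerate(V.labels) if i != ref_idx)
    return CovarianceMatrix(out, kind="contrast", model_tag=V.model_tag, labels=labels)


def enumerate_shift_models(tree: CalibratedTree) -> list[tuple[str, ...]]:
    """All candidate rate-shift subtrees: every proper clade of the tree,
    keeping exactly one member of each complement-equivalent pair.

    A shift (c, r) and a shift on the complement of c below the root with
    multiplier 1/r give identical maximized marginal likelihoods, because
    a global rescaling of the covariance is absorbed by the free scale
    parameter of the rate distribution; one member of each such pair is
    redundant.  Clades are returned sorted by size, then by tip order; the
    smaller member of each complement pair is retained.
    """
    all_tips = frozenset(tree.tip_names)
    order = {name: i for i, name in enumerate(tree.tip_names)}
    clades = sorted(
        {key for key in tree._clade_nodes if len(key) < tree.n_tips},
        key=lambda c: (len(c), sorted(order[t] for t in c)),
    )
    clade_set = set(clades)
    kept: list[frozenset[str]] = []
    kept_set: set[frozenset[str]] = set()
    for c in clades:
        comp = all_tips - c
        if comp in clade_set and comp in kept_set:
            continue
        kept.append(c)
        kept_set.add(c)
    return [tuple(sorted(c, key=order.__getitem__)) for c in kept]
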