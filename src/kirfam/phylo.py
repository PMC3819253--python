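"""Distance estimation, neighbor joining, bootstrap and model selection.

Distances follow the Kimura two-parameter (K2P) and Tamura-Nei (TN93)
corrections, optionally gamma-adjusted. Trees are built by Saitou-Nei
neighbor joining with deterministic tie-breaking; branch supports come from
column-resampling bootstrap. Likelihoods use Felsenstein pruning on a fixed
topology and serve only substitution-model selection by BIC -- topology
search is intentionally out of scope.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .records import Alignment

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """Distance correction outside the log domain (saturated pair)."""


@dataclass
class DistanceResult:
    P: float          # transition proportion
    Q: float          # transversion proportion
    d: float          # substitutions per site
    variance: float
    n_sites: int
    saturated: bool = False


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

def _pair_counts(a: str, b: str) -> tuple[int, int, int, int, np.ndarray]:
    """Return (n_sites, purine transitions, pyrimidine transitions,
    transversions, base counts) over sites where both sequences are
    unambiguous nucleotides."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    counts = np.zeros(4)
    n = ts1 = ts2 = tv = 0
    for x, y in zip(a, b):
        if x not in _BASE_INDEX or y not in _BASE_INDEX:
            continue
        n += 1
        counts[_BASE_INDEX[x]] += 1
        counts[_BASE_INDEX[y]] += 1
        if x != y:
            if (x in _PURINES) == (y in _PURINES):
                if x in _PURINES:
                    ts1 += 1
                else:
                    ts2 += 1
            else:
                tv += 1
    return n, ts1, ts2, tv, counts


def k2p_distance(
    seq_a: str, seq_b: str, gamma_alpha: float | None = None
) -> DistanceResult:
    """Kimura two-parameter distance, optionally gamma-rate adjusted.

    d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q); with gamma shape a the logs are
    replaced by the a((.)^(-1/a)-1) transform.
    """
    n, ts1, ts2, tv, _ = _pair_counts(seq_a, seq_b)
    if n < 1:
        raise ValueError("no comparable sites after filtering")
    return _k2p_result((ts1 + ts2) / n, tv / n, n, gamma_alpha)


def _k2p_result(
    P: float, Q: float, n: int, gamma_alpha: float | None
) -> DistanceResult:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return DistanceResult(P, Q, math.inf, math.inf, n, saturated=True)
    if gamma_alpha is None:
        d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
        c1, c2 = 1.0 / w1, 1.0 / w2
    else:
        a = gamma_alpha
        d = (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + (a / 4.0) * (
            w2 ** (-1.0 / a) - 1.0
        )
        c1 = w1 ** (-1.0 / a - 1.0)
        c2 = w2 ** (-1.0 / a - 1.0)
    c3 = 0.5 * (c1 + c2)
    var = (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / n
    return DistanceResult(P, Q, max(d, 0.0), var, n)


def tn93_distance(
    seq_a: str, seq_b: str, gamma_alpha: float | None = None
) -> DistanceResult:
    """Tamura-Nei (TN93) distance with observed base frequencies."""
    n, ts1, ts2, tv, counts = _pair_counts(seq_a, seq_b)
    if n < 1:
        raise ValueError("no comparable sites after filtering")
    return _tn93_result(
        ts1 / n, ts2 / n, tv / n, counts / counts.sum(), n, gamma_alpha
    )


def _tn93_result(
    P1: float, P2: float, Q: float, freqs: np.ndarray, n: int,
    gamma_alpha: float | None,
) -> DistanceResult:
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) <= 0:
        # degenerate composition: fall back to K2P (equal-frequency limit)
        return _k2p_result(P1 + P2, Q, n, gamma_alpha)
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return DistanceResult(P1 + P2, Q, math.inf, math.inf, n, saturated=True)
    if gamma_alpha is None:
        d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
        c1, c2, c3w = k1 / w1, k2 / w2, k3 / w3
    else:
        a = gamma_alpha
        d = a * (
            k1 * (w1 ** (-1.0 / a) - 1.0)
            + k2 * (w2 ** (-1.0 / a) - 1.0)
            + k3 * (w3 ** (-1.0 / a) - 1.0)
        )
        c1 = k1 * w1 ** (-1.0 / a - 1.0)
        c2 = k2 * w2 ** (-1.0 / a - 1.0)
        c3w = k3 * w3 ** (-1.0 / a - 1.0)
    # delta-method variance: d is a function of (P1, P2, Q)
    dP1 = c1 / k1
    dP2 = c2 / k2
    dQ = c1 / (2.0 * gR) + c2 / (2.0 * gY) + c3w / (2.0 * gR * gY)
    mean = dP1 * P1 + dP2 * P2 + dQ * Q
    var = (dP1 * dP1 * P1 + dP2 * dP2 * P2 + dQ * dQ * Q - mean * mean) / n
    return DistanceResult(P1 + P2, Q, max(d, 0.0), var, n)


_DISTANCE_FUNCS = {"k2p": k2p_distance, "tn93": tn93_distance}


def distance_matrix(
    alignment: Alignment,
    model: str = "k2p",
    gamma_alpha: float | None = None,
    gap_policy: str = "complete_deletion",
) -> pd.DataFrame:
    """Square symmetric distance matrix (substitutions/site) over members."""
    if model not in _DISTANCE_FUNCS:
        raise ValueError(f"unknown distance model {model!r}")
    if gap_policy == "complete_deletion":
        aln, _ = complete_deletion(alignment)
    else:
        aln = alignment
    ids = aln.ids
    n = len(ids)
    enc = _encode_alignment(aln)
    purine = (enc == 0) | (enc == 2)
    valid_rows = enc >= 0
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        valid = valid_rows[i] & valid_rows[j]
        nv = int(valid.sum())
        if nv < 1:
            raise ValueError(f"no comparable sites for pair ({ids[i]},{ids[j]})")
        diff = valid & (enc[i] != enc[j])
        ts = diff & (purine[i] == purine[j])
        ts1 = int((ts & purine[i]).sum())
        ts2 = int(ts.sum()) - ts1
        tv = int(diff.sum()) - ts1 - ts2
        if model == "k2p":
            res = _k2p_result((ts1 + ts2) / nv, tv / nv, nv, gamma_alpha)
        else:
            counts = (
                np.bincount(enc[i][valid], minlength=4)
                + np.bincount(enc[j][valid], minlength=4)
            ).astype(float)
            res = _tn93_result(
                ts1 / nv, ts2 / nv, tv / nv, counts / counts.sum(), nv,
                gamma_alpha,
            )
        if res.saturated:
            logger.warning("saturated pair (%s, %s)", ids[i], ids[j])
        mat[i, j] = mat[j, i] = res.d
    return pd.DataFrame(mat, index=ids, columns=ids)


def complete_deletion(alignment: Alignment) -> tuple[Alignment, np.ndarray]:
    """Drop columns containing any gap or N; return (alignment, kept cols)."""
    m = alignment.to_matrix()
    keep = ~((m == b"-") | (m == b"N")).any(axis=0)
    cols = np.flatnonzero(keep)
    if cols.size == 0:
        raise ValueError("complete deletion removed every column")
    return alignment.take_columns(cols), cols


def site_coverage_filter(
    alignment: Alignment, min_coverage: float = 0.95
) -> tuple[Alignment, np.ndarray]:
    """Remove columns whose non-gap fraction is below ``min_coverage``.

    The boundary is inclusive: a column at exactly the threshold is kept.
    Returns the filtered alignment and the retained original column indices.
    """
    m = alignment.to_matrix()
    cover = 1.0 - ((m == b"-") | (m == b"N")).mean(axis=0)
    cols = np.flatnonzero(cover >= min_coverage - 1e-12)
    if cols.size == 0:
        raise ValueError("site-coverage filter removed every column")
    return alignment.take_columns(cols), cols


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    On an additive matrix the generating topology and branch lengths are
    recovered exactly. Taxa are processed in sorted-label order, and ties in
    the Q criterion break to the smallest (row, column) index pair, making
    the result deterministic and invariant to input ordering; negative
    branch lengths are clamped to zero (and logged). The result is unrooted
    (trifurcating seed node).
    """
    order = sorted(dm.index)
    dm = dm.loc[order, order]
    labels = list(dm.index)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    mat = dm.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        bad = [
            (labels[i], labels[j])
            for i, j in zip(*np.where(~np.isfinite(mat)))
            if i < j
        ]
        raise ValueError(f"non-finite distances for pairs: {bad}")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)

    active = list(range(n))
    D = mat.copy()
    all_nodes = list(nodes)
    edge_lengths: dict[int, float] = {}

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                logger.info("NJ: clamped negative branch length %.3g", x)
            return 0.0
        return x

    while len(active) > 2:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Qm = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Qm, np.inf)
        # deterministic argmin: smallest (i, j) among minima
        qmin = Qm.min()
        ii, jj = next(
            (i, j)
            for i in range(r)
            for j in range(r)
            if i < j and Qm[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin))
        )
        a, b = active[ii], active[jj]
        d_ab = D[a, b]
        va = 0.5 * d_ab + (R[ii] - R[jj]) / (2.0 * (r - 2))
        vb = d_ab - va
        parent = dendropy.Node()
        parent.add_child(all_nodes[a])
        parent.add_child(all_nodes[b])
        all_nodes[a].edge.length = clamp(va)
        all_nodes[b].edge.length = clamp(vb)
        # distances from new node
        new_idx = len(all_nodes)
        all_nodes.append(parent)
        newD = np.zeros((new_idx + 1, new_idx + 1))
        newD[:new_idx, :new_idx] = D
        for k in active:
            if k in (a, b):
                continue
            dk = 0.5 * (D[a, k] + D[b, k] - d_ab)
            newD[new_idx, k] = newD[k, new_idx] = dk
        D = newD
        active = [k for k in active if k not in (a, b)] + [new_idx]

    # join final two (or three, when the loop left a trifurcation)
    seed = dendropy.Node()
    a, b = active
    seed_children = []
    d_ab = D[a, b]
    # attach both remaining nodes to the seed; the one that is a fresh
    # internal node absorbs the full remaining length split evenly only if
    # both are leaves; otherwise give the full distance to the leaf side
    na, nb = all_nodes[a], all_nodes[b]
    seed.add_child(na)
    seed.add_child(nb)
    if na.is_leaf() and nb.is_leaf():
        na.edge.length = clamp(d_ab / 2.0)
        nb.edge.length = clamp(d_ab / 2.0)
    elif na.is_leaf():
        na.edge.length = clamp(d_ab)
        nb.edge.length = 0.0
    else:
        na.edge.length = 0.0
        nb.edge.length = clamp(d_ab)
    # collapse: if one child of seed is internal, merge to a trifurcation
    for child in list(seed.child_nodes()):
        if not child.is_leaf() and child.edge.length == 0.0:
            for gc in list(child.child_nodes()):
                child.remove_child(gc)
                seed.add_child(gc)
            seed.remove_child(child)
    tree.seed_node = seed
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf labels, normalized to
    the side not containing the lexicographically first leaf."""
    leaves = sorted(t.label for t in tree.taxon_namespace)
    ref = leaves[0]
    full = frozenset(leaves)
    parts = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = full - side
        if 1 < len(side) < len(leaves) - 1:
            parts.add(side)
    return parts


def bootstrap_supports(
    alignment: Alignment,
    model: str = "k2p",
    reps: int = 1000,
    seed: int = 0,
    gamma_alpha: float | None = None,
    gap_policy: str = "complete_deletion",
) -> dendropy.Tree:
    """NJ tree with bootstrap percentages on internal nodes.

    Columns are resampled with replacement; support is the percentage of
    replicate NJ trees containing each bipartition of the full-data tree.
    Deterministic for a given seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    dm = distance_matrix(alignment, model, gamma_alpha, gap_policy)
    tree = nj_tree(dm)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    L = alignment.length
    m = alignment.to_matrix()
    ids = alignment.ids
    good = 0
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        rep_aln = Alignment.from_matrix(m[:, cols], ids)
        try:
            rep_dm = distance_matrix(rep_aln, model, gamma_alpha, gap_policy)
            rep_tree = nj_tree(rep_dm)
        except ValueError:
            continue
        good += 1
        for part in _bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1
    leaves = sorted(t.label for t in tree.taxon_namespace)
    ref, full = leaves[0], frozenset(leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = full - side
        if 1 < len(side) < len(leaves) - 1:
            support = 100.0 * counts.get(side, 0) / max(good, 1)
            node.label = f"{support:.0f}"
            node.support = support
    return tree


# ---------------------------------------------------------------------------
# likelihood and model selection
# ---------------------------------------------------------------------------

MODEL_NAMES = ("JC69", "K2P", "HKY85", "TN93", "GTR")

#: free substitution parameters per base model (frequencies counted
#: separately: 3 when estimated from the data)
_N_RATE_PARAMS = {"JC69": 0, "K2P": 1, "HKY85": 1, "TN93": 2, "GTR": 5}
_EMPIRICAL_FREQS = {"JC69": False, "K2P": False, "HKY85": True, "TN93": True,
                    "GTR": True}


@dataclass
class SubstitutionModel:
    name: str
    rates: dict = field(default_factory=dict)
    freqs: np.ndarray | None = None
    gamma_alpha: float | None = None
    p_invariant: float | None = None
    ncat: int = 4

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if self.freqs is None:
            self.freqs = np.full(4, 0.25)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not math.isclose(self.freqs.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("frequencies must sum to 1")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be > 0")

    @property
    def label(self) -> str:
        s = self.name
        if self.gamma_alpha is not None:
            s += "+G"
        if self.p_invariant is not None:
            s += "+I"
        return s

    def n_free_params(self) -> int:
        k = _N_RATE_PARAMS[self.name]
        if _EMPIRICAL_FREQS[self.name]:
            k += 3
        if self.gamma_alpha is not None:
            k += 1
        if self.p_invariant is not None:
            k += 1
        return k

    def rate_matrix(self) -> np.ndarray:
        """Reversible rate matrix scaled to one expected substitution per
        unit branch length."""
        f = self.freqs
        r = self.rates
        ex = np.zeros((4, 4))
        if self.name == "JC69":
            ex[:] = 1.0
        elif self.name in ("K2P", "HKY85"):
            kappa = r.get("kappa", 1.0)
            ex[:] = 1.0
            for i, j in ((0, 2), (1, 3)):  # A-G, C-T
                ex[i, j] = ex[j, i] = kappa
        elif self.name == "TN93":
            ex[:] = 1.0
            ex[0, 2] = ex[2, 0] = r.get("kappa1", 1.0)
            ex[1, 3] = ex[3, 1] = r.get("kappa2", 1.0)
        elif self.name == "GTR":
            pairs = {("A", "C"): "ac", ("A", "G"): "ag", ("A", "T"): "at",
                     ("C", "G"): "cg", ("C", "T"): "ct", ("G", "T"): "gt"}
            for (x, y), key in pairs.items():
                i, j = _BASE_INDEX[x], _BASE_INDEX[y]
                ex[i, j] = ex[j, i] = r.get(key, 1.0)
        np.fill_diagonal(ex, 0.0)
        Q = ex * f[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(f * np.diag(Q)).sum()
        return Q / mu

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, probabilities) of the site-rate mixture."""
        if self.gamma_alpha is not None:
            rates = discrete_gamma_rates(self.gamma_alpha, self.ncat)
            probs = np.full(self.ncat, 1.0 / self.ncat)
        else:
            rates = np.array([1.0])
            probs = np.array([1.0])
        if self.p_invariant is not None:
            p = self.p_invariant
            rates = np.concatenate([[0.0], rates / (1.0 - p)])
            probs = np.concatenate([[p], probs * (1.0 - p)])
        return rates, probs


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability categories of a mean-1
    gamma distribution (shape = rate = alpha)."""
    qs = np.arange(1, ncat) / ncat
    bounds = np.concatenate([[0.0], gamma_dist.ppf(qs, alpha, scale=1.0 / alpha),
                             [np.inf]])
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    return (upper - lower) * ncat


def _encode_alignment(alignment: Alignment) -> np.ndarray:
    """(n, L) int8 matrix; 0..3 = ACGT, -1 = missing."""
    m = alignment.to_matrix()
    out = np.full(m.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[m == b.encode()] = i
    return out


def _eigen_decomposition(model: SubstitutionModel):
    """(left, eigenvalues, right) of the reversible rate matrix."""
    Q = model.rate_matrix()
    sq = np.sqrt(model.freqs)
    B = (Q * sq[:, None]) / sq[None, :]
    lam, U = np.linalg.eigh((B + B.T) / 2.0)
    left = U / sq[:, None]
    right = U.T * sq[None, :]
    return left, lam, right


def _transition_matrices(
    model: SubstitutionModel, t: float, eig=None
) -> np.ndarray:
    """P(t * rate_c) for every rate category; shape (ncat, 4, 4)."""
    left, lam, right = eig if eig is not None else _eigen_decomposition(model)
    rates, _ = model.category_rates()
    Ps = np.empty((len(rates), 4, 4))
    for c, r in enumerate(rates):
        Ps[c] = (left * np.exp(lam * t * r)[None, :]) @ right
    return np.clip(Ps, 0.0, None)


def _prepare_patterns(alignment: Alignment):
    if alignment.length == 0:
        raise ValueError("zero-length alignment")
    enc = _encode_alignment(alignment)
    patterns, counts = np.unique(enc.T, axis=0, return_counts=True)
    row_of = {t.id: i for i, t in enumerate(alignment.members)}
    return patterns, counts, row_of


def log_likelihood(
    alignment: Alignment, tree: dendropy.Tree, model: SubstitutionModel,
    branch_scale: float = 1.0, _prepared=None,
) -> float:
    """Felsenstein pruning log-likelihood on a fixed topology.

    Site-rate variation is integrated over the discrete-gamma/invariant
    mixture. Missing characters (gap, N) contribute flat partials.
    """
    patterns, counts, row_of = (
        _prepared if _prepared is not None else _prepare_patterns(alignment)
    )
    npat = patterns.shape[0]
    rates, probs = model.category_rates()
    ncat = len(rates)

    eig = _eigen_decomposition(model)

    def edge_P(node) -> np.ndarray:
        t = (node.edge.length or 0.0) * branch_scale
        return _transition_matrices(model, t, eig)

    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in row_of:
                raise ValueError(f"tree leaf {label!r} not in alignment")
            states = patterns[:, row_of[label]]
            part = np.zeros((ncat, npat, 4))
            known = states >= 0
            part[:, ~known, :] = 1.0
            part[:, known, :] = 0.0
            part[:, np.flatnonzero(known), states[known]] = 1.0
        else:
            part = np.ones((ncat, npat, 4))
            for child in node.child_nodes():
                P = edge_P(child)
                part = part * np.einsum("cij,cpj->cpi", P, partials[id(child)])
            for child in node.child_nodes():
                partials.pop(id(child), None)
        partials[id(node)] = part
    root_part = partials[id(tree.seed_node)]
    site_l = np.einsum("c,cpj,j->p", probs, root_part, model.freqs)
    if (site_l <= 0).any():
        return -math.inf
    return float((np.log(site_l) * counts).sum())


def _empirical_freqs(alignment: Alignment) -> np.ndarray:
    enc = _encode_alignment(alignment)
    counts = np.bincount(enc[enc >= 0].ravel(), minlength=4).astype(float)
    counts += 0.5  # avoid zero frequencies
    return counts / counts.sum()


def _candidate_models(alignment: Alignment) -> list[SubstitutionModel]:
    """The 5 base models crossed with {none, +G, +I, +G+I}."""
    freqs = _empirical_freqs(alignment)
    out = []
    for name in MODEL_NAMES:
        f = freqs if _EMPIRICAL_FREQS[name] else None
        for g, i in ((None, None), (1.0, None), (None, 0.1), (1.0, 0.1)):
            out.append(
                SubstitutionModel(name, freqs=f, gamma_alpha=g, p_invariant=i)
            )
    return out


_RATE_KEYS = {"K2P": ["kappa"], "HKY85": ["kappa"], "TN93": ["kappa1", "kappa2"],
              "GTR": ["ac", "ag", "at", "cg", "ct"], "JC69": []}


def _fit_candidate(
    alignment: Alignment, tree: dendropy.Tree, template: SubstitutionModel,
    prepared=None,
) -> tuple[SubstitutionModel, float, float, bool]:
    """Fit one candidate; returns (model, logL, branch_scale, converged)."""
    if prepared is None:
        prepared = _prepare_patterns(alignment)
    keys = _RATE_KEYS[template.name]
    has_g = template.gamma_alpha is not None
    has_i = template.p_invariant is not None

    def unpack(x):
        pos = 0
        rates = {}
        for k in keys:
            rates[k] = math.exp(x[pos]); pos += 1
        g = math.exp(x[pos]) if has_g else None
        if has_g:
            pos += 1
        pi = 1.0 / (1.0 + math.exp(-x[pos])) * 0.9 if has_i else None
        if has_i:
            pos += 1
        scale = math.exp(x[pos])
        model = SubstitutionModel(
            template.name, rates=rates, freqs=template.freqs,
            gamma_alpha=g, p_invariant=pi,
        )
        return model, scale

    def neg_ll(x):
        try:
            model, scale = unpack(x)
            return -log_likelihood(alignment, tree, model, scale,
                                   _prepared=prepared)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12

    x0 = [math.log(2.0)] * len(keys)
    if has_g:
        x0.append(0.0)
    if has_i:
        x0.append(-2.0)
    x0.append(0.0)
    bounds = [(-4.0, 5.0)] * len(keys)
    if has_g:
        bounds.append((math.log(0.05), math.log(20.0)))
    if has_i:
        bounds.append((-8.0, 8.0))
    bounds.append((math.log(1e-3), math.log(50.0)))
    res = optimize.minimize(
        neg_ll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-9},
    )
    model, scale = unpack(res.x)
    return model, -res.fun, scale, bool(res.success)


def select_model(
    alignment: Alignment,
    topology: dendropy.Tree,
    candidates: list[SubstitutionModel] | None = None,
) -> tuple[SubstitutionModel, pd.DataFrame]:
    """Fit candidate substitution models on a fixed topology; rank by BIC.

    BIC = -2 logL + k ln(n_sites); the lowest-BIC model wins. Non-converged
    candidates are flagged and excluded from the ranking.
    """
    if candidates is None:
        candidates = _candidate_models(alignment)
    n_sites = alignment.length
    prepared = _prepare_patterns(alignment)
    rows = []
    fitted = []
    for cand in candidates:
        model, ll, scale, ok = _fit_candidate(alignment, topology, cand,
                                              prepared)
        k = model.n_free_params() + 1  # +1 for the shared branch scale
        bic = -2.0 * ll + k * math.log(n_sites)
        rows.append(
            {"model": model.label, "logL": ll, "k": k, "BIC": bic,
             "branch_scale": scale, "converged": ok}
        )
        fitted.append(model)
        if not ok:
            logger.warning("model %s did not converge; excluded", model.label)
    table = pd.DataFrame(rows)
    ranked = table[table.converged].sort_values("BIC")
    if ranked.empty:
        raise RuntimeError("no candidate model converged")
    best = fitted[int(ranked.index[0])]
    return best, table.sort_values("BIC").reset_index(drop=True)
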