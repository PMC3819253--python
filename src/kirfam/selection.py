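"""Selection analysis on codon alignments.

Implements the modified Nei-Gojobori counting estimator of dN/dS (transition
bias R enters the synonymous/nonsynonymous site counts; R = 0.5 recovers the
classic equal-weight scheme), the codon-based Z-test, sliding-window omega
profiles, and a SLAC-style per-site counting test that reconstructs ancestral
codons by parsimony and compares observed synonymous/nonsynonymous changes at
each codon with their expected site fractions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import dendropy
import numpy as np
import pandas as pd
from scipy.special import betainc
from scipy.stats import norm

from .records import Alignment

_BASES = "ACGT"
_CODON_TABLE = {}
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(itertools.product("TCAG", repeat=3)):
    _CODON_TABLE[_b1 + _b2 + _b3] = _AA[_i]

STOP_CODONS = frozenset(c for c, a in _CODON_TABLE.items() if a == "*")
SENSE_CODONS = tuple(sorted(c for c in _CODON_TABLE if c not in STOP_CODONS))


def translate_codon(codon: str) -> str:
    return _CODON_TABLE.get(codon, "X")


def _is_transition(x: str, y: str) -> bool:
    return {x, y} in ({"A", "G"}, {"C", "T"})


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, R: float) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one codon.

    Each possible single-base change is weighted 2R (transition) or 1
    (transversion); changes to stop codons are excluded. R = 0.5 gives the
    classic Nei-Gojobori equal-weight counts.
    """
    s_total = n_total = 0.0
    for pos in range(3):
        ws = wn = 0.0
        wsum = 0.0
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            w = 2.0 * R if _is_transition(codon[pos], alt) else 1.0
            wsum += w
            if _CODON_TABLE[mutant] == _CODON_TABLE[codon]:
                ws += w
            else:
                wn += w
        if wsum > 0:
            s_total += ws / wsum
            n_total += wn / wsum
    return s_total, n_total


@lru_cache(maxsize=None)
def pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) change counts between two codons.

    All minimal mutational pathways are enumerated; pathways passing through
    stop codons are excluded unless every pathway does.
    """
    diffs = [p for p in range(3) if ca[p] != cb[p]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    through_stop: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        cur = ca
        s = n = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != cb:
                hit_stop = True
            if _CODON_TABLE.get(cur, "X") == _CODON_TABLE.get(nxt, "X"):
                s += 1
            else:
                n += 1
            cur = nxt
        (through_stop if hit_stop else valid).append((s, n))
    paths = valid or through_stop
    s_avg = sum(p[0] for p in paths) / len(paths)
    n_avg = sum(p[1] for p in paths) / len(paths)
    return s_avg, n_avg


def _jc_correct(p: float) -> float:
    """Jukes-Cantor correction of a proportion of differences."""
    if p >= 0.75:
        raise OverflowError("proportion saturated (>= 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def estimate_ts_tv_ratio(alignment: Alignment) -> float:
    """Transition/transversion ratio R pooled over all pairs."""
    from .phylo import _pair_counts

    ts = tv = 0
    for a, b in itertools.combinations(alignment.members, 2):
        _, t1, t2, v, _ = _pair_counts(a.sequence, b.sequence)
        ts += t1 + t2
        tv += v
    if tv == 0:
        return 0.5
    return ts / tv


@dataclass
class SiteCall:
    position: int          # 1-based codon position
    n_changes: float       # observed nonsynonymous changes (pathway-averaged)
    s_changes: float
    expected_n_fraction: float
    call: str              # positive | negative | neutral
    p: float


@dataclass
class SelectionResult:
    scope: str
    dN: float | None
    dS: float | None
    dN_se: float | None
    dS_se: float | None
    omega: float | None    # None when dS == 0 or undefined
    Z: float | None = None
    p: float | None = None
    n_pairs_excluded: int = 0
    site_calls: list[SiteCall] = field(default_factory=list)


def _codon_columns(alignment: Alignment) -> list[list[str]]:
    """Per-codon lists of member codons; length must be divisible by 3."""
    if alignment.length % 3 != 0:
        raise ValueError("codon alignment length must be divisible by 3")
    ncod = alignment.length // 3
    seqs = [t.sequence for t in alignment.members]
    return [
        [s[3 * c: 3 * c + 3] for s in seqs] for c in range(ncod)
    ]


def _usable(codon: str) -> bool:
    return all(b in _BASES for b in codon) and codon not in STOP_CODONS


def _pair_codon_arrays(
    columns: list[list[str]], R: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per (pair, codon) arrays of Sd, Nd, S sites, N sites (NaN where a
    codon is unusable for that pair)."""
    nseq = len(columns[0])
    pairs = list(itertools.combinations(range(nseq), 2))
    ncod = len(columns)
    sd = np.full((len(pairs), ncod), np.nan)
    nd = np.full_like(sd, np.nan)
    ss = np.full_like(sd, np.nan)
    ns = np.full_like(sd, np.nan)
    for c, col in enumerate(columns):
        site = {}
        for codon in set(col):
            if _usable(codon):
                site[codon] = codon_site_counts(codon, R)
        for pi, (i, j) in enumerate(pairs):
            ca, cb = col[i], col[j]
            if ca not in site or cb not in site:
                continue
            s, n = pathway_counts(ca, cb)
            sd[pi, c], nd[pi, c] = s, n
            ss[pi, c] = 0.5 * (site[ca][0] + site[cb][0])
            ns[pi, c] = 0.5 * (site[ca][1] + site[cb][1])
    return sd, nd, ss, ns


def _average_rates(
    sd: np.ndarray, nd: np.ndarray, ss: np.ndarray, ns: np.ndarray,
    codon_idx: np.ndarray | None = None,
) -> tuple[float | None, float | None, int]:
    """Average pairwise dS and dN (JC-corrected); returns (dS, dN, excluded)."""
    if codon_idx is not None:
        sd, nd, ss, ns = (a[:, codon_idx] for a in (sd, nd, ss, ns))
    dss, dns = [], []
    excluded = 0
    for pi in range(sd.shape[0]):
        ok = ~np.isnan(sd[pi])
        S, N = np.nansum(ss[pi]), np.nansum(ns[pi])
        if not ok.any() or S <= 0 or N <= 0:
            excluded += 1
            continue
        ps = np.nansum(sd[pi]) / S
        pn = np.nansum(nd[pi]) / N
        try:
            dss.append(_jc_correct(ps))
            dns.append(_jc_correct(pn))
        except OverflowError:
            excluded += 1
    if not dss:
        return None, None, excluded
    return float(np.mean(dss)), float(np.mean(dns)), excluded


def dn_ds(
    alignment: Alignment,
    R: float | None = None,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    scope: str = "alignment",
) -> SelectionResult:
    """Modified Nei-Gojobori dN and dS averaged over all sequence pairs.

    Proportions are Jukes-Cantor corrected; saturated pairs (proportion
    >= 0.75) are excluded with a count. Standard errors come from a
    codon-column bootstrap.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    columns = _codon_columns(alignment)
    if R is None:
        R = estimate_ts_tv_ratio(alignment)
    arrays = _pair_codon_arrays(columns, R)
    dS, dN, excluded = _average_rates(*arrays)
    if dS is None:
        return SelectionResult(scope, None, None, None, None, None,
                               n_pairs_excluded=excluded)
    ncod = len(columns)
    rng = np.random.default_rng(seed)
    reps_dn, reps_ds = [], []
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, ncod, size=ncod)
        ds_b, dn_b, _ = _average_rates(*arrays, codon_idx=idx)
        if ds_b is not None:
            reps_ds.append(ds_b)
            reps_dn.append(dn_b)
    dn_se = float(np.std(reps_dn, ddof=1)) if len(reps_dn) > 1 else None
    ds_se = float(np.std(reps_ds, ddof=1)) if len(reps_ds) > 1 else None
    omega = dN / dS if dS > 0 else None
    return SelectionResult(scope, dN, dS, dn_se, ds_se, omega,
                           n_pairs_excluded=excluded)


def codon_z_test(
    dN: float, dS: float, se_dN: float, se_dS: float,
    alternative: str = "purifying",
) -> tuple[float, float]:
    """Codon-based Z-test for a difference between dN and dS.

    purifying: Z = (dS - dN)/se, one-tailed; positive: Z = (dN - dS)/se,
    one-tailed; neutral: two-tailed on |dN - dS|.
    """
    if se_dN <= 0 or se_dS <= 0:
        raise ValueError("standard errors must be > 0")
    se = math.sqrt(se_dN**2 + se_dS**2)
    if alternative == "purifying":
        Z = (dS - dN) / se
        p = float(norm.sf(Z))
    elif alternative == "positive":
        Z = (dN - dS) / se
        p = float(norm.sf(Z))
    elif alternative == "neutral":
        Z = (dN - dS) / se
        p = float(2.0 * norm.sf(abs(Z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return Z, p


def sliding_omega(
    alignment: Alignment, window: int, step: int, R: float | None = None
) -> pd.DataFrame:
    """Windowed dN/dS profile over codons.

    Windows where dS = 0 or undefined report omega as NaN (missing), never 0.
    Columns: start, end (1-based codons, inclusive), dN, dS, omega.
    """
    columns = _codon_columns(alignment)
    ncod = len(columns)
    if window > ncod:
        raise ValueError("window exceeds alignment length in codons")
    if R is None:
        R = estimate_ts_tv_ratio(alignment)
    arrays = _pair_codon_arrays(columns, R)
    rows = []
    for start in range(0, ncod - window + 1, step):
        idx = np.arange(start, start + window)
        dS, dN, _ = _average_rates(*arrays, codon_idx=idx)
        omega = (
            dN / dS if (dS is not None and dS > 0 and dN is not None) else np.nan
        )
        rows.append(
            {"start": start + 1, "end": start + window,
             "dN": np.nan if dN is None else dN,
             "dS": np.nan if dS is None else dS, "omega": omega}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SLAC-style per-site counting test
# ---------------------------------------------------------------------------

def _fitch_assignments(
    tree: dendropy.Tree, leaf_states: dict[str, str]
) -> dict[int, str]:
    """Parsimony codon assignment for one site.

    Bottom-up Fitch sets; the top-down pass keeps the parent state when
    possible and otherwise picks the set member with the fewest
    nonsynonymous steps to the parent (ties broken lexicographically).
    """
    sets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = leaf_states.get(node.taxon.label)
            if state is None:
                sets[id(node)] = frozenset(SENSE_CODONS)  # missing: wildcard
            else:
                sets[id(node)] = frozenset([state])
        else:
            child_sets = [sets[id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            sets[id(node)] = inter if inter else frozenset.union(*child_sets)
    observed = [s for s in leaf_states.values() if s is not None]
    assign: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        s = sets[id(node)]
        if node.parent_node is None:
            # root: most common observed codon in the set, ties lexicographic
            cands = sorted(s)
            counts = {c: observed.count(c) for c in cands}
            assign[id(node)] = max(cands, key=lambda c: (counts[c], c))
            continue
        parent_state = assign[id(node.parent_node)]
        if parent_state in s:
            assign[id(node)] = parent_state
        else:
            best = min(
                sorted(s), key=lambda c: (pathway_counts(parent_state, c)[1], c)
            )
            assign[id(node)] = best
    return assign


def site_selection_counting(
    alignment: Alignment,
    tree: dendropy.Tree,
    p_max: float = 0.1,
    R: float | None = None,
) -> list[SiteCall]:
    """Per-codon selection calls from parsimony change counting.

    For each codon column, ancestral codons are reconstructed by Fitch
    parsimony; observed synonymous/nonsynonymous changes summed over branches
    are compared with the expected nonsynonymous site fraction by a one-tailed
    extended binomial test in each direction. Positive calls need an excess of
    nonsynonymous changes at p <= p_max, negative calls an excess of
    synonymous changes.
    """
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences")
    columns = _codon_columns(alignment)
    if R is None:
        R = estimate_ts_tv_ratio(alignment)
    calls: list[SiteCall] = []
    for c, col in enumerate(columns):
        leaf_states = {}
        for member, codon in zip(alignment.members, col):
            leaf_states[member.id] = codon if _usable(codon) else None
        usable_states = [s for s in leaf_states.values() if s is not None]
        if len(set(usable_states)) <= 1 or len(usable_states) < 3:
            calls.append(SiteCall(c + 1, 0.0, 0.0, np.nan, "neutral", 1.0))
            continue
        assign = _fitch_assignments(tree, leaf_states)
        n_obs = s_obs = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            pa = assign[id(node.parent_node)]
            ch = assign[id(node)]
            if pa != ch:
                s, n = pathway_counts(pa, ch)
                s_obs += s
                n_obs += n
        states = list(assign.values())
        fracs = []
        for st in states:
            s_c, n_c = codon_site_counts(st, R)
            if s_c + n_c > 0:
                fracs.append(n_c / (s_c + n_c))
        pN = float(np.mean(fracs)) if fracs else np.nan
        m = n_obs + s_obs
        if m == 0 or not np.isfinite(pN):
            calls.append(SiteCall(c + 1, n_obs, s_obs, pN, "neutral", 1.0))
            continue
        # extended binomial upper tails (fractional counts via betainc)
        p_pos = float(betainc(n_obs, m - n_obs + 1.0, pN)) if n_obs > 0 else 1.0
        p_neg = (
            float(betainc(s_obs, m - s_obs + 1.0, 1.0 - pN)) if s_obs > 0 else 1.0
        )
        if p_pos <= p_max and n_obs / m > pN:
            calls.append(SiteCall(c + 1, n_obs, s_obs, pN, "positive", p_pos))
        elif p_neg <= p_max and s_obs / m > 1.0 - pN:
            calls.append(SiteCall(c + 1, n_obs, s_obs, pN, "negative", p_neg))
        else:
            calls.append(
                SiteCall(c + 1, n_obs, s_obs, pN, "neutral", min(p_pos, p_neg))
            )
    return calls
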