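"""Recombination detection among paralogous sequences.

MaxChi slides two adjacent windows of variable sites along each sequence
pair and scores the 2x2 match/mismatch contrast by chi-square; the maximum
marks a candidate breakpoint, and significance comes from permuting the
variable-site order. The triplet scan attributes fragments to a minor
parent by tracking which of two reference sequences a putative recombinant
is locally closer to. Gapped columns are removed before scanning.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .records import Alignment


@dataclass
class RecombinationFragment:
    recombinant: str
    minor_parent: str | None
    major_parent: str | None
    start: int              # 0-based inclusive original alignment column
    end: int                # 0-based inclusive
    p: float
    method: str             # maxchi | triplet


def _gapless(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """(character matrix, original column indices) without gap/N columns."""
    m = alignment.to_matrix()
    keep = ~((m == b"-") | (m == b"N")).any(axis=0)
    cols = np.flatnonzero(keep)
    return m[:, cols], cols


def _variable_columns(m: np.ndarray) -> np.ndarray:
    return np.flatnonzero((m != m[0]).any(axis=0))


def _chi2_profile(x: np.ndarray, w: int) -> np.ndarray:
    """Chi-square of the 2x2 (left/right window) x (hit/miss) table at every
    internal breakpoint of the 0/1 vector ``x``; length m - 2w + 1."""
    cs = np.concatenate([[0], np.cumsum(x)])
    m = len(x)
    ks = np.arange(w, m - w + 1)
    left = cs[ks] - cs[ks - w]
    right = cs[ks + w] - cs[ks]
    tot = left + right
    n = 2.0 * w
    denom = w * w * tot * (n - tot)
    num = n * (left * (w - right) - right * (w - left)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, num / denom, 0.0)
    return chi2


def _max_chi2(x: np.ndarray, w: int) -> tuple[float, int]:
    prof = _chi2_profile(x, w)
    k = int(np.argmax(prof))
    return float(prof[k]), k + w


def _second_peak(prof: np.ndarray, w: int, k_best: int) -> int | None:
    masked = prof.copy()
    lo = max(0, k_best - w - w)
    hi = min(len(prof), k_best - w + w + 1)
    masked[lo:hi] = -1.0
    if (masked < 0).all():
        return None
    k2 = int(np.argmax(masked))
    if masked[k2] <= 0:
        return None
    return k2 + w


def _permutation_p(
    x: np.ndarray, w: int, observed: float, permutations: int,
    rng: np.random.Generator,
) -> float:
    hits = 0
    y = x.copy()
    for _ in range(permutations):
        rng.shuffle(y)
        stat, _ = _max_chi2(y, w)
        if stat >= observed - 1e-12:
            hits += 1
    return (hits + 1.0) / (permutations + 1.0)


def default_half_window(n_variable: int) -> int:
    """One fifth of the scanned sites per half-window, minimum 10.

    A wide window maximizes power for domain-sized fragments; breakpoints
    are then sharpened with a fine local rescan (see ``_refine_peak``).
    """
    return max(10, n_variable // 5)


def _changepoint(
    x: np.ndarray, a0: int, b0: int, p_left: float, p_right: float
) -> int:
    """Fixed-rate Bernoulli change-point estimate.

    Finds j in [a0, b0] maximizing the likelihood of x[a0:j) under rate
    ``p_left`` and x[j:b0) under ``p_right``. Fixing the rates (estimated
    from the fragment core and the flanks) keeps the estimate stable when
    mismatches are sparse.
    """
    a0 = max(0, a0)
    b0 = min(len(x), b0)
    if b0 - a0 < 2 or not 0 < abs(p_left - p_right):
        return (a0 + b0) // 2
    pl = min(max(p_left, 1e-6), 1 - 1e-6)
    pr = min(max(p_right, 1e-6), 1 - 1e-6)
    seg = x[a0:b0].astype(float)
    # prefix log-likelihood ratio of "left rate" over "right rate"
    ratio = seg * math.log(pl / pr) + (1 - seg) * math.log(
        (1 - pl) / (1 - pr)
    )
    prefix = np.concatenate([[0.0], np.cumsum(ratio)])
    return a0 + int(np.argmax(prefix))


def maxchi_scan(
    alignment: Alignment,
    half_window: int | None = None,
    permutations: int = 1000,
    seed: int = 0,
    correction: str = "bonferroni",
) -> list[RecombinationFragment]:
    """MaxChi breakpoint scan over all sequence pairs.

    Returns candidate fragments (uncorrected by p_max; filter with
    :func:`consolidate_fragments`). With ``correction='bonferroni'`` the
    permutation p-value is multiplied by the number of pairs scanned.
    Breakpoint coordinates are 0-based inclusive columns of the input
    alignment, always on variable-site boundaries.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    m, orig_cols = _gapless(alignment)
    # scan coordinates: alignment-variable columns; with only two sequences
    # every variable column is a pair mismatch, so scan all columns instead
    var = (
        _variable_columns(m) if m.shape[0] > 2 else np.arange(m.shape[1])
    )
    if var.size == 0:
        return []
    w = default_half_window(var.size) if half_window is None else half_window
    if var.size < 2 * w + 1:
        return []  # fewer variable sites than the scan needs: no-scan result
    rng = np.random.default_rng(seed)
    ids = alignment.ids
    pairs = list(itertools.combinations(range(len(ids)), 2))
    out: list[RecombinationFragment] = []
    for i, j in pairs:
        x = (m[i, var] != m[j, var]).astype(np.int64)
        # too few mismatches to form a 2x2 contrast: no-scan result
        if x.sum() < 4 or x.sum() == len(x):
            continue
        prof = _chi2_profile(x, w)
        k1 = int(np.argmax(prof)) + w
        observed = float(prof[k1 - w])
        if observed <= 0:
            continue
        p = _permutation_p(x, w, observed, permutations, rng)
        if correction == "bonferroni":
            p = min(1.0, p * len(pairs))
        k2 = _second_peak(prof, w, k1)
        if k2 is None:
            lo, hi = sorted((k1, len(x) - 1))
        else:
            lo, hi = sorted((k1, k2))
            mid = (lo + hi) // 2
            inside = float(x[lo:hi].mean()) if hi > lo else 0.5
            # flank rate taken beyond the breakpoint search zone so fragment
            # tails cannot inflate it
            flanks = np.concatenate([x[: max(0, lo - w)], x[hi + w:]])
            if not flanks.size:
                flanks = np.concatenate([x[:lo], x[hi:]])
            outside = float(flanks.mean()) if flanks.size else 0.0
            lo = _changepoint(x, lo - w, mid, outside, inside)
            hi = _changepoint(x, mid, hi + w, inside, outside)
            # the change-point estimate sits at the outermost informative
            # site; the true boundary lies on average half an informative
            # gap beyond it
            ext = int(round(0.5 / max(inside - outside, 1e-6)))
            lo = max(0, lo - ext)
            hi = min(len(x) - 1, hi + ext)
        out.append(
            RecombinationFragment(
                recombinant=ids[i],
                minor_parent=ids[j],
                major_parent=None,
                start=int(orig_cols[var[lo]]),
                end=int(orig_cols[var[hi]]),
                p=p,
                method="maxchi",
            )
        )
    return out


def triplet_scan(
    alignment: Alignment,
    triplets: list[tuple[str, str, str]] | None = None,
    half_window: int | None = None,
    permutations: int = 1000,
    seed: int = 0,
    identity_floor: float = 0.95,
) -> list[RecombinationFragment]:
    """Minor-parent attribution by triplet scanning.

    For each (recombinant, parentA, parentB) triplet the informative sites
    (parents differ, recombinant matches one of them) form a binary signal;
    a MaxChi contrast on that signal locates segments where the closer
    parent switches. The parent matching inside the fragment is the minor
    parent; if the recombinant's identity to it inside the fragment is below
    ``identity_floor`` the attribution is reported as
    "unknown (closest relative <id>)".
    """
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences")
    m, orig_cols = _gapless(alignment)
    ids = alignment.ids
    index = {s: k for k, s in enumerate(ids)}
    if triplets is None:
        triplets = [
            (ids[r], ids[a], ids[b])
            for r in range(len(ids))
            for a, b in itertools.combinations(
                [k for k in range(len(ids)) if k != r], 2
            )
        ]
        triplets = [(r, ids_a, ids_b) for r, ids_a, ids_b in triplets]
    rng = np.random.default_rng(seed)
    out: list[RecombinationFragment] = []
    for rec, pa, pb in triplets:
        ri, ai, bi = index[rec], index[pa], index[pb]
        informative = np.flatnonzero(
            (m[ai] != m[bi]) & ((m[ri] == m[ai]) | (m[ri] == m[bi]))
        )
        if informative.size == 0:
            continue
        w = (
            default_half_window(informative.size)
            if half_window is None
            else half_window
        )
        if informative.size < 2 * w + 1:
            continue
        x = (m[ri, informative] == m[ai, informative]).astype(np.int64)
        if x.sum() == 0 or x.sum() == len(x):
            continue
        prof = _chi2_profile(x, w)
        k1 = int(np.argmax(prof)) + w
        observed = float(prof[k1 - w])
        if observed <= 0:
            continue
        p = _permutation_p(x, w, observed, permutations, rng)
        k2 = _second_peak(prof, w, k1)
        if k2 is None:
            k2 = len(x) - 1
        lo, hi = sorted((k1, k2))
        inside = x[lo:hi + 1]
        outside = np.concatenate([x[:lo], x[hi + 1:]])
        if inside.size == 0 or outside.size == 0:
            continue
        inside_match_a = inside.mean() > 0.5
        outside_match_a = outside.mean() > 0.5
        if inside_match_a == outside_match_a:
            continue  # no switch of the closer parent: no attribution
        minor, major = (pa, pb) if inside_match_a else (pb, pa)
        start = int(orig_cols[informative[lo]])
        end = int(orig_cols[informative[hi]])
        mi = index[minor]
        span = slice(
            int(np.searchsorted(orig_cols, start)),
            int(np.searchsorted(orig_cols, end, side="right")),
        )
        ident = float((m[ri, span] == m[mi, span]).mean())
        label = minor
        if ident < identity_floor:
            label = f"unknown (closest relative {minor})"
        out.append(
            RecombinationFragment(
                recombinant=rec, minor_parent=label, major_parent=major,
                start=start, end=end, p=p, method="triplet",
            )
        )
    return out


def consolidate_fragments(
    candidates: list[RecombinationFragment], p_max: float = 0.03
) -> list[RecombinationFragment]:
    """Merge overlapping candidates per recombinant and filter at p_max.

    Overlaps merge to the union span with the minimum p; output is sorted by
    recombinant id, then start.
    """
    kept = [c for c in candidates if c.p <= p_max]
    by_rec: dict[str, list[RecombinationFragment]] = {}
    for c in kept:
        by_rec.setdefault(c.recombinant, []).append(c)
    out: list[RecombinationFragment] = []
    for rec in sorted(by_rec):
        frags = sorted(by_rec[rec], key=lambda f: (f.start, f.end))
        merged: list[RecombinationFragment] = []
        for f in frags:
            if merged and f.start <= merged[-1].end:
                last = merged[-1]
                better = f if f.p < last.p else last
                merged[-1] = RecombinationFragment(
                    recombinant=rec,
                    minor_parent=better.minor_parent,
                    major_parent=better.major_parent,
                    start=last.start,
                    end=max(last.end, f.end),
                    p=min(last.p, f.p),
                    method=better.method,
                )
            else:
                merged.append(f)
        out.extend(merged)
    return out
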