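"""Population-genetic diversity statistics.

Watterson's segregating-sites estimator and nucleotide diversity, both per
site, with the standard no-recombination coalescent variances. Values with
n < 2 sequences are undefined and reported as "-" in tables, as is usual for
singleton loci.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .records import Alignment


@dataclass
class DiversityStats:
    n: int
    L: int                      # analyzed sites after gap handling
    S: int                      # segregating sites
    theta_w: float | None       # per site
    theta_sd: float | None
    pi: float | None            # per site
    pi_sd: float | None

    def defined(self) -> bool:
        return self.theta_w is not None


def harmonic(n: int, power: int = 1) -> float:
    """a1 = sum 1/i (power=1) or a2 = sum 1/i^2 (power=2), i = 1..n-1."""
    return sum(1.0 / i**power for i in range(1, n))


def watterson_theta(n: int, S: int, L: int) -> tuple[float, float]:
    """Per-site Watterson estimator and its standard deviation.

    theta = S / (a1 * L); Var(theta) = theta/(a1*L) + a2*theta^2/a1^2.
    Rounding happens only at report time.
    """
    if n < 2:
        raise ValueError("Watterson estimator undefined for n < 2")
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0 <= S <= L:
        raise ValueError("S must satisfy 0 <= S <= L")
    a1 = harmonic(n, 1)
    a2 = harmonic(n, 2)
    theta = S / (a1 * L)
    var = theta / (a1 * L) + (a2 / a1**2) * theta**2
    return theta, math.sqrt(var)


def segregating_sites(alignment: Alignment) -> int:
    """Number of polymorphic columns (gap/N characters ignored per column)."""
    m = alignment.to_matrix()
    S = 0
    for col in m.T:
        bases = {c for c in col.tobytes().decode() if c in "ACGT"}
        if len(bases) > 1:
            S += 1
    return S


def pairwise_differences(a: str, b: str) -> tuple[int, int]:
    """(differences, comparable sites) over unambiguous positions."""
    diff = n = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            n += 1
            if x != y:
                diff += 1
    return diff, n


def nucleotide_diversity(
    alignment: Alignment, gap_policy: str = "complete_deletion"
) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and its standard deviation.

    pi = sum_{i<j} d_ij / (C(n,2) * L); under complete deletion, columns
    containing any gap/N are removed first (so every pair is compared over
    the same L sites). Variance by the Nei (1987) no-recombination formula.
    """
    n = len(alignment)
    if n < 2:
        raise ValueError("nucleotide diversity undefined for n < 2")
    if gap_policy == "complete_deletion":
        from .phylo import complete_deletion

        aln, _ = complete_deletion(alignment)
        L = aln.length
        total = 0
        for a, b in itertools.combinations(aln.members, 2):
            d, _ = pairwise_differences(a.sequence, b.sequence)
            total += d
        pi = total / (n * (n - 1) / 2.0) / L
    elif gap_policy == "pairwise_deletion":
        props = []
        for a, b in itertools.combinations(alignment.members, 2):
            d, m = pairwise_differences(a.sequence, b.sequence)
            if m == 0:
                raise ValueError(f"no comparable sites for pair ({a.id},{b.id})")
            props.append(d / m)
        pi = float(np.mean(props))
        L = alignment.length
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return pi, math.sqrt(var)


def diversity_stats(
    alignment: Alignment | None, gap_policy: str = "complete_deletion"
) -> DiversityStats:
    """Full per-alignment summary; undefined fields are None when n < 2."""
    if alignment is None or len(alignment) < 2:
        n = 0 if alignment is None else len(alignment)
        return DiversityStats(n, 0, 0, None, None, None, None)
    from .phylo import complete_deletion

    if gap_policy == "complete_deletion":
        aln, _ = complete_deletion(alignment)
    else:
        aln = alignment
    n, L = len(aln), aln.length
    S = segregating_sites(aln)
    theta, theta_sd = watterson_theta(n, S, L)
    pi, pi_sd = nucleotide_diversity(aln, gap_policy="pairwise_deletion"
                                     if gap_policy == "pairwise_deletion"
                                     else "complete_deletion")
    return DiversityStats(n, L, S, theta, theta_sd, pi, pi_sd)
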