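"""One-level AMOVA on sequence distances with a permutation test.

Molecular variance is partitioned into among- and within-group components
from squared pairwise substitution distances (Excoffier-style).  With N
sequences in G groups of sizes n_g:

    SSD_total  = sum_{i<j} d_ij^2 / N
    SSD_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    SSD_among  = SSD_total - SSD_within
    sigma2_w   = SSD_within / (N - G)
    sigma2_a   = (SSD_among / (G - 1) - sigma2_w) / n'
    n'         = (N - sum_g n_g^2 / N) / (G - 1)
    Phi_ST     = sigma2_a / (sigma2_a + sigma2_w)

Negative among-group components are legitimate (they indicate less structure
than random expectation) and are reported as such; percentages always sum to
100 by construction.  The permutation p-value shuffles sequences across groups
with group sizes fixed and counts permuted Phi_ST >= observed with the add-one
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._distance import encode, pairwise_matrix
from .errors import AnalysisError, ParameterError
from .seq_io import HaplotypeTable

__all__ = [
    "AmovaResult",
    "pairwise_distance_matrix",
    "expand_by_group",
    "amova_one_level",
    "amova_permutation_p",
    "amova",
]


def pairwise_distance_matrix(sequences: list[str] | tuple[str, ...]) -> np.ndarray:
    """Symmetric substitution-distance matrix (gap/N columns excluded pairwise)."""
    if len({len(s) for s in sequences}) > 1:
        raise ParameterError("sequences must be aligned (equal lengths)")
    return pairwise_matrix(encode(sequences))


def expand_by_group(
    haplotypes: HaplotypeTable, grouping: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Expand haplotype multiplicities to individual sequences with group labels.

    Each clone contributes one sequence whose group is its carrier's group.
    Returns (distance matrix over expanded sequences, group label array).
    """
    dist_h = pairwise_distance_matrix(haplotypes.sequences)
    idx: list[int] = []
    labels: list[str] = []
    for i, h in enumerate(haplotypes):
        for ind in sorted(h.carrier_counts):
            if ind not in grouping:
                raise ParameterError(f"individual {ind!r} missing from grouping")
            idx.extend([i] * h.carrier_counts[ind])
            labels.extend([grouping[ind]] * h.carrier_counts[ind])
    sel = np.asarray(idx, dtype=np.intp)
    return dist_h[np.ix_(sel, sel)], np.asarray(labels)


@dataclass(frozen=True)
class AmovaResult:
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    null_phi: np.ndarray | None = field(default=None, compare=False, repr=False)

    def to_frame(self, comparison: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "comparison": comparison,
                    "sigma2_among": self.sigma2_among,
                    "sigma2_within": self.sigma2_within,
                    "pct_among": self.pct_among,
                    "pct_within": self.pct_within,
                    "phi_st": self.phi_st,
                    "p_value": self.p_value,
                    "n_perm": self.n_perm,
                    "seed": self.seed,
                }
            ]
        )


def _check_groups(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, sizes = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise AnalysisError("AMOVA needs at least two groups")
    small = labels[sizes < 2]
    if len(small):
        raise AnalysisError(f"group(s) with fewer than 2 sequences: {list(small)}")
    return labels, sizes


def _components(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    labels, sizes = np.unique(groups, return_counts=True)
    n = len(groups)
    g = len(labels)
    ssd_total = d2.sum() / (2.0 * n)
    ssd_within = 0.0
    for lab, ng in zip(labels, sizes):
        m = groups == lab
        ssd_within += d2[np.ix_(m, m)].sum() / (2.0 * ng)
    ssd_among = ssd_total - ssd_within
    sigma2_w = ssd_within / (n - g)
    n_prime = (n - (sizes.astype(float) ** 2).sum() / n) / (g - 1)
    sigma2_a = (ssd_among / (g - 1) - sigma2_w) / n_prime
    return sigma2_a, sigma2_w


def amova_one_level(dist: np.ndarray, groups) -> AmovaResult:
    """Variance components, percentages and Phi_ST for one grouping level."""
    groups = np.asarray(groups)
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (len(groups), len(groups)):
        raise ParameterError("distance matrix and group labels are inconsistent")
    _check_groups(groups)
    sigma2_a, sigma2_w = _components(dist**2, groups)
    total = sigma2_a + sigma2_w
    if total == 0.0:
        warnings.warn("zero total molecular variance; reporting 0/100 by convention")
        return AmovaResult(0.0, 0.0, 0.0, 100.0, 0.0)
    pct_among = 100.0 * sigma2_a / total
    return AmovaResult(
        sigma2_among=sigma2_a,
        sigma2_within=sigma2_w,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        phi_st=sigma2_a / total,
    )


def amova_permutation_p(
    dist: np.ndarray,
    groups,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for Phi_ST (labels shuffled, group sizes fixed).

    Returns (p, null Phi array); p = (1 + #{Phi_perm >= Phi_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    groups = np.asarray(groups)
    dist = np.asarray(dist, dtype=float)
    labels, sizes = _check_groups(groups)
    d2 = dist**2
    n = len(groups)
    g = len(labels)
    phi_obs = amova_one_level(dist, groups).phi_st

    rng = np.random.default_rng(seed)
    perm_labels = rng.permuted(np.tile(groups, (n_perm, 1)), axis=1)
    ssd_total = d2.sum() / (2.0 * n)
    ssd_within = np.zeros(n_perm)
    for lab, ng in zip(labels, sizes):
        m = (perm_labels == lab).astype(float)
        ssd_within += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * ng)
    sigma2_w = ssd_within / (n - g)
    n_prime = (n - (sizes.astype(float) ** 2).sum() / n) / (g - 1)
    sigma2_a = ((ssd_total - ssd_within) / (g - 1) - sigma2_w) / n_prime
    total = sigma2_a + sigma2_w
    null_phi = np.where(total != 0.0, np.divide(sigma2_a, np.where(total == 0, 1.0, total)), 0.0)
    p = (1.0 + float((null_phi >= phi_obs).sum())) / (1.0 + n_perm)
    return p, null_phi


def amova(
    dist: np.ndarray,
    groups,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """Components plus permutation p in one call."""
    base = amova_one_level(dist, groups)
    p, null_phi = amova_permutation_p(dist, groups, n_perm=n_perm, seed=seed)
    return AmovaResult(
        sigma2_among=base.sigma2_among,
        sigma2_within=base.sigma2_within,
        pct_among=base.pct_among,
        pct_within=base.pct_within,
        phi_st=base.phi_st,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        null_phi=null_phi,
    )
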