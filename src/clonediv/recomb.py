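"""Recombinant screening by an inner-fragment permutation test.

A recombinant (natural gene conversion or a PCR-mediated chimera) shows up as
a pair of sequences that agree over an unexpectedly long run of consecutive
polymorphic sites.  The screen restricts the alignment to its polymorphic
columns, scores every pair by its maximal mismatch-free run ("inner
fragment"), and builds the null by jointly permuting the order of polymorphic
columns across all sequences — which destroys linkage along the sequence while
preserving every pairwise site-agreement profile.  Per-pair p-values compare
each observed pair score against the permutation distribution of the *global*
maximum score, and are then Bonferroni-corrected over tested pairs.  Of a
significant pair the lower-frequency member is flagged (removal is meant to be
conservative; which member is the recombinant is not identifiable from the
statistic alone).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._distance import VALID_CODE_MAX, encode
from .errors import ParameterError
from .seq_io import Alignment, HaplotypeTable

__all__ = [
    "InnerFragment",
    "RecombReport",
    "polymorphic_sites",
    "max_inner_fragment",
    "geneconv_test",
]


def polymorphic_sites(alignment: Alignment) -> list[int]:
    """Ascending indices of columns with >= 2 distinct unambiguous bases."""
    enc = encode(alignment.seqs)
    sites = []
    for j in range(enc.shape[1]):
        col = enc[:, j]
        states = np.unique(col[col <= VALID_CODE_MAX])
        if len(states) >= 2:
            sites.append(j)
    return sites


@dataclass(frozen=True)
class InnerFragment:
    """Maximal run of consecutive polymorphic sites at which a pair agrees.

    ``start``/``end`` are 0-based half-open indices in polymorphic-site
    coordinates; ``score = end - start`` under an infinite mismatch penalty.
    """

    pair: tuple[str, str]
    start: int
    end: int

    @property
    def score(self) -> int:
        return self.end - self.start


def _agreement(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a == b) & (a <= VALID_CODE_MAX) & (b <= VALID_CODE_MAX)


def max_inner_fragment(seq_a: str, seq_b: str, pair: tuple[str, str] = ("a", "b")) -> InnerFragment:
    """Longest mismatch-free run between two strings already restricted to
    polymorphic sites.  Ties broken by smallest start.  Returns a zero-score
    fragment at (0, 0) when the pair never agrees."""
    if len(seq_a) != len(seq_b) or not seq_a:
        raise ParameterError("restricted strings must be non-empty and of equal length")
    agree = _agreement(encode([seq_a])[0], encode([seq_b])[0])
    best_start, best_len, cur_start, cur_len = 0, 0, 0, 0
    for i, ok in enumerate(agree):
        if ok:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    return InnerFragment(pair=pair, start=best_start, end=best_start + best_len)


def _max_runs_scan(E: np.ndarray) -> np.ndarray:
    """Max run of True along the last axis of a boolean array (vectorized scan)."""
    cur = np.zeros(E.shape[:-1], dtype=np.int32)
    best = np.zeros(E.shape[:-1], dtype=np.int32)
    for s in range(E.shape[-1]):
        cur = (cur + 1) * E[..., s]
        np.maximum(best, cur, out=best)
    return best


@dataclass(frozen=True)
class RecombReport:
    tested: bool
    flagged: frozenset[str]
    table: pd.DataFrame
    n_perm: int
    seed: int | None

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def geneconv_test(
    haplotypes: HaplotypeTable,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> RecombReport:
    """Permutation screen for recombinant haplotypes.

    p = (1 + #{null global max >= observed pair score}) / (1 + n_perm);
    pairs with Bonferroni-corrected p < alpha flag their lower-frequency
    member (tie: lexicographically later sequence).  Fewer than 3 haplotypes
    or fewer than 2 polymorphic sites -> no test, nothing flagged.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    empty = pd.DataFrame(
        columns=["id_a", "id_b", "span_start", "span_end", "score", "p_raw", "p_corrected", "flagged"]
    )
    if len(haplotypes) < 3:
        return RecombReport(False, frozenset(), empty, n_perm, seed)
    aln = haplotypes.to_alignment()
    sites = polymorphic_sites(aln)
    if len(sites) < 2:
        return RecombReport(False, frozenset(), empty, n_perm, seed)

    enc = encode(aln.seqs)[:, sites]
    pairs = list(combinations(range(len(haplotypes)), 2))
    A = np.stack([_agreement(enc[i], enc[j]) for i, j in pairs])  # (n_pairs, S)
    S = A.shape[1]

    frags = [
        max_inner_fragment(
            "".join("ACGT?"[min(v, 4)] for v in enc[i]),
            "".join("ACGT?"[min(v, 4)] for v in enc[j]),
            pair=(haplotypes.ids[i], haplotypes.ids[j]),
        )
        for i, j in pairs
    ]
    obs = np.array([f.score for f in frags])

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, S)), axis=1)  # joint column shuffles
    cur = np.zeros((len(pairs), n_perm), dtype=np.int32)
    best = np.zeros((len(pairs), n_perm), dtype=np.int32)
    for s in range(S):
        cur = (cur + 1) * A[:, perms[:, s]]
        np.maximum(best, cur, out=best)
    null_max = best.max(axis=0)  # global maximum per permutation

    n_tests = len(pairs)
    p_raw = (1.0 + (null_max[None, :] >= obs[:, None]).sum(axis=1)) / (1.0 + n_perm)
    p_corr = np.minimum(1.0, p_raw * n_tests)

    flagged: set[str] = set()
    rows = []
    col_sites = np.asarray(sites)
    for k, (i, j) in enumerate(pairs):
        sig = p_corr[k] < alpha
        member = None
        if sig:
            hi, hj = haplotypes.haplotypes[i], haplotypes.haplotypes[j]
            if hi.count != hj.count:
                member = hi if hi.count < hj.count else hj
            else:
                member = hi if hi.sequence > hj.sequence else hj
            flagged.add(member.haplotype_id)
        f = frags[k]
        span_start = int(col_sites[f.start]) if f.score > 0 else -1
        span_end = int(col_sites[f.end - 1]) + 1 if f.score > 0 else -1
        rows.append(
            {
                "id_a": haplotypes.ids[i],
                "id_b": haplotypes.ids[j],
                "span_start": span_start,
                "span_end": span_end,
                "score": int(obs[k]),
                "p_raw": float(p_raw[k]),
                "p_corrected": float(p_corr[k]),
                "flagged": member.haplotype_id if member is not None else "",
            }
        )
    return RecombReport(True, frozenset(flagged), pd.DataFrame(rows), n_perm, seed)
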