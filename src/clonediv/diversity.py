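"""Haplotype and nucleotide diversity at any grouping level.

Statistics follow the standard population-genetic estimators:

* haplotype diversity (Nei's unbiased form)  Hd = n (1 - sum p_i^2) / (n - 1)
* average pairwise differences               k  = sum_{i<j} d_ij / C(n, 2)
* nucleotide diversity per site              pi = k / L_effective
* segregating sites                          S  = # analyzed columns with >= 2 states

Multiplicities are expanded exactly (no sampling).  Site exclusion defaults to
"complete deletion": any column carrying a gap or N in the analyzed subset is
dropped before computing pi, S and k, so L_effective is the number of columns
that survive; pairwise deletion is available as an option for k and pi.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._distance import VALID_CODE_MAX, encode
from .errors import ParameterError, UndefinedStatisticError
from .seq_io import Alignment, HaplotypeTable

__all__ = [
    "DiversitySummary",
    "haplotype_diversity",
    "nucleotide_diversity",
    "segregating_sites",
    "avg_pairwise_differences",
    "summarize_groups",
]


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Nei's unbiased haplotype diversity from haplotype multiplicities."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise UndefinedStatisticError(f"haplotype diversity undefined for n = {n}")
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return n * (1.0 - sum_p2) / (n - 1)


def _weights(alignment: Alignment, weights: Sequence[int] | None) -> np.ndarray:
    if weights is None:
        w = np.ones(len(alignment), dtype=np.int64)
    else:
        w = np.asarray(weights, dtype=np.int64)
        if w.shape != (len(alignment),) or (w < 0).any():
            raise ParameterError("weights must be one non-negative integer per sequence")
    return w


def _analyzed_columns(enc: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Complete-deletion mask: columns where every weighted sequence is unambiguous."""
    present = enc[w > 0]
    return (present <= VALID_CODE_MAX).all(axis=0)


def segregating_sites(alignment: Alignment, weights: Sequence[int] | None = None) -> int:
    """Number of analyzed columns (complete deletion) with >= 2 character states."""
    w = _weights(alignment, weights)
    if int(w.sum()) < 2:
        raise UndefinedStatisticError("segregating sites undefined for n < 2")
    enc = encode(alignment.seqs)
    cols = enc[w > 0][:, _analyzed_columns(enc, w)]
    return int((cols != cols[0]).any(axis=0).sum())


def _pair_stats(alignment: Alignment, w: np.ndarray, deletion: str) -> tuple[float, int]:
    """(average pairwise differences, L_effective) over the expanded multiset."""
    n = int(w.sum())
    if n < 2:
        raise UndefinedStatisticError(f"pairwise statistics undefined for n = {n}")
    enc = encode(alignment.seqs)
    if deletion == "complete":
        mask = _analyzed_columns(enc, w)
        l_eff = int(mask.sum())
        if l_eff == 0:
            raise UndefinedStatisticError("all sites excluded under complete deletion")
        cols = enc[:, mask]
        # per-column allele counts over the expanded multiset
        diff_pairs = 0.0
        for j in range(l_eff):
            col = cols[:, j]
            counts = np.bincount(col, weights=w, minlength=VALID_CODE_MAX + 1)[: VALID_CODE_MAX + 1]
            diff_pairs += (n * n - float((counts**2).sum())) / 2.0
        k = diff_pairs / (n * (n - 1) / 2.0)
        return k, l_eff
    elif deletion == "pairwise":
        idx = np.flatnonzero(w > 0)
        valid = enc <= VALID_CODE_MAX
        total_d = 0.0
        total_pairs = 0.0
        total_sites = 0.0
        for a_pos, i in enumerate(idx):
            for j in idx[a_pos + 1 :]:
                ok = valid[i] & valid[j]
                d = float(((enc[i] != enc[j]) & ok).sum())
                npairs = float(w[i] * w[j])
                total_d += d * npairs
                total_pairs += npairs
                total_sites += float(ok.sum()) * npairs
            # within-haplotype pairs contribute zero differences
            total_pairs += w[i] * (w[i] - 1) / 2.0
            total_sites += float(valid[i].sum()) * w[i] * (w[i] - 1) / 2.0
        if total_pairs == 0:
            raise UndefinedStatisticError("no sequence pairs")
        k = total_d / total_pairs
        l_eff = int(round(total_sites / total_pairs)) if total_sites else 0
        if l_eff == 0:
            raise UndefinedStatisticError("all sites excluded under pairwise deletion")
        return k, l_eff
    raise ParameterError(f"unknown deletion rule {deletion!r}")


def avg_pairwise_differences(
    alignment: Alignment,
    weights: Sequence[int] | None = None,
    deletion: str = "complete",
) -> float:
    """Average number of pairwise nucleotide differences, k."""
    w = _weights(alignment, weights)
    k, _ = _pair_stats(alignment, w, deletion)
    return k


def nucleotide_diversity(
    alignment: Alignment,
    weights: Sequence[int] | None = None,
    deletion: str = "complete",
) -> float:
    """Per-site nucleotide diversity, pi = k / L_effective."""
    w = _weights(alignment, weights)
    k, l_eff = _pair_stats(alignment, w, deletion)
    return k / l_eff


@dataclass(frozen=True)
class DiversitySummary:
    group_label: str
    n_sequences: int
    n_haplotypes: int
    hd: float
    pi: float
    s: int
    k: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.hd)


def _summary_for(label: str, seqs: tuple[str, ...], weights: np.ndarray) -> DiversitySummary:
    n = int(weights.sum())
    n_hap = int((weights > 0).sum())
    if n < 2:
        nan = float("nan")
        return DiversitySummary(label, n, n_hap, nan, nan, 0, nan)
    aln = Alignment(ids=tuple(f"s{i}" for i in range(len(seqs))), seqs=seqs)
    hd = haplotype_diversity([int(c) for c in weights if c > 0])
    k, l_eff = _pair_stats(aln, weights, "complete")
    s = segregating_sites(aln, weights)
    return DiversitySummary(label, n, n_hap, hd, k / l_eff, s, k)


def summarize_groups(
    haplotypes: HaplotypeTable,
    grouping: dict[str, str] | None = None,
    dataset_label: str = "all",
) -> list[DiversitySummary]:
    """Per-group diversity summaries plus a whole-dataset row.

    ``grouping`` maps individual ids to group labels and must cover every
    carrier; per-group haplotype multiplicities are the clone counts of that
    haplotype among the group's individuals.  Groups with n < 2 are reported
    with NaN statistics rather than dropped.
    """
    seqs = haplotypes.sequences
    total_w = np.array(haplotypes.counts, dtype=np.int64)
    out = [_summary_for(dataset_label, seqs, total_w)]
    if grouping is None:
        return out
    carriers = {ind for h in haplotypes for ind in h.carrier_counts}
    missing = carriers - set(grouping)
    if missing:
        raise ParameterError(f"grouping does not cover individuals: {sorted(missing)}")
    groups = sorted(set(grouping[i] for i in carriers))
    for g in groups:
        members = {i for i in carriers if grouping[i] == g}
        w = np.array(
            [sum(c for ind, c in h.carrier_counts.items() if ind in members) for h in haplotypes],
            dtype=np.int64,
        )
        keep = w > 0
        sub_seqs = tuple(s for s, k_ in zip(seqs, keep) if k_)
        out.append(_summary_for(g, sub_seqs, w[keep]))
    return out


def summaries_to_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    """TSV-ready table; Hd printed to 3 decimals and pi to 5, as is conventional."""
    df = pd.DataFrame([s.__dict__ for s in summaries])
    df = df.rename(
        columns={
            "group_label": "group",
            "hd": "Hd",
            "pi": "pi",
            "s": "segregating_sites",
            "k": "avg_pairwise_diff",
        }
    )
    df["Hd"] = df["Hd"].round(3)
    df["pi"] = df["pi"].round(5)
    return df[["group", "Hd", "pi", "n_haplotypes", "n_sequences", "segregating_sites", "avg_pairwise_diff"]]
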