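"""Population diversity statistics: N, K, S, pi, H, Hd.

Implements the standard polymorphism summary statistics for a collapsed
haplotype table: the unbiased (Nei) haplotype diversity
``Hd = n(1 - sum p_i^2)/(n - 1)``, the mean number of pairwise nucleotide
differences K, the nucleotide diversity ``pi = K / L_used``, and the
segregating-site count S, per population and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeTable

__all__ = [
    "DiversityReport",
    "haplotype_diversity",
    "mean_pairwise_differences",
    "nucleotide_diversity",
    "diversity_report",
]


def haplotype_diversity(counts) -> float:
    """Unbiased haplotype diversity Hd = n(1 - sum p_i^2) / (n - 1).

    `counts` are per-haplotype sample counts (zeros allowed and ignored).
    The estimator is the small-sample-corrected probability that two
    sequences drawn without replacement carry different haplotypes.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires at least 2 sequences")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def mean_pairwise_differences(counts, dist) -> float:
    """Mean number of nucleotide differences K over all sequence pairs.

    K = sum_{i<j} n_i n_j d_ij / C(n, 2), where n_i are haplotype counts and
    d_ij the pairwise mutational distances; same-haplotype pairs contribute 0.
    """
    c = np.asarray(counts, dtype=float)
    d = np.asarray(dist, dtype=float)
    if d.shape != (c.size, c.size):
        raise ValueError(f"distance matrix shape {d.shape} does not match {c.size} counts")
    n = c.sum()
    if n < 2:
        raise ValueError("K requires at least 2 sequences")
    total = 0.5 * c @ d @ c  # off-diagonal ordered pairs / 2; d_ii = 0
    return float(total / (n * (n - 1) / 2.0))


def nucleotide_diversity(K: float, L_used: int) -> float:
    """Per-site diversity pi = K / L_used."""
    if L_used < 1:
        raise ValueError("L_used must be >= 1")
    return float(K) / float(L_used)


@dataclass(frozen=True)
class DiversityReport:
    """Per-population diversity table plus a pooled "All" row."""

    frame: pd.DataFrame  # columns: population, N, K, S, pi, H, Hd, L_used

    def row(self, population: str) -> pd.Series:
        sel = self.frame[self.frame["population"] == population]
        if sel.empty:
            raise KeyError(population)
        return sel.iloc[0]

    def to_tsv(self, path) -> None:
        """Render with report precision: K and Hd to 3 dp, pi to 3 significant figures."""
        out = self.frame.copy()
        out["K"] = out["K"].map(lambda v: f"{v:.3f}")
        out["Hd"] = out["Hd"].map(lambda v: f"{v:.3f}")
        out["pi"] = out["pi"].map(lambda v: f"{v:.3g}")
        out.to_csv(path, sep="\t", index=False)


def _subset_segregating_sites(table: HaplotypeTable, counts: np.ndarray) -> int:
    """S over the haplotype sequences present (count > 0) in a subset."""
    present = [s for s, c in zip(table.sequences, counts) if c > 0]
    arr = np.array([list(s) for s in present])
    return int((arr != arr[0]).any(axis=0).sum())


def diversity_report(table: HaplotypeTable, L_used: int) -> DiversityReport:
    """Compute N, K, S, pi, H, Hd per population and pooled over all.

    The "All" row is computed from the pooled haplotype counts (its H is the
    number of distinct haplotypes overall, never a sum of per-population H).
    """
    if L_used < 1:
        raise ValueError("L_used must be >= 1")
    rows = []
    groups = [(p, table.population_counts(p)) for p in table.populations]
    groups.append(("All", table.total_counts))
    for label, counts in groups:
        n = int(counts.sum())
        if n == 0:
            raise ValueError(f"population {label!r} has no sequences")
        K = mean_pairwise_differences(counts, table.dist)
        S = _subset_segregating_sites(table, counts)
        H = int((counts > 0).sum())
        Hd = haplotype_diversity(counts)
        rows.append(
            {
                "population": label,
                "N": n,
                "K": K,
                "S": S,
                "pi": nucleotide_diversity(K, L_used),
                "H": H,
                "Hd": Hd,
                "L_used": L_used,
            }
        )
    return DiversityReport(frame=pd.DataFrame(rows))
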