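"""Haplotype collapsing, mutational distances, and segregating sites.

Reproduces the site handling of standard polymorphism software: alignment
columns containing a gap or ambiguity code in *any* sequence are excluded
once for the whole dataset (complete deletion), then identical sequences are
grouped into haplotypes with per-population counts and a pairwise Hamming
distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignio import AlignedSeqSet

__all__ = [
    "SiteFilterResult",
    "PopulationPartition",
    "HaplotypeTable",
    "complete_deletion",
    "collapse_haplotypes",
    "segregating_sites",
    "pairwise_distance",
    "read_population_map",
]


@dataclass(frozen=True)
class SiteFilterResult:
    """Outcome of a column filter: retained 0-based columns and exclusion count."""

    retained_columns: tuple[int, ...]
    n_excluded: int

    @property
    def length_used(self) -> int:
        return len(self.retained_columns)


def complete_deletion(seqs: AlignedSeqSet) -> tuple[AlignedSeqSet, SiteFilterResult]:
    """Drop every column holding a gap or ambiguity code in any sequence."""
    arr = np.array([list(s) for s in seqs.sequences])
    clean = np.isin(arr, list("ACGT")).all(axis=0)
    retained = tuple(int(c) for c in np.flatnonzero(clean))
    if not retained:
        raise ValueError("complete deletion removed every column")
    result = SiteFilterResult(retained_columns=retained, n_excluded=seqs.length - len(retained))
    if result.n_excluded == 0:
        return seqs, result
    return seqs.select_columns(retained), result


@dataclass(frozen=True)
class PopulationPartition:
    """Mapping from sample_id to population label."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty population partition")
        for sid, pop in self.mapping.items():
            if not sid or not pop:
                raise ValueError("sample ids and population labels must be non-empty")

    @property
    def populations(self) -> tuple[str, ...]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for pop in self.mapping.values():
            seen.setdefault(pop, None)
        return tuple(seen)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tpopulation\n")
            for sid, pop in self.mapping.items():
                fh.write(f"{sid}\t{pop}\n")


def read_population_map(path) -> PopulationPartition:
    """Read a 2-column TSV (sample_id, population); a header row is optional."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 tab-separated columns")
    if list(df.iloc[0, :2]) == ["sample_id", "population"]:
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(mapping) != len(df):
        raise ValueError(f"{path}: duplicate sample_ids in population map")
    return PopulationPartition(mapping=mapping)


def pairwise_distance(hap_a: str, hap_b: str) -> int:
    """Hamming distance between two equal-length sequences."""
    if len(hap_a) != len(hap_b):
        raise ValueError(f"length mismatch: {len(hap_a)} vs {len(hap_b)}")
    return sum(a != b for a, b in zip(hap_a, hap_b))


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes with per-population counts and pairwise distances.

    ``counts[i, j]`` is the number of sampled copies of haplotype ``i`` in
    population ``j``; ``dist[i, k]`` the Hamming distance between haplotype
    sequences ``i`` and ``k``. Haplotype ids are assigned by descending total
    count, ties broken by first appearance in the input alignment.
    """

    hap_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    populations: tuple[str, ...]
    counts: np.ndarray
    dist: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_ids)

    @property
    def n_sequences(self) -> int:
        return int(self.counts.sum())

    @property
    def total_counts(self) -> np.ndarray:
        """Per-haplotype counts pooled over populations."""
        return self.counts.sum(axis=1)

    @property
    def population_sizes(self) -> dict[str, int]:
        return {p: int(self.counts[:, j].sum()) for j, p in enumerate(self.populations)}

    def population_counts(self, population: str) -> np.ndarray:
        j = self.populations.index(population)
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.hap_ids), columns=list(self.populations))
        df.index.name = "hap_id"
        df["total"] = self.counts.sum(axis=1)
        return df

    def counts_to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def dist_to_tsv(self, path) -> None:
        pd.DataFrame(self.dist, index=list(self.hap_ids), columns=list(self.hap_ids)).to_csv(
            path, sep="\t", index_label="hap_id"
        )


def collapse_haplotypes(seqs: AlignedSeqSet, partition: PopulationPartition) -> HaplotypeTable:
    """Group identical sequences into haplotypes with per-population counts.

    Must be called after :func:`complete_deletion`; distinctness is exact
    string equality over the retained columns. Raises if a mapped sample is
    missing from the alignment or an aligned sample is unmapped.
    """
    ids = set(seqs.sample_ids)
    missing = set(partition.mapping) - ids
    if missing:
        raise KeyError(f"partition samples absent from alignment: {sorted(missing)}")
    unmapped = ids - set(partition.mapping)
    if unmapped:
        raise KeyError(f"alignment samples missing from partition: {sorted(unmapped)}")

    populations = partition.populations
    pop_index = {p: j for j, p in enumerate(populations)}

    first_seen: dict[str, int] = {}
    tallies: dict[str, np.ndarray] = {}
    for idx, (sid, seq) in enumerate(seqs.records):
        if seq not in tallies:
            first_seen[seq] = idx
            tallies[seq] = np.zeros(len(populations), dtype=int)
        tallies[seq][pop_index[partition.mapping[sid]]] += 1

    ordered = sorted(tallies, key=lambda s: (-int(tallies[s].sum()), first_seen[s]))
    hap_ids = tuple(f"Hap{i + 1}" for i in range(len(ordered)))
    counts = np.stack([tallies[s] for s in ordered])
    arr = np.array([list(s) for s in ordered])
    dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(int)
    return HaplotypeTable(
        hap_ids=hap_ids,
        sequences=tuple(ordered),
        populations=populations,
        counts=counts,
        dist=dist,
    )


def segregating_sites(seqs: AlignedSeqSet) -> int:
    """Number of columns with two or more distinct observed bases.

    Assumes :func:`complete_deletion` has been applied, so every symbol is a
    concrete base.
    """
    arr = np.array([list(s) for s in seqs.sequences])
    return int((arr != arr[0]).any(axis=0).sum())
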