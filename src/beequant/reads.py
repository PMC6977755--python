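"""FASTQ reads -> taxon-by-sample count table.

The processing chain mirrors a standard amplicon workflow on merged reads:
expected-error filtering, exact dereplication with a replicate-count floor
(>= 10 reads for taxa pools, >= 2 for community pools), and assignment of
each unique sequence to its best-matching reference by global alignment at
a minimum identity (default 99%).  Ties at the best identity are tallied
as ambiguous rather than assigned; hits to the spike-in calibrator are
tallied separately and excluded from the taxon matrix, so the per-sample
accounting identity

    mapped + unassigned + ambiguous + calibrator = post-filter reads

always holds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import FormatError
from .simulate import ReadBatch, ReferenceDB

#: Replicate-count floors: taxa pools keep uniques with >= 10 reads (used to
#: validate reference sequences), community pools keep uniques with >= 2.
MIN_REPLICATES = {"taxa": 10, "community": 2}

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def expected_errors(quality: str) -> float:
    """Expected number of errors E = sum_b 10^(-Q_b/10) of a quality string.

    Raises :class:`FormatError` on characters outside the Phred+33 range.
    """
    total = 0.0
    for ch in quality:
        q = ord(ch) - 33
        if q < 0 or q > 93:
            raise FormatError(f"invalid Phred+33 quality character {ch!r}")
        total += 10.0 ** (-q / 10.0)
    return total


@dataclass
class UniqueSequenceSet:
    """Exactly dereplicated post-filter reads of one sample."""

    sample_id: str
    entries: list[tuple[str, int]] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(count for _, count in self.entries)


def filter_and_dereplicate(
    batch: ReadBatch, max_expected_errors: float = 1.0, min_replicates: int = 2
) -> UniqueSequenceSet:
    """Drop error-prone reads, collapse identical survivors, floor the counts.

    A read is discarded when its expected-error statistic reaches
    ``max_expected_errors`` (strict: E >= threshold removes the read, i.e.
    reads with at least one predicted error are removed at the default of
    1.0).  Survivors are dereplicated by exact full-length string equality
    and uniques with fewer than ``min_replicates`` replicates are dropped.
    """
    tally: dict[str, int] = {}
    for _, seq, qual in batch.reads:
        if expected_errors(qual) >= max_expected_errors:
            continue
        tally[seq] = tally.get(seq, 0) + 1
    entries = [
        (seq, count) for seq, count in tally.items() if count >= min_replicates
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return UniqueSequenceSet(sample_id=batch.sample_id, entries=entries)


def alignment_identity(query: str, reference: str) -> float:
    """Global (end-to-end) identity: matches / alignment columns.

    Gap columns count against identity, so length variants are penalized.
    """
    res = edlib.align(query, reference, mode="NW", task="path")
    columns = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return (columns - res["editDistance"]) / columns


@dataclass
class ReadCountTable:
    """Samples x taxa read counts plus unassigned/ambiguous/calibrator tallies."""

    counts: pd.DataFrame
    tallies: pd.DataFrame  # columns: unassigned, ambiguous, calibrator

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_per_sample(self) -> pd.Series:
        """Post-filter reads per sample (mapped + unassigned + ambiguous + calibrator)."""
        return self.counts.sum(axis=1) + self.tallies.sum(axis=1)

    def to_tsv(self, counts_path, tallies_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        if tallies_path is not None:
            self.tallies.to_csv(tallies_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, tallies_path=None) -> "ReadCountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        if tallies_path is not None and Path(tallies_path).exists():
            tallies = pd.read_csv(tallies_path, sep="\t", index_col=0)
        else:
            tallies = pd.DataFrame(
                0, index=counts.index,
                columns=["unassigned", "ambiguous", "calibrator"],
            )
        return cls(counts=counts, tallies=tallies)


def _best_hits(
    seq: str, refdb: ReferenceDB, min_identity: float
) -> tuple[list[str], float]:
    """Taxa achieving the best identity >= min_identity for one sequence."""
    best: list[str] = []
    best_identity = -1.0
    for taxon, _, ref in refdb:
        ident = alignment_identity(seq, ref)
        if ident > best_identity:
            best_identity = ident
            best = [taxon]
        elif ident == best_identity:
            best.append(taxon)
    if best_identity < min_identity:
        return [], best_identity
    return best, best_identity


def map_and_tabulate(
    uniques: Sequence[UniqueSequenceSet],
    refdb: ReferenceDB,
    min_identity: float = 0.99,
    calibrator_taxon: str | None = None,
) -> ReadCountTable:
    """Assign unique sequences to references and tabulate read counts.

    Each unique sequence is globally aligned to every reference and assigned
    to the single best reference with identity >= ``min_identity``; its
    replicate count is added to that taxon's cell.  Ties at the best
    identity go to the ambiguous tally; best identity below the threshold
    goes to unassigned; hits to ``calibrator_taxon`` are tallied separately.
    """
    if len(refdb) == 0:
        raise ValueError("reference database is empty")
    taxa = [t for t in refdb.taxa if t != calibrator_taxon]
    samples = [u.sample_id for u in uniques]
    counts = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"), columns=taxa, dtype=np.int64
    )
    tallies = pd.DataFrame(
        0, index=counts.index,
        columns=["unassigned", "ambiguous", "calibrator"], dtype=np.int64,
    )
    cache: dict[str, list[str]] = {}
    for uset in uniques:
        for seq, n in uset.entries:
            if seq not in cache:
                cache[seq], _ = _best_hits(seq, refdb, min_identity)
            hits = cache[seq]
            if not hits:
                tallies.loc[uset.sample_id, "unassigned"] += n
            elif len(hits) > 1:
                tallies.loc[uset.sample_id, "ambiguous"] += n
            elif hits[0] == calibrator_taxon:
                tallies.loc[uset.sample_id, "calibrator"] += n
            else:
                counts.loc[uset.sample_id, hits[0]] += n
    return ReadCountTable(counts=counts, tallies=tallies)


def process_batches(
    batches: Sequence[ReadBatch],
    refdb: ReferenceDB,
    mode: str = "community",
    max_expected_errors: float = 1.0,
    min_identity: float = 0.99,
    calibrator_taxon: str | None = None,
) -> ReadCountTable:
    """Full chain: filter, dereplicate (mode-specific floor), map, tabulate."""
    if mode not in MIN_REPLICATES:
        raise ValueError(f"mode must be one of {sorted(MIN_REPLICATES)}")
    uniques = [
        filter_and_dereplicate(b, max_expected_errors, MIN_REPLICATES[mode])
        for b in batches
    ]
    return map_and_tabulate(uniques, refdb, min_identity, calibrator_taxon)


def distinguishable_targets(refdb: ReferenceDB, min_identity: float = 0.99) -> int:
    """Number of reference clusters separable at the mapping threshold.

    References within ``min_identity`` of each other cannot be told apart by
    identity-threshold mapping (reads from one hit both); single-linkage
    clusters of such references are counted as one distinguishable target.
    A low-divergence locus therefore yields fewer targets than taxa.
    """
    n = len(refdb)
    seqs = [seq for _, _, seq in refdb]
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if alignment_identity(seqs[i], seqs[j]) >= min_identity:
                rows += [i, j]
                cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_components, _ = connected_components(graph, directed=False)
    return int(n_components)


def read_specimen_table(path) -> pd.DataFrame:
    """Read a samples x taxa TSV (first column sample_id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_specimen_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_rank_map(path) -> dict[str, str]:
    """Read a two-column taxon -> genus TSV."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
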