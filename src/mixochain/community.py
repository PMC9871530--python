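"""ASV count-table operations: rarefaction, abundance views, clustering.

Counts live in a pandas DataFrame (samples × ASVs) together with
per-sample metadata (reactor and sampling day), an optional taxonomy map
and optional ASV sequences.  Rarefaction subsamples each sample without
replacement to a common depth (by default the smallest sample sum) with a
per-sample random substream, so adding or removing samples never changes
the draw for the others.

For a coarse view of sequence relatedness among abundant ASVs, pairwise
percent identities from global alignment feed an average-linkage
hierarchical clustering — a lightweight surrogate for reference-database
searches, not a replacement for them.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import squareform

__all__ = [
    "AsvMatrix",
    "ClusterResult",
    "RANKS",
    "rarefy",
    "relative_abundance",
    "aggregate",
    "top_n",
    "pairwise_identity",
    "identity_matrix",
    "cluster_asvs",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class AsvMatrix:
    """Sample × ASV integer counts with metadata.

    ``counts`` is indexed by sample id with one column per ASV id;
    ``sample_meta`` is indexed identically with columns ``reactor_id``
    and ``time_d``.  ``taxonomy`` maps ASV id → ranked lineage (a tuple
    ordered domain → species); ``sequences`` maps ASV id → nucleotide
    string.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    taxonomy: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    sequences: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts.values, np.round(self.counts.values)):
            raise ValueError("counts must be integers")
        if self.sample_meta is not None:
            missing = set(self.counts.index) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)}")
            for reactor, grp in self.sample_meta.loc[self.counts.index].groupby(
                "reactor_id", sort=False
            ):
                times = grp["time_d"].to_numpy()
                if (np.diff(times) <= 0).any():
                    raise ValueError(
                        f"sample times not strictly increasing for reactor "
                        f"{reactor!r}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def meta_for(self, sample_id: str) -> tuple[str, float]:
        if self.sample_meta is None:
            raise ValueError("matrix has no sample metadata")
        row = self.sample_meta.loc[sample_id]
        return str(row["reactor_id"]), float(row["time_d"])


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # substream keyed by (seed, sample id): stable under adding samples
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def rarefy(m: AsvMatrix, depth: int | None = None, seed: int = 0) -> AsvMatrix:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the smallest sample sum.  Samples with fewer
    reads than ``depth`` are dropped with a warning.  The draw is
    multivariate hypergeometric, so taxa absent from a sample stay absent
    and the result with a given seed is bit-reproducible.
    """
    sums = m.counts.sum(axis=1)
    if depth is None:
        depth = int(sums.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep, rows = [], []
    for sample_id, row in m.counts.iterrows():
        if sums[sample_id] < depth:
            warnings.warn(
                f"sample {sample_id!r} has {int(sums[sample_id])} reads "
                f"< depth {depth}; dropped",
                stacklevel=2,
            )
            continue
        rng = _sample_rng(seed, str(sample_id))
        rows.append(
            rng.multivariate_hypergeometric(row.to_numpy(dtype=np.int64), depth)
        )
        keep.append(sample_id)
    counts = pd.DataFrame(rows, index=keep, columns=m.counts.columns, dtype=np.int64)
    meta = None if m.sample_meta is None else m.sample_meta.loc[keep]
    return replace(m, counts=counts, sample_meta=meta)


def relative_abundance(m: AsvMatrix) -> pd.DataFrame:
    """Per-sample proportions; rows sum to 1."""
    sums = m.counts.sum(axis=1)
    if (sums == 0).any():
        empty = list(m.counts.index[sums == 0])
        raise ValueError(f"all-zero samples: {empty}")
    return m.counts.div(sums, axis=0)


def aggregate(m: AsvMatrix, rank: str) -> AsvMatrix:
    """Sum counts of ASVs sharing the lineage label at ``rank``.

    ASVs without taxonomy (or with a lineage shorter than the requested
    rank) are pooled under ``"unclassified"``.  Column sums are preserved
    exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    level = RANKS.index(rank)
    labels = {}
    for asv in m.asv_ids:
        lineage = m.taxonomy.get(asv, ())
        labels[asv] = lineage[level] if len(lineage) > level else "unclassified"
    counts = m.counts.T.groupby(pd.Series(labels)).sum().T
    counts = counts[sorted(counts.columns)]
    return AsvMatrix(counts=counts, sample_meta=m.sample_meta)


def top_n(m: AsvMatrix, n: int) -> AsvMatrix:
    """Restrict to the ``n`` taxa with highest mean relative abundance.

    Ties break lexicographically on the taxon id, so the selection is
    deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    means = relative_abundance(m).mean(axis=0)
    order = sorted(means.index, key=lambda a: (-means[a], a))
    chosen = order[: min(n, len(order))]
    return replace(
        m,
        counts=m.counts[chosen],
        taxonomy={a: m.taxonomy[a] for a in chosen if a in m.taxonomy},
        sequences={a: m.sequences[a] for a in chosen if a in m.sequences},
    )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def _validate_sequence(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"empty sequence for {label}")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"non-nucleotide characters in {label}: {sorted(bad)}"
        )
    return seq


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from global alignment.

    Scoring: match +1, mismatch 0, gap −1 per gapped position.  Identity
    is matched columns over total alignment length (including gap
    columns), in percent.  Symmetric by construction.
    """
    a = _validate_sequence(seq_a, "seq_a")
    b = _validate_sequence(seq_b, "seq_b")
    alignment = _make_aligner().align(a, b)[0]
    matches = sum(
        1
        for ca, cb in zip(alignment[0], alignment[1])
        if ca == cb and ca != "-"
    )
    return 100.0 * matches / alignment.length


def identity_matrix(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Symmetric percent-identity matrix for a set of named sequences."""
    ids = sorted(sequences)
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ident = pairwise_identity(sequences[a], sequences[b])
            mat.loc[a, b] = mat.loc[b, a] = ident
    return mat


@dataclass(frozen=True)
class ClusterResult:
    """Average-linkage clustering of ASVs on identity distance."""

    asv_ids: list[str]
    identity: pd.DataFrame          # percent identity, symmetric
    linkage: np.ndarray             # scipy linkage matrix on (100 − identity)
    groups: dict[str, int]          # asv id → flat group label
    leaf_order: list[str]           # dendrogram leaf ordering

    def n_groups(self) -> int:
        return len(set(self.groups.values()))


def cluster_asvs(
    m: AsvMatrix,
    *,
    taxon_filter: str | None = None,
    n_top: int = 25,
    identity_threshold: float = 99.0,
) -> ClusterResult:
    """Cluster abundant ASVs by pairwise sequence identity.

    ASVs are first restricted to the ``n_top`` most abundant, then
    optionally to those whose lineage contains ``taxon_filter`` (substring
    match on any rank, case-insensitive).  Average linkage runs on the
    distance 100 − identity, and flat groups cut the tree so that members
    of a group average at least ``identity_threshold`` percent identity.
    Input order of sequences does not affect the result.
    """
    selected = top_n(m, n_top)
    ids = sorted(selected.asv_ids)
    if taxon_filter is not None:
        needle = taxon_filter.lower()
        ids = [
            a
            for a in ids
            if any(needle in r.lower() for r in m.taxonomy.get(a, ()))
        ]
    missing = [a for a in ids if a not in m.sequences]
    if missing:
        raise ValueError(f"no sequence for ASVs: {missing}")
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences to cluster")
    ident = identity_matrix({a: m.sequences[a] for a in ids})
    dist = 100.0 - ident.to_numpy()
    np.fill_diagonal(dist, 0.0)
    linkage = average(squareform(dist, checks=False))
    flat = fcluster(linkage, t=100.0 - identity_threshold, criterion="distance")
    order = [ids[i] for i in leaves_list(linkage)]
    return ClusterResult(
        asv_ids=ids,
        identity=ident,
        linkage=linkage,
        groups=dict(zip(ids, (int(g) for g in flat))),
        leaf_order=order,
    )
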