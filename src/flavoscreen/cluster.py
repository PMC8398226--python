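"""Greedy incremental sequence clustering at a percent-identity threshold.

Sequences are visited in order of decreasing length (ties broken by id) and
each joins the first existing cluster whose representative it matches at or
above the threshold, else founds a new cluster — so every representative is
the longest member of its cluster.  Cluster sizes can be weighted by the
redundant occurrence counts behind each member, which is how representative
sets are scaled for downstream tree building.

Identity here is the gap-tolerant global identity used by greedy clusterers:
the maximal number of residues that can be paired identically in a global
alignment of the two sequences (their longest common subsequence), divided
by the length of the shorter sequence.  This deliberately differs from the
alignment-column PID used in hit filtering; both definitions are documented
side by side in the methods note.  No short-word prefilter is applied — the
identity is computed by full dynamic programming for every comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _dp
from .align import encode


@dataclass
class SeqCluster:
    cluster_id: str
    representative_id: str
    member_ids: list[str]
    weighted_size: int


def cluster_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over the shorter sequence (LCS-based, global)."""
    a = encode(seq_a)
    b = encode(seq_b)
    shorter = min(len(a), len(b))
    if shorter == 0:
        raise ValueError("sequences must be non-empty")
    return 100.0 * _dp.lcs_length(a, b) / shorter


def greedy_cluster(
    sequences: Sequence[tuple[str, str]],
    threshold_pid: float = 90.0,
    weights: Mapping[str, int] | None = None,
) -> list[SeqCluster]:
    """First-fit greedy clustering of (id, sequence) pairs.

    Deterministic under the fixed visiting order (descending length, then
    id).  ``weights`` maps sequence ids to redundant occurrence counts
    (default 1 each); a cluster's ``weighted_size`` is the sum over members.
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    if not 0.0 < threshold_pid <= 100.0:
        raise ValueError("threshold_pid must be in (0, 100]")
    weights = weights or {}
    ordered = sorted(sequences, key=lambda item: (-len(item[1]), item[0]))
    clusters: list[SeqCluster] = []
    rep_seqs: list[str] = []
    for seq_id, seq in ordered:
        placed = False
        for cluster, rep_seq in zip(clusters, rep_seqs):
            if cluster_identity(seq, rep_seq) >= threshold_pid:
                cluster.member_ids.append(seq_id)
                cluster.weighted_size += int(weights.get(seq_id, 1))
                placed = True
                break
        if not placed:
            clusters.append(
                SeqCluster(
                    cluster_id=f"cluster_{len(clusters) + 1:04d}",
                    representative_id=seq_id,
                    member_ids=[seq_id],
                    weighted_size=int(weights.get(seq_id, 1)),
                )
            )
            rep_seqs.append(seq)
    return clusters


def export_cluster_fasta(
    clusters: Sequence[SeqCluster],
    sequences: Mapping[str, str],
    out_path: str | Path,
) -> None:
    """Write one FASTA record per cluster representative; the header carries
    the cluster id and weighted size."""
    if not clusters:
        raise ValueError("clusters must be non-empty")
    with open(out_path, "w") as fh:
        for cluster in clusters:
            seq = sequences[cluster.representative_id]
            fh.write(
                f">{cluster.representative_id} {cluster.cluster_id} "
                f"weighted_size={cluster.weighted_size}\n"
            )
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def membership_table(clusters: Sequence[SeqCluster]):
    """Cluster membership rows: (cluster_id, member_id, is_representative,
    weighted_size)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "member_id": m,
                "is_representative": int(m == c.representative_id),
                "weighted_size": c.weighted_size,
            }
            for c in clusters
            for m in c.member_ids
        ]
    )
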