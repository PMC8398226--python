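"""Threshold filtering and best-bitscore deduplication of alignment hits.

Hits are retained when they pass, inclusively, the percent-identity floor
(default 30), the query-coverage floor (default 75%) and the per-class
e-value cutoff of their query.  A representative protein hit by several
queries is then reduced to the single best-bitscore hit, so each catalog
protein contributes to at most one query (and hence one pathway).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import AlignmentHit
from .registry import QueryRegistry, evalue_threshold_for


@dataclass(frozen=True)
class FilterConfig:
    """Retention thresholds; boundaries are inclusive ("at least")."""

    min_pid: float = 30.0
    min_qcov: float = 75.0
    evalue_overrides: dict | None = None  # evalue_class -> cutoff

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_pid <= 100.0:
            raise ValueError("min_pid must be in [0, 100]")
        if not 0.0 <= self.min_qcov <= 100.0:
            raise ValueError("min_qcov must be in [0, 100]")


def apply_thresholds(
    hits: Iterable[AlignmentHit],
    config: FilterConfig,
    registry: QueryRegistry,
) -> list[AlignmentHit]:
    """Keep hits with evalue <= class cutoff, pid >= min_pid, qcov >= min_qcov.

    Input order is preserved.  A hit whose query is not in the registry is an
    error.
    """
    retained = []
    overrides = config.evalue_overrides or {}
    for hit in hits:
        query = registry.get(hit.query_id)
        if query is None:
            raise KeyError(f"hit references unknown query_id {hit.query_id!r}")
        cutoff = overrides.get(query.evalue_class, evalue_threshold_for(query))
        if hit.evalue <= cutoff and hit.pid >= config.min_pid and hit.qcov >= config.min_qcov:
            retained.append(hit)
    return retained


def best_hit_per_target(
    hits: Iterable[AlignmentHit], scope_by: QueryRegistry | None = None, dedup_scope: str = "global"
) -> list[AlignmentHit]:
    """Keep one hit per target: maximal bitscore, ties by higher pid, then
    lexicographically smallest query_id.

    ``dedup_scope="pathway"`` dedups within each query's pathway group instead
    of across all queries (requires a registry).
    """
    if dedup_scope not in {"global", "pathway"}:
        raise ValueError(f"unknown dedup scope {dedup_scope!r}")
    if dedup_scope == "pathway" and scope_by is None:
        raise ValueError("pathway-scoped dedup requires a registry")
    best: dict[tuple, AlignmentHit] = {}
    for hit in hits:
        if dedup_scope == "pathway":
            key = (scope_by.pathway_of(hit.query_id), hit.target_id)  # type: ignore[union-attr]
        else:
            key = (hit.target_id,)
        cur = best.get(key)
        if cur is None or (-hit.bitscore, -hit.pid, hit.query_id) < (
            -cur.bitscore,
            -cur.pid,
            cur.query_id,
        ):
            best[key] = hit
    return sorted(best.values(), key=lambda h: (h.query_id, h.target_id))


DEFAULT_BIN_EDGES = (30.0, 40.0, 50.0, 65.0, 80.0, 90.0, 100.0)


def pid_bin(pid: float, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES) -> str:
    """Label of the half-open PID bin [edge_i, edge_{i+1}) containing ``pid``;
    the top bin is closed at 100."""
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    if not 0.0 <= pid <= 100.0:
        raise ValueError(f"pid {pid} outside [0, 100]")
    if pid < edges[0]:
        raise ValueError(f"pid {pid} below the first bin edge {edges[0]}")
    for lo, hi in zip(edges, edges[1:]):
        if lo <= pid < hi:
            return _label(lo, hi)
    return _label(edges[-2], edges[-1])  # pid == top edge: closed top bin


def _label(lo: float, hi: float) -> str:
    fmt = lambda x: f"{int(x)}" if float(x).is_integer() else f"{x}"
    return f"{fmt(lo)}-{fmt(hi)}"
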