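"""Prior overlay and differential-expression contextualization.

Overlay merges an inferred network with a curated signed prior, either by
intersection (the default, for a high-confidence network: keep only edges
present in both, weights from inference, signs from the prior) or by
annotation (keep all inferred edges, attach prior signs where known).

Contextualization prunes a parent network against a differential-expression
contrast: a node whose expression changed (called up or down) must be
*justifiable* by at least one sign-consistent, differentially expressed
regulator; nodes that cannot be justified are removed, together with their
incident edges, and removal is repeated until a fixed point.

Justification rules, evaluated against the current (partially pruned)
network:

(i)   declared input nodes are always justified;
(ii)  nodes called "unchanged" need no justification;
(iii) root nodes — nodes without regulators — are justified by convention
      (under the default *strict* convention only nodes that had no
      regulators in the original network qualify; nodes orphaned during
      pruning are re-evaluated under rule iv and fall if their change is
      left unexplained. The *lenient* convention grants root status to any
      currently regulator-less node);
(iv)  a node called up/down is justified if some remaining regulator r with
      call(r) ≠ unchanged satisfies
      direction(call(node)) = sign(r→node) × direction(call(r)),
      where direction(up) = +1 and direction(down) = −1. Edges of unknown
      sign (0) justify either direction by default (``unsigned_justifies``).

All currently unjustified nodes are removed simultaneously in each pass, so
the result is the unique maximal fixed point and is independent of node
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import Network

__all__ = [
    "ContextualizationResult",
    "overlay_prior",
    "is_justified",
    "contextualize",
]

_DIRECTION = {"up": 1, "down": -1}

REASON_INPUT = "input"
REASON_UNCHANGED = "unchanged"
REASON_ROOT = "root"
REASON_UNJUSTIFIED = "no sign-consistent active regulator"


def overlay_prior(inferred: Network, prior: Network, mode: str = "intersect") -> Network:
    """Merge an inferred network with a curated signed prior.

    mode "intersect": keep edges present in both; weight and support from
    the inferred edge, sign from the prior, provenance {inferred, prior}.
    mode "annotate": keep every inferred edge; attach the prior sign where
    the prior knows the edge, sign 0 otherwise.
    """
    if mode not in ("intersect", "annotate"):
        raise ValueError(f"unknown overlay mode {mode!r}")
    prior_signs = prior.sign_map()
    records = []
    for row in inferred.edges.itertuples(index=False):
        key = (row.regulator, row.target)
        in_prior = key in prior_signs
        if mode == "intersect" and not in_prior:
            continue
        records.append(
            {
                "regulator": row.regulator,
                "target": row.target,
                "weight": row.weight,
                "support": row.support,
                "sign": prior_signs[key] if in_prior else 0,
                "provenance": row.provenance
                | {"inferred"}
                | ({"prior"} if in_prior else set()),
            }
        )
    return Network.from_records(records)


def _regulators_of(network: Network) -> dict[str, list[tuple[str, int]]]:
    """node → [(regulator, edge sign)] from the edge table."""
    incoming: dict[str, list[tuple[str, int]]] = {n: [] for n in network.node_set()}
    for row in network.edges.itertuples(index=False):
        incoming[row.target].append((row.regulator, row.sign))
    return incoming


def is_justified(
    node: str,
    network: Network,
    de_calls: Mapping[str, str],
    input_nodes: Iterable[str] = (),
    *,
    root_nodes: Iterable[str] | None = None,
    unsigned_justifies: bool = True,
) -> tuple[bool, str]:
    """Whether a node's expression call is explainable within the network.

    ``root_nodes`` names the nodes granted the root convention (rule iii);
    by default every node without regulators in ``network`` qualifies.
    Raises ``KeyError`` for a node missing from ``de_calls``.
    """
    nodes = network.node_set()
    if node not in nodes:
        raise KeyError(f"node {node!r} not in network")
    if node not in de_calls:
        raise KeyError(f"node {node!r} missing from differential calls")
    incoming = _regulators_of(network)
    if root_nodes is None:
        root_nodes = {n for n in nodes if not incoming[n]}
    else:
        root_nodes = set(root_nodes)
    return _justified(
        node, incoming, de_calls, set(input_nodes), root_nodes, unsigned_justifies
    )


def _justified(
    node: str,
    incoming: Mapping[str, list[tuple[str, int]]],
    de_calls: Mapping[str, str],
    input_nodes: set[str],
    root_nodes: set[str],
    unsigned_justifies: bool,
) -> tuple[bool, str]:
    if node in input_nodes:
        return True, REASON_INPUT
    if node not in de_calls:
        raise KeyError(f"node {node!r} missing from differential calls")
    call = de_calls[node]
    if call == "unchanged":
        return True, REASON_UNCHANGED
    if node in root_nodes:
        return True, REASON_ROOT
    want = _DIRECTION[call]
    for reg, sign in incoming.get(node, ()):
        reg_call = de_calls.get(reg)
        if reg_call is None:
            raise KeyError(f"node {reg!r} missing from differential calls")
        if reg_call == "unchanged":
            continue
        if sign == 0:
            if unsigned_justifies:
                return True, f"consistent regulator {reg} (unsigned edge)"
            continue
        if want == sign * _DIRECTION[reg_call]:
            return True, f"consistent regulator {reg}"
    return False, REASON_UNJUSTIFIED


@dataclass(frozen=True)
class ContextualizationResult:
    """Pruned network plus the removal trace."""

    pruned: Network
    removed: pd.DataFrame  # columns node, reason, iteration
    iterations: int

    @property
    def removed_nodes(self) -> tuple[str, ...]:
        return tuple(self.removed["node"])


def contextualize(
    network: Network,
    de_calls: Mapping[str, str],
    input_nodes: Iterable[str] = (),
    *,
    strict_roots: bool = True,
    unsigned_justifies: bool = True,
) -> ContextualizationResult:
    """Prune a network to nodes whose expression change is justified.

    Each pass removes *all* currently unjustified nodes simultaneously,
    together with their incident edges, until a pass removes none; the
    final pass is counted, so an already-consistent network reports
    ``iterations == 1``. Under ``strict_roots`` (default) the root
    convention (rule iii) covers only nodes with zero regulators in the
    original network; with ``strict_roots=False`` any currently
    regulator-less node survives as a root.
    """
    input_nodes = set(input_nodes)
    all_nodes = network.node_set()
    missing = sorted(n for n in all_nodes if n not in de_calls)
    if missing:
        raise KeyError(f"nodes missing from differential calls: {missing}")
    original_incoming = _regulators_of(network)
    original_roots = {n for n in all_nodes if not original_incoming[n]}

    present = set(all_nodes)
    edges = network.edges
    removed_rows: list[dict] = []
    iteration = 0
    while True:
        iteration += 1
        incoming: dict[str, list[tuple[str, int]]] = {n: [] for n in present}
        for row in edges.itertuples(index=False):
            incoming[row.target].append((row.regulator, row.sign))
        if strict_roots:
            roots = original_roots & present
        else:
            roots = {n for n in present if not incoming[n]}
        doomed = []
        for node in sorted(present):
            ok, reason = _justified(
                node, incoming, de_calls, input_nodes, roots, unsigned_justifies
            )
            if not ok:
                doomed.append((node, reason))
        if not doomed:
            break
        for node, reason in doomed:
            removed_rows.append({"node": node, "reason": reason, "iteration": iteration})
            present.discard(node)
        keep = edges["regulator"].isin(present) & edges["target"].isin(present)
        edges = edges[keep]
    pruned = Network(
        edges.reset_index(drop=True),
        extra_nodes=tuple(
            sorted(present - (set(edges["regulator"]) | set(edges["target"])))
        ),
    )
    removed_df = pd.DataFrame(removed_rows, columns=["node", "reason", "iteration"])
    return ContextualizationResult(pruned=pruned, removed=removed_df, iterations=iteration)
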