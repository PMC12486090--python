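"""Variable Reduction Test: stability of edge directions under receiver removal.

An absolute receiver (in-degree ≥ 1, out-degree 0) influences nothing else,
so deleting it from the variable set cannot change any d-separation relation
among the remaining molecules; relearning the causal network on the reduced
set must therefore reproduce the same directions.  Direction flips under a
receiver removal signal an unstable (or mis-specified) network.  A
permutation variant — shuffling the receiver's values instead of removing
the column — is available; a shuffled receiver is independent noise, so the
same invariance argument applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causal import ROLE_ABSOLUTE_RECEIVER, CausalNetwork, PolygenicFactorSet, orient_edges
from .core_io import DataError, OmicsMatrix
from .network import learn_skeleton


@dataclass
class StabilityReport:
    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "removed_node",
                "is_absolute_receiver",
                "n_directed_before",
                "n_directed_after",
                "n_direction_flips",
                "pass",
            ]
        )
    )
    notice: str = ""

    @property
    def all_pass(self) -> bool:
        return bool(self.records["pass"].all()) if len(self.records) else True

    @property
    def n_total_flips(self) -> int:
        return int(self.records["n_direction_flips"].sum()) if len(self.records) else 0


def _directed_among(net: CausalNetwork, nodes: set[str]) -> dict[tuple[str, str], tuple[str, str]]:
    out = {}
    for key, e in net.network.edges.items():
        if e.direction is not None and key[0] in nodes and key[1] in nodes:
            out[key] = e.direction
    return out


def variable_reduction_test(
    data: OmicsMatrix,
    factors: PolygenicFactorSet | None,
    full_net: CausalNetwork,
    alpha: float,
    max_cond_size: int = 3,
    nodes_to_remove: list[str] | None = None,
    mode: str = "remove",
    rng: np.random.Generator | None = None,
) -> StabilityReport:
    """Leave-one-receiver-out relearning with direction comparison.

    By default every absolute receiver of ``full_net`` is removed in turn
    (``nodes_to_remove`` overrides the set, e.g. for negative controls with
    non-receivers); the causal network is relearned on the remaining
    molecules with the same pipeline and significance level, and directions
    of edges present in both networks are compared.  ``mode='permute'``
    shuffles the node's values instead of dropping the column.
    """
    if mode not in ("remove", "permute"):
        raise DataError("mode must be 'remove' or 'permute'")
    roles = full_net.roles
    if nodes_to_remove is None:
        nodes_to_remove = [n for n in full_net.network.nodes if roles.get(n) == ROLE_ABSOLUTE_RECEIVER]
    notice = "" if nodes_to_remove else "no absolute receivers in the network; nothing to test"
    rows = []
    for node in nodes_to_remove:
        if node not in full_net.network.nodes:
            raise DataError(f"unknown node {node!r}")
        if mode == "remove":
            reduced = data.drop_molecules([node])
        else:
            rng = rng or np.random.default_rng()
            reduced = data.copy()
            j = reduced.molecule_ids.index(node)
            reduced.values[:, j] = rng.permutation(reduced.values[:, j])
        skel = learn_skeleton(reduced, alpha, max_cond_size)
        relearned = orient_edges(skel, factors, reduced, alpha, max_cond_size)
        common = set(reduced.molecule_ids) - ({node} if mode == "permute" else set())
        before = _directed_among(full_net, common)
        after = _directed_among(relearned, common)
        flips = sum(
            1
            for key, d in before.items()
            if key in after and after[key] != d
        )
        rows.append(
            {
                "removed_node": node,
                "is_absolute_receiver": roles.get(node) == ROLE_ABSOLUTE_RECEIVER,
                "n_directed_before": len(before),
                "n_directed_after": len(after),
                "n_direction_flips": flips,
                "pass": flips == 0,
            }
        )
    return StabilityReport(records=pd.DataFrame(rows, columns=StabilityReport().records.columns)
                           if rows else StabilityReport().records, notice=notice)
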