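"""Four modularity parameters and the per-modulator modulated network.

Parameter 1 (ACI score) is the average, over all unordered gene pairs, of the
absolute change in absolute normalized interaction between the on and off
groups.  Parameters 2-4 are the node count, edge count, and connectivity
(average node degree, 2E/V) of the network formed by the pairs that pass both
MAGIC thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import ScreenConfig
from .magic import (
    DifferentialEdge,
    ModulatorPartition,
    call_differential_edges,
    pair_statistics,
    partition_samples,
)

PARAMETERS = ("aci", "n_nodes", "n_edges", "connectivity")


def aci_score(
    i_on: np.ndarray, i_off: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Mean of delta-I = ||I_on| - |I_off|| over eligible unordered pairs.

    ``mask`` (optional, G x G boolean) marks eligible pairs; only the strict
    upper triangle is averaged.  Raises if no pair is eligible.
    """
    i_on = np.asarray(i_on, dtype=np.float64)
    i_off = np.asarray(i_off, dtype=np.float64)
    if i_on.shape != i_off.shape or i_on.ndim != 2 or i_on.shape[0] != i_on.shape[1]:
        raise ValueError("interaction matrices must be square and conformable")
    delta = np.abs(np.abs(i_on) - np.abs(i_off))
    eligible = np.triu(np.ones_like(delta, dtype=bool), 1)
    if mask is not None:
        eligible &= np.asarray(mask, dtype=bool)
    if not eligible.any():
        raise ValueError("no eligible gene pair for the ACI average")
    return float(delta[eligible].mean())


@dataclass
class ModulatedNetwork:
    """Core modulated interaction network of one candidate modulator."""

    modulator_gene: str
    edges: list[DifferentialEdge]
    nodes: list[str] = field(init=False)
    n_nodes: int = field(init=False)
    n_edges: int = field(init=False)
    connectivity: float = field(init=False)

    def __post_init__(self) -> None:
        pairs = [tuple(sorted(e.pair)) for e in self.edges]
        if len(set(pairs)) != len(pairs):
            seen: set[tuple[str, str]] = set()
            dup = next(p for p in pairs if p in seen or seen.add(p))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate edge {dup}")
        node_set: set[str] = set()
        for a, b in pairs:
            node_set.add(a)
            node_set.add(b)
        self.nodes = sorted(node_set)
        self.n_nodes = len(self.nodes)
        self.n_edges = len(self.edges)
        self.connectivity = 2.0 * self.n_edges / self.n_nodes if self.n_nodes else 0.0
        assert abs(self.connectivity * self.n_nodes - 2.0 * self.n_edges) <= 1e-9 * max(
            1, self.n_edges
        )

    def degrees(self) -> pd.Series:
        deg = dict.fromkeys(self.nodes, 0)
        for e in self.edges:
            deg[e.gene_i] += 1
            deg[e.gene_j] += 1
        return pd.Series(deg, dtype=int)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(modulator=self.modulator_gene)
        for e in self.edges:
            g.add_edge(
                e.gene_i,
                e.gene_j,
                direction=e.direction,
                magic_p=e.magic_p,
                magic_score=e.magic_score,
            )
        deg = self.degrees()
        nx.set_node_attributes(g, {n: int(deg[n]) for n in g.nodes}, "degree")
        return g


def build_network(edges: Sequence[DifferentialEdge], modulator: str) -> ModulatedNetwork:
    """Merge called pairs into the modulator's network (errors on duplicates)."""
    return ModulatedNetwork(modulator, list(edges))


def hub_summary(net: ModulatedNetwork, label_fraction: float = 0.01) -> pd.DataFrame:
    """Per-node degree table; a node is labeled when it carries more than
    ``label_fraction`` of the network's edges.  Sorted by degree descending,
    ties by gene id."""
    if not 0.0 < label_fraction < 1.0:
        raise ValueError("label_fraction must be in (0, 1)")
    if net.n_edges == 0:
        return pd.DataFrame(columns=["gene", "degree", "edge_share", "labeled"])
    deg = net.degrees()
    df = pd.DataFrame(
        {
            "gene": deg.index,
            "degree": deg.to_numpy(),
            "edge_share": deg.to_numpy() / net.n_edges,
        }
    )
    df["labeled"] = df["edge_share"] > label_fraction
    return df.sort_values(["degree", "gene"], ascending=[False, True]).reset_index(drop=True)


def four_parameters(
    values: np.ndarray,
    on: np.ndarray,
    off: np.ndarray,
    config: ScreenConfig,
    exclude_gene_index: Optional[int] = None,
) -> tuple[float, int, int, float]:
    """Vectorized (ACI, n_nodes, n_edges, connectivity) for one partition.

    Shared by the per-modulator profile and the permutation null; excluding a
    gene removes every pair touching it from both the ACI average and edge
    calling.
    """
    st = pair_statistics(
        values,
        on,
        off,
        inverse_mode=config.inverse_mode,
        statistic=config.statistic,
        n_assigned=config.n_assigned,
    )
    eligible = np.triu(st.valid, 1)
    if exclude_gene_index is not None:
        eligible[exclude_gene_index, :] = False
        eligible[:, exclude_gene_index] = False
    if not eligible.any():
        raise ValueError("no eligible gene pair")
    aci = float(st.delta_i[eligible].mean())
    edge_sel = eligible & (st.p < config.magic_p_max) & (st.score >= config.magic_score_min)
    ii, jj = np.nonzero(edge_sel)
    n_edges = int(ii.size)
    n_nodes = int(np.union1d(ii, jj).size)
    connectivity = 2.0 * n_edges / n_nodes if n_nodes else 0.0
    return aci, n_nodes, n_edges, connectivity


@dataclass
class ModularityProfile:
    """Per-gene record of the four parameters (p-values/ranks filled by the screen)."""

    gene: str
    aci: float
    n_nodes: int
    n_edges: int
    connectivity: float
    p_aci: Optional[float] = None
    p_nodes: Optional[float] = None
    p_edges: Optional[float] = None
    p_conn: Optional[float] = None
    rank_aci: Optional[int] = None
    rank_nodes: Optional[int] = None
    rank_edges: Optional[int] = None
    rank_conn: Optional[int] = None
    avg_z: Optional[float] = None


def profile_modulator(E, modulator: str, config: ScreenConfig) -> ModularityProfile:
    """Partition -> correlations -> Fisher -> ACI + edge calling for one gene."""
    part = partition_samples(E, modulator, config.fraction)
    exclude = None if config.include_modulator_pairs else E.gene_index(modulator)
    aci, n_nodes, n_edges, conn = four_parameters(
        E.values, part.on_samples, part.off_samples, config, exclude_gene_index=exclude
    )
    return ModularityProfile(modulator, aci, n_nodes, n_edges, conn)


def modulated_network(E, modulator: str, config: ScreenConfig) -> ModulatedNetwork:
    """Call the modulator's differential edges and merge them into a network."""
    part = partition_samples(E, modulator, config.fraction)
    edges = call_differential_edges(
        E,
        part,
        p_max=config.magic_p_max,
        score_min=config.magic_score_min,
        inverse_mode=config.inverse_mode,
        statistic=config.statistic,
        n_assigned=config.n_assigned,
        include_modulator=config.include_modulator_pairs,
    )
    return build_network(edges, modulator)


def write_sif(net: ModulatedNetwork, path: str | Path) -> None:
    """Cytoscape SIF export: gene_i <interaction-type> gene_j per line."""
    with open(path, "w") as fh:
        for e in net.edges:
            fh.write(f"{e.gene_i}\t{e.direction}\t{e.gene_j}\n")


def write_graphml(net: ModulatedNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def write_node_attributes(
    net: ModulatedNetwork, path: str | Path, label_fraction: float = 0.01
) -> None:
    hub_summary(net, label_fraction).to_csv(path, sep="\t", index=False)
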