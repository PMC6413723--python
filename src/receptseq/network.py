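"""Interaction-network filtering, degree statistics and hub detection.

Edges are kept at combined score >= min_score (0.4 by default, the STRING
unit-scale convention).  Hub genes are nodes whose unweighted degree
strictly exceeds the mean plus two sample standard deviations of the
degree distribution.  A descriptive scale-free check fits a least-squares
line to the log10 degree survival function; it never gates hub detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import InteractionNetwork

__all__ = ["DegreeStats", "filter_edges", "degree_stats", "to_graph"]


@dataclass
class DegreeStats:
    degree_of_node: pd.Series     # node -> degree
    mean: float
    sd: float                     # sample SD, n-1 denominator
    threshold: float              # mean + 2*sd
    hubs: list[str]               # degree strictly > threshold
    powerlaw_slope: float         # log-log CCDF regression slope


def filter_edges(net: InteractionNetwork, min_score: float = 0.4) -> InteractionNetwork:
    """Keep edges with combined_score >= min_score; drop isolated nodes.

    The node set of the result is exactly the endpoints of surviving edges.
    """
    kept = net.edges[net.edges["combined_score"] >= min_score].reset_index(drop=True)
    return InteractionNetwork(kept)


def to_graph(net: InteractionNetwork) -> nx.Graph:
    g = nx.Graph()
    for a, b, s in net.edges.itertuples(index=False):
        g.add_edge(a, b, combined_score=s)
    return g


def degree_stats(net: InteractionNetwork) -> DegreeStats:
    """Degree distribution summary with mean+2SD hub calls.

    Each undirected edge contributes 1 to both endpoint degrees.  The
    power-law slope is the least-squares fit of log10 P(Degree >= d)
    against log10 d over the observed degrees d >= 1.
    """
    g = to_graph(net)
    if g.number_of_nodes() < 3:
        raise ValueError("need >= 3 nodes for degree statistics")
    degrees = pd.Series(dict(g.degree()), name="degree").astype(int)
    mean = float(degrees.mean())
    sd = float(degrees.std(ddof=1))
    threshold = mean + 2.0 * sd
    hubs = sorted(degrees.index[degrees > threshold])

    d = degrees.to_numpy()
    uniq = np.unique(d[d >= 1])
    ccdf = np.array([(d >= u).mean() for u in uniq])
    if len(uniq) >= 2:
        slope = float(np.polyfit(np.log10(uniq), np.log10(ccdf), 1)[0])
    else:
        slope = float("nan")
    return DegreeStats(
        degree_of_node=degrees,
        mean=mean,
        sd=sd,
        threshold=threshold,
        hubs=hubs,
        powerlaw_slope=slope,
    )
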