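"""Gephi-loadable cluster graph export (GEXF 1.2).

The clustering is rendered as a bipartite star graph: one node per
individual plus one hub node per cluster, with a single edge from each
individual to its cluster hub, weighted by ``1 / (1 + distance to the
centroid)`` so that tighter cluster members pull closer under Gephi's
force-directed layouts. Individual nodes carry their predicted cluster and,
when a panel is given, their annotated population label, so the graph can be
recoloured by truth to inspect where clusters and populations disagree.

Output is deterministic: identical inputs produce byte-identical files (no
timestamps).
"""

from __future__ import annotations

from pathlib import Path
from xml.etree import ElementTree as etree

import numpy as np

from .cluster import KMeansModel
from .encode import GenotypeMatrix
from .evaluate import PopulationTruth

__all__ = ["export_gexf", "GEXF_NS"]

GEXF_NS = "http://www.gexf.net/1.2draft"


def _sample_to_centroid_distances(
    model: KMeansModel, matrix: GenotypeMatrix
) -> np.ndarray:
    """Euclidean distance from each sample to its assigned centroid."""
    X = matrix.X.tocsr()
    assigned = model.centroids[model.assignments]  # (n, n_variants)
    sq = (
        np.asarray(X.multiply(X).sum(axis=1)).ravel()
        - 2.0 * np.asarray(X.multiply(assigned).sum(axis=1)).ravel()
        + np.einsum("ij,ij->i", assigned, assigned)
    )
    return np.sqrt(np.maximum(sq, 0.0))


def export_gexf(
    model: KMeansModel,
    matrix: GenotypeMatrix,
    truth: PopulationTruth | None = None,
    dest: str | Path = "clusters.gexf",
) -> tuple[int, int]:
    """Write the cluster star graph as GEXF; returns (n_nodes, n_edges).

    Nodes: samples in matrix row order, then the k cluster hubs. Edges: one
    per sample, to its hub, weight ``1/(1+d)`` where ``d`` is the distance
    to the assigned centroid. The ``true_label`` attribute is only declared
    when ``truth`` is provided.
    """
    if len(model.assignments) != matrix.n_samples:
        raise ValueError(
            f"model has {len(model.assignments)} assignments for "
            f"{matrix.n_samples} samples"
        )
    labels = truth.labels_for(matrix.sample_ids) if truth is not None else None
    distances = _sample_to_centroid_distances(model, matrix)

    etree.register_namespace("", GEXF_NS)
    root = etree.Element(f"{{{GEXF_NS}}}gexf")
    root.set("version", "1.2")
    graph = etree.SubElement(root, f"{{{GEXF_NS}}}graph")
    graph.set("mode", "static")
    graph.set("defaultedgetype", "undirected")

    attrs = etree.SubElement(graph, f"{{{GEXF_NS}}}attributes")
    attrs.set("class", "node")
    for attr_id, title, atype in (
        ("0", "cluster", "integer"),
        ("1", "is_hub", "boolean"),
        ("2", "true_label", "string"),
    ):
        if title == "true_label" and labels is None:
            continue
        a = etree.SubElement(attrs, f"{{{GEXF_NS}}}attribute")
        a.set("id", attr_id)
        a.set("title", title)
        a.set("type", atype)

    nodes = etree.SubElement(graph, f"{{{GEXF_NS}}}nodes")

    def _node(node_id: str, label: str, cluster: int, is_hub: bool, true_label):
        node = etree.SubElement(nodes, f"{{{GEXF_NS}}}node")
        node.set("id", node_id)
        node.set("label", label)
        av = etree.SubElement(node, f"{{{GEXF_NS}}}attvalues")
        for attr_id, value in (
            ("0", str(cluster)),
            ("1", "true" if is_hub else "false"),
        ):
            e = etree.SubElement(av, f"{{{GEXF_NS}}}attvalue")
            e.set("for", attr_id)
            e.set("value", value)
        if true_label is not None:
            e = etree.SubElement(av, f"{{{GEXF_NS}}}attvalue")
            e.set("for", "2")
            e.set("value", true_label)

    for i, sample in enumerate(matrix.sample_ids):
        _node(
            sample,
            sample,
            int(model.assignments[i]),
            False,
            labels[i] if labels is not None else None,
        )
    for c in range(model.k):
        _node(f"cluster_{c}", f"cluster {c}", c, True, None)

    edges = etree.SubElement(graph, f"{{{GEXF_NS}}}edges")
    for i, sample in enumerate(matrix.sample_ids):
        edge = etree.SubElement(edges, f"{{{GEXF_NS}}}edge")
        edge.set("id", str(i))
        edge.set("source", sample)
        edge.set("target", f"cluster_{int(model.assignments[i])}")
        edge.set("weight", repr(float(1.0 / (1.0 + distances[i]))))

    tree = etree.ElementTree(root)
    etree.indent(tree)
    tree.write(str(dest), xml_declaration=True, encoding="UTF-8")
    return matrix.n_samples + model.k, matrix.n_samples
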