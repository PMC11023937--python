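"""Worked-example inputs shipped with the package.

``h1_census()`` loads the published H1 embryonic-stem-cell cluster
tally (non-singleton DNA-only and RNA-DNA clusters by size class) as a
:class:`~musicpipe.clusters.ClusterCensus`, so the size-class
percentage arithmetic can be exercised against known totals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .clusters import ClusterCensus


def h1_census() -> ClusterCensus:
    path = resources.files("musicpipe.data") / "h1_cluster_census.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    counts: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        counts.setdefault(row.type, {})[row.size_class] = int(row.n_clusters)
    return ClusterCensus.from_cluster_counts(counts)
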