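"""End-to-end convenience wrapper: FASTQ triple -> deduplicated clusters."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import clusters as _clusters
from . import demux as _demux
from . import mapdedup as _mapdedup
from .layout import BarcodeTables, ReadLayout
from .synthdata.reference import SyntheticReference


@dataclass
class PipelineResult:
    tagged: list
    rejects: list
    demux_report: _demux.DemuxReport
    map_census: dict
    retained: list
    n_duplicates: int
    clusters: dict
    roster: pd.DataFrame


def run_pipeline(
    r1_path,
    i1_path,
    r2_path,
    tables: BarcodeTables,
    layout: ReadLayout,
    ref: SyntheticReference,
    k: int = 20,
) -> PipelineResult:
    """Demultiplex, map, deduplicate and cluster one read triplet."""
    triples = _demux.iter_fastq_triples(r1_path, i1_path, r2_path)
    tagged, rejects, report = _demux.demux(triples, tables, layout)
    index = _mapdedup.build_index(ref, k=k)
    unique, map_census = _mapdedup.map_tagged_reads(tagged, index)
    retained, n_dup = _mapdedup.deduplicate(_mapdedup.sort_reads(unique))
    clusters, roster = _clusters.build_clusters(retained)
    return PipelineResult(
        tagged=tagged,
        rejects=rejects,
        demux_report=report,
        map_census=map_census,
        retained=retained,
        n_duplicates=n_dup,
        clusters=clusters,
        roster=roster,
    )
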