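"""Barcode-based filtering of isoform clusters.

Two strategies: a minimum-abundance cut (clusters supported by too few
barcodes are likely fragments or noise) and a multi-isoform-barcode fix —
when one barcode supports several clusters within the same gene locus the
cloud was either fragmented or carried two molecules, so that barcode's
support is withdrawn from those clusters.  Gene loci are reference-free
here: the weakly connected component of the simplified global assembly
graph containing a cluster's walk serves as the locus proxy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .paths import PathCluster

__all__ = [
    "FilterReport",
    "filter_min_barcodes",
    "filter_multi_isoform_barcodes",
    "filter_sweep",
]


@dataclass
class FilterReport:
    n_input_clusters: int
    n_kept: int
    n_removed_min_barcode: int = 0
    n_removed_multi_isoform: int = 0
    n_barcode_support_removed: int = 0
    log: List[str] = field(default_factory=list)

    def __post_init__(self):
        removed = self.n_removed_min_barcode + self.n_removed_multi_isoform
        if self.n_input_clusters != self.n_kept + removed:
            raise ValueError("filter report does not balance")


def _clone(c: PathCluster) -> PathCluster:
    return PathCluster(cluster_id=c.cluster_id, representative=c.representative,
                       members=list(c.members), barcodes=set(c.barcodes))


def filter_min_barcodes(clusters: Sequence[PathCluster],
                        min_barcodes: int = 1) -> Tuple[List[PathCluster], FilterReport]:
    """Keep clusters supported by at least ``min_barcodes`` distinct barcodes."""
    if min_barcodes < 1:
        raise ValueError("min_barcodes must be >= 1")
    kept = [c for c in clusters if c.abundance >= min_barcodes]
    report = FilterReport(
        n_input_clusters=len(clusters),
        n_kept=len(kept),
        n_removed_min_barcode=len(clusters) - len(kept),
        log=[f"min_barcodes={min_barcodes}: kept {len(kept)}/{len(clusters)}"],
    )
    return kept, report


def filter_multi_isoform_barcodes(
    clusters: Sequence[PathCluster],
    gene_proxy: Dict[str, int],
) -> Tuple[List[PathCluster], FilterReport]:
    """Withdraw support of barcodes assigned to one gene locus multiple times.

    ``gene_proxy`` maps canonical edge id -> component id of the simplified
    global graph.  For every (barcode, component) pair supported by >= 2
    clusters the barcode is removed from those clusters; clusters whose
    abundance drops to zero are dropped.  Support removal (rather than whole
    contig removal) is the conservative reading — other barcodes may still
    legitimately support the cluster.
    """
    def component_of(c: PathCluster) -> int:
        for eid in c.representative.edge_walk:
            cid = eid[:-1] if eid.endswith("r") else eid
            if cid in gene_proxy:
                return gene_proxy[cid]
        return -1

    comp = {c.cluster_id: component_of(c) for c in clusters}
    seen: Dict[Tuple[str, int], List[str]] = {}
    for c in clusters:
        for b in c.barcodes:
            seen.setdefault((b, comp[c.cluster_id]), []).append(c.cluster_id)

    offending = {key for key, cl in seen.items() if len(cl) >= 2}
    out: List[PathCluster] = []
    n_support_removed = 0
    n_dropped = 0
    for c in clusters:
        cc = _clone(c)
        bad = {b for b in cc.barcodes if (b, comp[c.cluster_id]) in offending}
        if bad:
            n_support_removed += len(bad)
            cc.barcodes -= bad
            cc.members = [m for m in cc.members if m.barcode not in bad]
        if cc.abundance == 0:
            n_dropped += 1
            continue
        out.append(cc)
    report = FilterReport(
        n_input_clusters=len(clusters),
        n_kept=len(out),
        n_removed_multi_isoform=n_dropped,
        n_barcode_support_removed=n_support_removed,
        log=[f"multi-isoform fix: removed support of {n_support_removed} "
             f"(barcode, cluster) pairs; dropped {n_dropped} emptied clusters"],
    )
    return out, report


def filter_sweep(clusters: Sequence[PathCluster], gene_proxy: Dict[str, int],
                 thresholds: Sequence[int] = (1, 2, 3, 4)) -> pd.DataFrame:
    """Cluster counts surviving each min-barcode threshold, plain and fixed."""
    fixed, _ = filter_multi_isoform_barcodes(clusters, gene_proxy)
    rows = []
    for t in thresholds:
        plain_kept, _ = filter_min_barcodes(clusters, t)
        fixed_kept, _ = filter_min_barcodes(fixed, t)
        rows.append({"min_barcodes": str(t), "n_clusters": len(plain_kept)})
        rows.append({"min_barcodes": f"{t}-fixed", "n_clusters": len(fixed_kept)})
    return pd.DataFrame(rows)
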