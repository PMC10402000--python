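"""File handling, run configuration and the end-to-end pipeline.

The pipeline mirrors the method outline: co-assemble all reads into one
simplified de Bruijn graph, then per barcode align the cloud, induce and
simplify its subgraph and extract isoform paths; finally cluster paths
across barcodes, apply the barcode filters and write GFA / FASTA / TSV
outputs plus a run log.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .align import ReadCloud, ReadPair, align_cloud
from .cloud import CloudParams, extract_subgraph, simplify_cloud
from .filters import filter_min_barcodes, filter_multi_isoform_barcodes, filter_sweep
from .graph import build_graph, simplify_global, write_gfa
from .paths import (
    _LinkIndex,
    cluster_paths,
    extract_paths,
    write_clusters_fasta,
    write_clusters_tsv,
)

__all__ = ["RunConfig", "parse_barcoded_fastq", "run_pipeline", "assemble_clouds"]

logger = logging.getLogger("isocloud")


@dataclass
class RunConfig:
    """All pipeline parameters with defaults; serialized next to the outputs."""

    reads1: Optional[str] = None
    reads2: Optional[str] = None
    out_dir: str = "isocloud_out"
    barcode_dialect: str = "bx"
    k: int = 29
    min_coverage: float = 2.0
    tip_len: Optional[int] = None  # default 2k
    bulge_similarity: float = 0.8
    max_mismatch_rate: float = 0.03
    max_tip_len: Optional[int] = None  # cloud-local, default 2k
    rel_cov: float = 0.33
    cov_ratio: float = 0.5
    max_gap_edge_len: int = 150
    max_cycles: int = 10
    offset_tol: int = 10
    min_contig_len: int = 300
    min_barcodes: int = 1
    filter_multi: bool = False

    def validate(self) -> None:
        if self.k % 2 == 0 or self.k < 3:
            raise ValueError(f"k must be odd and >= 3 (got {self.k})")
        if self.barcode_dialect not in ("bx", "suffix"):
            raise ValueError(f"unknown barcode dialect {self.barcode_dialect!r}")
        if self.min_barcodes < 1:
            raise ValueError("min_barcodes must be >= 1")

    def cloud_params(self) -> CloudParams:
        return CloudParams(
            max_tip_len=self.max_tip_len,
            rel_cov=self.rel_cov,
            cov_ratio=self.cov_ratio,
            max_gap_edge_len=self.max_gap_edge_len,
            max_cycles=self.max_cycles,
        )


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _extract_barcode(title: str, dialect: str) -> Tuple[str, Optional[str]]:
    """Return (read name, barcode or None) from a FASTQ title line."""
    fields = title.split()
    name = fields[0]
    if dialect == "bx":
        for tok in fields[1:]:
            if tok.startswith("BX:Z:"):
                return name, tok[5:]
        return name, None
    # suffix dialect: name#BARCODE
    if "#" in name:
        name, _, bc = name.rpartition("#")
        return name, bc or None
    return name, None


def parse_barcoded_fastq(
    path1, path2, dialect: str = "bx"
) -> Tuple[Dict[str, ReadCloud], int]:
    """Single-pass paired FASTQ parse grouped into read clouds by barcode.

    Returns (barcode -> ReadCloud, number of skipped records).  Records
    whose barcode tag is missing are skipped with a warning; a mate-count
    mismatch between the two files is a format error.
    """
    clouds: Dict[str, ReadCloud] = {}
    n_skipped = 0
    with _open_maybe_gz(path1) as f1, _open_maybe_gz(path2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        n = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                raise ValueError("mate-count mismatch between FASTQ files")
            n += 1
            name1, bc1 = _extract_barcode(rec1[0], dialect)
            name2, bc2 = _extract_barcode(rec2[0], dialect)
            bc = bc1 or bc2
            if bc is None:
                n_skipped += 1
                continue
            pair_id = name1.rsplit("/", 1)[0]
            pair = ReadPair(bc, rec1[1].upper(), rec2[1].upper(), pair_id)
            cloud = clouds.get(bc)
            if cloud is None:
                clouds[bc] = ReadCloud(bc, [pair])
            else:
                cloud.pairs.append(pair)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} read pairs without a barcode tag")
    return clouds, n_skipped


def assemble_clouds(graph, clouds: Dict[str, ReadCloud], cfg: RunConfig):
    """Per-barcode assembly against a simplified global graph.

    Returns (clusters, stage_counts).  Library entry point used by both the
    CLI pipeline and the test/evaluation harnesses.
    """
    params = cfg.cloud_params()
    all_paths = []
    counts = {"clouds": len(clouds), "clouds_aligned": 0, "clouds_with_paths": 0,
              "alignments": 0, "paths": 0}
    for barcode in sorted(clouds):
        alignments = align_cloud(graph, clouds[barcode], cfg.max_mismatch_rate)
        if not alignments:
            continue
        counts["clouds_aligned"] += 1
        counts["alignments"] += len(alignments)
        sub = extract_subgraph(graph, alignments, barcode)
        links = _LinkIndex(graph, alignments)
        sub = simplify_cloud(sub, params, links)
        paths = extract_paths(sub, alignments, cfg.min_contig_len)
        if paths:
            counts["clouds_with_paths"] += 1
            counts["paths"] += len(paths)
            all_paths.extend(paths)
    clusters = cluster_paths(all_paths, cfg.offset_tol, graph)
    counts["clusters"] = len(clusters)
    return clusters, counts


def run_pipeline(cfg: RunConfig):
    """Full assemble run: FASTQ in, GFA + FASTA + TSV + filter report out."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)

        clouds, n_skipped = parse_barcoded_fastq(cfg.reads1, cfg.reads2,
                                                 cfg.barcode_dialect)
        n_pairs = sum(len(c) for c in clouds.values())
        logger.info("parsed %d read pairs in %d clouds (%d skipped, no barcode)",
                    n_pairs, len(clouds), n_skipped)

        reads = [seq for c in clouds.values() for p in c.pairs
                 for seq in (p.read1, p.read2)]
        graph = build_graph(reads, cfg.k)
        logger.info("raw graph: %d edges", graph.n_edges)
        graph = simplify_global(graph, cfg.min_coverage, cfg.tip_len,
                                cfg.bulge_similarity)
        logger.info("simplified graph: %d edges", graph.n_edges)
        write_gfa(graph, out / "assembly_graph.gfa")

        clusters, counts = assemble_clouds(graph, clouds, cfg)
        logger.info("per-cloud assembly: %s", counts)

        gene_proxy = graph.connected_components()
        sweep = filter_sweep(clusters, gene_proxy)
        sweep.to_csv(out / "filter_report.tsv", sep="\t", index=False)

        if cfg.filter_multi:
            clusters, rep = filter_multi_isoform_barcodes(clusters, gene_proxy)
            logger.info("%s", "; ".join(rep.log))
        clusters, rep = filter_min_barcodes(clusters, cfg.min_barcodes)
        logger.info("%s", "; ".join(rep.log))

        write_clusters_fasta(clusters, out / "transcripts.fasta")
        write_clusters_tsv(clusters, out / "clusters.tsv")
        summary = {"n_pairs": n_pairs, "n_clouds": len(clouds),
                   "n_skipped": n_skipped, "n_clusters": len(clusters), **counts}
        logger.info("done: %s", summary)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
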