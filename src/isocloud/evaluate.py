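"""Contig-to-isoform assignment and per-barcode precision / recall / fixed recall.

This is a self-contained evaluation harness valid only against synthetic
truth: each assembled contig is compared to the known isoform sequences by
edit distance (strand-agnostic infix alignment), classified as unique /
unique-with-minor-difference / ambiguous / inconsistent / non-informative,
and barcode-level metrics are derived:

* precision — among barcodes with exactly one uniquely assigned contig, the
  fraction whose assigned isoform equals the simulated one;
* recall — unique-correct barcodes over all truth barcodes with at least
  ``min_pairs`` read pairs;
* fixed recall — recall after excluding barcodes that produced two or more
  contigs for one gene (a self-diagnostic for fragmented clouds or barcode
  collisions; excluding them mimics the downstream-usable fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import edlib
import pandas as pd

from ._dna import revcomp

__all__ = ["AssignmentRecord", "EvalMetrics", "assign_contig", "score_run",
           "evaluate_clusters"]

CATEGORIES = ("unique", "unique_minor_difference", "ambiguous",
              "inconsistent", "non_informative")


@dataclass(frozen=True)
class AssignmentRecord:
    contig_id: str
    barcode: Optional[str]
    category: str
    assigned_isoform_id: Optional[str]
    edit_distance: int
    candidate_isoforms: Tuple[str, ...] = ()


@dataclass
class EvalMetrics:
    precision: Optional[float]
    recall: Optional[float]
    fixed_recall: Optional[float]
    n_barcodes: int
    n_barcodes_ge5: int
    per_gene: Dict[str, Dict[str, Optional[float]]] = field(default_factory=dict)


def _infix_distance(contig: str, isoform: str) -> int:
    """Edit distance of the best strand-agnostic infix placement of contig in isoform."""
    d1 = edlib.align(contig, isoform, mode="HW", task="distance")["editDistance"]
    d2 = edlib.align(revcomp(contig), isoform, mode="HW", task="distance")["editDistance"]
    ds = [d for d in (d1, d2) if d >= 0]
    return min(ds) if ds else len(contig)


def assign_contig(
    contig: str,
    truth: Dict[str, str],
    tol: float = 0.01,
    min_informative_len: int = 300,
    contig_id: str = "contig",
    barcode: Optional[str] = None,
) -> AssignmentRecord:
    """Classify one contig against the truth isoform sequences.

    A truth isoform qualifies when the contig fits inside it (either strand)
    within ``tol`` x contig length edit distance.  Exactly one qualifying
    isoform -> unique (distance 0) or unique_minor_difference; several ->
    ambiguous; none -> inconsistent.  Contigs shorter than
    ``min_informative_len`` are non-informative.
    """
    if not truth:
        raise ValueError("truth isoform set must be non-empty")
    dists = {iso: _infix_distance(contig, seq) for iso, seq in truth.items()}
    budget = tol * len(contig)
    qualifying = sorted(iso for iso, d in dists.items() if d <= budget)
    best = min(dists.values())
    if len(contig) < min_informative_len:
        category, assigned = "non_informative", None
    elif len(qualifying) == 1:
        assigned = qualifying[0]
        category = "unique" if dists[assigned] == 0 else "unique_minor_difference"
    elif len(qualifying) >= 2:
        category, assigned = "ambiguous", None
    else:
        category, assigned = "inconsistent", None
    return AssignmentRecord(
        contig_id=contig_id,
        barcode=barcode,
        category=category,
        assigned_isoform_id=assigned,
        edit_distance=best,
        candidate_isoforms=tuple(qualifying),
    )


def _record_gene(rec: AssignmentRecord, iso2gene: Dict[str, str]) -> Optional[str]:
    if rec.assigned_isoform_id is not None:
        return iso2gene.get(rec.assigned_isoform_id)
    genes = {iso2gene[i] for i in rec.candidate_isoforms if i in iso2gene}
    return genes.pop() if len(genes) == 1 else None


def evaluate_clusters(clusters, genes, truth: pd.DataFrame, min_pairs: int = 5,
                      tol: float = 0.01, min_informative_len: int = 300) -> EvalMetrics:
    """Assign every cluster contig against the genes' isoforms and score the run.

    Convenience wrapper tying :func:`assign_contig` and :func:`score_run`
    together for in-memory pipeline results.
    """
    import dataclasses

    iso_seqs = {iso_id: g.transcript(iso_id) for g in genes for iso_id in g.isoform_ids}
    records: List[AssignmentRecord] = []
    for c in clusters:
        base = assign_contig(c.sequence, iso_seqs, tol=tol,
                             min_informative_len=min_informative_len,
                             contig_id=c.cluster_id)
        for bc in sorted(c.barcodes):
            records.append(dataclasses.replace(base, barcode=bc))
    return score_run(records, truth, min_pairs=min_pairs)


def score_run(
    assignments: Sequence[AssignmentRecord],
    truth: pd.DataFrame,
    min_pairs: int = 5,
) -> EvalMetrics:
    """Barcode-level metrics from per-(contig, barcode) assignment records.

    ``truth`` columns: barcode, gene_id, isoform_id, n_pairs (one row per
    simulated molecule).  A barcode counts as uniquely assigned when it has
    exactly one unique-category record and no gene received two of its
    contigs; it is correct when that record's isoform matches a simulated
    one.  The recall denominator is the truth barcodes with >= ``min_pairs``
    pairs; fixed recall drops multi-contig-per-gene barcodes from it.
    """
    n_barcodes = truth["barcode"].nunique()
    by_bc_pairs = truth.groupby("barcode")["n_pairs"].max()
    denom_bcs = set(by_bc_pairs[by_bc_pairs >= min_pairs].index)
    iso2gene = dict(zip(truth["isoform_id"], truth["gene_id"]))
    truth_isos: Dict[str, Set[str]] = {}
    truth_genes: Dict[str, Set[str]] = {}
    for row in truth.itertuples():
        truth_isos.setdefault(row.barcode, set()).add(row.isoform_id)
        truth_genes.setdefault(row.barcode, set()).add(row.gene_id)

    if not assignments:
        return EvalMetrics(None, None, None, n_barcodes, len(denom_bcs))

    recs_by_bc: Dict[str, List[AssignmentRecord]] = {}
    for rec in assignments:
        if rec.barcode is not None:
            recs_by_bc.setdefault(rec.barcode, []).append(rec)

    unique_bcs: Dict[str, str] = {}  # barcode -> assigned isoform
    multi_gene_bcs: Set[str] = set()
    for bc, recs in recs_by_bc.items():
        gene_counts: Dict[str, int] = {}
        for r in recs:
            gg = _record_gene(r, iso2gene)
            if gg is not None:
                gene_counts[gg] = gene_counts.get(gg, 0) + 1
        if any(n >= 2 for n in gene_counts.values()):
            multi_gene_bcs.add(bc)
        uniq = [r for r in recs
                if r.category in ("unique", "unique_minor_difference")]
        if len(uniq) == 1 and bc not in multi_gene_bcs:
            unique_bcs[bc] = uniq[0].assigned_isoform_id

    def metrics_for(bc_subset: Optional[Set[str]] = None):
        def keep(bc):
            return bc_subset is None or bc in bc_subset

        uniq = {bc: iso for bc, iso in unique_bcs.items() if keep(bc)}
        correct = {bc for bc, iso in uniq.items() if iso in truth_isos.get(bc, set())}
        denom = {bc for bc in denom_bcs if keep(bc)}
        fixed_denom = denom - {bc for bc in multi_gene_bcs if keep(bc)}
        precision = len(correct) / len(uniq) if uniq else None
        recall = len(correct & denom) / len(denom) if denom else None
        fixed = len(correct & fixed_denom) / len(fixed_denom) if fixed_denom else None
        return precision, recall, fixed

    precision, recall, fixed = metrics_for()
    per_gene: Dict[str, Dict[str, Optional[float]]] = {}
    for gene in sorted(truth["gene_id"].unique()):
        gene_bcs = {bc for bc, gs in truth_genes.items() if gene in gs}
        p, r, f = metrics_for(gene_bcs)
        per_gene[gene] = {"precision": p, "recall": r, "fixed_recall": f}
    return EvalMetrics(precision, recall, fixed, n_barcodes, len(denom_bcs), per_gene)
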