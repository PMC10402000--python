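"""Synthetic gene models and barcoded read-cloud simulation.

The generator emulates sparse isoform sequencing (SPIso-seq-like) data: one
mRNA molecule per barcode (rarely two, via a configurable collision rate),
many small clouds whose sizes follow a zero-truncated negative binomial
calibrated so that ~59% of clouds carry >= 5 read pairs, paired-end reads
drawn uniformly along the transcript with a Gaussian insert model and
uniform substitution errors.  Genes are random exon blocks; isoforms are
distinct exon subsets that always keep the terminal exons, which creates
the shared-flank bubble structures the assembler must resolve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import nbinom

from ._dna import revcomp
from .align import ReadCloud, ReadPair

__all__ = [
    "GeneModel",
    "CloudSimConfig",
    "simulate_gene",
    "simulate_clouds",
    "write_clouds_fastq",
    "write_truth_tsv",
    "write_transcripts_fasta",
    "calibrate_nb_prob",
    "CLOUD_GE5_TARGET",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Fraction of read clouds with >= 5 read pairs observed in real sparse
# isoform sequencing data (320 of 539 clouds); the cloud-size distribution
# is calibrated to reproduce it.
CLOUD_GE5_TARGET = 320 / 539

# Negative binomial shape; the heavy right tail of a small-size parameter
# matches the many-tiny-clouds regime.  The success probability below is
# solved so that P(X >= 5 | X >= 1) hits CLOUD_GE5_TARGET.
NB_SIZE_DEFAULT = 1.2
NB_PROB_DEFAULT = 0.1473885341555657


def calibrate_nb_prob(size: float = NB_SIZE_DEFAULT,
                      p_ge5: float = CLOUD_GE5_TARGET) -> float:
    """Solve the negative binomial success probability for the >=5-pair target."""
    f = lambda p: nbinom.sf(4, size, p) / nbinom.sf(0, size, p) - p_ge5
    return float(brentq(f, 1e-9, 1 - 1e-9))


@dataclass(frozen=True)
class GeneModel:
    """A synthetic gene: exon blocks plus isoforms as increasing exon subsets."""

    gene_id: str
    exons: Tuple[str, ...]
    isoforms: Tuple[Tuple[str, Tuple[int, ...]], ...]
    expression: Tuple[float, ...]

    def transcript(self, isoform_id: str) -> str:
        for iso_id, idxs in self.isoforms:
            if iso_id == isoform_id:
                return "".join(self.exons[i] for i in idxs)
        raise KeyError(isoform_id)

    @property
    def isoform_ids(self) -> List[str]:
        return [iso_id for iso_id, _ in self.isoforms]


@dataclass
class CloudSimConfig:
    """Study conditions of the read-cloud simulation."""

    n_clouds: int = 539
    nb_size: float = NB_SIZE_DEFAULT
    nb_prob: float = NB_PROB_DEFAULT
    read_len: int = 100
    insert_mean: float = 250.0
    insert_sd: float = 30.0
    error_rate: float = 0.005
    barcode_collision_rate: float = 0.001
    barcode_len: int = 16
    seed: int = 0
    # when set, cloud sizes are deterministic at this per-cloud coverage
    # (pairs = ceil(cov * L / (2 * read_len))) instead of negative binomial;
    # used by noiseless oracle scenarios
    fixed_coverage: Optional[float] = None

    def __post_init__(self):
        for p in (self.nb_prob, self.error_rate, self.barcode_collision_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


def simulate_gene(
    n_exons: int,
    n_isoforms: int,
    exon_len_range: Tuple[int, int] = (150, 400),
    seed: int = 0,
    gene_id: str = "gene1",
) -> GeneModel:
    """Random gene with ``n_isoforms`` distinct isoforms over ``n_exons`` exons.

    Every isoform keeps the first and last exon (shared terminal flanks);
    the first isoform uses all exons, the rest are distinct random subsets
    of the middle exons.  Expression weights are uniform.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    n_middle = max(0, n_exons - 2)
    max_iso = 2 ** n_middle
    if n_isoforms < 1 or n_isoforms > max_iso:
        raise ValueError(
            f"cannot draw {n_isoforms} distinct isoforms from {n_exons} exons "
            f"with fixed terminal exons (max {max_iso})"
        )
    rng = np.random.default_rng(seed)
    lo, hi = exon_len_range
    exons = tuple(
        "".join(rng.choice(["A", "C", "G", "T"], size=int(rng.integers(lo, hi + 1))))
        for _ in range(n_exons)
    )
    masks = [tuple(range(n_exons))]  # full isoform first
    if n_isoforms > 1:
        middle = list(range(1, n_exons - 1))
        all_subsets = [
            s for r in range(n_middle + 1) for s in itertools.combinations(middle, r)
        ]
        full_middle = tuple(middle)
        candidates = [s for s in all_subsets if s != full_middle]
        chosen = rng.choice(len(candidates), size=n_isoforms - 1, replace=False)
        for ci in sorted(chosen):
            masks.append((0,) + candidates[ci] + (n_exons - 1,) if n_exons > 1 else (0,))
    isoforms = tuple(
        (f"{gene_id}.iso{i + 1}", tuple(m)) for i, m in enumerate(masks)
    )
    expression = tuple([1.0 / n_isoforms] * n_isoforms)
    return GeneModel(gene_id, exons, isoforms, expression)


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _draw_cloud_size(cfg: CloudSimConfig, rng: np.random.Generator) -> int:
    while True:
        x = int(rng.negative_binomial(cfg.nb_size, cfg.nb_prob))
        if x >= 1:
            return x


def _sample_molecule_reads(
    transcript: str,
    n_pairs: int,
    cfg: CloudSimConfig,
    rng: np.random.Generator,
    barcode: str,
    pair_prefix: str,
) -> List[ReadPair]:
    L = len(transcript)
    pairs = []
    for p in range(n_pairs):
        insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
        insert = max(cfg.read_len, min(insert, L))
        start = int(rng.integers(0, L - insert + 1))
        frag = transcript[start : start + insert]
        r1 = _mutate(frag[: cfg.read_len], cfg.error_rate, rng)
        r2 = _mutate(revcomp(frag)[: cfg.read_len], cfg.error_rate, rng)
        pairs.append(ReadPair(barcode, r1, r2, f"{pair_prefix}_{p}"))
    return pairs


def simulate_clouds(
    genes: Sequence[GeneModel],
    cfg: CloudSimConfig,
) -> Tuple[List[ReadCloud], pd.DataFrame]:
    """Simulate barcoded read clouds plus the ground-truth table.

    Each cloud draws one gene (uniform), one isoform (by expression), a
    fresh barcode and a cloud size; with probability
    ``barcode_collision_rate`` a second molecule from a *different* gene
    shares the barcode.  Truth rows: one per molecule.
    """
    rng = np.random.default_rng(cfg.seed)
    clouds: List[ReadCloud] = []
    truth_rows = []
    used_barcodes = set()
    for ci in range(cfg.n_clouds):
        while True:
            barcode = "".join(rng.choice(["A", "C", "G", "T"], size=cfg.barcode_len))
            if barcode not in used_barcodes:
                used_barcodes.add(barcode)
                break
        gi = int(rng.integers(0, len(genes)))
        molecules = [genes[gi]]
        if len(genes) > 1 and rng.random() < cfg.barcode_collision_rate:
            gj = int(rng.integers(0, len(genes) - 1))
            if gj >= gi:
                gj += 1
            molecules.append(genes[gj])
        pairs: List[ReadPair] = []
        for mi, gene in enumerate(molecules):
            weights = np.asarray(gene.expression, dtype=float)
            iso_idx = int(rng.choice(len(gene.isoforms), p=weights / weights.sum()))
            iso_id = gene.isoforms[iso_idx][0]
            transcript = gene.transcript(iso_id)
            if cfg.fixed_coverage is not None:
                n_pairs = int(np.ceil(cfg.fixed_coverage * len(transcript)
                                      / (2 * cfg.read_len)))
            else:
                n_pairs = _draw_cloud_size(cfg, rng)
            pairs.extend(
                _sample_molecule_reads(
                    transcript, n_pairs, cfg, rng, barcode, f"c{ci}m{mi}"
                )
            )
            truth_rows.append(
                {
                    "barcode": barcode,
                    "gene_id": gene.gene_id,
                    "isoform_id": iso_id,
                    "n_pairs": n_pairs,
                    "transcript_length": len(transcript),
                }
            )
        clouds.append(ReadCloud(barcode, pairs))
    truth = pd.DataFrame(
        truth_rows,
        columns=["barcode", "gene_id", "isoform_id", "n_pairs", "transcript_length"],
    )
    return clouds, truth


# -------------------------------------------------------------------- output


def write_clouds_fastq(clouds: Sequence[ReadCloud], path1, path2,
                       dialect: str = "bx") -> None:
    """Write paired FASTQ; barcode either as a BX:Z comment or a '#' name suffix."""
    if dialect not in ("bx", "suffix"):
        raise ValueError(f"unknown barcode dialect: {dialect}")
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for cloud in clouds:
            for p in cloud.pairs:
                if dialect == "bx":
                    h1 = f"@{p.pair_id}/1 BX:Z:{p.barcode}"
                    h2 = f"@{p.pair_id}/2 BX:Z:{p.barcode}"
                else:
                    h1 = f"@{p.pair_id}/1#{p.barcode}"
                    h2 = f"@{p.pair_id}/2#{p.barcode}"
                f1.write(f"{h1}\n{p.read1}\n+\n{'I' * len(p.read1)}\n")
                f2.write(f"{h2}\n{p.read2}\n+\n{'I' * len(p.read2)}\n")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_transcripts_fasta(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for iso_id, _ in g.isoforms:
                seq = g.transcript(iso_id)
                fh.write(f">{iso_id} gene={g.gene_id} length={len(seq)}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
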