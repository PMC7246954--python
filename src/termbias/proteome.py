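"""Proteome ingestion: parsing, validation, redundancy removal, gene-overlap flags.

A proteome is represented as a :class:`GeneTable` of :class:`ProteinRecord`
objects, each pairing an amino-acid sequence with its codon sequence, stop
codon and coordinates on a replicon.  Records failing translation consistency
under the declared codon table are dropped (and logged) at load time, so that
downstream composition statistics never see inconsistent sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = [
    "protein_id",
    "genome_id",
    "replicon",
    "start",
    "end",
    "strand",
    "stop_codon",
    "codon_table",
    "cog_category",
    "localization",
    "abundance_ppm",
    "taxon_lineage",
]

ANNOTATION_KEYS = ("taxon_lineage", "cog_category", "localization", "abundance_ppm")


@dataclass
class ProteinRecord:
    """One CDS/protein: amino-acid sequence, codons, stop codon, coordinates.

    Coordinates are 1-based inclusive on the replicon (GenBank convention).
    ``codon_seq`` excludes the stop codon, so ``len(codon_seq) == len(aa_seq)``.
    """

    protein_id: str
    genome_id: str
    aa_seq: str
    codon_seq: tuple[str, ...]
    stop_codon: str
    codon_table_id: int = 11
    replicon: str = "chr"
    strand: str = "+"
    start: int = 0
    end: int = 0
    annotations: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.aa_seq)

    @property
    def cds(self) -> str:
        """Full CDS nucleotide sequence including the stop codon."""
        return "".join(self.codon_seq) + self.stop_codon

    def validate(self) -> None:
        """Raise ValueError if the codon/aa/stop invariants do not hold."""
        if len(self.codon_seq) != len(self.aa_seq):
            raise ValueError(
                f"{self.protein_id}: {len(self.codon_seq)} codons vs "
                f"{len(self.aa_seq)} residues"
            )
        table = CodonTable.unambiguous_dna_by_id[self.codon_table_id]
        if self.stop_codon not in table.stop_codons:
            raise ValueError(
                f"{self.protein_id}: {self.stop_codon} is not a stop codon "
                f"under table {self.codon_table_id}"
            )
        translated = str(Seq("".join(self.codon_seq)).translate(table=self.codon_table_id))
        if translated != self.aa_seq:
            raise ValueError(f"{self.protein_id}: translation mismatch")


@dataclass
class GeneTable:
    """Coordinate-sorted collection of :class:`ProteinRecord` objects."""

    records: list[ProteinRecord]
    replicon_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from collections import Counter as _Counter

        id_counts = _Counter(r.protein_id for r in self.records)
        dupes = [i for i, n in id_counts.items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate protein_ids: {sorted(dupes)[:5]}")
        self.records.sort(key=lambda r: (r.genome_id, r.replicon, r.start, r.protein_id))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_genome(self) -> dict[str, list[ProteinRecord]]:
        out: dict[str, list[ProteinRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.genome_id, []).append(rec)
        return out


def _split_codons(cds: str) -> tuple[tuple[str, ...], str]:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    codons = tuple(cds[i : i + 3] for i in range(0, len(cds), 3))
    return codons[:-1], codons[-1]


def load_proteome(
    protein_fasta: str | Path,
    cds_fasta: str | Path,
    gene_table: str | Path,
    codon_table_id: int | None = None,
) -> GeneTable:
    """Load and cross-validate a proteome from FASTA + TSV inputs.

    ``gene_table`` is a TSV with the columns in :data:`GENE_TABLE_COLUMNS`.
    Every id in the gene table must be present in both FASTA files (hard
    error otherwise).  Records whose CDS does not translate to the protein
    sequence, or whose terminal codon is not a stop under the codon table in
    force, are dropped with a logged reason.
    """
    proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_fasta), "fasta")}
    cdss = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(cds_fasta), "fasta")}
    genes = pd.read_csv(gene_table, sep="\t", dtype={"protein_id": str})
    if genes.empty or not proteins or not cdss:
        raise ValueError("empty proteome input")

    missing = [
        pid
        for pid in genes["protein_id"]
        if pid not in proteins or pid not in cdss
    ]
    if missing:
        raise ValueError(f"gene table ids missing from FASTA inputs: {missing[:10]}")

    records: list[ProteinRecord] = []
    n_dropped = 0
    for row in genes.itertuples(index=False):
        pid = row.protein_id
        table_id = codon_table_id if codon_table_id is not None else int(row.codon_table)
        cds = cdss[pid]
        try:
            codons, stop = _split_codons(cds)
        except ValueError as exc:
            logger.warning("dropping %s: %s", pid, exc)
            n_dropped += 1
            continue
        annotations = {
            key: getattr(row, key)
            for key in ANNOTATION_KEYS
            if key in genes.columns and pd.notna(getattr(row, key))
        }
        rec = ProteinRecord(
            protein_id=pid,
            genome_id=str(row.genome_id),
            aa_seq=proteins[pid],
            codon_seq=codons,
            stop_codon=stop,
            codon_table_id=table_id,
            replicon=str(row.replicon),
            strand=str(row.strand),
            start=int(row.start),
            end=int(row.end),
            annotations=annotations,
        )
        try:
            rec.validate()
        except ValueError as exc:
            logger.warning("dropping %s: %s", pid, exc)
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        logger.info("dropped %d inconsistent records", n_dropped)
    return GeneTable(records=records)


def write_proteome(
    table: GeneTable,
    protein_fasta: str | Path,
    cds_fasta: str | Path,
    gene_table: str | Path,
) -> None:
    """Write a GeneTable back to the FASTA + TSV dialect read by load_proteome."""
    with open(protein_fasta, "w") as fh:
        for rec in table:
            fh.write(f">{rec.protein_id}\n{rec.aa_seq}\n")
    with open(cds_fasta, "w") as fh:
        for rec in table:
            fh.write(f">{rec.protein_id}\n{rec.cds}\n")
    rows = []
    for rec in table:
        row = {
            "protein_id": rec.protein_id,
            "genome_id": rec.genome_id,
            "replicon": rec.replicon,
            "start": rec.start,
            "end": rec.end,
            "strand": rec.strand,
            "stop_codon": rec.stop_codon,
            "codon_table": rec.codon_table_id,
        }
        for key in ANNOTATION_KEYS:
            row[key] = rec.annotations.get(key, "")
        rows.append(row)
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(gene_table, sep="\t", index=False)


_aligner = PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = 0.0
_aligner.extend_gap_score = 0.0


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matched residues under a unit-score global alignment.

    Identity is matches divided by the length of the shorter sequence, so a
    perfect substring scores 1.0.
    """
    if not a or not b:
        return 0.0
    matches = _aligner.score(a, b)
    return matches / min(len(a), len(b))


def _greedy_cluster(
    seqs: Sequence[str], ids: Sequence[str], threshold: float
) -> list[list[int]]:
    """Greedy single-linkage-to-representative clustering at >= threshold identity.

    Sequences are visited longest-first (ties by id) and joined to the first
    cluster whose representative they match, mirroring CD-HIT's greedy order
    without its word-filter heuristics.
    """
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), ids[i]))
    clusters: list[list[int]] = []
    for i in order:
        for cluster in clusters:
            rep = cluster[0]
            if pairwise_identity(seqs[i], seqs[rep]) >= threshold:
                cluster.append(i)
                break
        else:
            clusters.append([i])
    return clusters


def deduplicate(
    records: Iterable[ProteinRecord],
    full_threshold: float = 0.80,
    cterm_threshold: float = 0.85,
    cterm_len: int = 20,
) -> list[ProteinRecord]:
    """Remove redundant paralogs by two-step greedy identity clustering.

    Step 1 clusters full-length sequences at ``full_threshold`` identity;
    step 2 re-clusters the last ``cterm_len`` residues of multi-member
    clusters at ``cterm_threshold``.  One representative (longest sequence,
    ties broken by lexicographic id) is kept per final cluster.  Apply per
    genome; pooling across genomes would merge legitimate orthologs.
    """
    for name, thr in (("full_threshold", full_threshold), ("cterm_threshold", cterm_threshold)):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {thr}")
    recs = list(records)
    if not recs:
        return []
    seqs = [r.aa_seq for r in recs]
    ids = [r.protein_id for r in recs]
    kept: list[ProteinRecord] = []
    for cluster in _greedy_cluster(seqs, ids, full_threshold):
        if len(cluster) == 1:
            kept.append(recs[cluster[0]])
            continue
        tails = [seqs[i][-cterm_len:] for i in cluster]
        tail_ids = [ids[i] for i in cluster]
        for sub in _greedy_cluster(tails, tail_ids, cterm_threshold):
            members = [cluster[j] for j in sub]
            rep = min(members, key=lambda i: (-len(seqs[i]), ids[i]))
            kept.append(recs[rep])
    removed = len(recs) - len(kept)
    if removed:
        logger.info("deduplicate removed %d of %d records", removed, len(recs))
    kept.sort(key=lambda r: r.protein_id)
    return kept


def filter_min_length(
    records: Iterable[ProteinRecord], min_len: int = 50
) -> list[ProteinRecord]:
    """Drop proteins shorter than ``min_len`` residues (default < 50 removed)."""
    recs = list(records)
    kept = [r for r in recs if len(r) >= min_len]
    removed = len(recs) - len(kept)
    if removed:
        logger.info("filter_min_length removed %d of %d records", removed, len(recs))
    return kept


def detect_downstream_start_overlap(table: GeneTable) -> dict[str, bool]:
    """Flag genes whose stop codon overlaps the downstream gene's start codon.

    The flagged configuration is the 4-nt AUGA overlap: a same-strand gene
    starting exactly at the focal gene's last sense-codon third-nucleotide
    position, i.e. downstream start = stop-codon start - 1 in reading
    direction.  On the forward strand the stop codon occupies
    ``[end-2, end]`` so the overlap requires a gene with ``start == end - 3``;
    on the reverse strand (stop at ``[start, start+2]`` in genome
    coordinates) it requires a gene with ``end == start + 3``.
    """
    flags = {rec.protein_id: False for rec in table}
    starts_fwd: dict[tuple[str, str, int], bool] = {}
    ends_rev: dict[tuple[str, str, int], bool] = {}
    for rec in table:
        key = (rec.genome_id, rec.replicon)
        if rec.strand == "+":
            starts_fwd[key + (rec.start,)] = True
        else:
            ends_rev[key + (rec.end,)] = True
    for rec in table:
        key = (rec.genome_id, rec.replicon)
        if rec.strand == "+":
            flags[rec.protein_id] = key + (rec.end - 3,) in starts_fwd
        else:
            flags[rec.protein_id] = key + (rec.start + 3,) in ends_rev
    return flags
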