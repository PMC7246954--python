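"""Synthetic data generators with known ground truth for every pipeline stage.

Each generator is deterministic under a fixed seed and returns, alongside
the simulated dataset, a machine-readable truth record of every injected
parameter and event, so that downstream estimators can be checked against
what was actually simulated.

The sequence model is deliberately minimal: residues are drawn i.i.d. per
position from a bulk composition, with per-position multipliers on the last
20 positions injecting terminal bias.  The statistics under test depend
only on positional composition, so no attempt is made to emulate protein
structure, domains, or realistic codon autocorrelation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .elmseq import reconstruct_local_sequence
from .evolution import BULK, TripletAlignment
from .proteome import GeneTable, ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Bulk amino-acid frequencies typical of a bacterial proteome.
DEFAULT_BULK_FREQ: dict[str, float] = {
    "A": 0.095, "C": 0.012, "D": 0.054, "E": 0.061, "F": 0.038,
    "G": 0.074, "H": 0.022, "I": 0.060, "K": 0.047, "L": 0.105,
    "M": 0.027, "N": 0.040, "P": 0.042, "Q": 0.044, "R": 0.055,
    "S": 0.058, "T": 0.054, "V": 0.070, "W": 0.014, "Y": 0.028,
}


def _codons_by_aa(codon_table_id: int) -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[codon_table_id]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


@dataclass
class ProteomeConfig:
    """Study conditions for the synthetic proteome generator.

    ``mu`` maps amino acid -> {position -> multiplier} for positions in
    -20..-1; the position's composition is bulk_freq * mu renormalized.
    ``duplication_rate`` is the fraction of genes copied verbatim (gene
    duplication), ``short_fraction`` the fraction given lengths below 50
    residues, and ``overlap_fraction`` the fraction of genes laid out with
    a downstream same-strand gene whose ATG start overlaps their TGA stop
    (which forces an A-ending last codon, the NNA signal such overlaps
    create in real genomes).
    """

    n_genes: int = 1000
    length_range: tuple[int, int] = (100, 300)
    bulk_freq: Mapping[str, float] | None = None
    mu: Mapping[str, Mapping[int, float]] | None = None
    codon_table_id: int = 11
    stop_probs: Mapping[str, float] | None = None
    duplication_rate: float = 0.0
    short_fraction: float = 0.0
    short_length_range: tuple[int, int] = (20, 49)
    overlap_fraction: float = 0.0
    genome_id: str = "synth"
    seed: int = 0


def gen_proteome(config: ProteomeConfig) -> tuple[GeneTable, dict]:
    """Simulate a proteome with injected terminal composition biases.

    Residues are i.i.d.: bulk positions from ``bulk_freq``, the last 20
    positions from bulk * mu renormalized.  Codons are drawn uniformly from
    the synonymous codons of each residue; genes are laid head-to-tail on
    one forward-strand replicon.  Returns (GeneTable, truth dict) where the
    truth records duplicate/short/overlap gene ids and the injected
    parameters.
    """
    rng = np.random.default_rng(config.seed)
    aa_list = np.array(list(AMINO_ACIDS))
    freq = config.bulk_freq or DEFAULT_BULK_FREQ
    p_bulk = np.array([freq[a] for a in AMINO_ACIDS], float)
    if not math.isclose(p_bulk.sum(), 1.0, abs_tol=1e-6) or (p_bulk < 0).any():
        raise ValueError("bulk_freq must be a probability vector over the 20 amino acids")
    p_bulk = p_bulk / p_bulk.sum()

    mu = config.mu or {}
    for aa, by_pos in mu.items():
        for pos, m in by_pos.items():
            if m <= 0:
                raise ValueError(f"multiplier mu[{aa}][{pos}] must be > 0")

    table = CodonTable.unambiguous_dna_by_id[config.codon_table_id]
    codons_of = _codons_by_aa(config.codon_table_id)
    if config.stop_probs is None:
        stops = sorted(table.stop_codons)
        stop_probs = {s: 1.0 / len(stops) for s in stops}
    else:
        stop_probs = dict(config.stop_probs)
        for s in stop_probs:
            if s not in table.stop_codons:
                raise ValueError(f"{s} is not a stop under table {config.codon_table_id}")
    stop_list = sorted(stop_probs)
    p_stop = np.array([stop_probs[s] for s in stop_list], float)
    p_stop = p_stop / p_stop.sum()

    n = config.n_genes
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    n_short = round(config.short_fraction * n)
    short_idx = rng.choice(n, size=n_short, replace=False) if n_short else np.array([], int)
    if n_short:
        s_lo, s_hi = config.short_length_range
        lengths[short_idx] = rng.integers(s_lo, s_hi + 1, size=n_short)

    # terminal position distributions: bulk * mu renormalized
    term_p = {}
    for pos in range(-20, 0):
        mult = np.array([mu.get(a, {}).get(pos, 1.0) for a in AMINO_ACIDS], float)
        p = p_bulk * mult
        term_p[pos] = p / p.sum()

    bulk_lens = np.maximum(lengths - 20, 0)
    bulk_chars = rng.choice(aa_list, size=int(bulk_lens.sum()), p=p_bulk)
    term_chars = {pos: rng.choice(aa_list, size=n, p=term_p[pos]) for pos in range(-20, 0)}

    seqs: list[str] = []
    offset = 0
    for g in range(n):
        bl = int(bulk_lens[g])
        head = "".join(bulk_chars[offset : offset + bl])
        offset += bl
        n_term = min(int(lengths[g]), 20)
        tail = "".join(term_chars[pos][g] for pos in range(-n_term, 0))
        seqs.append(head + tail)

    stops_drawn = [str(s) for s in rng.choice(stop_list, size=n, p=p_stop)]

    # overlap genes: forced TGA stop and A-ending last sense codon
    n_overlap = round(config.overlap_fraction * n)
    overlap_idx = set(
        rng.choice(n - 1, size=n_overlap, replace=False).tolist() if n_overlap else []
    )
    a_ending = sorted(
        c for aa, cs in codons_of.items() for c in cs if c.endswith("A")
    )
    overlap_last_codon: dict[int, str] = {}
    if n_overlap and "TGA" not in table.stop_codons:
        raise ValueError("overlap_fraction requires a codon table where TGA is a stop")
    for g in sorted(overlap_idx):
        stops_drawn[g] = "TGA"
        codon = str(rng.choice(a_ending))
        overlap_last_codon[g] = codon
        aa = str(Seq(codon).translate(table=config.codon_table_id))
        seqs[g] = seqs[g][:-1] + aa

    # codon assignment, vectorized per amino acid
    all_chars = np.array(list("".join(seqs)))
    codon_arr = np.empty(len(all_chars), dtype=object)
    for aa in AMINO_ACIDS:
        idx = np.flatnonzero(all_chars == aa)
        if len(idx):
            codon_arr[idx] = rng.choice(np.array(codons_of[aa]), size=len(idx))

    records: list[ProteinRecord] = []
    cursor = 101
    offset = 0
    for g in range(n):
        L = int(lengths[g])
        codons = list(codon_arr[offset : offset + L])
        offset += L
        if g in overlap_last_codon:
            codons[-1] = overlap_last_codon[g]
        start = cursor
        end = start + 3 * (L + 1) - 1
        records.append(
            ProteinRecord(
                protein_id=f"g{g:06d}",
                genome_id=config.genome_id,
                aa_seq=seqs[g],
                codon_seq=tuple(codons),
                stop_codon=stops_drawn[g],
                codon_table_id=config.codon_table_id,
                replicon="chr",
                strand="+",
                start=start,
                end=end,
            )
        )
        if g in overlap_idx:
            # next gene's ATG shares the A of this gene's last sense codon
            cursor = end - 3
        else:
            cursor = end + 51

    n_dup = round(config.duplication_rate * n)
    dup_ids = []
    if n_dup:
        src = rng.choice(n, size=n_dup, replace=False)
        tail_start = records[-1].end + 51
        for k, g in enumerate(sorted(src)):
            base = records[g]
            L = len(base)
            start = tail_start
            end = start + 3 * (L + 1) - 1
            tail_start = end + 51
            dup_id = f"{base.protein_id}_dup{k}"
            dup_ids.append(dup_id)
            records.append(
                ProteinRecord(
                    protein_id=dup_id,
                    genome_id=base.genome_id,
                    aa_seq=base.aa_seq,
                    codon_seq=base.codon_seq,
                    stop_codon=base.stop_codon,
                    codon_table_id=base.codon_table_id,
                    replicon="chr",
                    strand="+",
                    start=start,
                    end=end,
                )
            )

    truth = {
        "mu": {a: dict(by_pos) for a, by_pos in mu.items()},
        "bulk_freq": dict(freq),
        "duplicate_ids": dup_ids,
        "short_ids": [f"g{g:06d}" for g in sorted(short_idx.tolist())],
        "overlap_ids": [f"g{g:06d}" for g in sorted(overlap_idx)],
        "stop_probs": stop_probs,
    }
    return GeneTable(records=records), truth


def gen_pair_biased_termini(
    n: int,
    pair: tuple[str, str] = ("K", "K"),
    excess: float = 1.8,
    freq: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[str]:
    """Sample terminal residue pairs with a joint excess at one pair.

    The joint law has the stated marginal frequencies at both positions
    exactly, with P(pair) = excess * f(a) * f(b): the boosted mass is
    compensated inside the pair's row and column so that the positional
    marginals do not shift.  The pair-epistasis ratio statistic therefore
    converges to ``excess`` itself.  Returns short sequences whose last two
    residues carry the injected law (a leading poly-M stub keeps them
    valid inputs for terminal statistics).
    """
    if not 0 < excess:
        raise ValueError("excess must be positive")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    f = np.array(
        [(freq or {a: 1 / 20 for a in AMINO_ACIDS})[a] for a in AMINO_ACIDS], float
    )
    f = f / f.sum()
    i = int(np.flatnonzero(aas == pair[0])[0])
    j = int(np.flatnonzero(aas == pair[1])[0])
    if i != j:
        raise NotImplementedError("marginal-preserving boost implemented for repeated pairs")
    fk = f[i]
    if excess * fk >= 1:
        raise ValueError("excess too large for the pair's marginal frequency")
    joint = np.outer(f, f) * (1 - 2 * fk + excess * fk**2) / (1 - fk) ** 2
    joint[i, :] = fk * (1 - excess * fk) * f / (1 - fk)
    joint[:, j] = f * (1 - excess * fk) * fk / (1 - fk)
    joint[i, j] = excess * fk**2
    if (joint < 0).any():
        raise ValueError("invalid joint law; reduce excess")
    joint = joint / joint.sum()
    picks = rng.choice(400, size=n, p=joint.ravel())
    return ["M" * 8 + aas[k // 20] + aas[k % 20] for k in picks]


@dataclass
class TripletConfig:
    """Study conditions for triplet-alignment simulation.

    ``sub_prob`` maps position label (-1..-max_pos or "bulk") to the
    per-branch substitution probability at that column; unlisted positions
    use ``base_prob``.  ``target_bias`` optionally biases the substitution
    target distribution at chosen positions (amino acid -> weight).
    """

    n_genes: int = 200
    length: int = 150
    ancestral_freq: Mapping[str, float] | None = None
    base_prob: float = 0.02
    sub_prob: Mapping = field(default_factory=dict)
    target_bias: Mapping = field(default_factory=dict)
    outgroup_scale: float = 1.5
    max_pos: int = 20
    seed: int = 0


def _position_label(i: int, length: int, max_pos: int):
    offset = i - length
    return offset if offset >= -max_pos else BULK


def gen_triplets(config: TripletConfig) -> tuple[list[TripletAlignment], pd.DataFrame, pd.DataFrame]:
    """Simulate gapless triplet alignments with position-dependent rates.

    An ancestral sequence is drawn per orthogroup; each ingroup branch
    mutates every site independently with its position's probability, to a
    uniformly random different residue (or per ``target_bias``).  The
    outgroup branch mutates likewise with probability scaled by
    ``outgroup_scale``.  Returns (alignments, dS table, truth event table);
    the truth table logs every mutation event with its branch and position.
    """
    rng = np.random.default_rng(config.seed)
    aa_list = np.array(list(AMINO_ACIDS))
    freq = config.ancestral_freq or DEFAULT_BULK_FREQ
    p = np.array([freq[a] for a in AMINO_ACIDS], float)
    p = p / p.sum()

    prob = np.full(config.length, config.base_prob)
    for i in range(config.length):
        label = _position_label(i, config.length, config.max_pos)
        if label in config.sub_prob:
            prob[i] = config.sub_prob[label]
        elif BULK in config.sub_prob and label == BULK:
            prob[i] = config.sub_prob[BULK]

    target_weights: dict[int, np.ndarray] = {}
    for i in range(config.length):
        label = _position_label(i, config.length, config.max_pos)
        if label in config.target_bias:
            w = np.array([config.target_bias[label].get(a, 1.0) for a in AMINO_ACIDS], float)
            target_weights[i] = w

    alns: list[TripletAlignment] = []
    events: list[dict] = []

    def mutate(root: np.ndarray, branch: str, gene: str, scale: float) -> np.ndarray:
        out = root.copy()
        hits = np.flatnonzero(rng.random(config.length) < np.minimum(prob * scale, 0.999))
        for i in hits:
            cur = out[i]
            w = target_weights.get(i)
            if w is None:
                weights = np.ones(20)
            else:
                weights = w.copy()
            weights[aa_list == cur] = 0.0
            weights = weights / weights.sum()
            new = str(rng.choice(aa_list, p=weights))
            events.append(
                {
                    "orthogroup_id": gene,
                    "column": int(i),
                    "position": _position_label(int(i), config.length, config.max_pos),
                    "branch": branch,
                    "from": str(cur),
                    "to": new,
                }
            )
            out[i] = new
        return out

    for g in range(config.n_genes):
        gene = f"og{g:05d}"
        root = rng.choice(aa_list, size=config.length, p=p)
        in1 = mutate(root, "in1", gene, 1.0)
        in2 = mutate(root, "in2", gene, 1.0)
        out = mutate(root, "out", gene, config.outgroup_scale)
        alns.append(
            TripletAlignment(
                orthogroup_id=gene,
                seq_in1="".join(in1),
                seq_in2="".join(in2),
                seq_out="".join(out),
                species=("sp_in1", "sp_in2", "sp_out"),
            )
        )

    ds = pd.DataFrame(
        [
            {"species_a": "sp_in1", "species_b": "sp_in2", "dS": 0.30},
            {"species_a": "sp_in1", "species_b": "sp_out", "dS": 0.45},
            {"species_a": "sp_in2", "species_b": "sp_out", "dS": 0.45},
        ]
    )
    return alns, ds, pd.DataFrame(events)


@dataclass
class ElmSeqConfig:
    """Study conditions for the ELM-seq count simulator.

    True expression of a variant is e_minus2[aa] * e_minus1[aa] *
    q_pair[(aa2, aa1)]; methylation follows the saturating link
    m = E / (E + Km) (a test-harness contract, not assay chemistry), and
    reads split multinomially between the DpnI sample (weight proportional
    to m) and the MboI sample (proportional to 1 - m).
    """

    e_minus2: Mapping[str, float] = field(default_factory=dict)
    e_minus1: Mapping[str, float] = field(default_factory=dict)
    q_pair: Mapping[tuple[str, str], float] = field(default_factory=dict)
    stop_effect: float = 1.0
    n_variants: int = 4096
    reads_per_sample: int = 1_000_000
    km: float | None = None
    codon_table_id: int = 4
    seed: int = 0


def _translate_codon(codon: str, codon_table_id: int) -> str:
    if codon in ("TAA", "TAG"):
        return "*"
    return str(Seq(codon).translate(table=codon_table_id))


def gen_elmseq(config: ElmSeqConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired DpnI/MboI variant read counts from true effects.

    Variant keys are drawn uniformly from the 4^6 up6 space (all 4096 when
    ``n_variants`` >= 4096, a random subset otherwise), each paired with a
    random down6; abundances are uniform.  Returns (count table, truth
    table with the true expression and methylation of each variant).
    """
    rng = np.random.default_rng(config.seed)
    all_up6 = ["".join(c) for c in itertools.product("ACGT", repeat=6)]
    if config.n_variants >= len(all_up6):
        up6s = all_up6
    else:
        up6s = sorted(rng.choice(all_up6, size=config.n_variants, replace=False))
    down6s = ["".join(rng.choice(list("ACGT"), size=6)) for _ in up6s]

    aa2 = [_translate_codon(u[:3], config.codon_table_id) for u in up6s]
    aa1 = [_translate_codon(u[3:], config.codon_table_id) for u in up6s]

    def eff(table: Mapping[str, float], aa: str) -> float:
        if aa == "*":
            return config.stop_effect
        return float(table.get(aa, 1.0))

    E = np.array(
        [
            eff(config.e_minus2, a2)
            * eff(config.e_minus1, a1)
            * float(config.q_pair.get((a2, a1), 1.0))
            for a2, a1 in zip(aa2, aa1)
        ]
    )
    km = float(np.median(E)) if config.km is None else config.km
    m = E / (E + km)

    w_dpn = m / m.sum()
    w_mbo = (1 - m) / (1 - m).sum()
    reads_dpn = rng.multinomial(config.reads_per_sample, w_dpn)
    reads_mbo = rng.multinomial(config.reads_per_sample, w_mbo)

    counts = pd.DataFrame(
        {
            "up6": up6s,
            "down6": down6s,
            "reads_dpnI": reads_dpn,
            "reads_mboI": reads_mbo,
        }
    )
    truth = pd.DataFrame(
        {
            "up6": up6s,
            "down6": down6s,
            "aa_minus2": aa2,
            "aa_minus1": aa1,
            "expression": E,
            "methylation": m,
        }
    )
    return counts, truth


def elmseq_reads(counts: pd.DataFrame, sample: str) -> list[str]:
    """Expand a count table into the literal template reads of one sample."""
    col = {"dpnI": "reads_dpnI", "mboI": "reads_mboI"}[sample]
    reads = []
    for rec in counts.itertuples(index=False):
        seq = reconstruct_local_sequence(rec.up6, rec.down6)
        reads.extend([seq] * int(getattr(rec, col)))
    return reads


def write_fastq(reads: Sequence[str], path: str | Path) -> None:
    """Write reads as plain FASTQ with uniform qualities."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


@dataclass
class LuminescenceConfig:
    """Study conditions for shut-off luminescence simulation.

    ``variants`` maps variant name -> (steady-state luminescence X0,
    degradation rate d per hour).  Noise is multiplicative log-normal with
    log-scale sigma ``cv`` (luminescence errors scale with signal).
    """

    variants: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    cv: float = 0.0
    replicates: int = 3
    times: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0)
    cat_norm: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0


def gen_luminescence(config: LuminescenceConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate exponential-decay luminescence tracks with known rates.

    luminescence = X0 * exp(-d t) * exp(cv * Z) per point, Z standard
    normal; replicates independent.  Returns (time-series table, truth
    table of the injected X0 and d per variant).
    """
    if config.cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(config.seed)
    rows = []
    for variant, (x0, d) in config.variants.items():
        if d < 0:
            raise ValueError(f"negative decay rate for {variant}")
        for rep in range(1, config.replicates + 1):
            for t in config.times:
                noise = math.exp(config.cv * rng.standard_normal()) if config.cv else 1.0
                rows.append(
                    {
                        "variant": variant,
                        "replicate": rep,
                        "time_h": float(t),
                        "luminescence": x0 * math.exp(-d * t) * noise,
                        "cat_norm": float(config.cat_norm.get(variant, 1.0)),
                    }
                )
    truth = pd.DataFrame(
        [
            {"variant": v, "X0": x0, "d": d}
            for v, (x0, d) in config.variants.items()
        ]
    )
    return pd.DataFrame(rows), truth
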