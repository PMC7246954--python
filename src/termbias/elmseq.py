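"""Quantification of C-terminal variant expression from ELM-seq read counts.

ELM-seq reads out the abundance of a DNA adenine methylase (Dam) reporter:
the more Dam, the more its GATC target sites are methylated, which is
measured by differential digestion with DpnI (cuts methylated GATC) and
MboI (cuts unmethylated GATC) followed by sequencing.  Each library variant
carries 6 randomized nucleotides before the designed TAA stop codon (the
last two codons) and 6 after it.  The per-variant DAMratio — the ratio of
its read share in the DpnI sample to its share in the MboI sample — is a
proxy for reporter protein abundance.

The pipeline filters reads against the fixed library template, requires a
minimum read count in both digestion samples, excludes variants whose local
sequence contains a GATC site (which would perturb the digestion readout),
normalizes DAMratios to their geometric mean, and aggregates the resulting
log10 relative expression by nucleotide position, codon slot, amino-acid
slot, or amino-acid pair.  Pair epistasis Q compares each pair's measured
effect with the product of its two single-residue effects.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

logger = logging.getLogger(__name__)

#: Library read template: constant left flank, 6 randomized nt (codons -2
#: and -1), the designed TAA stop, 6 randomized nt, constant right flank.
TEMPLATE = "CGCGAAAAAANNNNNNTAANNNNNNCAGGCCTTGA"

_N_START = TEMPLATE.index("N")
_LEFT = TEMPLATE[:_N_START]  # CGCGAAAAAA
_STOP = TEMPLATE[_N_START + 6 : _N_START + 9]  # TAA
_RIGHT = TEMPLATE[_N_START + 15 :]  # CAGGCCTTGA


def reconstruct_local_sequence(up6: str, down6: str, template: str = TEMPLATE) -> str:
    """Fill a variant's randomized positions back into the template."""
    n = template.index("N")
    return template[:n] + up6 + template[n + 6 : n + 9] + down6 + template[n + 15 :]


def _iter_reads(reads) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for i, line in enumerate(fh):
                mod = i % 4
                if mod == 0 and not line.startswith("@"):
                    raise ValueError(f"malformed FASTQ at line {i + 1}")
                if mod == 2 and not line.startswith("+"):
                    raise ValueError(f"malformed FASTQ at line {i + 1}")
                if mod == 1:
                    yield line.strip().upper()
    else:
        for read in reads:
            yield str(read).upper()


def filter_reads(
    reads, template: str = TEMPLATE
) -> tuple[Counter, int]:
    """Extract (up6, down6) variant counts from reads matching the template.

    Constant template positions must match exactly (no mismatch tolerance);
    the 12 N positions are captured.  The template may sit at any offset in
    the read (libraries stagger a few leading nucleotides for sequencer
    diversity).  Returns (variant counter, number of discarded reads).
    """
    n = template.index("N")
    left = template[:n]
    stop = template[n + 6 : n + 9]
    right = template[n + 15 :]
    counts: Counter = Counter()
    n_discarded = 0
    for read in _iter_reads(reads):
        matched = False
        start = read.find(left)
        while start != -1:
            end = start + len(template)
            if end <= len(read):
                up6 = read[start + n : start + n + 6]
                down6 = read[start + n + 9 : start + n + 15]
                if (
                    read[start + n + 6 : start + n + 9] == stop
                    and read[start + n + 15 : end] == right
                    and set(up6 + down6) <= set("ACGT")
                ):
                    counts[(up6, down6)] += 1
                    matched = True
                    break
            start = read.find(left, start + 1)
        if not matched:
            n_discarded += 1
    if n_discarded:
        logger.info("filter_reads discarded %d non-matching reads", n_discarded)
    return counts, n_discarded


def counts_to_frame(dpn: Mapping, mbo: Mapping) -> pd.DataFrame:
    """Combine per-sample variant counters into a paired count table."""
    keys = sorted(set(dpn) | set(mbo))
    return pd.DataFrame(
        {
            "up6": [k[0] for k in keys],
            "down6": [k[1] for k in keys],
            "reads_dpnI": [int(dpn.get(k, 0)) for k in keys],
            "reads_mboI": [int(mbo.get(k, 0)) for k in keys],
        }
    )


def filter_min_reads(counts: pd.DataFrame, min_reads: int = 30) -> pd.DataFrame:
    """Keep variants with at least ``min_reads`` in BOTH digestion samples."""
    mask = (counts["reads_dpnI"] >= min_reads) & (counts["reads_mboI"] >= min_reads)
    return counts[mask].reset_index(drop=True)


def filter_gatc(counts: pd.DataFrame, template: str = TEMPLATE) -> pd.DataFrame:
    """Drop variants whose reconstructed local sequence contains GATC.

    The scan covers the full reconstructed sequence, so motifs spanning the
    junctions between randomized and constant segments are caught.
    """
    seqs = [
        reconstruct_local_sequence(u, d, template)
        for u, d in zip(counts["up6"], counts["down6"])
    ]
    mask = np.array(["GATC" not in s for s in seqs])
    removed = int((~mask).sum())
    if removed:
        logger.info("filter_gatc removed %d variants", removed)
    return counts[mask].reset_index(drop=True)


def compute_damratio(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-variant DAMratio and average-normalized relative expression R.

    DAMratio = (variant's share of DpnI reads) / (share of MboI reads),
    with shares computed over retained variants only, making the statistic
    invariant to per-sample sequencing depth.  R is the DAMratio divided by
    the geometric mean over retained variants, so mean(log10 R) = 0.
    """
    df = counts.copy()
    total_dpn = df["reads_dpnI"].sum()
    total_mbo = df["reads_mboI"].sum()
    if total_dpn == 0 or total_mbo == 0:
        raise ValueError("zero total reads in a sample")
    ratio = (df["reads_dpnI"] / total_dpn) / (df["reads_mboI"] / total_mbo)
    df["damratio"] = ratio
    log10 = np.log10(ratio)
    df["norm_effect"] = 10 ** (log10 - log10.mean())
    df["log10_R"] = np.log10(df["norm_effect"])
    return df


def _translate(codon: str, codon_table_id: int = 4) -> str:
    """Translate one codon; designed stops TAA/TAG read as '*' controls."""
    if codon in ("TAA", "TAG"):
        return "*"
    return str(Seq(codon).translate(table=codon_table_id))


def aggregate_effects(
    records: pd.DataFrame,
    level: str = "aa_slot",
    codon_table_id: int = 4,
    center: bool = True,
) -> pd.DataFrame:
    """Average log10 relative expression by symbol at a sequence level.

    Levels: ``nt_position`` (12 randomized positions, labelled -6..-1
    upstream and +1..+6 downstream of the stop), ``codon_slot`` (in-frame
    codons -2, -1, +1, +2), ``aa_slot`` (translated codons -2 and -1;
    TAA/TAG report as '*' internal stop controls), ``aa_pair`` (ordered
    amino-acid pair at -2,-1; variants with an internal stop excluded).

    The effect of a symbol is 10^(mean log10_R over variants carrying it);
    with ``center`` the log effects are re-centred so each slot's mean log
    effect is zero.
    """
    if "log10_R" not in records:
        raise ValueError("run compute_damratio first")
    rows = []
    for rec in records.itertuples(index=False):
        up6, down6, lr = rec.up6, rec.down6, rec.log10_R
        if level == "nt_position":
            for i in range(6):
                rows.append((-6 + i, up6[i], lr))
            for i in range(6):
                rows.append((i + 1, down6[i], lr))
        elif level == "codon_slot":
            rows.append((-2, up6[:3], lr))
            rows.append((-1, up6[3:], lr))
            rows.append((1, down6[:3], lr))
            rows.append((2, down6[3:], lr))
        elif level == "aa_slot":
            rows.append((-2, _translate(up6[:3], codon_table_id), lr))
            rows.append((-1, _translate(up6[3:], codon_table_id), lr))
        elif level == "aa_pair":
            aa2 = _translate(up6[:3], codon_table_id)
            aa1 = _translate(up6[3:], codon_table_id)
            if "*" in (aa2, aa1):
                continue
            rows.append(("-2,-1", aa2 + aa1, lr))
        else:
            raise ValueError(f"unknown level {level!r}")
    long = pd.DataFrame(rows, columns=["slot", "symbol", "log10_R"])
    agg = (
        long.groupby(["slot", "symbol"], as_index=False)
        .agg(log10_effect=("log10_R", "mean"), n_variants=("log10_R", "size"))
    )
    if center:
        agg["log10_effect"] -= agg.groupby("slot")["log10_effect"].transform("mean")
    agg["effect"] = 10 ** agg["log10_effect"]
    return agg


def epistasis_q(pair_effects: pd.DataFrame, slot_effects: pd.DataFrame) -> pd.DataFrame:
    """Cooperativity Q of each amino-acid pair against the independent model.

    log10 Q(aa-2, aa-1) = log10 R(pair) - log10 R(aa-2) - log10 R(aa-1),
    with R values taken from the aggregated effect tables (which must come
    from the same record set).  Q = 1 means purely multiplicative effects.
    """
    e2 = slot_effects[slot_effects["slot"] == -2].set_index("symbol")["log10_effect"]
    e1 = slot_effects[slot_effects["slot"] == -1].set_index("symbol")["log10_effect"]
    rows = []
    for rec in pair_effects.itertuples(index=False):
        aa2, aa1 = rec.symbol[0], rec.symbol[1]
        if aa2 not in e2.index or aa1 not in e1.index:
            continue
        log_r_ind = e2[aa2] + e1[aa1]
        log_q = rec.log10_effect - log_r_ind
        rows.append(
            {
                "pair": rec.symbol,
                "aa_minus2": aa2,
                "aa_minus1": aa1,
                "r_pair": 10 ** rec.log10_effect,
                "r_ind": 10 ** log_r_ind,
                "q": 10 ** log_q,
                "log10_q": log_q,
                "n_variants": rec.n_variants,
            }
        )
    return pd.DataFrame(rows)


def cross_library_correlation(
    effects_a: pd.DataFrame, effects_b: pd.DataFrame
) -> dict:
    """Pearson correlation of log10 effects shared between two libraries."""
    merged = effects_a.merge(effects_b, on=["slot", "symbol"], suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared symbols; need >= 3")
    r, p = stats.pearsonr(merged["log10_effect_a"], merged["log10_effect_b"])
    return {"r": float(r), "p": float(p), "n": len(merged)}


def fold_range(pair_effects: pd.DataFrame) -> dict:
    """Ratio of the strongest to the weakest pair effect, with identities."""
    if len(pair_effects) < 2:
        raise ValueError("need at least 2 pairs")
    imax = pair_effects["effect"].idxmax()
    imin = pair_effects["effect"].idxmin()
    return {
        "max_pair": pair_effects.loc[imax, "symbol"],
        "min_pair": pair_effects.loc[imin, "symbol"],
        "ratio": float(pair_effects.loc[imax, "effect"] / pair_effects.loc[imin, "effect"]),
    }
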