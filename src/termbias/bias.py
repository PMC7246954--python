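"""Position-specific composition bias statistics for protein C-termini.

The central object is a *bias table*: for each (symbol, position) pair, the
occurrence count of the symbol at that terminal position across a set of
sequences is compared to the symbol's count in the *bulk* (the middle of the
sequences, excluding the first and last ``n_N``/``n_C`` residues) with a
two-sided Fisher exact test.  Benjamini-Hochberg FDR control is applied
within each table, and cells whose expected terminal count is too small to
ever reach significance at a 2-fold depletion are flagged as underpowered.

Symbols may be amino acids, codons, or pairs thereof; the same machinery
serves stratified analyses (by functional category, localization, abundance
bin, or stop-codon context).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

BIAS_COLUMNS = [
    "symbol",
    "position",
    "obs_count",
    "obs_total",
    "bulk_count",
    "bulk_total",
    "odds_ratio",
    "p_value",
    "q_value",
    "significant",
    "underpowered",
]


@dataclass
class RegionPartition:
    """Split of one sequence into N-terminal, bulk and C-terminal regions."""

    nterm: str
    bulk: str
    cterm: str


def _aa_seq(record) -> str:
    return record if isinstance(record, str) else record.aa_seq


def _codon_seq(record) -> tuple[str, ...]:
    return record.codon_seq


def partition_regions(record, n_N: int = 20, n_C: int = 20) -> RegionPartition:
    """Split a sequence into N-terminal / bulk / C-terminal regions.

    Sequences must be at least ``n_N + n_C + 1`` residues long so that the
    bulk is non-empty; shorter records are the caller's responsibility to
    exclude (see :func:`position_bias`, which drops and logs them).
    """
    seq = _aa_seq(record)
    # bulk must hold at least 2 residues (a 41-mer with the default 20/20
    # split is excluded; its single-residue bulk cannot anchor dipeptides)
    if len(seq) < n_N + n_C + 2:
        raise ValueError(f"sequence of length {len(seq)} < {n_N + n_C + 2}")
    return RegionPartition(nterm=seq[:n_N], bulk=seq[n_N : len(seq) - n_C], cterm=seq[-n_C:])


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Unconditional sample odds ratio (a*d)/(b*c) with +/-inf sentinels."""
    if b == 0 or c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def _bh(df: pd.DataFrame, fdr: float) -> pd.DataFrame:
    if len(df) == 0:
        df["q_value"] = []
        df["significant"] = []
        return df
    rejected, q, _, _ = multipletests(df["p_value"].to_numpy(), alpha=fdr, method="fdr_bh")
    df = df.copy()
    df["q_value"] = q
    df["significant"] = rejected
    return df


def flag_underpowered(
    bulk_count: int, bulk_total: int, obs_total: int, alpha: float = 0.05
) -> bool:
    """True when the expected terminal count is too small to detect a 2-fold bias.

    Finds the smallest expected count m* such that observing half of it
    (odds ratio 0.5 against expectation) would give a two-sided Fisher p
    below ``alpha``; flags the cell when the actual expected count
    ``obs_total * bulk_count / bulk_total`` falls below m*.
    """
    if bulk_total == 0 or bulk_count == 0 or obs_total == 0:
        return True
    f = bulk_count / bulk_total
    expected = obs_total * f
    for m in range(1, obs_total + 1):
        obs = round(0.5 * m)
        if obs > obs_total:
            break
        _, p = stats.fisher_exact(
            [[obs, obs_total - obs], [bulk_count, bulk_total - bulk_count]],
            alternative="two-sided",
        )
        if p < alpha:
            return expected < m
    return True


def _terminal_symbols(records, alphabet: str, positions: Sequence[int], n_N: int, n_C: int):
    """Yield per-record terminal symbols; skip records too short for the split."""
    min_len = n_N + n_C + 2
    n_skipped = 0
    usable = []
    for rec in records:
        seq = _aa_seq(rec)
        if len(seq) < min_len:
            n_skipped += 1
            continue
        usable.append(rec)
    if n_skipped:
        logger.info("excluded %d records shorter than %d residues", n_skipped, min_len)
    return usable


def position_bias(
    records: Iterable,
    alphabet: str = "aa",
    positions: Sequence[int] | None = None,
    n_N: int = 20,
    n_C: int = 20,
    fdr: float = 0.05,
    underpowered: bool = True,
) -> pd.DataFrame:
    """Per (symbol, position) terminal-vs-bulk bias table with Fisher/BH stats.

    ``positions`` are negative offsets from the end (-1 = last residue).
    Bulk counts are pooled over the bulk regions of all contributing
    sequences and shared across positions.  Returns a long-format DataFrame
    with :data:`BIAS_COLUMNS`.
    """
    if positions is None:
        positions = list(range(-n_C, 0))
    usable = _terminal_symbols(records, alphabet, positions, n_N, n_C)
    if not usable:
        raise ValueError("no records long enough for region partition")

    if alphabet == "aa":
        get = _aa_seq
    elif alphabet == "codon":
        get = _codon_seq
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")

    bulk_counter: Counter = Counter()
    for rec in usable:
        seq = get(rec)
        bulk_counter.update(seq[n_N : len(seq) - n_C])
    bulk_total = sum(bulk_counter.values())
    if bulk_total == 0:
        raise ValueError("empty bulk region")

    pos_counters: dict[int, Counter] = {}
    for pos in positions:
        counter: Counter = Counter()
        for rec in usable:
            counter[get(rec)[pos]] += 1
        pos_counters[pos] = counter

    symbols = sorted(set(bulk_counter) | {s for c in pos_counters.values() for s in c})
    obs_total = len(usable)
    rows = []
    for pos in positions:
        counter = pos_counters[pos]
        for sym in symbols:
            a = counter.get(sym, 0)
            c = bulk_counter.get(sym, 0)
            b = obs_total - a
            d = bulk_total - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "symbol": sym,
                    "position": pos,
                    "obs_count": a,
                    "obs_total": obs_total,
                    "bulk_count": c,
                    "bulk_total": bulk_total,
                    "odds_ratio": sample_odds_ratio(a, b, c, d),
                    "p_value": p,
                }
            )
    df = _bh(pd.DataFrame(rows), fdr)
    if underpowered:
        cache: dict[int, bool] = {}
        flags = []
        for row in df.itertuples(index=False):
            key = row.bulk_count
            if key not in cache:
                cache[key] = flag_underpowered(row.bulk_count, row.bulk_total, row.obs_total)
            flags.append(cache[key])
        df["underpowered"] = flags
    else:
        df["underpowered"] = False
    return df[BIAS_COLUMNS]


def dipeptide_bias(
    records: Iterable,
    n_N: int = 20,
    n_C: int = 20,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Bias of the terminal residue pair (-2,-1) against bulk dipeptides.

    Bulk dipeptide counts use all overlapping windows within the bulk
    region.  Output columns follow :data:`BIAS_COLUMNS` with position
    labelled ``-1`` (the pair's right edge).
    """
    usable = _terminal_symbols(records, "aa", [-2, -1], n_N, n_C)
    if not usable:
        raise ValueError("no records long enough for region partition")
    bulk_counter: Counter = Counter()
    term_counter: Counter = Counter()
    for rec in usable:
        seq = _aa_seq(rec)
        bulk = seq[n_N : len(seq) - n_C]
        bulk_counter.update(bulk[i : i + 2] for i in range(len(bulk) - 1))
        term_counter[seq[-2:]] += 1
    bulk_total = sum(bulk_counter.values())
    obs_total = len(usable)
    symbols = sorted(set(bulk_counter) | set(term_counter))
    rows = []
    for sym in symbols:
        a = term_counter.get(sym, 0)
        c = bulk_counter.get(sym, 0)
        b, d = obs_total - a, bulk_total - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "symbol": sym,
                "position": -1,
                "obs_count": a,
                "obs_total": obs_total,
                "bulk_count": c,
                "bulk_total": bulk_total,
                "odds_ratio": sample_odds_ratio(a, b, c, d),
                "p_value": p,
            }
        )
    df = _bh(pd.DataFrame(rows), fdr)
    df["underpowered"] = False
    return df[BIAS_COLUMNS]


def pair_epistasis(records: Iterable, fdr: float = 0.05) -> pd.DataFrame:
    """Deviation of terminal pair frequencies from positional independence.

    The null frequency of pair (a, b) at positions (-2, -1) is the product
    of the marginal frequencies of a at -2 and b at -1, recomputed from the
    same sequence set.  Deviations are tested with the exact two-sided
    binomial test (minimum-likelihood definition) and BH-corrected.
    """
    seqs = [s for s in (_aa_seq(r) for r in records) if len(s) >= 2]
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    f2 = Counter(s[-2] for s in seqs)
    f1 = Counter(s[-1] for s in seqs)
    pairs = Counter(s[-2:] for s in seqs)
    rows = []
    for a2, c2 in sorted(f2.items()):
        for a1, c1 in sorted(f1.items()):
            expected = (c2 / n) * (c1 / n)
            obs = pairs.get(a2 + a1, 0)
            if expected == 0:
                if obs > 0:
                    logger.warning("pair %s%s observed with zero expectation", a2, a1)
                    rows.append(
                        {"pair": a2 + a1, "obs_count": obs, "n_sequences": n,
                         "expected_freq": 0.0, "ratio": math.inf,
                         "odds_ratio": math.inf, "p_value": 0.0}
                    )
                continue
            p = stats.binomtest(obs, n, expected, alternative="two-sided").pvalue
            exp_count = n * expected
            ratio = (obs / n) / expected
            odds = sample_odds_ratio(obs, n - obs, exp_count, n - exp_count)
            rows.append(
                {
                    "pair": a2 + a1,
                    "obs_count": obs,
                    "n_sequences": n,
                    "expected_freq": expected,
                    "ratio": ratio,
                    "odds_ratio": odds,
                    "p_value": p,
                }
            )
    return _bh(pd.DataFrame(rows), fdr)


def stratified_bias(
    records: Iterable,
    grouping: Mapping[str, str],
    alphabet: str = "aa",
    positions: Sequence[int] | None = None,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Bias tables per group, each against the group's own bulk composition.

    ``grouping`` maps protein_id -> label; unlabeled records are ignored
    (count logged).  BH correction is applied within each group's table.
    """
    groups: dict[str, list] = {}
    n_unlabeled = 0
    for rec in records:
        label = grouping.get(rec.protein_id)
        if label is None:
            n_unlabeled += 1
            continue
        groups.setdefault(label, []).append(rec)
    if n_unlabeled:
        logger.info("stratified_bias ignored %d unlabeled records", n_unlabeled)
    return {
        label: position_bias(recs, alphabet=alphabet, positions=positions, **kwargs)
        for label, recs in sorted(groups.items())
    }


def abundance_bins(
    records: Iterable,
    ppm: Mapping[str, float | Sequence[float]],
    coverage_min: float = 0.40,
    bins: tuple[float, float] = (0.20, 0.80),
) -> dict[str, str]:
    """Label proteins low/medium/high abundance by within-species ppm percentile.

    Species (genome_id) where fewer than ``coverage_min`` of proteins have
    an abundance value are excluded entirely.  Multiple ppm values for one
    protein are averaged.  Default bins: low = 0-20th percentile, medium =
    20-80th, high = 80-100th.
    """
    by_species: dict[str, list] = {}
    for rec in records:
        by_species.setdefault(rec.genome_id, []).append(rec)

    def mean_ppm(pid: str) -> float | None:
        val = ppm.get(pid)
        if val is None:
            return None
        if isinstance(val, (list, tuple, np.ndarray)):
            return float(np.mean(val))
        return float(val)

    labels: dict[str, str] = {}
    for species, recs in by_species.items():
        values = {r.protein_id: mean_ppm(r.protein_id) for r in recs}
        covered = {pid: v for pid, v in values.items() if v is not None}
        coverage = len(covered) / len(recs)
        if coverage < coverage_min:
            logger.info("species %s excluded: coverage %.2f", species, coverage)
            continue
        vals = np.array(list(covered.values()))
        lo = np.quantile(vals, bins[0])
        hi = np.quantile(vals, bins[1])
        for pid, v in covered.items():
            if v <= lo:
                labels[pid] = "low"
            elif v >= hi:
                labels[pid] = "high"
            else:
                labels[pid] = "medium"
    return labels


def stop_context_bias(
    records: Iterable,
    exclude_overlap: bool = False,
    overlap_flags: Mapping[str, bool] | None = None,
    positions: Sequence[int] = (-1,),
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Codon bias tables at the terminal positions, stratified by stop codon.

    With ``exclude_overlap``, TGA-context genes flagged as having a
    downstream start codon overlapping their stop (AUGA 4-nt overlap) are
    removed before computing the TGA-class table; this isolates codon
    preferences not attributable to overlapping start codons.
    """
    classes: dict[str, list] = {}
    for rec in records:
        if exclude_overlap and rec.stop_codon == "TGA":
            if overlap_flags is None:
                raise ValueError("exclude_overlap requires overlap_flags")
            if overlap_flags.get(rec.protein_id, False):
                continue
        classes.setdefault(rec.stop_codon, []).append(rec)
    return {
        stop: position_bias(recs, alphabet="codon", positions=list(positions), **kwargs)
        for stop, recs in sorted(classes.items())
        if recs
    }


def third_base_comparison(bias_table: pd.DataFrame) -> dict:
    """Contrast log2 odds ratios of codons by third base (NNA vs others/NNG).

    Operates on a codon-level bias table; codons with non-finite odds
    ratios are dropped.  Returns mean log2(OR) per third base and two-sided
    independent t-test results for NNA-vs-others and NNA-vs-NNG.
    """
    df = bias_table[np.isfinite(bias_table["odds_ratio"]) & (bias_table["odds_ratio"] > 0)]
    log2or = np.log2(df["odds_ratio"].to_numpy())
    third = df["symbol"].str[-1].to_numpy()
    means = {
        base: float(log2or[third == base].mean()) if (third == base).any() else math.nan
        for base in "ACGT"
    }

    def contrast(mask_a, mask_b):
        a, b = log2or[mask_a], log2or[mask_b]
        if len(a) < 2 or len(b) < 2:
            return {"t": math.nan, "p": math.nan, "n_a": len(a), "n_b": len(b)}
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0, "n_a": len(a), "n_b": len(b)}
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return {"t": float(t), "p": float(p), "n_a": len(a), "n_b": len(b)}

    return {
        "mean_log2_or": means,
        "nna_vs_others": contrast(third == "A", third != "A"),
        "nna_vs_nng": contrast(third == "A", third == "G"),
    }
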