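"""Position-resolved amino-acid substitution rates from 3-taxon parsimony.

Given alignments of orthologous proteins from triplets of closely related
genomes — two ingroup species and one outgroup — the ancestral state at each
column is inferred by parsimony: a column is informative only when the
outgroup agrees with at least one ingroup member and at most one change is
implied.  Substitution events are tallied per position measured from the
C-terminal end of the alignment (last column = -1), and rates between
amino-acid groups are compared across positions with Fisher exact tests.

Triplets themselves are chosen from a synonymous-distance (dS) table: the
ingroup pair should be close enough to avoid mutational saturation but
divergent enough to carry substitutions (dS in [0.2, 1.0], preferring 0.2),
with an outgroup 1.2-2x (ideally 1.5x) more distant.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from scipy import stats

from .bias import AMINO_ACIDS, sample_odds_ratio

logger = logging.getLogger(__name__)

#: Amino-acid groups used for rate aggregation: positively charged,
#: hydrophobic, threonine alone, and all remaining residues.
DEFAULT_GROUPS: dict[str, frozenset[str]] = {
    "positive": frozenset("KR"),
    "hydrophobic": frozenset("AILMFWYV"),
    "T": frozenset("T"),
    "other": frozenset("HDENQSPCG"),
}

GAP = "-"
BULK = "bulk"


@dataclass
class TripletAlignment:
    """Aligned protein sequences of (ingroup1, ingroup2, outgroup)."""

    orthogroup_id: str
    seq_in1: str
    seq_in2: str
    seq_out: str
    species: tuple[str, str, str] = ("in1", "in2", "out")

    def __post_init__(self) -> None:
        if not (len(self.seq_in1) == len(self.seq_in2) == len(self.seq_out)):
            raise ValueError(f"{self.orthogroup_id}: unequal alignment lengths")

    def __len__(self) -> int:
        return len(self.seq_in1)

    def column(self, i: int) -> tuple[str, str, str]:
        return (self.seq_in1[i], self.seq_in2[i], self.seq_out[i])


class TripletSelection(NamedTuple):
    """One candidate (ingroup pair, outgroup) triplet with its dS distances."""

    in1: str
    in2: str
    outgroup: str
    ds_in: float
    ds_out1: float
    ds_out2: float
    accepted: bool


def triplet_acceptable(
    ds_in: float,
    ds_out1: float,
    ds_out2: float,
    ds_range: tuple[float, float] = (0.2, 1.0),
    out_factor: tuple[float, float] = (1.2, 2.0),
) -> bool:
    """Acceptance rule: ingroup dS in range, both outgroup distances 1.2-2x it."""
    lo, hi = ds_range
    if not lo <= ds_in <= hi:
        return False
    return all(
        out_factor[0] * ds_in <= d <= out_factor[1] * ds_in for d in (ds_out1, ds_out2)
    )


def _distance_lookup(distances) -> tuple[list[str], Mapping[tuple[str, str], float]]:
    """Normalize a dS table (long DataFrame or dict) to a symmetric lookup."""
    lookup: dict[tuple[str, str], float] = {}
    species: set[str] = set()
    if isinstance(distances, pd.DataFrame):
        items = (
            (str(r.species_a), str(r.species_b), float(r.dS))
            for r in distances.itertuples(index=False)
        )
    else:
        items = ((a, b, float(d)) for (a, b), d in distances.items())
    for a, b, d in items:
        if d < 0:
            raise ValueError("negative dS")
        lookup[(a, b)] = d
        lookup[(b, a)] = d
        species.update((a, b))
    return sorted(species), lookup


def select_triplets(
    distances,
    ds_range: tuple[float, float] = (0.2, 1.0),
    out_factor: tuple[float, float] = (1.2, 2.0),
    out_target: float = 1.5,
) -> list[TripletSelection]:
    """Rank all acceptable (pair, outgroup) triplets in one genome cluster.

    Pairs are ranked by |dS - ds_range[0]| ascending (closest to 0.2 first);
    within a pair the outgroup whose distances are closest to ``out_target``
    times the ingroup dS is preferred.  The first element is the cluster's
    selected triplet; callers wanting one triplet per cluster take it.

    ``distances`` is either a long DataFrame (species_a, species_b, dS) or a
    mapping {(a, b): dS}; symmetry is implied.
    """
    species, lookup = _distance_lookup(distances)
    candidates: list[tuple[float, float, TripletSelection]] = []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            ds_in = lookup.get((a, b))
            if ds_in is None:
                continue
            for out in species:
                if out in (a, b):
                    continue
                d1, d2 = lookup.get((a, out)), lookup.get((b, out))
                if d1 is None or d2 is None:
                    continue
                if not triplet_acceptable(ds_in, d1, d2, ds_range, out_factor):
                    continue
                pair_score = abs(ds_in - ds_range[0])
                out_score = abs(d1 - out_target * ds_in) + abs(d2 - out_target * ds_in)
                sel = TripletSelection(a, b, out, ds_in, d1, d2, True)
                candidates.append((pair_score, out_score, sel))
    candidates.sort(key=lambda t: (t[0], t[1], t[2].in1, t[2].in2, t[2].outgroup))
    if not candidates:
        logger.info("no valid triplet in distance table")
    return [sel for _, _, sel in candidates]


def filter_alignment(aln: TripletAlignment) -> bool:
    """True iff the last 3 alignment columns contain no gap in any sequence.

    This excludes orthogroups with length-variable C-termini (stop-codon
    gain/loss events); internal gaps at deeper positions are allowed.
    """
    tail = aln.seq_in1[-3:] + aln.seq_in2[-3:] + aln.seq_out[-3:]
    return GAP not in tail and len(aln) >= 3


class AncestralCall(NamedTuple):
    """Parsimony call for one ungapped column: ancestral state and the event."""

    state: str
    substitution: tuple[str, str] | None  # (ancestral, derived)
    branch: int | None  # 1 or 2 (ingroup branch carrying the change)


def infer_ancestral(column: tuple[str, str, str]) -> AncestralCall | None:
    """3-taxon parsimony on tree ((in1, in2), out); None when ambiguous.

    Informative patterns: (A,A,A) — no change; (A,B,A) — A->B on the in2
    branch; (B,A,A) — A->B on the in1 branch.  Columns where the outgroup
    differs from both ingroup states (including in1 == in2 != out, a change
    on the stem with ambiguous direction, and three-state columns) are
    excluded, matching the rule that the outgroup must agree with one
    ingroup member and at most one ingroup change is implied.
    """
    a, b, out = column
    if a == b == out:
        return AncestralCall(state=out, substitution=None, branch=None)
    if a == out and b != out:
        return AncestralCall(state=out, substitution=(out, b), branch=2)
    if b == out and a != out:
        return AncestralCall(state=out, substitution=(out, a), branch=1)
    return None


class SubstitutionCounts:
    """Ancestral-site and substitution tallies per C-terminal position.

    ``n_sites[pos][i]`` counts informative columns with ancestral amino
    acid ``i`` at position ``pos`` (-1 = last column, ..., ``bulk`` pools
    everything beyond ``-max_pos``); ``n_subs[pos][i][j]`` counts inferred
    i -> j events.  The per-cell substitution rate is
    ``q_ij(pos) = n_subs[pos][i][j] / n_sites[pos][i]``.
    """

    def __init__(self, max_pos: int = 20):
        self.max_pos = max_pos
        positions = [-(k + 1) for k in range(max_pos)] + [BULK]
        self.n_sites: dict = {p: Counter() for p in positions}
        self.n_subs: dict = {p: {} for p in positions}

    @property
    def positions(self) -> list:
        return list(self.n_sites)

    def add(self, pos, ancestral: str, derived: str | None) -> None:
        self.n_sites[pos][ancestral] += 1
        if derived is not None:
            self.n_subs[pos].setdefault(ancestral, Counter())[derived] += 1

    def sites(self, pos, group: Iterable[str] | None = None) -> int:
        counter = self.n_sites[pos]
        if group is None:
            return sum(counter.values())
        return sum(counter[aa] for aa in group)

    def subs(
        self, pos, group_from: Iterable[str] | None = None,
        group_to: Iterable[str] | None = None,
    ) -> int:
        total = 0
        for i, targets in self.n_subs[pos].items():
            if group_from is not None and i not in group_from:
                continue
            for j, n in targets.items():
                if group_to is not None and j not in group_to:
                    continue
                total += n
        return total

    def rate(self, pos, group_from=None, group_to=None) -> float:
        denom = self.sites(pos, group_from)
        if denom == 0:
            return float("nan")
        return self.subs(pos, group_from, group_to) / denom


def count_substitutions(
    alns: Iterable[TripletAlignment], max_pos: int = 20
) -> SubstitutionCounts:
    """Tally parsimony-inferred substitutions per position from the C-terminus.

    Alignments must pass :func:`filter_alignment`.  Position is the column
    offset from the final column (last = -1); columns deeper than
    ``-max_pos`` are pooled into the ``bulk`` bin.  Gapped columns and
    parsimony-ambiguous columns are skipped.
    """
    counts = SubstitutionCounts(max_pos=max_pos)
    for aln in alns:
        length = len(aln)
        for i in range(length):
            col = aln.column(i)
            if GAP in col:
                continue
            call = infer_ancestral(col)
            if call is None:
                continue
            offset = i - length  # -1 for the last column
            pos = offset if offset >= -max_pos else BULK
            derived = call.substitution[1] if call.substitution else None
            counts.add(pos, call.state, derived)
    return counts


def group_rates(
    counts: SubstitutionCounts,
    groups: Mapping[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Substitution rates between amino-acid groups, per position.

    For ordered group pair (G, H), the rate at position x is the number of
    i -> j events with i in G, j in H (i != j) divided by the number of
    ancestral-state sites with i in G.  All ordered pairs, including
    within-group, are reported.  ``groups`` must partition the 20-letter
    alphabet.
    """
    if groups is None:
        groups = DEFAULT_GROUPS
    union = set().union(*groups.values())
    if union != set(AMINO_ACIDS) or sum(len(g) for g in groups.values()) != 20:
        raise ValueError("groups must partition the 20 amino acids")
    rows = []
    for pos in counts.positions:
        for gname, g in groups.items():
            denom = counts.sites(pos, g)
            for hname, h in groups.items():
                n_sub = counts.subs(pos, g, h)
                rows.append(
                    {
                        "position": pos,
                        "group_from": gname,
                        "group_to": hname,
                        "n_subs": n_sub,
                        "n_sites": denom,
                        "rate": n_sub / denom if denom > 0 else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def compare_positions(
    counts: SubstitutionCounts,
    pos_a=-1,
    pos_b=-2,
    group_from: Iterable[str] | None = None,
    group_to: Iterable[str] | None = None,
) -> dict:
    """Fisher test of the substitution rate difference between two positions.

    The 2x2 table is [[subs_a, sites_a - subs_a], [subs_b, sites_b -
    subs_b]]; the reported ratio is q(pos_a) / q(pos_b).
    """
    sites_a = counts.sites(pos_a, group_from)
    sites_b = counts.sites(pos_b, group_from)
    if sites_a == 0 or sites_b == 0:
        raise ValueError("zero ancestral-site denominator")
    subs_a = counts.subs(pos_a, group_from, group_to)
    subs_b = counts.subs(pos_b, group_from, group_to)
    table = [[subs_a, sites_a - subs_a], [subs_b, sites_b - subs_b]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    rate_a = subs_a / sites_a
    rate_b = subs_b / sites_b
    if rate_b > 0:
        ratio = rate_a / rate_b
    else:
        ratio = float("nan") if rate_a == 0 else float("inf")
    return {
        "ratio": ratio,
        "p": p,
        "rate_a": rate_a,
        "rate_b": rate_b,
        "table": table,
        "odds_ratio": sample_odds_ratio(*table[0], *table[1]),
    }


def load_triplet_alignments(
    alignment_dir: str | Path, manifest: str | Path
) -> list[TripletAlignment]:
    """Read aligned FASTA triplets listed in a manifest TSV.

    The manifest has columns orthogroup_id, fasta, in1, in2, out; each
    FASTA holds exactly the three named records.
    """
    from Bio import SeqIO

    alignment_dir = Path(alignment_dir)
    rows = pd.read_csv(manifest, sep="\t")
    alns = []
    for row in rows.itertuples(index=False):
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(alignment_dir / row.fasta), "fasta")}
        alns.append(
            TripletAlignment(
                orthogroup_id=str(row.orthogroup_id),
                seq_in1=seqs[row.in1],
                seq_in2=seqs[row.in2],
                seq_out=seqs[row.out],
                species=(str(row.in1), str(row.in2), str(row.out)),
            )
        )
    return alns
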