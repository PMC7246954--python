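# termbias

Analysis toolkit for the composition and consequences of protein
**C-terminal sequences in bacteria**: position-specific amino-acid and
codon biases across proteomes, substitution rates at terminal positions
from 3-taxon parsimony, expression effects of the last two codons measured
by a methylation-reporter assay (ELM-seq), and protein degradation kinetics
from reporter shut-off time courses.

## Who this is for

Computational biologists asking whether the last residues of proteins are
under selection and why: the last amino acid sits at the interface of
translation termination and protein degradation, and its identity turns
out to shift protein abundance severalfold.  The package provides the
statistics for each layer of that question, plus synthetic-data generators
with known ground truth so every estimator can be validated end to end.

## The statistics at the core

- **Terminal bias.** For residue (or codon) *X* at position *j* ∈ [-20, -1],
  compare terminal counts with pooled *bulk* counts (sequence middles,
  first/last 20 residues excluded) in a 2×2 table: two-sided Fisher exact
  test, sample odds ratio, Benjamini–Hochberg FDR at 5% within each table,
  and an *underpowered* flag for cells that could never reach significance
  at a 2-fold depletion.
- **Pair epistasis (genomic).** Terminal pair frequency vs the product of
  the positional marginals, exact two-sided binomial test.
- **Substitution rates.** From triplets of closely related genomes
  (ingroup pair with dS in [0.2, 1.0], outgroup 1.2–2× more distant),
  parsimony ancestral states give position-resolved rates
  q_ij(x) = n_subs(i→j, x) / n_sites(i, x), compared between positions by
  Fisher exact test, with amino acids grouped into positive {K,R},
  hydrophobic {A,I,L,M,F,W,Y,V}, {T}, and others.
- **ELM-seq DAMratio.** Per variant, the DpnI read share over the MboI
  read share (depth-invariant), normalized to the geometric mean:
  relative expression *R*.  Effects are geometric means of *R* per symbol;
  pair cooperativity is Q = R(pair) / (R(aa₋₂)·R(aa₋₁)), i.e.
  log₁₀Q = log₁₀R(pair) − log₁₀R(aa₋₂) − log₁₀R(aa₋₁).
- **Degradation kinetics.** d from OLS of ln L(t)/L(0) over 2–8 h,
  half-life ln 2/d, and the steady-state balance X = s/d tested by
  regressing X on 1/d.

## Worked example

Each script in `examples/` builds a small synthetic input, runs one
capability, and explains its output.  For instance:

```bash
$ python examples/01_terminal_bias.py
symbol  obs_count  obs_total  odds_ratio       q_value  significant
     K       2056      20000    2.313774 6.283510e-226         True
     L       1966      20000    0.927061  9.448267e-03         True
     M        489      20000    0.904949  7.512341e-02        False
     R       1043      20000    0.949324  1.642251e-01        False
     T        960      20000    0.884290  1.738026e-03         True

Injected lysine multiplier 2.32 at position -1; recovered odds ratio 2.31
(q = 6.28e-226).
```

The generator made lysine 2.32× more likely at the last position of 20,000
proteins; the bias table recovers that as a terminal-vs-bulk odds ratio of
2.31 with an overwhelming BH-corrected q-value, while unmanipulated
residues stay near 1.  The other examples cover stop-codon context and
the overlapping-start-codon artifact (`02`), parsimony substitution rates
(`03`), ELM-seq effects and epistasis (`04`), and decay kinetics with the
X = s/d regression (`05`).

A thin CLI wraps the same functions for shell pipelines
(`termbias ingest|bias|epistasis|stopcontext|evo|elmseq|decay|simulate`);
see `termbias --help`.

## Layout

```
src/termbias/
  proteome.py    ingestion, validation, dedup clustering, overlap flags
  bias.py        terminal bias tables, epistasis, stratified analyses
  evolution.py   triplet selection, parsimony, group substitution rates
  elmseq.py      read filtering, DAMratio, effect aggregation, Q
  kinetics.py    decay fits, half-lives, X = s/d regression
  simulate.py    ground-truth generators for all of the above
  cli.py         thin command-line wrapper
docs/methods.md  model assumptions, parameter choices, limitations
examples/        one narrative script per capability
tests/           pytest suite with independent enumeration/DP oracles
```
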