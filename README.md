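# modscan

Genome-wide screening for **key modulator genes** — genes whose expression
level conditions (strengthens or weakens) the correlation between other gene
pairs — from a gene expression matrix.

Classical co-expression analysis asks whether two genes are correlated.
Modulated interaction analysis asks a higher-order question: does that
correlation *depend on* a third gene?  In breast tumors the estrogen receptor
gene *ESR1* is the archetype — whole blocks of the co-expression network
rewire between ER-high and ER-low tumors.  `modscan` screens **every** gene
for this behavior and builds the per-modulator "modulated interaction
network" of pairs whose correlation changes with it.

## Method

For each candidate modulator *m* in an expression matrix
**E** = {e<sub>g,n</sub>}<sub>G×N</sub>, samples are sorted by *m*'s
expression and the top/bottom 25% form the *m*-on / *m*-off groups (size
*k* = ⌊N/4⌋).  In each group the gene-gene Pearson correlation matrix
**C**<sub>M</sub> is mapped to the standard-normal domain by a scaled Fisher
transform

&nbsp;&nbsp;&nbsp;&nbsp;I<sub>M</sub>(i,j) = √(k−3) · atanh C<sub>M</sub>(i,j),

so that under a fixed population correlation each I<sub>M</sub> has
approximately unit variance.  Four **modularity parameters** quantify how
much *m* reshapes the network:

1. **ACI score** — mean over all unordered pairs of
   ΔI = | |I<sub>on</sub>| − |I<sub>off</sub>| |, the genome-wide average
   change in interaction strength;
2. **number of nodes**, 3. **number of edges**, 4. **connectivity**
   (average node degree, 2E/V) of the *core modulated network*: the pairs
   with a significant correlation change (MAGIC p-value, a two-sample
   Fisher-z test with I<sub>on</sub> − I<sub>off</sub> ~ N(0, 2) under the
   null) **and** a material effect size (MAGIC score: the absolute change in
   correlations projected back to an assigned sample size N′ by the inverse
   transform).

Each parameter is tested against a null distribution built from random
sample partitions (default 10,000), with add-one empirical p-values
p = (1 + #{null ≥ observed}) / (1 + n_perm).  Genes significant in **all
four** parameters (empirical p < 10⁻⁴ at default settings) are **key
modulators**, ranked by the average z-value of the four parameters.

A synthetic-data module generates matrices with *planted* modulators —
target pairs with stated conditional correlations per expression stratum —
so every stage of the screen can be validated against known ground truth.

## Worked example

Plant one modulator (`MOD1`) controlling 30 gene pairs (conditional
correlation 0.7 when MOD1 is high, 0.0 when low) among 120 genes and 340
samples, then screen every gene:

```python
from modscan import ScreenConfig, run_screen, modulated_network
from modscan.synthdata import benchmark_spec, generate

spec = benchmark_spec(n_genes=120, n_samples=340, n_pairs=30, seed=11)
E, truth, _ = generate(spec)
cfg = ScreenConfig(n_perm=500, seed=1, empirical_cutoff=2e-3)
result = run_screen(E, cfg)
print("key modulators:", result.key_modulators)
print(result.ranked.head(3)[["gene", "rank", "aci", "n_nodes", "n_edges",
                             "connectivity", "avg_z"]].round(3).to_string(index=False))
net = modulated_network(E, "MOD1", cfg)
called = {tuple(sorted(e.pair)) for e in net.edges}
planted = {tuple(sorted(p)) for p in zip(truth.gene_i, truth.gene_j)}
print(f"edge recall: {len(called & planted) / len(planted):.2f}")
```

prints

```
key modulators: ['MOD1']
 gene  rank   aci  n_nodes  n_edges  connectivity  avg_z
 MOD1     1 0.689       30       27         1.800  6.612
T0018     2 0.675        3        2         1.333  1.116
T0020     3 0.674        4        2         1.000  1.029
edge recall: 0.90
```

The planted gene is the only one significant in all four parameters: its
modulated network recovers 27 of the 30 planted pairs (two false pairs give
other genes an edge or two, far below significance), its ACI score stands
above the genome background, and it ranks first by average z.  The
empirical cutoff 2×10⁻³ at 500 permutations accepts exactly the genes whose
observed parameters exceed every null value — the analogue of 10⁻⁴ at
10,000 permutations.

The same workflow from the shell:

```bash
modscan simulate --spec spec.yaml --out sim/
modscan screen --expr sim/expression.tsv --out screen/ --n-perm 10000 --seed 1
modscan network --expr sim/expression.tsv --modulator MOD1 --out net/   # SIF + GraphML
modscan status --expr sim/expression.tsv --modulators screen/key_modulators.tsv
```

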