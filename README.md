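# shmindel

Probabilistic statistics of somatic-hypermutation-induced insertions and
deletions (indels) in antibody heavy-chain V segments.

## The problem

During affinity maturation, B cells diversify their immunoglobulin genes
through somatic hypermutation (SHM): mostly point substitutions, but also
rare insertions and deletions. Indel statistics — their rate relative to
point mutations, their length law, their positions — constrain the
molecular mechanism (e.g. polymerase slippage predicts duplicated
inserts, a geometric length law suggests processive slipping with random
stopping). The standard way to measure them is to align each read to its
germline V template and keep the single best-scoring alignment. That
deterministic annotation is biased: it merges nearby indel events into
one long one, fabricates long-event tails, and labels every mutation-free
read as "naive" even though an experienced cell can escape mutation by
chance.

`shmindel` removes these biases by treating annotation probabilistically.
For a read `s` and template `t` the likelihood sums over *all* mutation
scenarios,

    S(s,t | mu; phi) = sum over alignments of
        prod M(s_i, t_j) * prod Gamma_del(l) * prod Gamma_ins(l),

computed by a forward recursion (a pair-HMM-style sum instead of the
Needleman-Wunsch max). Each sequence carries a hidden *maturation age*
`mu` — its point-mutation rate per bp — with repertoire prior
`P(mu) = f delta(mu) + (1-f) Ptilde(mu)`; indel event rates are
`mu*beta_del` and `mu*beta_ins`, with length laws `P_del`, `P_ins`
truncated at `theta_max`. The full parameter set
`theta = (f, Ptilde, beta_del, beta_ins, P_del, P_ins)` is learned by
maximum likelihood: exact EM for the age prior, projected momentum
gradient ascent (finite-difference gradients, one Monte-Carlo age sample
per read per iteration) for the indel parameters, with the alignment
matrix pruned to cells the alignment plausibly passes through.

The package also ships the deterministic baseline (affine-gap NW with
log-odds penalties derived from average mutation statistics), a
synthetic-repertoire generator with ground truth, and the descriptive
statistics used to characterize indels (count distributions, length
profiles, flank overlaps, inter-deletion distances, positional profiles,
co-localization ratios).

## Worked example

```python
import numpy as np
from shmindel import (RepertoireModel, OptimizerConfig,
                      benchmark_model, generate_repertoire, random_templates)

# synthetic benchmark repertoire: 10% naive cells, experienced ages from a
# shifted Gamma (mode 0.05), beta_del = beta_ins = 0.025, geometric indel
# lengths (scale 15 bp, cutoff 30 bp)
templates = random_templates(8, 300, seed=7)
rep = generate_repertoire(templates, benchmark_model(), n=500, seed=11)

rm = RepertoireModel(rep.reads, templates, theta_max=40)
res = rm.fit(config=OptimizerConfig(T=40, seed=5))
print(res.summary())
```

```
SHM-indel repertoire fit
========================
reads: 500   templates: 8   theta_max: 40
iterations: 40   converged: False   log-likelihood: -40414.095

parameter                      probabilistic   deterministic
naive fraction f                      0.1060          0.1080
beta_del                              0.0225          0.0232
beta_ins                              0.0248          0.0254
mean mu (experienced)                 0.0708          0.0703
mean deletion length                   10.82           11.48
mean insertion length                  11.18           11.73
```

Reading the table: the fitted naive fraction (true value 0.10) sits
*below* the deterministic estimate — the deterministic method must call
every mutation-free read naive, while the probabilistic fit splits those
reads between "naive" and "experienced but unmutated, probability
`~exp(-L*mu)`". The rescaled indel rates (events per point mutation per
bp; truth 0.025) and the mean event lengths (truth 11.4 bp for the
geometric-15 law truncated at 30) agree between the two methods at this
low indel density, as they should. At 500 reads the naive
fraction carries a sampling error of ~1.5 percentage points; the
acceptance benchmark below uses 4,000 reads.

`res.params` is the fitted `IndelModel` (JSON-serializable with
`shmindel.save_model`), `res.trajectory` the per-iteration log-likelihood
and parameters, and `res.simulate(n, seed)` generates from the fitted
model. The same workflow is available from a shell:

```sh
shmindel generate --templates t.fasta --model m.json --n 2000 --seed 1 --out rep
shmindel infer    --reads rep_reads.fasta --templates t.fasta --seed 1 \
                  --theta-max 60 --out fitted.json
shmindel evaluate --reads rep_reads.fasta --templates t.fasta \
                  --model fitted.json --out lik.tsv
shmindel annotate --reads rep_reads.fasta --templates t.fasta --out ann.tsv
shmindel stats    --annotations rep_truth.json --reads rep_reads.fasta \
                  --templates t.fasta --out stats/
```

See `docs/methods.md` for the model's assumptions, the optimizer's
defaults and the numerical choices.

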