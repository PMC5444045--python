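# layerprop

Graph-based semi-supervised learning on **multi-layered biomedical networks**
— label propagation through a block tri-diagonal weight matrix whose
intra-layer and inter-layer parts carry separate smoothness penalties, with
an exact solver and a Nyström + Woodbury fast solver — applied to **disease
co-occurrence (comorbidity) prediction** on two-layer symptom–disease
networks.

Biological and clinical data stratify naturally into layers (proteins,
diseases, symptoms, ...). Within a layer, nodes are linked by similarity;
between adjacent layers, by association. `layerprop` is for anyone who wants
to score unlabeled nodes from a few labeled ones while letting information
flow both within and across layers — here, ranking candidate comorbid
diseases for a target disease by exploiting the symptoms they share.

## The model

A K-layer network with `n_k` nodes per layer has an `N × N` block
tri-diagonal weight matrix `W` (`N = Σ n_k`): `K` symmetric diagonal blocks
of intra-layer similarities and `2K − 2` banded rectangular blocks of
inter-layer links. Matrix separation writes `W = W_intra + W_inter`, each
part with its own unnormalized graph Laplacian `L = D − W`. Given labels
`Y` (0 for unlabeled nodes), the score vector `f` minimizes

```
Σ_i (f_i − Y_i)²  +  μ_a f' L_intra f  +  μ_b f' L_inter f
```

whose closed-form solution is

```
f = (I + μ_a L_intra + μ_b L_inter)⁻¹ Y .
```

With `μ_b = 0` this decouples into independent single-layer problems
`f = (I + μL)⁻¹ Y` per layer. The direct solver factorizes the
positive-definite system (Cholesky); the fast solver replaces `L_inter` by
its Nyström approximation `C Q⁺ C'` from `r` sampled columns and applies the
Woodbury identity, so only the per-layer blocks of `A = I + μ_a L_intra` and
one `r × r` system are ever inverted — `O(max_k n_k³ + rN²)` instead of
`O(N³)`.

Intra-layer similarity blocks come from binary feature profiles through the
Tanimoto kernel `s(x, y) = x·y / (‖x‖² + ‖y‖² − x·y)` (diseases sharing
proteins; symptoms sharing diseases).

## Worked example

`examples/03_cooccurrence_experiment.py` generates the default synthetic
two-layer network (200 diseases in 20 planted co-occurrence modules, 60
symptoms, Tanimoto disease similarities from protein bit profiles, binary
disease–symptom links) and runs the leave-one-target-out scoring sweep:
label one target disease and 20% of its known co-occurring partners, label
0–100% of its related symptoms, solve, and measure the AUC of ranking the
remaining diseases against the co-occurrence truth:

```
network: 200 diseases, 60 symptoms; 900 planted co-occurring pairs
symptom label fraction -> mean leave-one-target-out AUC
    0%   0.577
   20%   0.642
   40%   0.670
   60%   0.693
   80%   0.705
  100%   0.719
```

0% is the single-layer reference (disease layer alone, no inter-layer
edges); every added symptom label raises the mean AUC — knowing more of a
disease's symptoms improves comorbidity ranking. `examples/04_enrichment.py`
backs this with the shared-symptom enrichment test (paired one-sided t on
the per-disease difference of mean shared-symptom counts, co-occurring vs
non-co-occurring partners): `t = 16.2, p = 1.4e-38, df = 199` on the planted
network versus `p = 0.95` on a null network with no symptom signal.

The other examples show the multi-layer propagation mechanics on a
hand-built network (`01`) and the fast solver's error shrinking with the
Nyström rank down to `2e-15` at full sampling (`02`).

## Command line

```
layerprop simulate --seed 1 --out net/          # synthetic network + truth
layerprop solve --network net/ --labels labels.tsv --mu-a 1 --mu-b 1 --out scores.tsv
layerprop evaluate --network net/ --cooccurrence net/cooccurrence.tsv --out eval/
layerprop enrich --network net/ --cooccurrence net/cooccurrence.tsv --out enrichment.tsv
```

All formats are tab-separated text; every run writes a JSON manifest with
parameters, seeds and input checksums.

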