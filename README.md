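# metaprox

Metabolic proximity analysis of colonization order in layered microbial
biofilms.

Multi-species biofilms such as dental plaque assemble in a repeatable
sequence: early colonizers bind receptor sites on the salivary pellicle
and each later layer binds the one beneath it.  `metaprox` asks whether
the *metabolic enzyme content* of the member species predicts that order.
It is aimed at microbial-ecology and systems-biology researchers who want
to run this analysis on their own communities (any KEGG-style
organism→EC annotation export) or study its statistical behaviour on
synthetic data.

## The quantities it computes

Each organism A is a binary enzyme profile **S**^(A) (presence/absence of
EC numbers).  For a colonization order o₁…oₙ consistent with the layered
model (a concatenation of within-layer permutations; 3!·3!·1!·4! = 864
orders for the packaged 11-species, 4-layer map):

* mean adjacent Jaccard distance
  ⟨J⟩ = (1/(n−1)) Σᵢ J(oᵢ, oᵢ₊₁),  J(A,B) = 1 − |A∩B|/|A∪B|;
* summed added information Σᵢ ΔI(oᵢ, oᵢ₊₁) with
  ΔI(A,B) = Σ_{k: S^(A)_k=0, S^(B)_k=1} −ln P_k (nats), P_k the
  community prevalence of enzyme k — asymmetric, so it scores a
  colonization order differently from its reverse.

These distributions are compared (two-sample Kolmogorov–Smirnov) against
random permutations, random background communities, and enzyme-deletion
perturbations.  Per-layer pathway enrichment uses exact layer carriage
profiles B^(x) and a GSEA-style weighted running sum with an enzyme-label
permutation null and Benjamini–Hochberg FDR.  Finally, an elementary
flux-mode (EFM) analysis measures the *synergy* of paired stoichiometric
networks with a prescribed reaction overlap Jc:
ΔEFM = EFM(1,2)/(EFM(1)+EFM(2)), exactly 1 for disjoint pairs and 0.5
for identical pairs, with a maximum at intermediate overlap.  EFMs are
enumerated exactly (rational double description) and cross-checked
against an independent brute-force enumerator.

## Worked example

Everything runs on synthetic data out of the box (no database access):

```sh
metaprox simulate --outdir demo --seed 1
metaprox score-orders --profiles demo/profiles.tsv --model demo/model.yaml \
    --n-random 100000 --seed 1 --outdir demo/out
```

prints

```
layered orders: 864  KS D=1.0000  p=0
```

The simulated community plants a metabolic gradient across the four
layers of the packaged dental-biofilm map.  All 864 layer-consistent
orders are enumerated and scored; their mean ⟨J⟩ is 0.287 against 0.539
for 100,000 random permutations (the full report, with both
distributions as TSV, lands in `demo/out/`).  The KS statistic D ≈ 1
says the layered orders are almost completely left-shifted: adjacent
organisms in the layered structure share far more enzymes than random
adjacency would give — the planted signal, recovered.

```sh
metaprox synergy --network demo/network.txt --n-pairs 20 --seed 1 --outdir demo/out
```

```
Jc=0.0  mean=1.000 sem=0.000 n=20 skipped=0
Jc=0.2  mean=1.637 sem=0.296 n=20 skipped=0
Jc=0.4  mean=1.249 sem=0.350 n=20 skipped=0
Jc=0.6  mean=0.884 sem=0.151 n=19 skipped=1
Jc=0.8  mean=0.770 sem=0.163 n=19 skipped=1
Jc=1.0  mean=0.500 sem=0.000 n=20 skipped=0
```

Each row is the mean ± SEM synergy score of 20 random network pairs at
that target overlap.  The endpoints are exact identities (1.0 for
disjoint pairs, 0.5 for identical pairs); the peak at Jc = 0.2 — joint
networks with ~33% per-component reaction overlap gaining the most new
flux modes — is the interior "sweet spot" between metabolic redundancy
and incompatibility.

Other subcommands: `null-compare` (community vs random background
groups), `sensitivity` (significance under enzyme removal), `enrich`
(pathway × layer enrichment matrix).  The library API mirrors the CLI;
see `docs/methods.md` for the model, parameters, and numerical choices.

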