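# sucbigram

Prediction of lysine succinylation sites from protein profile bigrams.

Succinylation is a post-translational modification that attaches a
succinyl group to a lysine side chain, flipping its charge and altering
protein function. Experimentally mapping succinylated lysines by mass
spectrometry is slow, so sequence-based predictors are used to triage
candidate sites. `sucbigram` implements a profile-bigram predictor for
bioinformaticians who have, for each protein, a PSI-BLAST
position-specific scoring matrix (PSSM) and per-residue secondary-structure
probabilities (e.g. from SPIDER2), plus a table of annotated lysines.

## Method

Each lysine *K* is described by the segment of 15 residues upstream and
15 downstream (31 residues total); segments that run past a terminus are
completed by mirroring the profile rows about the terminal residue. Over
the windowed profiles *M* (31×20 substitution probabilities) and *N*
(31×3 helix/strand/coil probabilities) the **profile bigram** matrices
are computed:

    B[p,q]  = Σ_{k=1}^{30} M[k,p] · M[k+1,q]      (20×20)
    B'[r,s] = Σ_{k=1}^{30} N[k,r] · N[k+1,s]      (3×3)

Row-major flattening and concatenation give a 409-dimensional feature
vector (400 + 9 transitional probabilities) per lysine, independent of
the window size.

Because non-sites vastly outnumber sites (the curated benchmark has
18,344 negatives to 1,782 positives), the negative class is thinned by
iterative k-NN undersampling: with base threshold
k = ⌊N⁻/N⁺⌋ (= 10 for the benchmark counts), every negative whose k
nearest neighbors (Euclidean, feature space) contain a positive is
removed; k is escalated in integer multiples until negatives no longer
outnumber positives. An AdaBoost.M1 ensemble of decision stumps
(default 1,000 rounds, α = ln((1−ε)/ε)) is then trained, and performance
is reported as sensitivity, specificity, accuracy, Matthews correlation
coefficient and ROC AUC under stratified n-fold cross-validation.

The estimators follow scikit-learn conventions: `StumpBoostClassifier`
(fit / predict / decision_function) and `KnnUndersampler`
(fit / fit_resample) compose with sklearn pipelines and model selection.
A synthetic generator fabricates all four input families with a plantable,
window-local class signal, so the full pipeline is testable without
PSI-BLAST or SPIDER2.

## Worked example

Generate a synthetic benchmark with ~10:1 class imbalance and run the
whole pipeline (featurize → balance → train → evaluate):

```sh
sucbigram synth --n-proteins 320 --seed 3 --imbalance-ratio 10.3 \
    --outdir fixtures/
sucbigram run --fasta fixtures/proteins.fasta --pssm-dir fixtures/pssm \
    --ss-dir fixtures/ss --sites fixtures/sites.tsv \
    --workdir work/ --rounds 100 --seed 1
```

which prints

```
wrote 878 sites (82 positive) to fixtures
done: Sn=1.000 Sp=1.000 Acc=1.000 MCC=1.000 AUC=1.000
```

At the default effect size the planted profile signal separates the
classes completely, so all metrics saturate; `work/manifest.json`
records the per-stage counts (sites in, negatives removed per balancing
round, boosting rounds trained) and the per-fold metric breakdown.
Lowering `--effect-size` when generating produces overlapping classes:
at effect size 0 the balancer removes negatives exactly as on real data
(k = 10 removed 550 of 831 negatives, k = 20 another 247 in one seeded
run) and cross-validated AUC falls to chance.

Individual stages are available as `sucbigram featurize`, `balance`,
`train`, `predict` and `evaluate`; models serialize to plain JSON.

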