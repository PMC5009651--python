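# harman-batch

Confidence-limited removal of batch effects from high-throughput genomic
matrices (microarray, RNA-seq, methylation — any log-scale
feature-by-sample matrix), for analysts who need to remove technical
batch noise while controlling the risk of also removing biological
signal.

## The method

Batch effects are additive on the log scale and shared by every sample
in a processing batch, so on each principal component of the
mean-centred data they appear as an offset of the batch's mean score
away from zero.  Whether an observed batch mean *BM<sub>b</sub>*
reflects batch noise or just small-sample wander is decided against a
combinatorial null: if batch membership carried no signal, a batch
holding *k<sub>α</sub>* of the *n<sub>α</sub>* replicates of each
treatment *α* would be one of
∏<sub>α</sub> C(n<sub>α</sub>, k<sub>α</sub>) equally likely candidate
batches drawn from the observed scores.  The means of those candidate
batches form a finite population — normal by the central limit theorem,
zero-mean by centring — whose standard deviation *σ* gives each batch a
tail probability

&nbsp;&nbsp;&nbsp;&nbsp;z<sub>b</sub> = Φ(−|BM<sub>b</sub>| / σ),&nbsp;&nbsp;&nbsp;&nbsp;z<sub>b</sub> ∈ (0, 0.5],

and the *b* batches combine into a normalized likelihood

&nbsp;&nbsp;&nbsp;&nbsp;L = (2<sup>b−1</sup>/b) Σ<sub>i</sub> ∏<sub>j≠i</sub> z<sub>j</sub>,

which equals 1 when every batch mean is zero.  1 − L is the confidence
that batch noise is present.  Where that confidence exceeds the
user-set **confidence limit**, the component's scores
s<sub>ji</sub> = BM<sub>j</sub> + r<sub>ji</sub> are corrected to
k·BM<sub>j</sub> + r<sub>ji</sub> with the largest k ∈ [0, 1] that
brings the confidence back down to the limit — batch means shrink
toward zero, within-batch geometry is untouched.  Corrected scores are
mapped back through the inverse PCA, yielding a matrix of the original
shape ready for any downstream analysis.

## Worked example

```python
import harman as H

cfg = H.dataset1_shaped(seed=7, p=2000)       # 7 treatments x 4 replicates,
matrix, design, truth = H.generate_study(cfg)  # 4 batches of 7, batch_sd = 0.3
study = H.validate_study(matrix, design)
res = H.harman(study, limit=0.95)
print(res.report_frame().head(4).to_string(index=False))
```

```
 pc_index  var_fraction  confidence_before    k
        1      0.214326           0.999540 0.41
        2      0.206270           0.999833 0.42
        3      0.197089           0.999777 0.42
        4      0.059723           0.999851 0.45
```

The three leading components carry the injected batch offsets (the
batch effect spans b − 1 = 3 dimensions): each is detected with
confidence ≈ 0.9995 and its batch means are compressed to ≈ 0.4 of
their original size, the point where the confidence of a remaining
effect drops to the 0.95 limit.  Evaluating the correction:

```python
H.preserved_variance(matrix, res.corrected_matrix)       # 0.49
H.gpca_pvalue(matrix, design.batch_of, 1000, seed=1)      # delta=1.000 p=0.001
H.gpca_pvalue(res.corrected_matrix, design.batch_of,
              1000, seed=1)                               # delta=0.614 p=0.999
```

The guided-PCA permutation test detects the batch effect decisively
before correction (p = 0.001) and not after (p = 0.999), while the
ANOVA-style partition shows batch-attributable variance falling from
0.0719 to 0.0125 with treatment-attributable variance unchanged at
0.0380 — batches move, samples within them do not.

The same pipeline is available from a shell:

```
harman simulate --config sim.yaml --seed 7 --out-prefix sim
harman correct  --matrix sim_matrix.tsv --design sim_design.tsv \
                --limit 0.95 --out corrected.tsv --report report.tsv
harman evaluate --matrix sim_matrix.tsv --design sim_design.tsv \
                --corrected corrected.tsv --permutations 1000 --seed 1
```

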