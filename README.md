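# eigensteer

Maps complex-trait transcriptomes to candidate causal gene sets:

1. **curation** — filters raw RNA-seq count tables (gene mean > 5, sample
   total > 1e5), normalizes to transcripts-per-million using reference
   transcript lengths (NTPM, each sample sums to 1e6), and stores expression
   as `log10(NTPM + 1e-10) + 10` with one-hot phenotype labels.
2. **cvae** — a label-conditioned variational autoencoder (encoder
   256→128→latent, mirrored sigmoid decoder, linear latent classifier)
   trained with a weighted sum of reconstruction, KL, and classification
   losses (Adam, lr 1e-4). Per-class Gaussian-kernel KDEs (bandwidth 0.2) on
   the latent posterior means generate denoised, balanced expression
   profiles; an AUROC score checks that the generated data retain the
   original differential-expression rankings. Implemented directly on NumPy
   (no deep-learning framework required).
3. **eigengenes** — SVD of the generated expression matrix yields an
   orthonormal gene-space basis; data are projected onto the top-d
   eigengenes (default d=200).
4. **finemap** — ridge logistic regression over eigengenes produces log-odds
   summaries; a Metropolis MCMC over binary inclusion vectors (with a
   sampled scale hyperparameter s) yields posterior inclusion probabilities
   and selects the top-r causal eigengenes.
5. **transitions** — given a perturbation-response library projected into
   causal-eigengene coordinates, solves bounded L1-penalized least-distance
   problems (`min D(u) + λΣu` over `u ∈ [0,1]^P`, L-BFGS-B) to steer
   baseline↔variant transitions; a λ-sweep keeps the sparsest solution with
   R² = 1 − D(u)/D(0) > 0.99 over many sampled state pairs.
6. **coocnet** — scores perturbation co-occurrence among accepted solutions
   against a maximum-entropy bipartite null model with fixed expected
   row/column sums; z-scores above a threshold (QQ-plot guided, default 20)
   define the co-occurrence network.

`eigensteer.syndata` generates all inputs synthetically — planted two-cluster
low-rank expression data, response libraries with feasible steering
solutions, and bipartite occurrence matrices with planted co-occurring
pairs — so the full pipeline runs and is tested without any downloads.

## CLI

Every stage is a subcommand of `eigensteer` (see `--help` on each):

```sh
eigensteer synth --out-dir data --n-genes 200 --n-samples 60 --seed 1
eigensteer curate --counts data/counts.tsv --lengths data/gene_lengths.tsv \
    --labels data/labels.txt --out-prefix run
eigensteer train --expr run.expr.tsv --config cvae.yaml --out-prefix run
eigensteer generate --checkpoint run.ckpt.npz --expr run.expr.tsv \
    --n-per-class 500 --seed 1 --out run.gen.tsv
eigensteer validate --original run.expr.tsv --generated run.gen.tsv --out run.auroc.csv
eigensteer eigengenes --expr run.gen.tsv --d 200 --out-prefix run
eigensteer finemap --projected run.projected.tsv --r 50 --out-prefix run
eigensteer optimize --projected run.projected.tsv --responses B.tsv \
    --meta meta.tsv --n-pairs 2500 --out-prefix run
eigensteer cooccur --a-matrix run.A.tsv --z-threshold 20 --out-prefix run
```

The `train` config is YAML with `CvaeConfig` fields
(`latent_dim`, `hidden_sizes`, `learning_rate`, `epochs`, `batch_size`,
`loss_weights`, `kde_bandwidth`, `recon_loss`, `seed`).

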