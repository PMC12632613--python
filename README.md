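# tlscp — survival-based clustering of predictors with rank transfer

`tlscp` groups the predictors of a Cox proportional hazards model into
clusters with a *shared* regression coefficient. The motivating use case is
annotating rare genetic variants (e.g. germline mutations of a cancer gene)
by their effect on a time-to-event outcome such as age at first diagnosis:
each variant enters the model as one predictor, and variants whose hazard
effects are indistinguishable should receive a common, jointly estimated
coefficient and a common annotation.

## The model

For right-censored data \((y_i, \delta_i, x_i)\), the Cox model assumes
\(h_i(t) = h_0(t)\,e^{x_i^\top\beta}\), estimated through the log partial
likelihood \(\ell(\beta)\) (Breslow convention for ties). Clustering is
obtained by **SCP** (survival-based clustering of predictors), a fusion
penalty on rank-adjacent coefficient differences:

1. fit an unpenalized Cox model to get a preliminary estimate
   \(\tilde\beta\);
2. build the rank map \(\tau\) sorting \(\tilde\beta\) ascending, and the
   fusion matrix \(D_\tau\) whose rows are
   \(e_{\tau(j)} - e_{\tau(j+1)}\);
3. solve \(\min_\beta -\tfrac1n \ell(\beta) + \lambda\,
   P(D_\tau\beta)\).

The workhorse choice of \(P\) is the **distance-to-set penalty**
\(\tfrac12\,\mathrm{dist}(D_\tau\beta,\ C)^2\) with
\(C=\{z : \|z\|_0 \le k\}\); driving \(\lambda\to\infty\) on a geometric
schedule forces at most \(k\) nonzero fused differences, i.e. at most
\(k+1\) coefficient clusters — so the tuning parameter is the integer
cluster budget itself, selected by BIC over \(k\in\{1,\dots,5\}\).
Lasso/SCAD/MCP variants of \(P\) are available as solver options. The
likelihood is handled by iteratively reweighted least squares: each outer
step expands \(\ell\) into working weights \(w_i\) and responses \(z_i\)
and solves a fusion-penalized weighted least squares subproblem.

When the target cohort is small, the preliminary *ranking* is the weak
link. **TL-SCP** borrows it from a larger source cohort under a
ranking-similarity assumption: Cox fits on source and target give rank
vectors \(\tau_S, \tau_T\), merged by weighted rank averaging
(\(\mathrm{score}_j = w_{S}\,\mathrm{rank}_S(j) + w_{T}\,
\mathrm{rank}_T(j)\), weights defaulting to sample-size ratios, or
per-feature carrier-count ratios), and SCP runs on the target with the
merged ordering. Only ranks cross the cohort boundary, so a
summary-level rank vector suffices when source data cannot be shared.

## Worked example

Simulate a small target cohort (n=200, p=90, three true coefficient
clusters at 2, 0.5 and −1, 30% censoring) with a large consistent-ranking
source cohort (n=2000), then fit both methods and score them against the
simulated truth:

```sh
tlscp simulate --n-target 200 --n-source 2000 --p 90 --seed 7 --out-dir demo
tlscp fit-scp   --data demo/target.csv --out demo/scp.json
tlscp fit-tlscp --data demo/target.csv --source demo/source.csv --out demo/tlscp.json
tlscp evaluate --fit demo/scp.json   --truth demo/truth.json --out demo/scp_metrics.json
tlscp evaluate --fit demo/tlscp.json --truth demo/truth.json --out demo/tlscp_metrics.json
```

Output of the run above:

```
simulate: wrote target.csv, source.csv, truth.json -> demo
fit-scp: 6 clusters (k=5, BIC=894.03) -> demo/scp.json
fit-tlscp: 5 clusters (k=4, BIC=974.11) -> demo/tlscp.json
evaluate: NMI=0.623 relErr=0.142 -> demo/scp_metrics.json
evaluate: NMI=0.704 relErr=0.146 -> demo/tlscp_metrics.json
```

NMI is the normalized mutual information between the recovered and true
partitions of the 90 predictors (1 = perfect recovery); relErr is
\(\|\hat\beta-\beta^*\|^2/\|\beta^*\|^2\). On this draw the transferred
ranking lifts cluster recovery from NMI 0.62 to 0.70 at comparable
estimation error; on 200 target observations alone neither method can
pin down the exact three-cluster structure. The fit JSONs carry the
coefficients, labels, centers, selected k, BIC and the resolved
configuration; `--source-ranks ranks.json` replaces `--source` when only
summary-level source information is available.

The same pipeline is callable as a library (`SurvivalDataset`,
`fit_scp`, `fit_tlscp`, `select_k_bic`, `nmi`, `rel_err`,
`generate_target`, `run_benchmark`), and `tlscp benchmark` runs
replicated scenario studies to a tidy metrics CSV.

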