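# deerlaterate

Multilateration of spin-label pseudo-rotamer ensembles against raw DEER
time-domain data.

Double electron-electron resonance (DEER/PELDOR) spectroscopy measures
distance distributions between pairs of nitroxide spin labels on a
protein. Because the label itself is flexible, each measurement reports
on a cloud of label positions rather than a backbone coordinate — a
problem when the distributions are meant to restrain structural models.
When many label pairs share common sites, the network of decays
over-determines the label positions, and they can be *multilaterated*:
this package refines, for every labeled residue, a weighted ensemble of
coarse-grained label positions (pseudo-rotamers placed around the
residue's CB) by fitting all dipolar decays simultaneously, directly in
the time domain.

For a candidate weighting θ, each pair's distance histogram is broadened
by the B-factor-derived backbone RMSF, passed through the
powder-averaged dipolar kernel

    V_intra(t) = Σ_j P(r_j | θ) ∫_0^{π/2} sin x · cos((1 − 3cos²x) ω_dd(r_j) t) dx,

and composed with a stretched-exponential background
`B(t) = exp(−(kt)^(d/3))` and modulation depth λ. Fit quality is the
noise-normalized log-likelihood

    ln L = −(n/2) ln( (1/n) Σ_i Σ_t ((V_exp,i − V_sim,i)/σ_i)² ),

with σ_i estimated from each trace's phase-corrected imaginary channel.
Weights are optimized by simulated annealing (Metropolis on −lnL, kT
starting at 1.5 with per-round decay and tenfold move-size reduction on
stalled rounds), and independent replicas are ranked by the
small-sample-corrected Akaike criterion AICc = −2 lnL + 2K +
2K(K+1)/(n−K−1), which prefers ensembles with as few active rotamers as
the data allow. The five best replicas yield distance distributions with
95% confidence bands, and a distribution-overlap score
`S = −Σ_pairs ln Σ_j p_sim,j p_exp,j` (floored at 87 per disjoint pair)
ranks candidate structural models against the restraints.

See `docs/methods.md` for the full model description and design
decisions.

## Worked example

Generate a synthetic benchmark dataset (an ideal helix with 6 labeled
sites, 10 interconnected DEER pairs, 1% noise), fit it with 20 annealing
replicas, and score the refined distributions against themselves:

```
$ deerlaterate synth --seed 1 --out demo/data
wrote 10 traces for 6 labeled sites to demo/data

$ deerlaterate fit --pairs demo/data/manifest.yaml --pdb demo/data/structure.pdb \
      --replicas 20 --seed 7 --d-policy fixed --out demo/fit
best AICc -36.96 (9 active rotamers); results in demo/fit

$ deerlaterate score --sim demo/fit --exp demo/fit \
      --pairs demo/data/manifest.yaml --out demo/scores.csv
total overlap score 23.723 over 10 pairs
```

`demo/fit/` now contains the ranked pseudo-rotamer ensembles
(`ensemble_rank*.txt`, one `residue x y z weight` record per rotamer), a
per-pair distribution table with confidence bands
(`distribution_*.tsv`), and `run_log.json` with each replica's
log-likelihood, parameter count, AICc, and per-round SSR descent. The
best model fits the ten decays at the noise floor using 9 active
rotamers across the 6 sites; against the planted ground truth
(`demo/data/ground_truth.txt`, one rotamer per site) its per-site weight
centroids land 0.6-3.8 A from the planted positions on this fixture
instance — the acceptance benchmark below quantifies recovery
systematically over repeated instances. The self-score of 23.7 over ten
pairs (about 2.4 per pair, i.e. −ln of each distribution's
self-overlap) is the natural floor for distributions of this width;
disjoint distributions would score 87 per pair.

Python API sketch:

```python
from deerlaterate import (read_trace, truncate_trace, estimate_noise,
                          parse_backbone, generate_cloud, clash_filter,
                          TraceNetwork, run_replicas, confidence_bands)

trace = truncate_trace(read_trace("pair_131_155.dat", "131-155", "A:131", "A:155"))
estimate_noise(trace)
backbone = parse_backbone("structure.pdb")
clouds = {rid: clash_filter(generate_cloud(res), backbone)
          for rid, res in ((r.residue_id, r) for r in backbone)
          if rid in {("A", 131), ("A", 155)}}
network = TraceNetwork(traces=[trace], clouds=clouds, d_policy="fixed")
models = run_replicas(network, n_replicas=100, base_seed=0)
dist = confidence_bands(models, (("A", 131), ("A", 155)))
```

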