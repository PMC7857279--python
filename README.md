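# repsel

Variance decomposition, repeatability, and the **repeatable opportunity for
selection** (`I_R = R × I`) for multiplicative pre- and postcopulatory
fitness components of male reproductive success in a mating-group design.

A focal sperm donor is exposed to three independent mating groups (labels
B/C/D) of four partners each. Per group, three measurement episodes are
recorded: copulation counts, stored-sperm counts in each recipient (with the
focal's sperm distinguishable by a dominant fluorescent marker), and
offspring counts with paternity assignment. From the summed counts per focal
the package computes the multiplicative decomposition

```
mRS = F × MS × STE × SFE
```

(partner fecundity, mating success, sperm-transfer efficiency, sperm
fertilizing efficiency), relativizes every measure to mean 1, and provides:

- **`repsel.io_data`** — canonical CSV schema (`groups.csv`,
  `recipients.csv`, `penetrance.csv`), row-level validation,
  marker-penetrance exclusion filter, replicate-level aggregation.
- **`repsel.fitness`** — imputation of sperm totals that were unobservable
  because of an egg in the recipient's antrum (observable-mean imputation),
  component computation, relativization.
- **`repsel.variance`** — decomposition of `Var(mRS*)` into component
  variances and doubled covariances; binomial sampling-error variance of the
  derived ratio components (closed-form delta method and Monte-Carlo
  redrawing); percentile bootstrap; pairwise signed-difference tests.
- **`repsel.repeatability`** — variance-stabilizing transformations
  (`√mRS`, `√(F+0.5)`, `√STE`, `log10(SFE+1)`, MS untransformed),
  intraclass correlation from an exact-profile REML random-intercept model
  (method-of-moments ANOVA ICC as a fast alternative), boundary-corrected
  likelihood-ratio significance, focal-level bootstrap CIs, and mixed-model
  trend tests for mating-group/batch effects.
- **`repsel.ir_metric`** — joint bootstrap resampling whole focals that
  recomputes each component's total variance share and repeatability per
  iteration and reports `I_R` with CIs and pairwise sign-test p-values.
- **`repsel.synthetic`** — generative model of the whole design (latent
  focal quality on log/log-odds scales, group noise, batch effects,
  Poisson/Binomial observation layers) with brute-force "true ICC"
  computation and parameter-recovery experiments.

## CLI

```sh
repsel simulate --config sim.yaml --seed 7 -o simdir/   # synthetic dataset
repsel validate simdir/                                 # schema + invariants
repsel aggregate simdir/ -o aggregates.csv              # filter, impute, sum
repsel components aggregates.csv -o components.csv      # F, MS, STE, SFE, mRS
repsel decompose aggregates.csv --bootstrap 10000 --seed 42 -o decomposition.json
repsel repeatability per_group.csv --component STE --bootstrap 10000 -o rpt.json
repsel ir simdir/ --bootstrap 10000 --seed 42 -o table1  # writes .csv/.json/.png
```

A YAML schema file (`--schema`) maps arbitrary column names onto the
canonical ones, e.g.

```yaml
groups:
  total_matings: TotalCop
  focal_matings: FocalCop
```

## Data layout

`groups.csv`: `replicate_id, batch, group_label, total_matings, focal_matings`
— one row per focal × mating group.

`recipients.csv`: `replicate_id, group_label, recipient_index, total_sperm,
focal_sperm, egg_in_antrum, total_offspring, focal_offspring` — one row per
sperm recipient (4 per group); `total_sperm` empty iff an egg in the antrum
prevented counting (`egg_in_antrum` true).

`penetrance.csv`: `replicate_id, offspring_screened, gfp_positive` — the
marker-penetrance screen used by the exclusion filter (default: exclude
focals under 90% penetrance or with no screened offspring).

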