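# sbanet

Social-behavioral association networks (SBAN) for wintering-waterbird
communities: from activity-based species abundance observations to
correlation-thresholded networks, edge-classification scores, keystone
(hub) species rankings, and a regime × habitat comparison of network
attributes.

## What it does

The observational unit is a *selection event*: one day's stable bird
aggregation at a site, recorded as per-(species, behavior class) head
counts across five habitat types (BG, DW, GL, SW, MF) under two
hydrological regimes (R1 managed, R2 unmanaged). Each of 14 catalog
species contributes five network nodes — two activities (forage, roost)
and three short-term behaviors (competition, aggression, courtship) — for
a fixed 70-node universe per stratum.

Pipeline stages, one module each:

| module | role |
| --- | --- |
| `event_store` | event validation, daily best-event filtering, pivot to event × node abundance matrices |
| `synthetic_data` | community simulator with plantable block-correlation structure (negative-binomial counts, event-level latent factors) |
| `sban_build` | Pearson correlation of node columns → sign policy (negatives zeroed by default) → threshold (0.05, ties kept) → weighted undirected graph |
| `network_metrics` | active species/nodes, edge counts, edge density over the 70-node universe, intra/inter-species (SIPS) and intra/inter-behavior (BIPS) edge tallies |
| `keystone_rank` | 0.4-cutoff simplification, hub centrality (per-component principal eigenvector) and weighted PageRank, species-level ranking |
| `group_compare` | balanced two-way sites × habitat ANOVA (Type III SS) over the 8 numeric attributes per cell, Fisher's LSD post hoc |
| `cli` | `sban` command-line orchestration |

A reference per-stratum attribute table and the default species catalog
are bundled (`sbanet.datasets`), so the comparison stage runs without any
external data.

## CLI

```bash
# simulate a synthetic observation-event table (deterministic per seed)
sban simulate --days 60 --seed 42 --out events.csv

# build per-stratum networks (GraphML + edge lists)
sban build --events events.csv --threshold 0.05 --sign-policy zero-negative --out networks/

# attribute summary table (one row per regime × habitat)
sban summarize --networks networks/ --out summary.csv

# keystone ranking for one network
sban keystone --network networks/sban_R1_MF.graphml --cutoff 0.4 --method hub --aggregate max --out keystones.csv

# two-way ANOVA + LSD from a summary table
sban compare --summaries summary.csv --alpha 0.05 --out-anova anova.csv --out-lsd lsd.csv

# everything end to end
sban all --days 60 --seed 42 --outdir run/
```

Logs go to stderr; all artifacts are files.

## Notes

- Edge density uses the complete pair count of the fixed 70-node universe
  as denominator; 6 of the 10 bundled reference rows match this formula
  exactly, the other 4 are recorded as discrepancies in the tests.
- The build threshold keeps ties (entries below 0.05 are dropped); the
  keystone cutoff is strict (only weights above 0.4 survive). The
  asymmetry is deliberate and tested.
- Treating the 8 heterogeneous network attributes as replicate responses
  in one ANOVA is statistically questionable; the module documents the
  caveat and reproduces that design faithfully.
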