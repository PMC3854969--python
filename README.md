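# ciliagate

Quantitative tools for studying how the ciliary **transition zone (TZ)**
acts as a membrane diffusion barrier, built around the biology of
ARL13B/ARL-13 — a Joubert-syndrome-associated GTPase confined to an
Inversin-like subdomain of the proximal ciliary membrane. The package is
aimed at cilia researchers who want to simulate, fit and classify
compartmental FRAP experiments, measure IFT-like particle velocities from
kymographs, and apply standard AP-MS interactor-filtering rules.

It provides four pieces, usable as a library or through the `ciliagate`
command line:

1. **Membrane simulator** (`ciliagate.simulate`) — stochastic 1D Brownian
   dynamics of membrane molecules in two pools (periciliary membrane, PCM,
   and ciliary middle segment, MS) separated by a ~1 µm TZ whose boundaries
   pass a crossing attempt with probability `p_tz`; photobleach events,
   optional IFT-like directed transport, imaging noise, plus an exact
   transition-kernel integrator (`expected_trace`) that serves as the
   simulator's seed-free oracle.
2. **FRAP analysis** (`ciliagate.frap`) — the background-subtracted,
   pre-bleach-normalised bleached:non-bleached ratio statistic, one-phase
   association fitting

   F(t) = plateau − (plateau − f0)·exp(−k·t),  t½ = ln 2 / k,

   with an R² > 0.75 quality gate, barrier classification
   (exchanging / restricted / indeterminate) from compartment-bleach
   designs, compartment signal-ratio and length measurements, and one-way
   ANOVA with Bonferroni-corrected pairwise comparisons.
3. **Kymograph velocimetry** (`ciliagate.kymo`) — per-frame particle
   detection (median + 5·MAD threshold, sub-pixel parabolic refinement),
   greedy nearest-neighbour linking, and signed velocity summaries
   (anterograde positive, mean ± SEM).
4. **AP-MS filtering** (`ciliagate.apms`) — TAP spectral-count retention
   rules (2-of-3 experiments with ≥2 peptides, peptide probability >80%,
   protein probability ≥95%, <15% control-run frequency), SILAC enrichment
   gating (≥2-fold on the median log2 H/L), the significance-A outlier
   statistic, and summary counts of the packaged ARL13B complex table.

## Worked example: is the TZ barrier intact?

Simulate a whole-cilium bleach in intact-barrier (wild-type-like) and
compromised-barrier (mks-5-like) conditions and fit the recovery:

```python
from ciliagate import SimConfig, fit_recovery
from ciliagate.frap import simulate_compartment_frap

for label, cfg in [
    ("intact (wild-type-like)",
     SimConfig(p_tz=0.01, n_molecules=2000, seed=1)),
    ("compromised (mks-5-like)",
     SimConfig(p_tz=1.0, tz_occupancy=True, n_molecules=2000, seed=1)),
]:
    curve, _ = simulate_compartment_frap(cfg, "cilium_only", seed=1)
    fit = fit_recovery(curve)
    print(f"{label}: t1/2 = {fit.t_half:.0f} s, "
          f"plateau = {fit.plateau:.2f}, R2 = {fit.r_squared:.2f}")
```

prints

```
intact (wild-type-like): t1/2 = 552 s, plateau = 1.30, R2 = 0.99
compromised (mks-5-like): t1/2 = 34 s, plateau = 1.07, R2 = 0.99
```

With an intact barrier the bleached ciliary pool re-equilibrates with the
PCM only through rare TZ crossings, so the fitted half-time is an order of
magnitude slower than in the compromised case, where the pools exchange
freely — the qualitative signature used to read barrier integrity off FRAP
curves. (`p_tz` and `D` are model parameters, not measured worm values, so
the absolute half-times are simulation-specific; the intact:compromised
ordering is the robust readout.)

Summarising the packaged ARL13B complex table:

```sh
$ ciliagate apms summarize
{
  "n_total": 47,
  "n_silac_detected": 41,
  "n_silac_nd": 6,
  "top_nonbait_count": 13.3,
  "max_count": 31.2
}
```

47 proteins co-purified with the ARL13B bait, 41 of which were also
quantified (≥2-fold enriched) by the more sensitive SILAC approach; 6 were
not detected (`nd`). The bait tops the table at an average of 31.2
peptides, with IFT74 the strongest interactor at 13.3.

Other entry points: `ciliagate simulate {frap,kymo,apms}`,
`ciliagate frap {ratio,fit,classify}`, `ciliagate kymo track`,
`ciliagate quantify {ratio,length,groups}`,
`ciliagate apms {tap-filter,silac,summarize}` — all with `--seed`,
`--config` (YAML) and `--out` for reproducible runs.

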