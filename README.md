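# hippoferro

Regional non-heme-iron analysis of the entorhinal-hippocampal system from
quantitative susceptibility mapping (QSM), for researchers studying iron
redistribution in aging and mild cognitive impairment (MCI).

The package implements, as a tested and seedable pipeline, the full analysis
chain behind a 7 T study design comparing cognitively healthy controls (HC)
with MCI:

1. **Synthetic data** (`hippoferro.synthetic`) — subject tables (bilateral
   susceptibility in ppm and volume in mm³ for parasubiculum, presubiculum,
   subiculum, CA1, CA3, CA4, the granule cell layer of the dentate gyrus and
   the entorhinal cortex, plus age/sex/group) drawn from configurable group
   moments, and 3-D labeled ellipsoid phantoms with a dipole forward model
   producing wrapped single-echo GRE phase.
2. **Reconstruction** (`hippoferro.recon`) — single-step total-generalized-
   variation (TGV) dipole inversion from wrapped phase. The variational
   problem

   min over χ, v of α₁‖∇χ − v‖₁ + α₀‖ℰ(v)‖₁ + ½‖M(s·Δ(d ⊛ χ) − Δφ)‖₂²

   couples Laplacian-based phase unwrapping, background-field removal and
   dipole inversion (d ⊛ is the dipole convolution, Δ the discrete
   Laplacian, M the brain-mask restriction, s = 2π·γ̄·B₀·TE the ppm→radian
   scale, ℰ the symmetrized derivative). Solved with a monotone
   Chambolle-Pock primal-dual loop; defaults α = (0.0015, 0.0005) and 1000
   iterations.
3. **Regional quantification** (`hippoferro.regions`) — per-label means with
   optional vascular-outlier exclusion, eroded-ventricle reference selection
   (lowest across-subject SD), offset referencing and bilateral averaging.
4. **Group statistics** (`hippoferro.stats`) — ICC(2,1) (two-way random
   effects, single measurement, absolute agreement) of the regions-by-
   subjects matrix as a spatial-coherence statistic; Welch tests with
   Hedges-corrected effect sizes and Benjamini-Hochberg FDR; Jarque-Bera
   normality and volume-CV summaries; two-sample Kolmogorov-Smirnov
   comparison of group region-mean profiles (Stephens-corrected asymptotic
   p plus an exact lattice-path enumeration); covariate splits and a PCA
   screen.

## Worked example

```python
from hippoferro.pipeline import RunConfig, run_pipeline

config = RunConfig.from_dict({"stages": ["simulate", "stats"],
                              "seed": 7, "out_dir": "run_out"})
report = run_pipeline(config)
print({k: round(v["icc"], 2) for k, v in report.to_json_dict()["iccs"].items()})
ks = report.ks_groups
print(f"KS D = {ks.D:.3f}, p = {ks.p_asymptotic:.4f}")
```

prints

```
{'all': 0.55, 'HC': 0.48, 'MCI': 0.72}
KS D = 0.625, p = 0.0497
```

One simulated 40-subject cohort: the intraclass correlation of the regional
susceptibility profile is moderate-to-high in every group and higher in MCI
than HC — iron distribution across subfields is more uniform across MCI
subjects. The KS statistic compares the two groups' 8-region mean
susceptibility profiles; here they differ significantly at α = 0.05.
`run_out/report/` holds the full per-region test table (Welch t, FDR-adjusted
p, Hedges g), the ICC and KS blocks as JSON, and a long-format per-subject
scatter table.

The same stages run from the shell:

```sh
hippoferro simulate --seed 7 --out cohort.tsv
hippoferro stats --table cohort.tsv --value chi --out report/
hippoferro recon --phase phase.nii.gz --mag mag.nii.gz --out chi.nii.gz
hippoferro run --config run.yaml
```

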