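# fdopa

Automated quantification of dynamic 6-[¹⁸F]fluoro-L-DOPA (FDOPA) brain
PET: rigid-body motion correction and quality control, cerebellar
reference-region Gjedde–Patlak mapping of the net influx rate constant
Ki^cer (a proxy of presynaptic dopamine synthesis capacity), SUVr, and
test–retest reliability statistics — plus a compartmental phantom
generator with known ground truth so the whole pipeline can be
validated on a desk.

Intended users: PET methodologists and psychiatric-imaging researchers
who need a reproducible, scriptable FDOPA pipeline, and anyone needing
a self-validating reference implementation of reference-region Patlak
analysis.

## The method

For an irreversibly trapped tracer, the Patlak transformation

  y(t) = C_T(t)/C_ref(t),  x(t) = ∫₀ᵗ C_ref dτ / C_ref(t)

is linear for t ≥ t\* (20 min); the slope of the ordinary
least-squares line through the late points is Ki^cer (min⁻¹).  The
pipeline stages run in the acquisition's order: frame realignment to
the 15-min reference frame (6-DOF rigid, intensity-rescaled MSE,
multi-resolution), framewise-displacement QC (spikes > 5 mm flag the
scan, max FD ≥ 8 mm fails it), static summation, regional TAC
extraction, region-wise and voxel-wise Patlak with Chambolle
total-variation denoising before the parametric fit, and SUVr over
60–75 min.  Reliability of outcomes across sessions or pipelines is
summarized by two-way mixed ICC, %VAR, Bland–Altman limits of
agreement, Pearson r and mean absolute percentage difference.

See `docs/methods.md` for the model, parameter defaults and the
phantom's design.

## Worked example

Simulate a phantom scan (95-min, 32-frame FDOPA acquisition with a
striatal Ki^cer of 0.0137 min⁻¹ built in) and quantify it:

```bash
cat > spec.json <<'JSON'
{"seed": 7, "noise_sigma0": 0.5}
JSON
fdopa simulate spec.json phantom/
fdopa quantify --dyn phantom/phantom.nii.gz --timing phantom/phantom.json \
    --labels phantom/phantom_labels.nii.gz \
    --label-names '{"striatum":1,"cerebellum":2,"background":3}' \
    --out out/
fdopa report out/report.json
```

The report summary prints:

```
scan scan: status=ok (schema 1.0, fdopa 0.1.0)
  QC: max FD 0.13 mm, 0 spike(s), PASS
  striatum: Ki 0.0137 /min (R^2 1.000), SUVr 2.33
```

Reading: the scan shows negligible inter-frame motion (maximum
framewise displacement 0.13 mm, no spikes above 5 mm, QC pass), and
the striatal Patlak slope recovers the phantom's generative
0.0137 min⁻¹; the SUVr of 2.33 sits at the population-typical
striatum/cerebellum ratio.  `out/` also contains
the motion-corrected static image, the TAC table, the voxelwise
`ki.nii.gz`/`intercept.nii.gz` maps and `regional.csv`.

Reliability of repeated measurements, from a long-format CSV
(`subject, session, region, value`):

```bash
fdopa reliability --table pairs.csv --region striatum
```

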