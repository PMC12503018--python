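# data/

Place the deposited peroxidase screening dataset here as
`htps_screening.csv` to enable the two dataset-dependent acceptance tests
(published 1-D projection percentages and 30-campaign benchmark
statistics).

Download it from the public deposition (DOI 10.5281/zenodo.15730516) and
convert it to the canonical schema:

```
pH, temperature_C, na2so4_mM, acn_pct_vv, h2o2_mM, activity_U_per_mg, replicate
```

one row per replicate measurement (activities in U mg⁻¹). If you keep the
original column names, load it with a `column_mapping` block instead (see
`enzopt.io.read_dataset`).
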