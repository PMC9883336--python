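# TSV peak-list dialect

A human-diffable long-format table for centroided MS² spectra: UTF-8,
tab-separated, one row per peak, with exactly this header line:

```
spectrum_id	precursor_mz	rt_min	mz	intensity
```

| column         | type   | notes                                             |
|----------------|--------|---------------------------------------------------|
| `spectrum_id`  | string | rows of one spectrum must be contiguous           |
| `precursor_mz` | float  | declared precursor m/z (Th), constant per spectrum|
| `rt_min`       | float  | retention time in minutes; empty or `NA` if absent|
| `mz`           | float  | peak m/z, written with 6 decimals                 |
| `intensity`    | float  | arbitrary counts ≥ 0, `%.6g`                      |

Peaks need not be sorted on disk; readers sort by m/z. Blank lines are
ignored. Writing then reading a file reproduces every spectrum exactly at
6-decimal m/z precision (`fufatag.write_peaklist_tsv` /
`fufatag.read_peaklist_tsv`).
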