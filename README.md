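# betalains

Identification of betalain plant pigments (betacyanins, betacyanin
derivatives, betaxanthins) from LC-MS/MS data.

The package provides:

- **`betalains.chem`** — molecular-formula parsing (compact `C24H26N2O13`
  and underscore-subscript `C_24_H_26_N_2_O_13_` dialects), monoisotopic
  mass and protonated-ion ([M+H]+) m/z computation, signed ppm mass
  accuracy, and element-wise composition arithmetic.
- **`betalains.catalog`** — the betalain data model plus a bundled
  reference catalog of the 86 betalains reported in red pitaya
  (`src/betalains/data/red_pitaya_catalog.tsv`): class taxonomy with
  framework ions, derivative enumeration (decarboxylation −CO2,
  2,3-/14,15-dehydrogenation −H2), betaxanthin condensation (betalamic
  acid + amine − H2O), relative retention times, catalog statistics and
  validation.
- **`betalains.fingerprint`** — diagnostic-ion screening of MS/MS spectra:
  the shared low-mass core ions (m/z 211.07, 194.04, 179.08, 178.05,
  166.05, 138.05, 132.04, 106.06) gate the betalain call, then the
  aglycone ion 389.09 marks intact betacyanins, 345.10 decarboxylated
  derivatives, 343.09 dehydrogenated derivatives, and 211.07 (with a small
  precursor) betaxanthins.
- **`betalains.annotate`** — matching of screened features to catalog
  records by precursor ppm (default ±5 ppm), fragment coverage, and
  retention-time resolution of iso-epimers; Table-style report output.
- **`betalains.msn`** — multistage-MS (MS2→MS3→MS4) precursor-chain
  interpretation as successive neutral losses against a bundled residue
  table (glucosyl 162.0528, pentosyl 132.0423, malonyl 86.0004, …), and
  parent-composition proposal.
- **`betalains.simulate`** — seed-deterministic synthetic DDA runs from
  the catalog (ppm/mz/rt jitter, log-uniform intensities, decoy features
  avoiding the diagnostic windows) for end-to-end benchmarking.
- **`betalains.mgf`** — minimal MGF and plain peak-list I/O.

## Command line

```sh
betalains mass C24H26N2O13            # 551.1508
betalains ppm 551.1483 C24H26N2O13    # -4.54
betalains stats                       # bundled-catalog summary (86 records)
betalains validate-db                 # recompute m/z / ppm / relative Rt
betalains simulate --seed 1 --decoys 50 --out run.mgf
betalains screen --spectra run.mgf
betalains annotate --spectra run.mgf --ppm-tol 5 --out report.tsv
betalains losses --chain 827.2353,695.1930,551.1508,389.0979
```

`betalains show-config` prints the effective defaults; a YAML config file
(`--config`) can override any tolerance, with CLI flags taking precedence.

## Notes

- All ions are treated as singly protonated, positive mode; reported m/z
  values are rounded (half away from zero) to 4 decimals, ppm to 2.
- Four catalog rows (the xanneobetanins and tridecarboxy-neobetanins)
  publish fragment lists carrying almost none of the core ions; the
  screen reports them as exceptions (`betalains.fingerprint.KNOWN_EXCEPTIONS`)
  rather than forcing a class call.
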