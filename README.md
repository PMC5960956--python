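# microferm

Analysis toolkit for anoxic gut-content microcosm fermentation
experiments: speciation of headspace/dissolved gases and organic acids,
net-product accounting against unsupplemented controls, carbon and
reducing-equivalent (electron) recovery balances from biomass elemental
chemistry, and a 16S rRNA amplicon responder screen — plus a synthetic
data generator so the whole pipeline is testable without lab data.

## Modules

| module | what it does |
|---|---|
| `microferm.chem` | condensed elemental-formula parsing, per-carbon molar mass, mean carbon oxidation state, degree of reduction per carbon, fermentation-product registry (carbon atoms / reducing equivalents) |
| `microferm.presets` | shipped substrate presets (yeast/E. coli lysate, BSA protein, RNA, sugars) with printed-constant overrides |
| `microferm.speciation` | ideal-gas headspace amounts, Bunsen-solubility dissolved amounts, bicarbonate from pH and pKa, normalization to µmol per g fresh weight |
| `microferm.balance` | treatment-minus-control net profiles (with transient-product flagging), substrate carbon inventories, recovery tables (%C, %e⁻) and ribose-basis rescaling for RNA |
| `microferm.community` | relative abundances with singleton removal, similarity-matrix phylotype merging (single linkage), family/phylotype responder screen (5 pp / 2 pp rules), time-averaged abundances, Shannon / rarefaction / Chao1 |
| `microferm.simulate` | fermentation scenarios inverted through the speciation model, paired-arm amplicon count tables with designated responders, detector benchmarking |

## CLI

One console script with pipeline-stage subcommands:

```bash
# raw measurement TSV -> per-analyte umol per g fresh weight
microferm speciate --measurements measurements.tsv --out amounts.tsv

# net products + recovery table at the final sampling time
microferm balance --amounts amounts.tsv --treatment treatment --control control \
    --substrate yeast_lysate --carbon-umol 2290

# responder screen (family level, 5 percentage-point rule)
microferm respond --counts counts.tsv --taxonomy taxonomy.tsv \
    --design design.tsv --level family --threshold 5

# per-sample diversity summaries
microferm diversity --counts counts.tsv --mode rarefaction --depth 1000

# synthetic data with ground truth
microferm simulate-microcosm --scenario scenario.yaml --seed 7 --out sim/
microferm simulate-counts --scenario community.yaml --seed 7 --out sim/
```

Measurement schema (TSV, one observation per row): `microcosm_id,
treatment, replicate, time_h, analyte, phase{headspace,liquid}, value,
unit{mol_fraction,mM}, pressure_kPa, temperature_K, pH`.

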