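# ctfish

3D-FISH chromosome territory analysis: nucleus and territory segmentation,
homologous-pairing classification, heterologous-association metrics, nuclear
volume proportions, and the population statistics built on top of them — plus
a synthetic confocal-stack generator with voxel-level ground truth for
validating every stage.

## The science in one paragraph

In sequential chromosome-painting (3D-FISH) experiments, each hybridization
round labels a few chromosomes in a fluorochrome each, and a confocal z-stack
is captured per round.  Within a nucleus, the two homologs of a chromosome
are called **paired** when all voxels of their painting signal form a single
continuous connected component, and **unpaired** when they form two or more
separate voxel groups sharing no voxel.  Two *different* chromosomes are
**associated** when their territories share at least one voxel, with the
overlap expressed as a percentage of each territory.  The **nuclear volume
proportion (NVP)** of a signal is its voxel volume as a percentage of the
nucleus volume.  Aggregated over a cell population, these per-nucleus calls
yield per-chromosome pairing rates, their relationship to chromosome size /
GC content / gene density / NOR status, association rates with confidence
intervals, and per-chromosome NVP profiles.

## Quick start (CLI)

```sh
# everything in memory: simulate → segment → classify → summarize
ctfish run --stage spermatogonia-early-preleptotene --n-cells 8 --seed 7 --out out/
```

`out/pairing_table.csv` then starts like:

```
                           stage chromosome  n_two_signal  n_one_signal  total  pct_one_signal
spermatogonia-early-preleptotene          1             3             5      8            62.5
spermatogonia-early-preleptotene          2             2             6      8            75.0
```

alongside `calls.csv`, `associations.csv`, `association_summary.csv`,
`nvp.csv`, `nvp_summary.csv`, a `resolved_config.yaml` and a `run_log.jsonl`
(version, config hash, seed; reruns with the same config are bit-identical).

The stages can also run separately, on files:

```sh
ctfish simulate --stage pachytene --n-cells 2 --seed 3 --out sim/
ctfish segment  --in sim/ --out masks/
ctfish metrics  --masks masks/ --out metrics/
ctfish summarize --calls metrics/calls.csv --out summary/
```

## Quick start (API)

```python
from ctfish.synthetic import stage_preset, generate_population
from ctfish.pipeline import analyze_nucleus
from ctfish.stats import build_pairing_table, stage_summary

preset = stage_preset("spermatogonia-early-preleptotene")
calls = []
for record in generate_population(preset, 20, seed=1):
    calls.extend(analyze_nucleus(record).calls)      # ground truth in record.ground_truth
table = build_pairing_table(calls)
print(stage_summary(table, preset.stage))
```

Every simulated nucleus carries voxel-exact ground truth (territory masks,
pairing state, shared voxels), so recovery of any quantity can be verified.

## Package layout

| module | contents |
| --- | --- |
| `ctfish.types` | dataclasses and labels shared by all stages |
| `ctfish.io` | multi-page TIFF + JSON-sidecar stacks, binary masks, packaged tables |
| `ctfish.synthetic` | seeded nucleus/population generator with ground truth |
| `ctfish.segmentation` | Otsu-based nucleus and territory masks |
| `ctfish.metrics` | connected components, pairing calls, association, NVP |
| `ctfish.stats` | pairing tables, correlations, NOR t-test, Wald/Wilson CIs, flags |
| `ctfish.pipeline` | `RunConfig`, end-to-end runs, published-summary recomputation |
| `ctfish.cli` | `ctfish` command-line verbs |

Method details, parameter defaults and their rationale are documented in
[docs/methods.md](docs/methods.md).

## Testing

```sh
python -m pytest            # full suite, including acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion.  One of
them (`test_criterion_2_size_correlations_at_printed_precision`) fails by
design: it asserts the printed correlation values, which are not recoverable
from the printed tables (see above); it is kept at face value rather than
weakened.
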