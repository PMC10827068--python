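# hillnet

Logic-based differential-equation (LDE) simulation of signaling and
gene-regulatory networks, for systems biologists who sketch a network as
"A activates C, B inhibits E" and want continuous, quantitative dynamics
without writing ODEs by hand.

Networks of this kind are usually drawn from many reductionist studies:
each edge is a single activating or inhibiting interaction, and the model
integrates them so that perturbations — stimuli, washouts, gene knockouts —
can be simulated *in silico*. `hillnet` provides the model format, the
mathematics, staged simulation protocols, a systematic knockout screen, and
exports for Cytoscape.

## The model

Every species *i* carries a normalized activity
*y*<sub>*i*</sub> ∈ [0, *y*<sub>max,*i*</sub>] obeying

    dy_i/dt = ( φ_i(y) · y_max,i − y_i ) / τ_i

where φ<sub>*i*</sub> ∈ [0, 1] is a fuzzy-logic drive built from
**normalized Hill functions**. An activating edge with source activity *x*
contributes

    f_act(x) = β x^n / (K^n + x^n),      f_inhib(x) = 1 − f_act(x)

with β and K fixed by the three anchors *f*(0) = 0, *f*(EC50) = ½,
*f*(1) = 1:

    K^n = EC50^n / (1 − 2·EC50^n),   β = 1 + K^n

(which exists iff EC50<sup>n</sup> < ½). Terms joined by `&` inside one
rule multiply (fuzzy AND); several reactions converging on one target
combine by the probabilistic OR *a* + *b* − *ab*. Reactions with no source
(`=> A`) are environmental inputs whose drive is just their weight
*w* ∈ [0, 1]. Setting a species' *y*<sub>max</sub> to 0 models a knockout.

Models are defined in two-sheet spreadsheets (the format used by the
Netflux tool family): a `species` sheet with columns `module, ID, name,
Yinit, Ymax, tau` and a `reactions` sheet with `module, ID, Rule, Weight,
n, EC50`. Rules use a minimal grammar — `A & !B => E` means "A activates
and B inhibits E"; a leading apostrophe (`'=> A`) keeps spreadsheet
software from parsing the rule as a formula and is stripped on read.
Unrecognized columns round-trip verbatim as metadata; blank parameter
cells take the defaults τ=1, y<sub>init</sub>=0, y<sub>max</sub>=1, w=1,
n=1.4, EC50=0.5.

## Worked example

Two bundled models can be built in code (`build_examplenet`,
`build_cardiacdevnet`) or written as workbooks with `hillnet init-models`.
The cardiac-development network has GATA6 driving NKX2-5, TBX1 and PITX2,
with NKX2-5 repressing ISL1 (which starts at activity 1):

```sh
python examples/cardiac_knockout.py
```

```
 species  baseline t=10  knockout t=10
   GATA6          1.000          1.000
   NKX25          0.997          0.000
    TBX1          0.999          0.997
    ISL1          0.011          1.000
   PITX2          0.998          0.989

TBX1 reaches half-activity at t=3.52 (baseline) vs t=3.68 (knockout)
```

After GATA6 induction the baseline run drives NKX2-5, TBX1 and PITX2 to
full activity while ISL1 is repressed to ~0. Under an NKX2-5 knockout its
activity is pinned at 0, ISL1 is never suppressed, and TBX1/PITX2 rise
later because one of their two activating routes is gone — the qualitative
signature of reduced NKX2-5 expression in development.

The other example scripts show the staged stimulate/washout protocol
(`stimulate_washout.py`), the systematic knockout screen
(`knockout_screen.py`) and workbook/Cytoscape I/O
(`workbook_and_export.py`).

### Python API in one breath

```python
import hillnet as hn

model = hn.read_model_workbook("models/cardiacDevNet.xlsx")
proto = hn.SimulationProtocol((hn.ProtocolStep(2),
                               hn.ProtocolStep(8, {"r1": 1.0})))
tc = hn.run_protocol(model, proto)          # TimeCourse
ko = hn.run_knockout_protocol(model, "NKX25", proto)
screen = hn.knockout_screen(model)          # steady-state delta table
hn.write_timecourse(tc, "baseline.csv")
```

### Command line

```sh
hillnet init-models models/                 # write bundled workbooks
hillnet validate models/cardiacDevNet.xlsx
hillnet simulate models/cardiacDevNet.xlsx -p proto.yaml -o run --plot
hillnet screen models/cardiacDevNet.xlsx -o screen.csv
hillnet export models/cardiacDevNet.xlsx -o network   # SIF + edge TSV
```

Protocol files are YAML/JSON:

```yaml
steps:
  - duration: 2
  - duration: 8
    weights: {r1: 1}
    species: {NKX25: {ymax: 0}}
```

Exit codes: 0 success, 1 validation/domain error, 2 I/O error.

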