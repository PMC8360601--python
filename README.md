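# placecode

A toolkit for place coding on the auditory tonotopic axis.  The tonotopic
axis is modelled as a row of unit-width cells; a pure tone occupies a
half-open *synaptic interval* ``[start, start + length)`` whose location
encodes frequency and whose length encodes sound pressure.  Interval sets
carry two operations — **addition** (set union; overlapping intervals fuse)
and **multiplication** by an inhibitor (set difference; inhibition shortens,
splits, or cancels intervals) — and the package derives the consequences of
that algebra for stimulus coding, loudness summation, and a spiking-network
implementation.

## Modules

| module | contents |
| --- | --- |
| `placecode.algebra` | `TonotopicAxis`, `Interval`, `IntervalSet`; `canonicalize`, `add`, `multiply`, `total_length`; plain-text serialization |
| `placecode.acoustic` | discretized frequency x pressure space, tone -> interval mapping and its inverse, multi-tone encoding, coding-capacity relations for flexible vs columnar layouts |
| `placecode.predictions` | exact (parameter, length) curves for the canonical E/I configurations: co-located and shifted addition, co-located and shifted multiplication, two E with shared I, and center-surround composites (simultaneous vs sequential) |
| `placecode.loudness` | loudness-summation model: multi-tone unions, a dominant interval with abutting inhibitory flanks, the loudness proxy \|h_l\|, critical-band curves, and the four-tone variant |
| `placecode.network` | 2-D feedforward E/I grid of AdEx neurons (75 % E / 25 % I, Gaussian I->E connectivity), Gaussian synaptic-barrage drives, synaptic-field / activated-area extraction, minimal-enclosing-circle and projection measurements, and the six sweep protocols |
| `placecode.cli` | `placecode` command-line entry point |

## CLI

```sh
placecode algebra --a 0:10 --b 4:2 --op multiply          # -> 0:4,6:4
placecode encode --tone 1000:3 --tone 1200:3              # tones -> interval set
placecode predict --out curves/                           # 6 CSV curve files
placecode loudness --out loudness.csv                     # critical-band curves
placecode --seed 1 simulate --protocol multiplication_colocated --out exp.csv
placecode fixture small_axis --out fixtures/
```

Every CSV embeds its fully resolved configuration and seed as commented
header lines, so a run can be reproduced from its own output
(`placecode.cli.read_embedded_config`).

## Notes on the simulator

AdEx and unitary synaptic parameters are not constrained by published
values; the defaults are calibrated so that (i) the feedforward inhibitory
conductance lags the excitatory drive by roughly ten milliseconds, (ii) the
default center drive makes central E cells fire, and (iii) a single
drive's synaptic field sits well inside the desk-scale grid.  All parameters
are overridable through `NetworkConfig` / `StimulusConfig`.  The synaptic
field supports two aggregations of the net current over the stimulus window:
the extremum (`reduce="min"`, the per-instant inclusion rule) and the window
mean (`reduce="mean"`, used by the sweep protocols, where the extremum would
be blind to the delayed inhibition).
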