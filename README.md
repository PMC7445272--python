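# gridhead

Head-direction analysis of grid-cell firing fields, plus the
conjunctive-cell input model that explains it.

Grid cells of the medial entorhinal cortex fire at the vertices of a
triangular lattice tiling the environment. "Pure" grid cells were long
assumed to fire regardless of which way the animal faces, unlike
conjunctive grid × head-direction cells. A closer look shows that the
individual firing fields of pure grid cells are themselves tuned to head
direction — each field to its *own* set of directions. `gridhead`
implements the full analysis chain needed to establish and study this
local directional modulation, and the generative model that reproduces
it, for anyone analysing open-field recordings (or simulations) of
spatially tuned neurons:

- **Session I/O** — delimited-text trajectory + spike-time files, spike
  kinematics by interpolation, half-session splitting.
- **Synthetic sessions** — a random-walk forager and ground-truth cells
  (omnidirectional grid, unidirectional conjunctive, multidirectional
  grid), so every stage is testable without recorded data.
- **Classification** — 42×42 smoothed rate maps, spatial
  autocorrelograms, grid score (six-fold rotational symmetry,
  threshold 0.4), head-direction score (mean vector of the smoothed
  spike-direction histogram, threshold 0.5), speed score (threshold 0.1).
- **Field detection** — recursive peak-growing segmentation (>45 bins,
  35% growth contour) with automated false-positive guards.
- **Directional statistics** — classic (1°, 23°-smoothed) and
  distributive (20 × 18°) head-direction curves; the
  distributive-hypothesis spike shuffle (1000 rate-map-conditioned
  shuffles); per-bin significance with Benjamini–Hochberg correction; a
  field-level directionality verdict at the 97.5th percentile of the
  shuffle null; the two-sample Watson U² test; between-field and
  half-session curve correlations with a shuffle-pair stability
  percentile.
- **Conjunctive-input model** — populations of conjunctive cells on a
  shared 50 cm lattice (20 cm FWHM fields, 141° FWHM directional tuning,
  per-millisecond firing probability `0.28 · G(x,y) · 0.12 · H(hd)`)
  driving a conductance-based leaky integrate-and-fire neuron through
  9-synapse inputs (2 ms decay). With spatially **uniform** input fields
  the output cell's fields share their directional tuning; with
  **non-uniform** (per-field uniform(0,1)-scaled) inputs each output
  field acquires its own directional mixture — local tuning emerges.
- **Pipeline & CLI** — a config-driven end-to-end run producing
  deterministic per-cell and per-field TSV tables, exposed as the
  `gridhead` command (`synth`, `score`, `fields`, `directional`,
  `model`, `run`).

## Worked example

Simulate a 25-minute session with one omnidirectional grid cell and one
conjunctive cell, then score it:

```bash
gridhead synth --duration 1500 --arena 100 --seed 7 --out demo/
gridhead score --session demo/ --out demo/scores.tsv
cat demo/scores.tsv
```

```
cell_id	grid_score	hd_score	speed_score	label
conj0	1.3165	0.6055	0.0417	conjunctive
grid0	1.3630	0.0342	0.0099	grid
```

Both cells are strongly grid-like (grid score ≫ 0.4: their rate-map
autocorrelograms carry clear six-fold symmetry). The conjunctive cell's
head-direction score (0.61) crosses the 0.5 unimodality criterion — it
fires only while the agent faces its preferred direction — so it is
labelled conjunctive, while the omnidirectional cell (0.03) is a pure
grid cell. Speed scores near zero confirm neither cell is speed
modulated.

The same steps in Python, continuing to the per-field directional
verdict:

```python
import gridhead as gh

traj = gh.simulate_trajectory(1500, 100, seed=7)
cell = gh.generate_spikes(traj, gh.make_grid_cell(peak_rate=15), seed=1)
rm = gh.compute_rate_map(traj, cell)
fields = [gh.assign_events_to_field(traj, cell, f, rm)
          for f in gh.detect_fields(rm)]
ens = gh.shuffle_spike_locations(
    rm, traj, fields[0].n_spikes, n_shuffles=1000, seed=2,
    sample_indices=fields[0].trajectory_sample_indices)
obs = gh.distributive_curve(cell.spike_hd[fields[0].spike_indices],
                            traj.hd[fields[0].trajectory_sample_indices],
                            traj.frame_rate)
sig = gh.significant_bins(obs, ens)
print(len(fields), sig.n_significant, sig.directional)
# 5 0 False
```

Five firing fields are detected; the first field shows zero
significantly modulated direction bins against its distributive-shuffle
null and is (correctly, for an omnidirectional truth cell) not called
directional.

## Layout

```
src/gridhead/
  session_io.py    sessions, trajectories, spike trains, file formats
  synthetic.py     trajectory + ground-truth cell generators
  tuning.py        rate maps, autocorrelograms, grid/HD/speed scores
  fields.py        firing-field segmentation
  directional.py   curves, shuffle test, Watson U², correlations
  conjunctive.py   conjunctive-cell input model + surrogate integrator
  pipeline.py      end-to-end orchestration and reports
  cli.py           the `gridhead` command
docs/methods.md    model and statistics documentation
```
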