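# smfretkin

Kinetic analysis of camera-based single-molecule FRET (smFRET)
trajectories: trace I/O, FRET-efficiency preprocessing, hidden-Markov
idealization, dwell-time rate extraction, transition-density summaries,
and Arrhenius free-energy landscapes — plus a synthetic-trace generator
that gives every stage a ground truth.

The package was built around the conformational dynamics of the
uranyl-specific DNAzyme 39E, a two-strand catalytic DNA whose donor/
acceptor labeling resolves four conformations by FRET efficiency
`E = I_A / (I_A + I_D)`: native (N, E ≈ 0.25), folded (F, ≈ 0.47),
compact (C, ≈ 0.58), and extended (E, ≈ 0.12).  With Mg²⁺ the molecule
folds and then shuttles between F, C, and E; without divalent ions it
shuttles spontaneously between N, C, and E; uranyl drives it to the
extended state.  Everything is parameterized, so any small-state-space
smFRET system fits.

## The model in brief

Dynamics are a continuous-time Markov chain with rate constants `k_ij`
(s⁻¹) between conformations; the camera integrates 50 ms frames, and each
state emits Gaussian-distributed E values.  The analysis chain is

1. `E_t = I_A / (I_A + I_D)` per frame, with direct-excitation and
   photobleach masking;
2. a pooled Gaussian-emission HMM per condition (Baum–Welch), Viterbi
   decoding per molecule;
3. dwell-time extraction with censoring bookkeeping; single-exponential
   rate fits (`k = 1/⟨τ⟩` for complete dwells) refined by a
   discretization-aware geometric fit and a simulation-based missed-event
   calibration;
4. TDP (per-event) and TODP (per-molecule) transition maps;
5. activation energies `E_a = RT (ln A − ln k)` and a free-energy
   landscape whose well gaps are `ΔG(i→j) = RT ln(k_ji / k_ij)`;
   distances via `r = R0 (1/E − 1)^{1/6}`.

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

Simulate the divalent-free condition at its published rates and run the
full in-memory analysis:

```python
from smfretkin import recover_rates, build_landscape

fit, labels, rates, paths = recover_rates(
    "NoDivalent", n_traces=100, n_frames=2000, seed=0
)
print({lab: round(float(fit.model.means[i]), 3) for i, lab in labels.items()})
for (i, j), e in sorted(rates.included().items()):
    print(f"k {i}->{j} = {e.k:.3f} 1/s   ({e.n_transitions} transitions, "
          f"{e.n_molecules} molecules)")
ls = build_landscape(rates, ["E", "N", "C"])
print("wells (J/mol):", {s: round(ls.wells[s]) for s in ls.states})
```

prints

```
{'E': 0.12, 'C': 0.569, 'N': 0.251}
k C->N = 2.900 1/s   (1671 transitions, 100 molecules)
k E->N = 0.556 1/s   (1646 transitions, 100 molecules)
k N->C = 0.373 1/s   (1677 transitions, 100 molecules)
k N->E = 0.337 1/s   (1677 transitions, 100 molecules)
wells (J/mol): {'E': 1237, 'N': 0, 'C': 5062}
```

The fitted emission means sit on the three expected levels; the four
recovered rate constants land within a few percent of the generator's
0.36 / 2.74 / 0.33 / 0.58 s⁻¹, and the landscape says the native state is
the stable well, with the compact state ~5 kJ/mol above it — i.e. C is
visited often but briefly, E rarely but for seconds.

The same machinery is scriptable from the shell:

```sh
smfret simulate --scheme Mg30 --n-traces 100 --n-frames 2000 --seed 1 --out traces.csv
smfret rates traces.csv --k 3 --out rates.json
smfret run --config run.yaml --out results/   # full pipeline + manifest
```

`smfret run` writes every stage product (E table, model, idealized paths,
dwells, rate table, TDP/TODP grids, landscape) plus a manifest with
SHA-256 digests; identical config + seed reproduces identical digests.

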