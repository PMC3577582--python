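# fourcurrent

A simulation toolkit for a four-current semiphysiological model of the
cardiac action potential, for researchers studying wave propagation,
restitution and arrhythmia mechanisms in excitable cardiac tissue who
need a model that is cheap enough for large 2D/3D simulations yet still
reproduces action-potential *morphology* — including the phase-1 notch
— and not only restitution curves.

## The model

The dimensionless transmembrane voltage V (0 at rest, ~1 at the peak;
Ṽ = V·100 mV − 85 mV) evolves under the monodomain equation

    ∂V/∂t = ∇·(D∇V) − (J_fi + J_si + J_so + J_to) + J_stim

with four lumped currents classified by function rather than by ion:

| current | role | expression |
|---|---|---|
| J_fi | fast inward (Na-like), upstroke & CV | −g_fi·h·m∞(V)·(V_fi−V) |
| J_si | slow inward (Ca-like), plateau | −g_si·d∞(V)·f·f′∞(V) |
| J_so | slow outward (K-like), repolarization | g_so·k∞(V) |
| J_to | fast transient outward (I_to), notch | g_to·r·s·(V−V_to) |

The gates h, f, r, s follow ġ = (g∞(V)−g)/τ_g(V) with step-function
steady states and two-valued time constants; m∞, d∞, f′∞, k∞ are
instantaneous.  Five built-in parameter sets cover human epicardial,
endocardial and mid-myocardial cells (fits to experiments) and fits to
the TNNP human and LRd guinea-pig ionic models.  On top of the cell
model the package provides: explicit monodomain integration on 1D
cables, 2D sheets and 3D voxel geometries (no-flux boundaries,
fiber-anisotropic diffusion tensors); stimulation-threshold search;
dynamic APD and CV restitution protocols; S1–S2 spiral-wave initiation
with phase-singularity tip tracking; a synthetic two-shell ventricle
generator with His–Purkinje-like timed endocardial activation and a
heart-dipole pseudo-ECG; and Levenberg–Marquardt-type fitting of model
parameters to action-potential templates.

## Worked example

```python
from fourcurrent import builtin_set, simulate_cell, StimulusProtocol
from fourcurrent.protocols import find_stimulus_threshold, measure_apd

params = builtin_set("epi")
thr = find_stimulus_threshold(params)          # 0.140 ms^-1
trace = simulate_cell(
    params, StimulusProtocol.pacing(1.5 * thr, bcl=1000.0, n_beats=3))
apd = measure_apd(trace)[-1].apd
```

Running `python examples/01_single_cell_ap.py` prints:

```
stimulation threshold: 0.140 ms^-1 (1-ms pulse)
beats elicited: 3
last-beat APD:  277.2 ms (threshold V = 0.1)
peak voltage:   1.287 (~44 mV)
phase-1 notch:  V falls to 0.89 then the dome rebounds to 1.01
```

The threshold is the smallest 1-ms current pulse that fires a resting
epicardial cell; paced at 1 Hz with 1.5× that amplitude the cell
produces a ~277 ms action potential whose early notch-and-dome is the
signature of the transient outward current.  The other scripts in
`examples/` walk through restitution curves, cable conduction velocity
(~57 cm/s for the LRd-fit set at D = 10⁻³ cm²/ms), spiral initiation
and period measurement (~10 rotations/s), the paced-ventricle
pseudo-ECG (biphasic QRS analog with a discordant T deflection), and
synthetic parameter recovery by least squares.

There is also a thin CLI over the same functions:

```
fourcurrent threshold --set epi --out out/thr
fourcurrent restitution-cv --set lrd --out out/cv
fourcurrent spiral --set lrd --size 6 --out out/spiral
```

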