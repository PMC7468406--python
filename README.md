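# rewiremap

Monte-Carlo simulator of experience-dependent orientation-map development
in primary visual cortex, built around activity-dependent rewiring of
thalamo-cortical afferent synapses.

## The problem

In cats, cortical neurons acquire orientation selectivity early in life,
and their preferences form smooth, band-pass-structured orientation maps.
Rearing kittens with cylindrical-lens goggles (continuous exposure to a
single orientation) expands the cortical territory representing the
exposed orientation — but only inside a sensitive period: exposure
starting too early is truncated, exposure starting too late leaves the
map untouched, and maps reorganized by prolonged exposure never recover.
`rewiremap` is for computational neuroscientists who want a mechanistic,
synapse-level model of these phenomena: it implements competitive
rewiring of individual synaptic contacts — stabilization vs elimination
driven by the balance of mature and precursor BDNF signaling, with an
age-dependent p75^NTR gate closing the sensitive period — and the
analysis toolkit (vector-sum maps, orientation histograms, ORI, OSI,
map power spectra) used to quantify the outcome.

## The model in brief

Model LGN cells (ON/OFF × non-lagged/lagged on a periodic lattice) have
separable difference-of-Gaussians spatiotemporal receptive fields; their
half-rectified responses to drifting gratings,

    η_LGN = F[ Σ_l ∫ R(t−t′) z_l(t′) dt′ ],     F(x) = xΘ(x),

drive a periodic cortical lattice through ς_aff = v Σ n η_LGN, where
n_{i,k,μ₁,μ₂} counts the synapses each LGN cell makes on neuron i's 254
dendritic sites. Firing is half-rectified about a homeostatic threshold
(the long-time mean of the potential), with short-range-excitatory /
long-range-inhibitory lateral coupling U (a balanced DOG). Each
Monte-Carlo trial proposes, for one random synaptic site, one random
candidate from its 9×9×4 retinotopic pool; the candidate survives the
age-dependent spine-contact gate

    P(contact) = 1 / (1 + e^{−β g(t)}),   g(t) = −ξ_max (t/(T_p+t))⁴,

and then replaces the current synapse with the logistic probability

    P(swap) = 1 / (1 + e^{−β(⟨b_new⟩ − ⟨b_old⟩)}),

where ⟨b⟩ is the stimulus-averaged synapse growth rate — potentiation for
afferent input coincident with suprathreshold (backpropagating-spike)
episodes, depression (ratio c_D/P = 2) for subthreshold coincidence, plus
first-order lateral corrections. One MC step is one trial per site
(585 216 at full scale) and maps to developmental time: map formation
starts at t = 0 ≙ P24 and 2.25 MCs ≙ 10 days. Above a critical inverse
temperature β_c the wiring self-organizes into a band-pass orientation
map; the operating point is β = 250. The full account, including the two
normalization choices that make the printed parameters an ordered phase,
is in [docs/methods.md](docs/methods.md).

## Worked example

Develop a map under balanced 12-orientation exposure for 1.57 MC steps,
then expose to a single vertical orientation for 3.15 MCs (a model
2-week goggle rearing), at the reduced desk scale (16×16 cortex, 8×8
LGN, 64 sites):

```python
from rewiremap import ProtocolSchedule, run_protocol, twelve, single
from rewiremap.cortex import CortexGeometry

summary = run_protocol(
    ProtocolSchedule((twelve(1.57), single(3.15))),
    geometry=CortexGeometry.reduced(), seed=1)
print(summary.to_frame().to_string(index=False))
```

```
       t  postnatal_day segment      ori  mean_osi  nonselective_frac  band_fraction  band_fraction_aff  accepted
0.000000             24 initial 0.015625  0.137287           0.175781       0.464410           0.196898         0
1.570007             31  twelve 0.015625  0.145162           0.113281       0.675844           0.335301      5540
4.719971             45  single 0.953125  0.357488           0.000000       0.574588           0.298804      8124
```

Reading the rows: the initial random wiring is unbiased (ORI ≈ 0) and
spatially unstructured (afferent band-pass power fraction ≈ 0.20, the
noise baseline). Balanced exposure to 1.57 MCs (≙ P31) organizes the map
(band fraction rises) while keeping the histogram uniform. The subsequent
single-orientation exposure drives the over-representation index to 0.95
— 95% of the way from a uniform histogram to every neuron preferring the
exposed vertical orientation — and sharpens tuning (mean OSI 0.36). The
same exposure started at 7.87 MCs (≙ P59) leaves ORI near 0: the
spine-contact gate has closed the sensitive period.

The same experiments are available from a shell:

```bash
rewiremap develop --duration 4.72 --outdir runs/      # normal development
rewiremap expose --onset 1.57 --duration 3.15         # goggle rearing
rewiremap sweep-onset --onsets 0.79,1.57,4.72,7.87    # sensitive period
rewiremap sweep-beta --betas 5,30,250                 # critical beta bracket
rewiremap recover                                     # short vs prolonged GR
rewiremap analyze runs/checkpoint.h5                  # metrics from a checkpoint
```

Each writes CSV metric tables, polar-map PNGs, HDF5 checkpoints, and a
JSON manifest. `--full-scale` switches to the 48×48 cortex / 24×24 LGN /
254-site geometry (a few seconds per MC step).

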