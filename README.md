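# contactdyn

Contact-cluster analysis of protein molecular-dynamics ensembles.

Allosteric communication — long-range coupling between distant protein
sites — proceeds through cooperative changes of inter-residue contacts.
`contactdyn` distills large MD ensembles (equilibrium or photoswitch-style
nonequilibrium campaigns) into that contact-level picture in four stages:

1. **Contacts** — identify residue pairs whose shortest heavy-atom distance
   drops below 0.45 nm in at least 10% of frames (sequence neighbors
   |i−j| ≤ 2 excluded), or the cheaper Cα-distance variant (< 0.8 nm), and
   monitor the distances r_j(t).
2. **Clusters** — compute the |Pearson| (or normalized-mutual-information)
   correlation matrix between all contact distances and partition it into
   *contact clusters* by Leiden community detection under the constant Potts
   model, maximizing Σ_c [W_c − γ·n_c(n_c−1)/2] with resolution γ ∈ (0,1].
3. **Timescales** — fit each ensemble-averaged response with the
   multiexponential expansion
   r_j(t) = Σ_k a_kj exp(−t/τ_k) + c_j,
   τ_k log-spaced (10 per decade), by maximum-entropy regularization:
   minimize χ − λS_ent, with χ the SEM-weighted RMS deviation and S_ent a
   two-channel Skilling entropy that admits signed amplitudes.
4. **Dynamical content** — D(τ_k) = Σ_j |a_kj|², whose peaks mark the
   system's characteristic response times; restricting the sum to one
   cluster's features attributes each peak to a structural module.

A synthetic-data module generates ensembles with planted correlation
structure, planted relaxation spectra, and toy atomic structures, so every
stage is testable against exact ground truth without any MD data.

Intended users: simulators analyzing μs-scale (non)equilibrium ensembles of
small proteins (e.g. PDZ domains) who want a mechanistic, time-resolved
decomposition of the response rather than a static network model.

## Worked example

Generate a synthetic 30-trajectory ensemble whose mean rises on 30 ns and
falls back on 800 ns (amplitudes +0.3/−0.2 nm, 5% SEM noise, a quarter of
the runs 10× longer than the rest), then fit and summarize it:

```sh
cat > spec.json <<'EOF'
{"components": [[30.0, 0.3], [800.0, -0.2]], "offset": 1.0, "noise_sd": 0.27,
 "n_traj": 30, "long_traj_fraction": 0.25, "t_max": 10000.0, "frame_interval": 1.0}
EOF
contactdyn simulate response --spec spec.json --seed 1 --out sim
python -c "
import contactdyn as cd
from contactdyn import io as cio
series = cio.read_distance_h5('sim/distances.h5')
cio.write_response_csv(cd.ensemble_average(series), 'response.csv')
"
contactdyn fit --response response.csv --lambda 10 --out spectrum
contactdyn content --spectra spectrum.csv --out content
```

which prints

```
30 trajectories -> sim/distances.h5
chi=0.0298089  offset=1.003  -> spectrum.csv
peak: tau=31.7 ns  D=0.0008451
peak: tau=796.2 ns  D=0.0002711
```

The fit recovers both planted processes: a spectral peak at 31.7 ns
(planted 30 ns, positive amplitude — the rise) and one at 796 ns (planted
800 ns, negative amplitude — the decay), each well within the half-decade
resolution of a multiexponential inversion; the offset 1.003 matches the
planted long-time plateau of 1.0 nm.

For real data, start from coordinates instead:

```sh
contactdyn contacts --top system.pdb --traj run1.xtc --traj run2.xtc \
    --cutoff 0.45 --population 0.10
contactdyn cluster --distances contacts_distances.h5 --gamma 0.5 --stride 5
contactdyn pipeline --config run.toml        # the whole chain, resumable
```

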