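# coulombgas

Thermodynamics and ion-transport barriers of one-dimensional Coulomb gases
confined to narrow water-filled channels, computed two independent ways:

* **Exact spectra** — the grand-canonical partition function of a gas of
  cations (valency `n1`) and anions (valency `-n2`) maps onto a non-Hermitian
  Bloch Hamiltonian on the circle, with the fractional boundary charge `q`
  playing the role of quasi-momentum.  `coulombgas.spectral` diagonalises the
  Fourier-truncated operator (with convergence certification by cutoff
  doubling), assembles complex band structures, evaluates the partition
  function with bi-orthogonal weights, and locates the energy where the
  narrow-band branches coalesce.
* **Riemann-surface semiclassics** — at large dimensionless concentration
  `alpha` the same problem is classical with effective Planck constant
  `alpha**-0.5`.  Classical trajectories live on a genus-1 or genus-2
  spectral curve; `coulombgas.surface` computes the period integrals of the
  action 1-form over a homology cycle basis by contour quadrature (with
  hypergeometric closed forms as a validation surface for the genus-1
  cases), `coulombgas.semiclassics` quantizes them (Bohr–Sommerfeld along
  complex branch lines, Gamow bandwidths, the asymptotic bandwidth law with
  decay constant `b`), and `coulombgas.wkb2` adds the second-order WKB term
  and extracts the three-term pressure expansion
  `P = c0 kBT f - sqrt(c1 e E0 kBT f) - c2 e E0`.

Supported valency pairs for the full semiclassical machinery:
`(1,1)`, `(2,1)` (genus 1) and `(3,1)`, `(4,1)`, `(3,2)` (genus 2).
The spectral solver itself works for any coprime pair.

## Command line

A single entry point with subcommands; every output echoes its full
configuration.  Exit codes: 0 ok, 2 usage error, 3 numerical
non-convergence.

```sh
coulombgas spectrum      --n1 2 --n2 1 --alpha 200 --q-grid 0,0.5 --out bands.csv
coulombgas actions       --n1 2 --n2 1 --u-re -0.5 --out actions.json
coulombgas semiclassics  --n1 3 --n2 2 --alpha 400 --m-max 5 --out levels.csv
coulombgas bandwidth     --n1 1 --n2 1 --alpha-grid 25,100,400 --out widths.csv
coulombgas wkb2          --n1 2 --n2 1 --alpha 64 --m 2 --out levels2.csv
coulombgas pressure      --n1 1 --n2 1 --out pressure.json
coulombgas merge-point   --n1 3 --n2 2 --alpha 400
```

`pressure` accepts `--geometry geom.yaml` (keys `a`, `L`, `kappa1`,
`kappa2`, `T`; lengths in Angstrom, temperature in K) to also evaluate the
physical 1D pressure at a state point.

## Library example

```python
from coulombgas import ValencyPair, GasModel, ChannelGeometry
from coulombgas.spectral import merge_point
from coulombgas.semiclassics import asymptotic_coefficients, transport_barrier
from coulombgas.wkb2 import pressure_expansion

v = ValencyPair(3, 2)
merge_point(GasModel(v, 400.0), cutoff=192)   # 0.84
asymptotic_coefficients(v).b                  # 5.65 (bandwidth decay constant)
pressure_expansion(v).c2                      # 13/36 (geometry-only pressure term)
transport_barrier(v, 100.0, ChannelGeometry(a=5.0, L=40.0))  # barrier in kBT
```
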