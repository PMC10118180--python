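# corrloss

Loss functions for nonlinear curve fitting that tolerate — and correct —
multiplicative systematic errors, built on 2D correlation analysis.

The conventional residual sum of squares (RSS) forces modelled curves to
match measured ones point by point, so a uniform multiplicative error in
the data biases every fitted parameter. The losses here instead penalize
violations of the structural relations of 2D correlation maps (symmetry of
the synchronous map, antisymmetry / nullity of the asynchronous map, or
equality of phase-angle maps), all of which are invariant under scalar
rescaling of the data. A fit driven by one of them recovers the true
parameters even from data corrupted by an unknown constant factor.

## Loss families

| family | input | invariant exploited |
|---|---|---|
| `RSS` | curve or series | none (baseline) |
| `SES_SERIES` | series pair | ln(SRSS+ε) + ln(ARSS+ε) of hybrid maps |
| `ASYNC_2T2D` | curve pair | upper-triangle Σ Ψ² of two-trace maps |
| `ASYNC_2T2D_FAST` | curve pair | O(N) closed form, ≡ 2 × `ASYNC_2T2D` |
| `PHASE_2T2D` | curve pair | upper-triangle Σ Θ² of two-trace phase angles |
| `PHASE_SERIES` | series pair | Σ (Θ_measured − Θ_simulated)² |
| `NEG_NCC` | curve pair | −(normalized cross-correlation) |
| `NEG_ZNCC` | curve pair | −(zero-mean NCC; also offset-invariant) |

## Layout

- `corrloss.corr2d` — curve/series containers, Hilbert–Noda matrix,
  synchronous/asynchronous/two-trace correlation maps, phase-angle maps,
  CSV map export.
- `corrloss.losses` — the loss families above as pure functions plus a
  `LossSpec`-driven dispatcher.
- `corrloss.simulate` — synthetic Cauchy-type (Lorentzian) band series
  with amplitude nonlinearity `a`, perturbation-coupled peak shift `b`,
  and multiplicative/additive corruption.
- `corrloss.fitting` — bounded Nelder–Mead fitting harness (per-curve or
  joint over a series), misspecified-model fit, the asynchronous-map
  antisymmetry diagnostic for model rejection, and `reproduce_table1`,
  which runs the full loss-family comparison experiment.
- `corrloss.cli` — series CSV I/O and the `corrloss` command.

## CLI

```sh
# write the reference corrupted five-curve series
corrloss simulate --error-factor 1.1 --out series.csv

# conventional correlation maps of a series file
corrloss maps series.csv --kind all --out-prefix maps

# fit each curve with a chosen loss
corrloss fit series.csv --loss ncc --out fit.csv

# the whole comparison experiment: one row of fitted t per loss family
corrloss table1 --out table1.csv
```

Subcommands accept a TOML config (`--config conf.toml` with `[simulate]`,
`[loss]`, `[optimizer]` sections); explicit flags override config values.

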