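# coldphase

A deterministic, coupled phase–temperature model of burst firing in
mammalian cold receptors.

Spiking is reduced to a single membrane-potential phase `theta` obeying
an Adler-type equation `dtheta/dt = f1(t) + f2(t)*cos(theta)` with slow
periodic modulation `f1 = b - A*cos(phi)`, `f2 = 1 + A*cos(phi)`; one
full `2*pi` rotation is one action potential, and bursts occur while
`f1 > f2`. The parameters `(b, A, Omega)` depend on an *effective
temperature* through saturating tanh forms (with the classic linear
forms available for comparison). High→low temperature steps drive the
effective temperature along a Morse-like relaxation
`Teff = D*(1 - exp(-a*(t - tbar)))**2 + T0_eff`, generated by a
half-width ODE `dw/dt = a(w)*(sqrt(D) - w)` that is coupled into the
phase equation. The package provides:

- `coldphase.model` — parameter forms, modulation terms, phase velocity
- `coldphase.temperature` — transition specs, Morse curve, width ODE,
  exponential width function `a(w) = a0*exp(alpha*(w^2 + T0_eff))`
- `coldphase.simulate` — fixed-step RK4 integration (steady and coupled
  transient runs), TSV trajectory output
- `coldphase.analysis` — spike detection from the unwrapped phase,
  `f1 > f2` overlap windows, burst segmentation (SB/BP), ISI histograms
  and ISI clusters
- `coldphase.calibrate` — endpoint calibration of the tanh constants
  from the linear forms, bisection search for the Morse width `a`
  (matching the first burst to the temperature minimum), least-squares
  fit of the exponential width function
- `coldphase.configio` / `coldphase.scenarios` / `coldphase.cli` —
  plain-text configs (values like `3*pi/200` parse exactly), bundled
  scenario presets, command-line interface

## Command line

```sh
# steady-temperature runs with the default tanh set
coldphase steady --teff 15 20 25 30 35 40 --out-dir out/steady

# one transition with a constant Morse width
coldphase transition --ti 40 --tf 15 --a 0.002 --out-dir out/trans

# derive the tanh constants from the linear forms
coldphase calibrate-params --out tanh_params.cfg

# matching-condition search and width-function fit
coldphase calibrate-matching --ti 40 --tf 15
coldphase fit-width --tf 15 20 25 30 35

# bundled presets: steady_sweep | transitions_from_40 | step_series
coldphase scenario steady_sweep --out-dir out/sweep
```

All outputs are TSV plus a JSON run manifest; reruns are byte-identical.
Use `-v`/`-vv` before the subcommand for progress logging on stderr.

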