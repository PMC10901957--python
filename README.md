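# planarcrn

Qualitative analysis of planar mass-action systems whose vertices are
exponent pairs in the plane: structural invariants (deficiency, weak
reversibility), positive equilibria and scaling to `(1, 1)`, symbolic focal
values (Lyapunov quantities) at a fine focus, center certificates
(Bendixson–Dulac, time-reversal symmetry, Liénard composition), numerical
return maps with limit-cycle witnesses, and parameter searches for
degenerate Andronov–Hopf points that bifurcate multiple small limit cycles.

## Layout

| module | contents |
|---|---|
| `planarcrn.network_model` | `ExponentPoint`, `ReactionNetwork`, `MassActionSystem`, `PowerLawField`; JSON I/O, deficiency, structure report, translation, random networks |
| `planarcrn.fixtures` | constructors for all worked example families (4-cycle, chains, three-reaction systems, the single-parameter "zigzag" network) |
| `planarcrn.equilibria` | chain geometry (`h`-vector), exact binomial equilibria, damped-Newton quadrangle equilibria, `ScaledSystem`, Jacobian reports |
| `planarcrn.lyapunov` | exact Taylor expansion about `(1, 1)`, Poincaré–Lyapunov recursion for focal values `L1..L4`, numeric return-map oracle, Hopf classification |
| `planarcrn.qualitative` | monomial Dulac test for 4-cycles, reversibility checks, reversible- and Liénard-center certificates, center-realizing rate constants |
| `planarcrn.bifurcation_search` | closed-form Hopf loci, bisection / damped-Newton searches for zeros of `L1`, `L2`, `L3`, perturbation schedules for 1–3 small cycles |
| `planarcrn.dynamics` | positivity-preserving integration in log coordinates, Poincaré return maps, cycle counting with stability, homoclinic-bound probe |

Focal values are exact for rational data (the recursion's linear stages
reduce to cached integer matrices), and carry the conventional factor `pi`:
the first nonzero `L_k` is the leading coefficient of the return-map
displacement on the section `{y = 1, x > 1}`.

## CLI

`crn` works on JSON network files of the form

```json
{"species": ["X", "Y"],
 "vertices": [["0", "1"], ["1", "0"], ["1", "2"], ["0", "3"]],
 "edges": [{"from": 0, "to": 1, "kappa": "1"},
           {"from": 1, "to": 2, "kappa": "1"},
           {"from": 2, "to": 3, "kappa": "1"},
           {"from": 3, "to": 0, "kappa": "1"}]}
```

(rationals may be strings like `"-1/4"`). Commands:

```sh
crn analyze net.json          # weak reversibility, l, t, deficiency
crn equilibrium net.json      # equilibrium + Jacobian report
crn focal net.json --kmax 3   # focal values of the scaled system
crn dulac net.json            # monomial Bendixson-Dulac certificate
crn center net.json --kind lienard
crn search --family chain_4_1 --kill L2
crn simulate net.json --x0 1.2 --y0 0.8 --t 50   # CSV trajectory
crn cycles net.json           # limit-cycle witnesses
crn portrait net.json         # trajectory grid as CSV
```

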