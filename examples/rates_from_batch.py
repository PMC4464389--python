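"""Volumetric rates from a simulated shake-flask batch record.

The declared batch model (Monod growth on lactose with nitrogen
co-limitation and mixed growth-associated lovastatin production) is
integrated, sampled every 12 h with 2 % observation noise, smoothed with
cubic splines and differentiated; the estimated peak rates are compared
with the generator's exact ones.
"""

from pelletox import BatchScenario, generate_batch, peak_rates, smooth_and_differentiate

observed, truth = generate_batch(BatchScenario(seed=1))
rates = smooth_and_differentiate(observed, lam=300.0)

est = peak_rates(rates)
ref = peak_rates(truth)
print(f"{'analyte':>8} {'true peak':>10} {'estimated':>10} {'unit':>10} {'t_est (h)':>9}")
for name in ("X", "LAC", "LOV", "N"):
    if name in est:
        print(f"{name:>8} {ref[name]['value']:10.3f} {est[name]['value']:10.3f} "
              f"{est[name]['unit']:>10} {est[name]['time_h']:9.0f}")
final = {k: v[-1] for k, v in truth.smoothed.items()}
print(f"\nend of run (168 h): X = {final['X']:.1f} g/l, LOV = {final['LOV']:.0f} mg/l, "
      f"LAC = {final['LAC']:.2f} g/l")
# Peak uptake/formation rates are recovered within a few percent; the
# lactose peak (~0.3 g/l/h) arrives shortly before exhaustion, when
# biomass (and hence maintenance demand) is largest.
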