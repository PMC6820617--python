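"""Fit one Random Impact Test assay and read off its RIT50 half-life.

Builds a small bench-sheet-style record (20 pods counted every 8 s), fits the
exponential decay count(t) = A exp(-b t), and prints the fitted parameters and
the half-life with its error-propagation confidence interval.
"""

from ritfit import RITAssay, RITObservation, estimate_assay

counts = [20, 14, 9, 6, 4, 3, 2, 1, 1]  # intact pods after each 8-s interval
assay = RITAssay(
    genotype="Cabriolet",
    replicate_id="r1",
    observations=[RITObservation(8.0 * k, c) for k, c in enumerate(counts)],
)

fit, est = estimate_assay(assay)
print(f"A_hat  = {fit.A_hat:6.2f} pods   (intercept; should sit near 20)")
print(f"b_hat  = {fit.b_hat:6.4f} 1/s    (decay rate)")
print(f"RIT50  = {est.rit50_s:6.2f} s  +/- {est.se_s:.2f}  "
      f"[{est.ci_low_s:.2f}, {est.ci_high_s:.2f}] ({est.level:.0%} CI)")
print("RIT50 is the shaking time at which half the 20 starting pods have "
      "shattered; larger means more shatter-resistant.")
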