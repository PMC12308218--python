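"""Segment a synthetic limb phantom and compare against ground truth.

Builds a noisy limb cross-section phantom with 20% intramuscular fat,
runs the full soft-tissue pipeline (filter, downscale, limb contour, skin
peel, bone exclusion, seeded iterative classification) and prints the
muscle outcomes next to the phantom's exact composition.
"""

import myodens as md

spec = md.PhantomSpec(shape=(260, 260, 16), fat_fraction=0.20,
                      noise_sd=15.0, seed=7)
volume, truth = md.generate_phantom(spec)
labels, out = md.segment(volume)

print(f"ground truth : MV = {truth.muscle_volume_cm3:.4f} cm^3, "
      f"mean muscle density = {truth.mean_muscle_density:.2f} mgHA/cm^3")
print(f"segmentation : MV = {out.mv_cm3:.4f} cm^3, TV = {out.tv_cm3:.4f} cm^3, "
      f"MV/TV = {out.mvtv_pct:.1f} %, MusD = {out.musd:.2f} mgHA/cm^3")
print(f"MV error     : {100 * (out.mv_cm3 / truth.muscle_volume_cm3 - 1):+.2f} % "
      "(muscle volume recovered from a noisy, fat-infiltrated phantom)")

# precision: re-instantiate the same anatomy with fresh noise three times,
# as in a short-term repeat-scan precision study, and report the RMS-CV
import pandas as pd

repeats = []
for k in range(3):
    respec = md.PhantomSpec(shape=(260, 260, 16), fat_fraction=0.20,
                            noise_sd=15.0, seed=100 + k)
    vol_k, _ = md.generate_phantom(respec)
    _, out_k = md.segment(vol_k)
    repeats.append((out_k.musd, out_k.mvtv_pct))
rep = pd.DataFrame(repeats, columns=["musd", "mvtv"])
print(f"repeat 'scans': MusD RMS-CV = {md.rms_cv(rep[['musd']].T):.2f} %, "
      f"MV/TV RMS-CV = {md.rms_cv(rep[['mvtv']].T):.2f} % "
      "(short-term precision across three noisy re-instantiations)")
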