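"""Extract the ten volumetric-capnography features from one breath.

Builds a noise-free synthetic expiration with known phase geometry,
runs the phase-line fitting and feature extraction, and compares the
recovered values with the construction parameters.
"""

import numpy as np

from capnopred import CohortConfig, compute_features, generate_cohort

record = generate_cohort(CohortConfig(n=1, seed=4, noise_sigma=0.0))[0]
extracted = compute_features(record.trace)

print(f"subject {record.id}: FEV1 {record.fev1:.2f} L, FVC {record.fvc:.2f} L, "
      f"obstructed={record.obstructed}")
print()
print(f"{'feature':<12}{'generator':>12}{'extracted':>12}")
for name in ("C12", "C23", "V12", "V23", "V2", "V3",
             "S2", "S3", "S3_over_S2", "Angle23"):
    truth = getattr(record.features, name)
    est = getattr(extracted, name)
    print(f"{name:<12}{truth:>12.3f}{est:>12.3f}")
print()
print("With a noise-free trace the fitted phase II/III lines reproduce")
print("the generating geometry, so every feature matches to <1 %.")
print("C/V pairs are the phase-boundary CO2 (mmHg) / volume (mL); S2, S3")
print("are phase slopes in mmHg/L; Angle23 is the knee angle in degrees.")
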