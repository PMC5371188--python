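"""Estimate copy number from qPCR Ct values and score validation rates.

Three mock assays against a two-copy control locus: the test sample
amplifies one cycle earlier than the two-copy reference (a gain), one
cycle later (a loss), and identically (normal).  The 2^-ddCt model
turns each cycle difference into a two-fold template difference.
"""

from rdcnv import (QpcrAssay, classify_cn, relative_cn,
                   std_curve_efficiency, validation_rate)

assays = [
    QpcrAssay("region_dup", "bull3", ct_target=(19.0, 19.1, 18.9),
              ct_control=(20.0, 20.0, 20.0),
              reference_ct_target=(20.0, 20.0, 20.0),
              reference_ct_control=(20.0, 20.0, 20.0),
              predicted_class="gain"),
    QpcrAssay("region_del", "bull3", ct_target=(21.0, 21.0, 21.0),
              ct_control=(20.0, 20.0, 20.0),
              reference_ct_target=(20.0, 20.0, 20.0),
              reference_ct_control=(20.0, 20.0, 20.0),
              predicted_class="loss"),
    QpcrAssay("region_norm", "bull3", ct_target=(20.0, 20.0, 20.0),
              ct_control=(20.0, 20.0, 20.0),
              reference_ct_target=(20.0, 20.0, 20.0),
              reference_ct_control=(20.0, 20.0, 20.0),
              predicted_class="gain"),   # a prediction qPCR fails to confirm
]

for a in assays:
    copies = relative_cn(a)
    print(f"{a.region_id:12s} estimated {copies:4.2f} copies "
          f"-> {classify_cn(copies):6s} (pipeline predicted {a.predicted_class})")

per_sample, mean = validation_rate(assays)
print(f"\nvalidation rate for bull3: {per_sample['bull3']:.2f}% "
      f"(cohort mean {mean:.2f}%)")

slope, eff = std_curve_efficiency([0, -1, -2, -3],
                                  [20.00, 23.32, 26.64, 29.97])
print(f"\nstandard curve slope {slope:.3f} cycles/decade -> "
      f"amplification efficiency {eff:.2f}")
print("A slope of -3.32 means each 10-fold dilution costs 3.32 cycles,")
print("i.e. the reaction doubles perfectly every cycle (efficiency 1.0).")
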